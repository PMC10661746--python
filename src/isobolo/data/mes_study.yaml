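# Summary-mode study configuration over the bundled published estimates.
# Run with: isobolo run --config src/isobolo/data/mes_study.yaml --out results/tables
label: mes-isop-bor-interaction-study
mode: summary
alpha: 0.05
solo_potencies_csv: mes_solo_potencies.csv
mixture_summary_csv: mes_mixture_summary.csv
designs:
  - name: "CBZ + ISOP (25)"
    varied: CBZ
    adjuncts: [{drug: ISOP, dose_mg_kg: 25}]
  - name: "CBZ + ISOP (50)"
    varied: CBZ
    adjuncts: [{drug: ISOP, dose_mg_kg: 50}]
  - name: "PHT + ISOP (25)"
    varied: PHT
    adjuncts: [{drug: ISOP, dose_mg_kg: 25}]
  - name: "PHT + ISOP (50)"
    varied: PHT
    adjuncts: [{drug: ISOP, dose_mg_kg: 50}]
  - name: "PB + ISOP (25)"
    varied: PB
    adjuncts: [{drug: ISOP, dose_mg_kg: 25}]
  - name: "PB + ISOP (50)"
    varied: PB
    adjuncts: [{drug: ISOP, dose_mg_kg: 50}]
  - name: "VPA + ISOP (25)"
    varied: VPA
    adjuncts: [{drug: ISOP, dose_mg_kg: 25}]
  - name: "VPA + ISOP (50)"
    varied: VPA
    adjuncts: [{drug: ISOP, dose_mg_kg: 50}]
  - name: "CBZ + ISOP (25) + BOR (25)"
    varied: CBZ
    adjuncts: [{drug: ISOP, dose_mg_kg: 25}, {drug: BOR, dose_mg_kg: 25}]
    additivity_adjuncts: [{drug: ISOP, dose_mg_kg: 50}]
  - name: "PHT + ISOP (25) + BOR (25)"
    varied: PHT
    adjuncts: [{drug: ISOP, dose_mg_kg: 25}, {drug: BOR, dose_mg_kg: 25}]
    additivity_adjuncts: [{drug: ISOP, dose_mg_kg: 50}]
  - name: "PB + ISOP (25) + BOR (25)"
    varied: PB
    adjuncts: [{drug: ISOP, dose_mg_kg: 25}, {drug: BOR, dose_mg_kg: 25}]
    additivity_adjuncts: [{drug: ISOP, dose_mg_kg: 50}]
  - name: "VPA + ISOP (25) + BOR (25)"
    varied: VPA
    adjuncts: [{drug: ISOP, dose_mg_kg: 25}, {drug: BOR, dose_mg_kg: 25}]
    additivity_adjuncts: [{drug: ISOP, dose_mg_kg: 50}]
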