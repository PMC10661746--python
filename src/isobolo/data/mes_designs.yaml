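# Fixed-dose mixture designs of the mouse MES interaction study: four classic
# antiseizure drugs (varied) with isopimpinellin (ISOP) at 25/50 mg/kg and, in
# the three-drug arms, borneol (BOR) at 25 mg/kg.
#
# Three-drug arms carry an additivity_adjuncts override: the study's additive
# predictions pooled ISOP (25) + BOR (25) into one 50 mg/kg adjunct on ISOP's
# dose-response curve, while BOR keeps its own (implied, never directly
# reported) solo ED50 of 250 mg/kg for the per-drug fraction bookkeeping.
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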