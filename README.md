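# isobolo

Isobolographic analysis of quantal dose–response bioassays: log-probit ED50
estimation, Loewe-additive predictions for fixed-dose drug mixtures, and
statistical classification of drug–drug interactions as synergistic, additive
or antagonistic.

The package implements the quantitative pipeline of a mouse
maximal-electroshock (MES) seizure interaction study — four classic
antiseizure drugs (carbamazepine CBZ, phenytoin PHT, phenobarbital PB,
valproate VPA) combined with the furanocoumarin isopimpinellin (ISOP) and the
monoterpenoid borneol (BOR) at fixed doses — and ships the study's published
summary estimates so the full analysis reruns without any animal data. It is
aimed at pharmacologists running quantal (all-or-none endpoint) combination
assays and at anyone auditing published isobolographic tables.

## The model

**Potency.** Protection is Bernoulli per animal with probability following a
probit curve in log dose, Φ⁻¹(p) = a + b·log₁₀(d). The median effective dose
is ED50 = 10^(−a/b), fitted by maximum-likelihood probit regression; the SEM
and 95% confidence limits come from the delta method on the log₁₀ scale. The
animal count *n* reported with each estimate sums the groups whose observed
effect lay between the 4th and 6th probit (15.87–84.13% response).

**Additivity.** In a fixed-dose (ray) design the adjuncts are held at constant
doses D_i while the test drug's dose varies. Under Loewe dose equivalence the
theoretically additive ED50 of the mixture is

    ED50_add = ED50_varied · (1 − Σᵢ Dᵢ/ED50ᵢ) + Σᵢ Dᵢ   (total mixture dose),

the straight additivity line of the isobologram. The experimental mixture
ED50 (refit of the varied drug in the adjuncts' presence, plus the fixed
doses) is compared to this prediction with an unpaired t-test using Welch's
correction, t = |ED50_exp − ED50_add| / √(SEM²_exp + SEM²_add), with
Welch–Satterthwaite degrees of freedom rounded to the nearest integer.
p < α with ED50_exp below the additive value is synergy; above, antagonism.
The fraction index Σᵢ dᵢ/ED50ᵢ at the mixture ED50 (each fraction rounded to
2 decimals before summing, as in published tables) summarises the same
comparison: ≈1 additive, <1 synergistic, >1 antagonistic.

## Worked example

```python
from isobolo import (
    DoseResponseDataset, QuantalDoseGroup, fit_log_probit,
    MixtureComponent, MixtureDesign, additive_ed50,
    AdditivePrediction, ExperimentalMixturePotency, classify_interaction,
)
from isobolo.study_data import load_solo_potencies

# fit a quantal curve: 2/8 protected at 6 mg/kg, 6/8 at 16 mg/kg
est = fit_log_probit(DoseResponseDataset("drug", [
    QuantalDoseGroup(6, 2, 8), QuantalDoseGroup(16, 6, 8),
]))
print(round(est.ed50, 2), est.n_probit)      # 9.8 16

# valproate + isopimpinellin (50 mg/kg): published summary estimates
solo = load_solo_potencies()
design = MixtureDesign("VPA", solo["VPA"],
                       [MixtureComponent("ISOP", 50.0, solo["ISOP"])])
add = additive_ed50(design)
print(round(add.ed50_add_total, 2))          # 280.06

# compare the published experimental and additive estimates (value, SEM, n)
exp = ExperimentalMixturePotency(313.8, 263.8, 10.15, 32)
published_add = AdditivePrediction(280.0, 230.0, 8.19, 52)
res = classify_interaction(exp, published_add)
print(round(res.t_statistic, 3), res.df, res.classification)
# 2.592 67 antagonistic
```

The first fit says a drug protecting 2/8 mice at 6 mg/kg and 6/8 at 16 mg/kg
has ED50 9.8 mg/kg with all 16 animals inside the informative probit window.
The additive prediction for valproate with 50 mg/kg isopimpinellin is
280.06 mg/kg total mixture dose; the experimentally observed 313.8 mg/kg is
significantly higher (t₆₇ = 2.592, p ≈ 0.012), an antagonistic interaction.

The full published analysis (12 combinations, Welch tests, classifications,
fraction indices, isobologram coordinates) reruns with:

```sh
python analysis/01_reproduce_interaction_tables.py
python analysis/02_probit_calibration.py
python analysis/03_classification_operating_characteristics.py
```

or from the CLI with the bundled study configuration:

```sh
isobolo run --config src/isobolo/data/mes_study.yaml --out results/tables
```

with `isobolo fit`, `isobolo interact` and `isobolo simulate` for the
individual steps.

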