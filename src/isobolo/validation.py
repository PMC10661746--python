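"""Simulation studies validating the pipeline end-to-end on synthetic data.

The raw per-animal data behind published MES interaction tables are not
available, so the pipeline is validated on its own generator instead: probit
parameter recovery, type-I error and power of the interaction classification
at assay-realistic group sizes, Loewe-additivity-by-construction of the
mixture generator, and the family-wise calibration of the Dunnett-style
comparison.  Each study is a plain function with explicit seeds, returning a
small results record; the default conditions mirror the mouse MES assay
(8 animals per group, a carbamazepine-like varied drug with ED50 9.52 mg/kg
and an isopimpinellin-like adjunct with ED50 235.7 mg/kg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .interaction import classify_interaction, dunnett_null_max_z
from .isobole import MixtureComponent, MixtureDesign, additive_ed50, experimental_mixture_ed50
from .probit import (
    DoseResponseDataset,
    NonEstimableError,
    QuantalDoseGroup,
    fit_log_probit,
)
from .simulate import SimulationConfig, simulate_mixture, simulate_quantal

__all__ = [
    "RecoveryResult",
    "ClassificationStudy",
    "AdditivityCheck",
    "FwerResult",
    "STUDY_VARIED_ED50",
    "STUDY_VARIED_SLOPE",
    "STUDY_ADJUNCT_ED50",
    "recovery_study",
    "classification_study",
    "additivity_check",
    "dunnett_fwer_study",
]

# Assay-like study conditions: carbamazepine- and isopimpinellin-like curves.
STUDY_VARIED_ED50 = 9.52
STUDY_VARIED_SLOPE = 6.0
STUDY_ADJUNCT_ED50 = 235.7
STUDY_VARIED_DOSES = tuple(np.geomspace(6.0, 16.0, 6))
STUDY_ADJUNCT_DOSES = tuple(np.geomspace(140.0, 380.0, 6))


@dataclass(frozen=True)
class RecoveryResult:
    """Parameter-recovery summary over repeated simulated experiments."""

    ed50_true: float
    mean_ed50: float
    relative_bias: float
    empirical_se: float
    mean_delta_sem: float
    n_replicates: int
    n_failed: int


def recovery_study(
    ed50_true: float = 250.0,
    slope_true: float = 3.0,
    doses: tuple[float, ...] = tuple(np.geomspace(100.0, 600.0, 5)),
    n_per_group: int = 100,
    n_replicates: int = 500,
    seed: int = 0,
) -> RecoveryResult:
    """Fit repeated simulated single-drug experiments and summarise ED50 recovery.

    The default conditions (ED50 250 mg/kg, slope 3, five log-spaced doses over
    100-600 mg/kg, 100 animals per group) are a calibration-scale design where
    the ML fit should be essentially unbiased and the delta-method SEM should
    track the empirical spread of the fitted ED50s.
    """
    fits, sems = [], []
    failed = 0
    for r in range(n_replicates):
        cfg = SimulationConfig(
            ed50_true, slope_true, doses, n_per_group=n_per_group, seed=seed + r
        )
        try:
            est = fit_log_probit(simulate_quantal(cfg))
        except NonEstimableError:
            failed += 1
            continue
        if not est.converged:
            failed += 1
            continue
        fits.append(est.ed50)
        sems.append(est.sem)
    fits_arr = np.asarray(fits)
    return RecoveryResult(
        ed50_true=ed50_true,
        mean_ed50=float(fits_arr.mean()),
        relative_bias=float(fits_arr.mean() / ed50_true - 1.0),
        empirical_se=float(fits_arr.std(ddof=1)),
        mean_delta_sem=float(np.mean(sems)),
        n_replicates=n_replicates,
        n_failed=failed,
    )


@dataclass(frozen=True)
class ClassificationStudy:
    """Outcome counts of repeated simulate -> fit -> isobole -> classify runs."""

    counts: dict[str, int]
    n_evaluable: int
    n_failed: int
    interaction_factor: float

    def proportion(self, label: str) -> float:
        return self.counts.get(label, 0) / self.n_evaluable


def classification_study(
    interaction_factor: float = 1.0,
    adjunct_dose: float = 25.0,
    mixture_doses: Optional[tuple[float, ...]] = None,
    n_per_group: int = 8,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClassificationStudy:
    """Run the full pipeline on simulated fixed-dose mixtures and tally classifications.

    Per replicate, the varied drug's solo curve, the adjunct's solo curve and
    the mixture curve are each simulated and refit; the additive prediction
    comes from the fitted solo potencies, the experimental estimate from the
    fitted mixture curve, and the Welch comparison classifies the interaction.
    With ``interaction_factor = 1`` the generator is exactly additive, so
    non-additive calls measure the procedure's type-I error; with a factor > 1
    the synergistic fraction measures power.  Replicates where any curve is
    non-estimable (all-or-none response or separation at small n) are excluded
    and counted in ``n_failed``.
    """
    f = adjunct_dose / STUDY_ADJUNCT_ED50
    if mixture_doses is None:
        # straddle the mixture's true varied-component ED50 under the factor:
        # IF * (d + ED50_v * f) = ED50_v  at 50% protection
        centre = STUDY_VARIED_ED50 * (1.0 / interaction_factor - f)
        if centre <= 0:
            raise ValueError(
                "interaction factor and adjunct fraction leave no positive varied dose"
            )
        mixture_doses = tuple(np.geomspace(centre / 1.7, centre * 1.7, 6))
    counts: dict[str, int] = {}
    failed = 0
    for r in range(n_replicates):
        base = seed + 3 * r
        try:
            solo_v = fit_log_probit(
                simulate_quantal(
                    SimulationConfig(
                        STUDY_VARIED_ED50, STUDY_VARIED_SLOPE, STUDY_VARIED_DOSES,
                        n_per_group=n_per_group, seed=base, drug_id="varied",
                    )
                )
            )
            solo_a = fit_log_probit(
                simulate_quantal(
                    SimulationConfig(
                        STUDY_ADJUNCT_ED50, STUDY_VARIED_SLOPE, STUDY_ADJUNCT_DOSES,
                        n_per_group=n_per_group, seed=base + 1, drug_id="adjunct",
                    )
                )
            )
            mix = fit_log_probit(
                simulate_mixture(
                    SimulationConfig(
                        STUDY_VARIED_ED50, STUDY_VARIED_SLOPE, mixture_doses,
                        n_per_group=n_per_group, seed=base + 2,
                        interaction_factor=interaction_factor,
                        adjuncts=((adjunct_dose, STUDY_ADJUNCT_ED50),),
                        drug_id="mixture",
                    )
                )
            )
        except NonEstimableError:
            failed += 1
            continue
        if not (solo_v.converged and solo_a.converged and mix.converged):
            failed += 1
            continue
        if mix.n_probit < 2 or solo_v.n_probit + solo_a.n_probit < 2:
            failed += 1
            continue
        design = MixtureDesign(
            "varied", solo_v, (MixtureComponent("adjunct", adjunct_dose, solo_a),)
        )
        try:
            add = additive_ed50(design)
        except ValueError:
            failed += 1
            continue
        exp = experimental_mixture_ed50(mix, [adjunct_dose])
        label = classify_interaction(exp, add, alpha=alpha).classification
        counts[label] = counts.get(label, 0) + 1
    return ClassificationStudy(
        counts=counts,
        n_evaluable=n_replicates - failed,
        n_failed=failed,
        interaction_factor=interaction_factor,
    )


@dataclass(frozen=True)
class AdditivityCheck:
    """Paired comparison of experimental vs additive totals under exact additivity."""

    mean_difference: float
    mc_se: float
    n_replicates: int


def additivity_check(
    adjunct_dose: float = 25.0,
    n_per_group: int = 100,
    n_replicates: int = 1000,
    seed: int = 0,
) -> AdditivityCheck:
    """Check that the additive generator yields an unbiased experimental ED50.

    The mixture responses are probit-linear in the log10 *Loewe-equivalent
    total* dose, so the mixture curve is refit on that scale and the adjunct
    equivalents subtracted afterwards; the paired solo experiment uses doses
    equal to the mixture's equivalent totals.  Under ``interaction_factor = 1``
    the paired difference of experimental and additive totals is then exactly
    mean-zero, and its Monte-Carlo mean should sit within sampling error of 0.
    """
    f = adjunct_dose / STUDY_ADJUNCT_ED50
    equiv = STUDY_VARIED_ED50 * f  # adjunct Loewe-equivalent dose, mg/kg
    mixture_doses = tuple(d * (1.0 - f) for d in STUDY_VARIED_DOSES)
    solo_doses = tuple(d + equiv for d in mixture_doses)
    diffs = []
    for r in range(n_replicates):
        solo = fit_log_probit(
            simulate_quantal(
                SimulationConfig(
                    STUDY_VARIED_ED50, STUDY_VARIED_SLOPE, solo_doses,
                    n_per_group=n_per_group, seed=seed + 2 * r, drug_id="solo",
                )
            )
        )
        mix_ds = simulate_mixture(
            SimulationConfig(
                STUDY_VARIED_ED50, STUDY_VARIED_SLOPE, mixture_doses,
                n_per_group=n_per_group, seed=seed + 2 * r + 1,
                adjuncts=((adjunct_dose, STUDY_ADJUNCT_ED50),), drug_id="mixture",
            )
        )
        equiv_ds = DoseResponseDataset(
            "mixture-equivalent",
            [QuantalDoseGroup(g.dose + equiv, g.n_protected, g.n_total) for g in mix_ds.groups],
        )
        mix = fit_log_probit(equiv_ds)
        exp_total = mix.ed50 * (1.0 - f) + adjunct_dose
        add_total = solo.ed50 * (1.0 - f) + adjunct_dose
        diffs.append(exp_total - add_total)
    arr = np.asarray(diffs)
    return AdditivityCheck(
        mean_difference=float(arr.mean()),
        mc_se=float(arr.std(ddof=1) / math.sqrt(len(arr))),
        n_replicates=len(arr),
    )


@dataclass(frozen=True)
class FwerResult:
    """Family-wise error rate of the Dunnett-style comparison under the joint null."""

    fwer: float
    alpha: float
    n_replicates: int
    k: int


def dunnett_fwer_study(
    k: int = 3,
    alpha: float = 0.05,
    n_replicates: int = 10_000,
    n_null_draws: int = 200_000,
    seed: int = 0,
) -> FwerResult:
    """Estimate the family-wise rejection rate when all true ED50s are equal.

    A critical value for the maximum |z| is taken from the Monte-Carlo null
    used by ``dunnett_compare`` (equal SEMs, shared control), then fresh null
    replicates are scored against it.  The rate should sit at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    sems = np.ones(k)
    crit = float(np.quantile(dunnett_null_max_z(1.0, sems, rng, n_null_draws), 1.0 - alpha))
    control = rng.standard_normal(n_replicates)
    treat = rng.standard_normal((n_replicates, k))
    z = np.abs(control[:, None] - treat) / np.sqrt(2.0)
    fwer = float((z.max(axis=1) > crit).mean())
    return FwerResult(fwer=fwer, alpha=alpha, n_replicates=n_replicates, k=k)
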