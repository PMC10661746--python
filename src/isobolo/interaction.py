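"""Statistical comparison of experimental vs additive mixture ED50s.

Mixture potency tables compare the experimentally determined ED50 (± SEM,
with an animal count n) against the theoretically additive one using an
unpaired t-test with Welch's correction: the statistic pools the two SEMs and
the degrees of freedom follow the Welch-Satterthwaite approximation, rounded
to the nearest integer as in published tables.  A significant difference with
the experimental total below the additive total is synergy (supra-additivity);
above, antagonism (sub-additivity); otherwise the interaction is additive.

A Dunnett-style family-wise comparison of several ED50s against a shared
control is provided for the single-drug-addition claims.  Because ED50s are
summary estimates without per-animal replicates, it is implemented as a
normal z comparison on (value, SEM) pairs with a Monte-Carlo family-wise
adjustment that honours the correlation induced by the shared control term —
an approximation of the classical ANOVA + Dunnett procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .isobole import AdditivePrediction, ExperimentalMixturePotency, round_half_away
from .probit import PotencyEstimate

__all__ = [
    "WelchResult",
    "InteractionResult",
    "DunnettResult",
    "welch_t",
    "classify_interaction",
    "dunnett_compare",
]

CLASSIFICATIONS = ("synergistic", "additive", "antagonistic")


@dataclass(frozen=True)
class WelchResult:
    """Welch's t statistic (absolute), integer Satterthwaite df, two-sided p."""

    t: float
    df: int
    p: float


@dataclass(frozen=True)
class InteractionResult:
    """Classified comparison of experimental vs additive mixture ED50s."""

    t_statistic: float
    df: int
    p_value: float
    classification: str
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")


@dataclass(frozen=True)
class DunnettResult:
    """Per-treatment family-wise-adjusted comparison against a shared control."""

    statistics: tuple[float, ...]
    p_adjusted: tuple[float, ...]
    significant: tuple[bool, ...]
    n_draws: int
    seed: int


def welch_t(
    value1: float,
    sem1: float,
    n1: int,
    value2: float,
    sem2: float,
    n2: int,
) -> WelchResult:
    """Unpaired t-test with Welch's correction on two summary estimates.

    ``t = |v1 - v2| / sqrt(sem1^2 + sem2^2)``; the Welch-Satterthwaite degrees
    of freedom ``(sem1^2+sem2^2)^2 / (sem1^4/(n1-1) + sem2^4/(n2-1))`` are
    rounded to the nearest integer, and p is the two-sided tail of Student's t
    at that df.
    """
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need n >= 2 in both groups, got {n1}, {n2}")
    pooled_var = sem1**2 + sem2**2
    if pooled_var == 0:
        raise ValueError(
            "both SEMs are zero; the t statistic is undefined"
            + (" (infinite for unequal values)" if value1 != value2 else "")
        )
    t = abs(value1 - value2) / math.sqrt(pooled_var)
    df_raw = pooled_var**2 / (sem1**4 / (n1 - 1) + sem2**4 / (n2 - 1))
    df = int(round_half_away(df_raw, 0))
    p = float(2.0 * stats.t.sf(t, df))
    return WelchResult(t=t, df=df, p=p)


def classify_interaction(
    exp: ExperimentalMixturePotency,
    add: AdditivePrediction,
    alpha: float = 0.05,
) -> InteractionResult:
    """Welch-test the experimental against the additive mixture ED50 and classify.

    ``p < alpha`` with the experimental total below the additive total is
    synergistic; above, antagonistic; otherwise (including p exactly at alpha)
    additive.
    """
    res = welch_t(
        exp.ed50_exp_total, exp.sem_exp, exp.n_exp,
        add.ed50_add_total, add.sem_add, add.n_add,
    )
    if res.p < alpha:
        label = "synergistic" if exp.ed50_exp_total < add.ed50_add_total else "antagonistic"
        if exp.ed50_exp_total == add.ed50_add_total:  # unreachable with p < alpha, kept for safety
            label = "additive"
    else:
        label = "additive"
    return InteractionResult(
        t_statistic=res.t, df=res.df, p_value=res.p, classification=label, alpha=alpha
    )


def dunnett_null_max_z(
    sem_control: float,
    sems: Sequence[float],
    rng: np.random.Generator,
    n_draws: int,
) -> np.ndarray:
    """Null-distribution sample of the maximum |z| over comparisons sharing a control.

    Draws control and treatment estimates as independent zero-mean normals with
    the given SEMs and returns, per draw, the maximum standardised absolute
    difference.  The shared control term makes the comparisons equicorrelated.
    """
    sems = np.asarray(sems, dtype=float)
    c = rng.standard_normal(n_draws) * sem_control
    t = rng.standard_normal((n_draws, sems.size)) * sems
    z = np.abs(c[:, None] - t) / np.sqrt(sem_control**2 + sems**2)
    return z.max(axis=1)


def dunnett_compare(
    control: PotencyEstimate,
    treatments: Sequence[PotencyEstimate],
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """Compare treatment ED50s against a control with a family-wise adjustment.

    Each statistic is ``z_i = |ED50_c - ED50_i| / sqrt(sem_c^2 + sem_i^2)``.
    The adjusted p-value is the probability, under a Monte-Carlo sample of the
    joint null (all true ED50s equal, comparisons correlated through the
    shared control), that the maximum |z| across the family exceeds the
    observed ``z_i``.
    """
    if not treatments:
        raise ValueError("need at least one treatment to compare against the control")
    if control.sem <= 0 or any(t.sem <= 0 for t in treatments):
        raise ValueError("all SEMs must be positive for the z comparison")
    sems = np.array([t.sem for t in treatments])
    z_obs = np.abs(control.ed50 - np.array([t.ed50 for t in treatments])) / np.sqrt(
        control.sem**2 + sems**2
    )
    rng = np.random.default_rng(seed)
    max_z = dunnett_null_max_z(control.sem, sems, rng, n_draws)
    p_adj = (max_z[:, None] >= z_obs[None, :]).mean(axis=0)
    return DunnettResult(
        statistics=tuple(float(z) for z in z_obs),
        p_adjusted=tuple(float(p) for p in p_adj),
        significant=tuple(bool(p < alpha) for p in p_adj),
        n_draws=n_draws,
        seed=seed,
    )
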