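"""Log-probit estimation of median effective doses from quantal bioassay data.

The quantal maximal-electroshock (MES) endpoint is binary per animal: protected
from the tonic-clonic seizure or not.  Groups of animals receive graded doses,
and the dose expected to protect half the animals (the ED50) is estimated by
probit regression of the protected fraction on log10(dose) — the modern
maximum-likelihood equivalent of the classical graphical log-probit procedure.

The fitted model is

    Phi^-1(p(d)) = a + b * log10(d)

so the ED50 is ``10**(-a/b)`` and ``b`` is the slope in probits per log10 dose
unit.  Dispersion (SEM and 95% confidence limits of the ED50) comes from the
delta method on the log10 scale.  The classical probit scale adds an offset of
5 so that 50% response sits at the "5th probit"; the 4th-6th probit window
(15.87%-84.13% response) is the informative region whose animal counts the
potency tables report as ``n``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PROBIT_OFFSET",
    "QuantalDoseGroup",
    "DoseResponseDataset",
    "PotencyEstimate",
    "NonEstimableError",
    "probit_transform",
    "fit_log_probit",
    "count_probit_window_n",
    "sem_from_cl",
]

#: Classical probit offset: probit(p) = Phi^-1(p) + 5, so p = 0.5 maps to 5.
PROBIT_OFFSET = 5.0

#: Observed-fraction window corresponding to the 4th-6th probit (Phi(-1), Phi(1)).
PROBIT_WINDOW = (stats.norm.cdf(-1.0), stats.norm.cdf(1.0))

_WINDOW_TOL = 1e-9
_Z95 = 1.96  # conventional two-sided 95% normal quantile used by the CL<->SEM rule


class NonEstimableError(ValueError):
    """The dataset carries no information about the ED50 (e.g. all-or-none response)."""


@dataclass(frozen=True)
class QuantalDoseGroup:
    """One dose group: ``n_protected`` of ``n_total`` animals protected at ``dose`` mg/kg."""

    dose: float
    n_protected: int
    n_total: int

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        if self.n_total <= 0:
            raise ValueError(f"n_total must be a positive integer, got {self.n_total}")
        if not 0 <= self.n_protected <= self.n_total:
            raise ValueError(
                f"n_protected must lie in [0, n_total], got {self.n_protected}/{self.n_total}"
            )

    @property
    def fraction(self) -> float:
        """Observed protected fraction."""
        return self.n_protected / self.n_total


@dataclass(frozen=True)
class DoseResponseDataset:
    """A labelled collection of quantal dose groups for one drug or mixture arm.

    ``pretreatment_min`` is administration-to-test latency metadata (minutes);
    it plays no role in fitting.
    """

    drug_id: str
    groups: tuple[QuantalDoseGroup, ...]
    pretreatment_min: Optional[float] = None

    def __init__(
        self,
        drug_id: str,
        groups: Iterable[QuantalDoseGroup],
        pretreatment_min: Optional[float] = None,
    ) -> None:
        object.__setattr__(self, "drug_id", drug_id)
        object.__setattr__(self, "groups", tuple(groups))
        object.__setattr__(self, "pretreatment_min", pretreatment_min)
        if not self.groups:
            raise ValueError("dataset needs at least one dose group")

    def aggregated(self) -> "DoseResponseDataset":
        """Pool groups at identical doses by summing counts (duplicates are never an error)."""
        pooled: dict[float, list[int]] = {}
        for g in self.groups:
            protected, total = pooled.setdefault(g.dose, [0, 0])
            pooled[g.dose][0] = protected + g.n_protected
            pooled[g.dose][1] = total + g.n_total
        groups = tuple(
            QuantalDoseGroup(dose, p, n) for dose, (p, n) in sorted(pooled.items())
        )
        return DoseResponseDataset(self.drug_id, groups, self.pretreatment_min)

    def to_frame(self):
        """Long-format table with the canonical raw-CSV columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "drug": self.drug_id,
                "dose_mg_kg": [g.dose for g in self.groups],
                "n_protected": [g.n_protected for g in self.groups],
                "n_total": [g.n_total for g in self.groups],
            }
        )


@dataclass(frozen=True)
class PotencyEstimate:
    """An ED50 with its dispersion and the animal-count bookkeeping of potency tables.

    ``n_probit`` is the number of animals tested at doses whose observed effect
    fell between the 4th and 6th probit; ``slope`` is in probits per log10(dose).
    A non-converged estimate (complete separation) carries ``slope = inf`` and
    NaN dispersion.
    """

    ed50: float
    sem: float
    cl95_lower: float
    cl95_upper: float
    slope: float
    n_probit: int
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.ed50 > 0:
            raise ValueError(f"ed50 must be positive, got {self.ed50}")
        if not (math.isnan(self.sem) or self.sem >= 0):
            raise ValueError(f"sem must be non-negative, got {self.sem}")
        if self.n_probit < 0:
            raise ValueError("n_probit must be non-negative")
        if (
            not math.isnan(self.cl95_lower)
            and not math.isnan(self.cl95_upper)
            and not (self.cl95_lower <= self.ed50 <= self.cl95_upper)
        ):
            raise ValueError("confidence limits must bracket the ED50")


def probit_transform(p: float) -> float:
    """Map a response proportion to the classical probit scale, ``Phi^-1(p) + 5``.

    Parameters
    ----------
    p
        Proportion strictly inside (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"proportion must lie strictly in (0, 1), got {p}")
    return float(stats.norm.ppf(p)) + PROBIT_OFFSET


def count_probit_window_n(data: DoseResponseDataset) -> int:
    """Animals tested at doses whose observed protected fraction lies in the 4th-6th probit window.

    The window is inclusive at Phi(-1) and Phi(1) (15.87%-84.13%), matching the
    ``n`` footnote convention of quantal potency tables.  Equal doses are pooled
    before their fraction is assessed.
    """
    lo, hi = PROBIT_WINDOW
    total = 0
    for g in data.aggregated().groups:
        if lo - _WINDOW_TOL <= g.fraction <= hi + _WINDOW_TOL:
            total += g.n_total
    return total


def sem_from_cl(cl95_lower: float, cl95_upper: float) -> float:
    """Back-transform 95% confidence limits to a SEM: ``(upper - lower) / (2 * 1.96)``.

    This is the conventional rule for recovering a standard error from published
    confidence limits when only the interval is reported.
    """
    if cl95_lower < 0 or cl95_upper < cl95_lower:
        raise ValueError(
            f"need 0 <= cl95_lower <= cl95_upper, got ({cl95_lower}, {cl95_upper})"
        )
    return (cl95_upper - cl95_lower) / (2.0 * _Z95)


def _separation_split(groups: Sequence[QuantalDoseGroup]) -> Optional[float]:
    """Detect complete separation: a dose threshold perfectly splits 0% from 100% groups.

    Returns the geometric midpoint of the separating gap (the profile-likelihood
    ridge of log10 ED50) or None if the data are not completely separated.
    """
    if any(0.0 < g.fraction < 1.0 for g in groups):
        return None
    zeros = [g.dose for g in groups if g.fraction == 0.0]
    ones = [g.dose for g in groups if g.fraction == 1.0]
    if not zeros or not ones:
        return None  # all-or-none handled upstream
    if max(zeros) < min(ones):
        return math.sqrt(max(zeros) * min(ones))
    return None


def fit_log_probit(data: DoseResponseDataset) -> PotencyEstimate:
    """Maximum-likelihood probit regression of protection on log10(dose).

    Equal doses are pooled first.  Fully unprotected and fully protected groups
    are retained in the likelihood (they are informative about the tails); no
    empirical-probit corrections are applied.  Fitting uses iteratively
    reweighted least squares to a log-likelihood tolerance of 1e-10 (at most
    100 iterations).

    Returns
    -------
    PotencyEstimate
        ED50 (mg/kg), delta-method SEM and 95% CL on the dose scale, slope in
        probits per log10(dose), and the 4th-6th-probit animal count.

    Raises
    ------
    NonEstimableError
        If fewer than two distinct doses are present, or every group responded
        0% or every group responded 100%.

    Notes
    -----
    Completely separated data (all 0% below a threshold dose, all 100% above)
    admit no finite ML slope; the returned estimate is flagged
    ``converged=False`` with ``slope = inf``, its ED50 placed at the geometric
    midpoint of the separating dose gap, and NaN dispersion.
    """
    pooled = data.aggregated()
    groups = pooled.groups
    if len(groups) < 2:
        raise NonEstimableError(
            f"{data.drug_id}: need at least 2 distinct doses, got {len(groups)}"
        )
    fractions = [g.fraction for g in groups]
    n_probit = count_probit_window_n(pooled)
    if all(f == 0.0 for f in fractions) or all(f == 1.0 for f in fractions):
        raise NonEstimableError(
            f"{data.drug_id}: all groups responded "
            f"{'0%' if fractions[0] == 0.0 else '100%'}; ED50 is not estimable"
        )
    sep = _separation_split(groups)
    if sep is not None:
        return PotencyEstimate(
            ed50=sep,
            sem=math.nan,
            cl95_lower=math.nan,
            cl95_upper=math.nan,
            slope=math.inf,
            n_probit=n_probit,
            converged=False,
        )

    x = np.log10([g.dose for g in groups])
    endog = np.column_stack(
        [[g.n_protected for g in groups], [g.n_total - g.n_protected for g in groups]]
    )
    exog = sm.add_constant(x)
    model = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit()))
    # separation is diagnosed structurally above; statsmodels' own heuristics
    # also fire on saturated (just-identified) fits, where they are spurious
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

            warnings.simplefilter("ignore", category=PerfectSeparationWarning)
        except ImportError:
            pass
        res = model.fit(maxiter=100, tol=1e-10)

    a, b = res.params
    cov = res.cov_params()
    converged = bool(res.converged) and np.isfinite(b) and b != 0
    if not converged or abs(b) < 1e-12:
        # quasi-separation drifting to an unbounded slope without a clean split
        return PotencyEstimate(
            ed50=float(10 ** (-a / b)) if b != 0 else float(np.median([g.dose for g in groups])),
            sem=math.nan,
            cl95_lower=math.nan,
            cl95_upper=math.nan,
            slope=math.inf,
            n_probit=n_probit,
            converged=False,
        )

    log10_ed50 = -a / b
    grad = np.array([-1.0 / b, -log10_ed50 / b])
    var_log10 = float(grad @ cov @ grad)
    se_log10 = math.sqrt(max(var_log10, 0.0))
    if not (abs(log10_ed50) < 300 and math.isfinite(se_log10)):
        # numerically degenerate fit (quasi-separation drift): no usable estimate
        return PotencyEstimate(
            ed50=float(np.median([g.dose for g in groups])),
            sem=math.nan,
            cl95_lower=math.nan,
            cl95_upper=math.nan,
            slope=math.inf if b > 0 else -math.inf,
            n_probit=n_probit,
            converged=False,
        )
    ed50 = float(10.0**log10_ed50)
    sem = ed50 * math.log(10.0) * se_log10
    half_width = _Z95 * se_log10
    cl_lo = ed50 * 10.0**-half_width
    cl_hi = ed50 * 10.0**half_width if half_width < 300 else math.inf
    return PotencyEstimate(
        ed50=ed50,
        sem=sem,
        cl95_lower=cl_lo,
        cl95_upper=cl_hi,
        slope=float(b),
        n_probit=n_probit,
        converged=True,
    )
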