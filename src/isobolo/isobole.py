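"""Isobolographic transformation of fixed-dose drug mixtures.

In a fixed-dose (ray) design one drug's dose is varied while co-administered
adjuncts are held at constant doses.  Under Loewe additivity (dose
equivalence), a mixture sits on the additivity isobole when the component
fractions sum to one:

    sum_i  d_i / ED50_i  =  1     at the mixture's ED50.

With adjuncts fixed at doses D_i, the varied drug's theoretically additive
ED50 component is

    ED50_add,varied = ED50_varied * (1 - sum_i D_i / ED50_i)

and the additive total is that component plus the fixed doses.  The
experimentally determined mixture ED50 (varied-drug refit in the presence of
the adjuncts, plus the fixed doses) is compared against this prediction; the
per-drug fractions at the experimental mixture ED50 and their sum (the
fraction index) summarise the interaction: ~1 additive, <1 synergistic,
>1 antagonistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .probit import PotencyEstimate

__all__ = [
    "AdditivityError",
    "MixtureComponent",
    "MixtureDesign",
    "AdditivePrediction",
    "ExperimentalMixturePotency",
    "FractionBreakdown",
    "IsobologramCoordinates",
    "round_half_away",
    "additive_ed50",
    "experimental_mixture_ed50",
    "fraction_breakdown",
    "percent_change",
    "isobologram_coordinates",
]


class AdditivityError(ValueError):
    """The fixed adjunct doses alone reach or exceed the additive ED50."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed potency tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MixtureComponent:
    """One fixed-dose adjunct: drug label, constant dose (mg/kg), solo potency."""

    drug: str
    dose: float
    potency: PotencyEstimate

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"{self.drug}: fixed dose must be non-negative, got {self.dose}")

    @property
    def fraction(self) -> float:
        """Loewe fraction contributed by the fixed dose, ``dose / solo ED50``."""
        return self.dose / self.potency.ed50


@dataclass(frozen=True)
class MixtureDesign:
    """A fixed-dose mixture: one varied drug plus constant-dose adjuncts.

    ``additivity_adjuncts``, when given, replaces ``adjuncts`` in the additive
    prediction only — the convention needed when a study pools two adjuncts
    onto a single reference dose-response curve for the theoretical
    calculation while keeping separate per-drug fractions in its bookkeeping.
    Fraction and isobologram bookkeeping always use ``adjuncts``.
    """

    varied_drug: str
    varied_potency: PotencyEstimate
    adjuncts: tuple[MixtureComponent, ...]
    additivity_adjuncts: Optional[tuple[MixtureComponent, ...]] = None
    name: Optional[str] = None

    def __init__(
        self,
        varied_drug: str,
        varied_potency: PotencyEstimate,
        adjuncts: Sequence[MixtureComponent],
        additivity_adjuncts: Optional[Sequence[MixtureComponent]] = None,
        name: Optional[str] = None,
    ) -> None:
        object.__setattr__(self, "varied_drug", varied_drug)
        object.__setattr__(self, "varied_potency", varied_potency)
        object.__setattr__(self, "adjuncts", tuple(adjuncts))
        object.__setattr__(
            self,
            "additivity_adjuncts",
            None if additivity_adjuncts is None else tuple(additivity_adjuncts),
        )
        object.__setattr__(self, "name", name)
        for comps in (self.adjuncts, self.additivity_adjuncts or ()):
            f = sum(c.fraction for c in comps)
            if f >= 1.0:
                raise AdditivityError(
                    f"{self.label}: adjunct fraction sum {f:.3f} >= 1; the fixed doses "
                    "alone reach the additive ED50"
                )

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        parts = [self.varied_drug] + [f"{c.drug} ({c.dose:g})" for c in self.adjuncts]
        return " + ".join(parts)

    @property
    def effective_adjuncts(self) -> tuple[MixtureComponent, ...]:
        """Adjunct set used by the additive prediction."""
        return self.additivity_adjuncts if self.additivity_adjuncts is not None else self.adjuncts

    @property
    def total_fixed_dose(self) -> float:
        return sum(c.dose for c in self.adjuncts)


@dataclass(frozen=True)
class AdditivePrediction:
    """Theoretical Loewe-additive mixture ED50 (total and varied component) with dispersion."""

    ed50_add_total: float
    ed50_add_varied: float
    sem_add: float
    n_add: int


@dataclass(frozen=True)
class ExperimentalMixturePotency:
    """Experimentally determined mixture ED50: varied-drug refit plus the fixed doses."""

    ed50_exp_total: float
    ed50_exp_varied: float
    sem_exp: float
    n_exp: int


@dataclass(frozen=True)
class FractionBreakdown:
    """Per-drug ED50 fractions at the mixture ED50 and their sum (the fraction index).

    ``fractions`` holds the 2-decimal table-rounded values whose sum is
    ``fraction_index``; ``fractions_exact`` keeps the unrounded values for
    algebraic checks (they sum to exactly 1 on the additivity line).
    """

    fractions: dict[str, float]
    fraction_index: float
    fractions_exact: dict[str, float]


@dataclass(frozen=True)
class IsobologramCoordinates:
    """Plot-ready coordinates for a two-drug (or pooled-adjunct) isobologram.

    The additivity line joins (0, ED50_varied) and (ED50_adjunct, 0); the fixed
    adjunct dose is a vertical line whose intersections with the additivity
    line and with the experimental estimate give points A and E.
    """

    varied_drug: str
    adjunct_label: str
    varied_intercept: float  # Y-axis: solo ED50 of the varied drug
    adjunct_intercept: float  # X-axis: solo ED50 of the (pooled) adjunct
    fixed_dose: float
    point_additive: tuple[float, float]
    point_experimental: tuple[float, float]
    pooled_note: Optional[str] = None


def additive_ed50(design: MixtureDesign) -> AdditivePrediction:
    """Theoretical additive mixture ED50 under Loewe dose equivalence.

    The varied component is ``ED50_varied * (1 - sum_i D_i/ED50_i)`` and the
    total adds back the fixed doses.  The SEM propagates component variances by
    the delta method,

        Var_add = (1 - sum f_i)^2 Var(ED50_v) + sum_i (ED50_v D_i / ED50_i^2)^2 Var(ED50_i),

    and is NaN when any component SEM is unavailable.  ``n_add`` sums the
    4th-6th-probit animal counts of the solo curves entering the calculation.
    """
    comps = design.effective_adjuncts
    ed50_v = design.varied_potency.ed50
    f_sum = sum(c.fraction for c in comps)
    if f_sum >= 1.0:
        raise AdditivityError(
            f"{design.label}: adjunct fractions sum to {f_sum:.3f} >= 1"
        )
    varied = ed50_v * (1.0 - f_sum)
    total = varied + sum(c.dose for c in comps)
    var_add = (1.0 - f_sum) ** 2 * design.varied_potency.sem**2
    for c in comps:
        var_add += (ed50_v * c.dose / c.potency.ed50**2) ** 2 * c.potency.sem**2
    n_add = design.varied_potency.n_probit + sum(c.potency.n_probit for c in comps)
    return AdditivePrediction(
        ed50_add_total=total,
        ed50_add_varied=varied,
        sem_add=math.sqrt(var_add) if not math.isnan(var_add) else math.nan,
        n_add=n_add,
    )


def experimental_mixture_ed50(
    varied_in_mixture: PotencyEstimate, fixed_doses: Sequence[float]
) -> ExperimentalMixturePotency:
    """Total experimental mixture ED50 from the varied drug's in-mixture potency.

    The fixed adjunct doses are constants (zero variance), so the SEM of the
    mixture fit carries through unchanged and ``n_exp`` is the mixture curve's
    probit-window count.
    """
    if any(d < 0 for d in fixed_doses):
        raise ValueError("fixed doses must be non-negative")
    total_fixed = float(sum(fixed_doses))
    return ExperimentalMixturePotency(
        ed50_exp_total=varied_in_mixture.ed50 + total_fixed,
        ed50_exp_varied=varied_in_mixture.ed50,
        sem_exp=varied_in_mixture.sem,
        n_exp=varied_in_mixture.n_probit,
    )


def fraction_breakdown(
    mix: ExperimentalMixturePotency, design: MixtureDesign
) -> FractionBreakdown:
    """Per-drug ED50 fractions at the experimental mixture ED50.

    The varied drug's fraction is its in-mixture ED50 over its solo ED50; each
    adjunct's fraction is its fixed dose over its solo ED50.  Printed tables
    round each fraction to 2 decimals (half away from zero) before summing, so
    the index is the sum of the rounded values.
    """
    exact: dict[str, float] = {}
    if design.varied_potency.ed50 <= 0:
        raise ValueError("varied drug solo ED50 must be positive")
    exact[design.varied_drug] = mix.ed50_exp_varied / design.varied_potency.ed50
    for c in design.adjuncts:
        if c.potency.ed50 <= 0:
            raise ValueError(f"{c.drug}: solo ED50 must be positive")
        exact[c.drug] = c.fraction
    rounded = {drug: round_half_away(f, 2) for drug, f in exact.items()}
    return FractionBreakdown(
        fractions=rounded,
        fraction_index=round_half_away(sum(rounded.values()), 2),
        fractions_exact=exact,
    )


def percent_change(ed50_control: float, ed50_treated: float) -> int:
    """Signed percent change of an ED50 relative to control, rounded to an integer.

    Positive values are reductions (potentiation of the varied drug).
    """
    if ed50_control <= 0:
        raise ValueError(f"control ED50 must be positive, got {ed50_control}")
    return int(round_half_away((ed50_control - ed50_treated) / ed50_control * 100.0, 0))


def isobologram_coordinates(
    design: MixtureDesign,
    add: AdditivePrediction,
    exp: ExperimentalMixturePotency,
) -> IsobologramCoordinates:
    """Coordinates of the additivity line, fixed-dose line and points A/E.

    Two-drug designs map directly onto the (adjunct dose, varied dose) plane.
    Multi-adjunct designs are collapsed onto one pooled-adjunct axis whose
    intercept is the total fixed dose divided by the summed adjunct fractions
    (the dose at which the pooled adjuncts alone would reach additivity); the
    pooling is stated in ``pooled_note``.
    """
    comps = design.adjuncts
    if len(comps) == 1:
        adjunct_label = comps[0].drug
        adjunct_intercept = comps[0].potency.ed50
        pooled_note = None
    else:
        f_sum = sum(c.fraction for c in comps)
        adjunct_label = " + ".join(c.drug for c in comps)
        adjunct_intercept = design.total_fixed_dose / f_sum if f_sum > 0 else math.inf
        pooled_note = (
            f"adjuncts {adjunct_label} pooled onto one axis with effective ED50 "
            f"{adjunct_intercept:.4g} mg/kg (total fixed dose / summed fractions)"
        )
    x = design.total_fixed_dose
    return IsobologramCoordinates(
        varied_drug=design.varied_drug,
        adjunct_label=adjunct_label,
        varied_intercept=design.varied_potency.ed50,
        adjunct_intercept=adjunct_intercept,
        fixed_dose=x,
        point_additive=(x, add.ed50_add_varied),
        point_experimental=(x, exp.ed50_exp_varied),
        pooled_note=pooled_note,
    )
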