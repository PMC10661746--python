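"""Synthetic quantal MES-style data with known ground truth.

Each animal's protection is Bernoulli with probability following a probit
curve in log10 dose,

    p(d) = Phi( slope * (log10 d - log10 ED50) ),

mirroring the 8-mice-per-group design of the mouse maximal-electroshock
assay.  Fixed-dose mixtures are generated under Loewe dose equivalence: the
varied dose d is augmented by the adjuncts' equivalent doses
``ED50_true * D_i / ED50_i`` before the curve is evaluated.  A potency
multiplier (the interaction factor) perturbs the equivalent dose — 1 leaves
the mixture exactly additive by construction, >1 makes it synergistic,
<1 antagonistic — giving the fitting, isobole and classification machinery an
end-to-end testbed with known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .probit import DoseResponseDataset, QuantalDoseGroup

__all__ = ["DEFAULT_SEED", "SimulationConfig", "simulate_quantal", "simulate_mixture"]

#: Package-default simulation seed (used by bundled fixtures and examples).
DEFAULT_SEED = 20231011


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and design for one simulated dose-response experiment.

    ``adjuncts`` lists (fixed dose mg/kg, solo ED50 mg/kg) pairs for mixture
    designs; ``interaction_factor`` multiplies the Loewe-equivalent dose
    (1 = exactly additive).  Group size defaults to 8 animals, the standard
    MES design.
    """

    ed50_true: float
    slope_true: float
    doses: tuple[float, ...]
    n_per_group: int = 8
    seed: int = DEFAULT_SEED
    interaction_factor: float = 1.0
    adjuncts: tuple[tuple[float, float], ...] = ()
    drug_id: str = "synthetic"

    def __init__(
        self,
        ed50_true: float,
        slope_true: float,
        doses: Sequence[float],
        n_per_group: int = 8,
        seed: int = DEFAULT_SEED,
        interaction_factor: float = 1.0,
        adjuncts: Sequence[tuple[float, float]] = (),
        drug_id: str = "synthetic",
    ) -> None:
        if ed50_true <= 0:
            raise ValueError(f"ed50_true must be positive, got {ed50_true}")
        if slope_true <= 0:
            raise ValueError(f"slope_true must be positive, got {slope_true}")
        if interaction_factor <= 0:
            raise ValueError(f"interaction_factor must be positive, got {interaction_factor}")
        doses = tuple(float(d) for d in doses)
        if not doses or any(d <= 0 for d in doses):
            raise ValueError("doses must be a non-empty list of positive values")
        if n_per_group <= 0:
            raise ValueError("n_per_group must be a positive integer")
        adjuncts = tuple((float(d), float(e)) for d, e in adjuncts)
        if any(e <= 0 or d < 0 for d, e in adjuncts):
            raise ValueError("adjuncts need non-negative doses and positive solo ED50s")
        object.__setattr__(self, "ed50_true", float(ed50_true))
        object.__setattr__(self, "slope_true", float(slope_true))
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "n_per_group", int(n_per_group))
        object.__setattr__(self, "seed", int(seed))
        object.__setattr__(self, "interaction_factor", float(interaction_factor))
        object.__setattr__(self, "adjuncts", adjuncts)
        object.__setattr__(self, "drug_id", drug_id)

    @property
    def adjunct_fraction(self) -> float:
        """Loewe fraction contributed by the fixed adjunct doses."""
        return sum(d / e for d, e in self.adjuncts)

    def protection_probability(self, dose: float) -> float:
        """True protection probability at a varied-drug dose, adjuncts included."""
        d_eq = dose + sum(self.ed50_true * d / e for d, e in self.adjuncts)
        z = self.slope_true * (
            np.log10(self.interaction_factor * d_eq) - np.log10(self.ed50_true)
        )
        return float(stats.norm.cdf(z))

    def ground_truth(self) -> dict:
        """JSON-serialisable record of the generating parameters."""
        return {
            "drug_id": self.drug_id,
            "ed50_true": self.ed50_true,
            "slope_true": self.slope_true,
            "doses": list(self.doses),
            "n_per_group": self.n_per_group,
            "seed": self.seed,
            "interaction_factor": self.interaction_factor,
            "adjuncts": [list(a) for a in self.adjuncts],
        }

    def write_ground_truth(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.ground_truth(), fh, indent=2)
            fh.write("\n")


def _draw(config: SimulationConfig) -> DoseResponseDataset:
    rng = np.random.default_rng(config.seed)
    groups = []
    for d in config.doses:
        p = config.protection_probability(d)
        k = int(rng.binomial(config.n_per_group, p))
        groups.append(QuantalDoseGroup(dose=d, n_protected=k, n_total=config.n_per_group))
    return DoseResponseDataset(config.drug_id, groups)


def simulate_quantal(config: SimulationConfig) -> DoseResponseDataset:
    """Simulate a single-drug quantal dose-response experiment.

    Per dose, ``n_protected ~ Binomial(n_per_group, Phi(slope * log10(d/ED50)))``
    with one seeded generator per dataset; identical (config, seed) yields an
    identical dataset.
    """
    if config.adjuncts:
        raise ValueError("simulate_quantal is for single drugs; use simulate_mixture")
    return _draw(config)


def simulate_mixture(config: SimulationConfig) -> DoseResponseDataset:
    """Simulate a fixed-dose mixture experiment under perturbed Loewe additivity.

    The varied dose is converted to its Loewe-equivalent total, multiplied by
    the interaction factor, and pushed through the solo probit curve.  With
    ``interaction_factor = 1`` the mixture is exactly additive by construction.
    """
    if not config.adjuncts:
        raise ValueError("simulate_mixture needs at least one adjunct")
    if config.adjunct_fraction >= 1.0:
        raise ValueError(
            f"adjunct fraction sum {config.adjunct_fraction:.3f} >= 1: the fixed "
            "doses alone exceed the additive ED50"
        )
    return _draw(config)
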