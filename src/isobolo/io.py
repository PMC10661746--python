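"""Reading and writing the package's tabular interchange formats.

Raw quantal data travel as UTF-8 CSV with the exact header
``drug,dose_mg_kg,n_protected,n_total`` (one row per dose group); potency and
summary-estimate tables are plain CSV with ED50/SEM/n columns.
"""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from .probit import DoseResponseDataset, PotencyEstimate, QuantalDoseGroup

__all__ = [
    "RAW_COLUMNS",
    "read_quantal_csv",
    "write_quantal_csv",
    "read_summary_potencies",
    "potency_table",
]

RAW_COLUMNS = ["drug", "dose_mg_kg", "n_protected", "n_total"]


def read_quantal_csv(path) -> dict[str, DoseResponseDataset]:
    """Read raw quantal dose-group CSV into one dataset per drug label.

    The header must be exactly ``drug,dose_mg_kg,n_protected,n_total``.
    """
    df = pd.read_csv(path)
    if list(df.columns) != RAW_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(RAW_COLUMNS)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    out: dict[str, DoseResponseDataset] = {}
    for drug, sub in df.groupby("drug", sort=False):
        groups = [
            QuantalDoseGroup(
                dose=float(r.dose_mg_kg),
                n_protected=int(r.n_protected),
                n_total=int(r.n_total),
            )
            for r in sub.itertuples()
        ]
        out[str(drug)] = DoseResponseDataset(str(drug), groups)
    return out


def write_quantal_csv(datasets: Mapping[str, DoseResponseDataset] | DoseResponseDataset, path) -> None:
    """Write datasets back to the canonical raw CSV layout (deterministic row order)."""
    if isinstance(datasets, DoseResponseDataset):
        datasets = {datasets.drug_id: datasets}
    frames = [ds.to_frame() for ds in datasets.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_summary_potencies(path) -> dict[str, PotencyEstimate]:
    """Read a summary-estimate table (``drug,ed50_mg_kg,sem_mg_kg,n_probit``).

    Missing SEMs (unpublished dispersion) become NaN; missing n becomes 0.
    Summary rows carry no fitted slope or confidence limits, which are set to
    NaN/inf-free placeholder values derived from the SEM where possible.
    """
    df = pd.read_csv(path)
    required = {"drug", "ed50_mg_kg"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: summary table needs columns {sorted(required)}")
    out: dict[str, PotencyEstimate] = {}
    for r in df.itertuples():
        ed50 = float(r.ed50_mg_kg)
        sem = float(getattr(r, "sem_mg_kg", math.nan))
        n = getattr(r, "n_probit", 0)
        n = 0 if pd.isna(n) else int(n)
        if math.isnan(sem):
            lo = hi = math.nan
        else:
            lo, hi = ed50 - 1.96 * sem, ed50 + 1.96 * sem
        out[str(r.drug)] = PotencyEstimate(
            ed50=ed50, sem=sem, cl95_lower=lo, cl95_upper=hi,
            slope=math.nan, n_probit=n, converged=True,
        )
    return out


def potency_table(potencies: Mapping[str, PotencyEstimate]) -> pd.DataFrame:
    """Flatten potency estimates to the canonical output record per drug."""
    rows = [
        {
            "drug": drug,
            "ed50": p.ed50,
            "sem": p.sem,
            "cl95_lower": p.cl95_lower,
            "cl95_upper": p.cl95_upper,
            "slope": p.slope,
            "n_probit": p.n_probit,
            "converged": p.converged,
        }
        for drug, p in potencies.items()
    ]
    return pd.DataFrame(rows)
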