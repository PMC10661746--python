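"""Bundled summary estimates of the mouse MES interaction study.

The package ships the published summary numbers — solo ED50s of carbamazepine
(CBZ), phenytoin (PHT), phenobarbital (PB), valproate (VPA) and isopimpinellin
(ISOP), plus the experimental and additive mixture ED50s (± SEM, n) for the
twelve fixed-dose combinations with ISOP (25/50 mg/kg) and borneol (BOR,
25 mg/kg) — as plain CSV/YAML under ``isobolo/data``.  They are the
summary-mode input that reproduces the study's interaction tables, since the
raw per-animal quantal data were never published.

Two bookkeeping values in the solo table are back-derived conventions rather
than published numbers: BOR's solo ED50 (250 mg/kg, implied by its printed
0.10 fraction at a 25 mg/kg dose) and the per-drug probit-window animal counts
(consistent with the printed pooled n of the additive predictions).  Solo SEMs
of the four classic drugs were not published and are left missing; the Welch
comparisons therefore consume the published additive SEMs directly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .io import read_summary_potencies
from .pipeline import StudyConfig, _design_from_dict
from .probit import PotencyEstimate

__all__ = [
    "data_path",
    "load_solo_potencies",
    "load_mixture_summary",
    "load_designs",
    "load_study_config",
]


def data_path(name: str):
    """Path-like handle to a bundled data file."""
    return resources.files("isobolo").joinpath("data", name)


def load_solo_potencies() -> dict[str, PotencyEstimate]:
    """Solo ED50 (± SEM where published) per drug."""
    with resources.as_file(data_path("mes_solo_potencies.csv")) as p:
        return read_summary_potencies(p)


def load_mixture_summary() -> pd.DataFrame:
    """Published experimental and additive mixture estimates per combination."""
    with resources.as_file(data_path("mes_mixture_summary.csv")) as p:
        return pd.read_csv(p)


def load_designs():
    """The twelve fixed-dose mixture designs (two- and three-drug)."""
    with data_path("mes_designs.yaml").open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return tuple(_design_from_dict(d) for d in cfg["designs"])


def load_study_config(alpha: float = 0.05) -> StudyConfig:
    """Summary-mode study configuration over the bundled estimates, ready to run."""
    return StudyConfig(
        mode="summary",
        designs=load_designs(),
        solo_potencies=load_solo_potencies(),
        mixture_summary=load_mixture_summary(),
        alpha=alpha,
        label="mes-isop-bor-interaction-study",
    )
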