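"""End-to-end study orchestration: potencies -> isoboles -> classification tables.

Two ingestion modes cover the two ways interaction studies circulate:

* ``raw`` — quantal dose-group CSVs are refit by log-probit regression for
  every solo drug and mixture arm, and all downstream quantities derive from
  the fits.
* ``summary`` — published ED50 ± SEM (n) estimates are ingested directly;
  this is the mode that reproduces a study's printed interaction tables,
  since raw per-animal data are rarely published.  When the summary table
  also supplies the study's own additive predictions (SEM and n included),
  those feed the Welch comparison, and the recomputed additive total is
  reported alongside for cross-checking.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .interaction import InteractionResult, classify_interaction
from .io import potency_table, read_quantal_csv, read_summary_potencies
from .isobole import (
    AdditivePrediction,
    ExperimentalMixturePotency,
    FractionBreakdown,
    IsobologramCoordinates,
    MixtureComponent,
    MixtureDesign,
    additive_ed50,
    experimental_mixture_ed50,
    fraction_breakdown,
    isobologram_coordinates,
    percent_change,
)
from .probit import DoseResponseDataset, PotencyEstimate, fit_log_probit
from .simulate import DEFAULT_SEED

__all__ = ["DesignSpec", "StudyConfig", "StudyReport", "run_study", "significance_marker"]


@dataclass(frozen=True)
class DesignSpec:
    """Declarative mixture design: varied drug + fixed-dose adjunct labels.

    ``additivity_adjuncts`` optionally overrides the adjunct set used by the
    additive prediction (see MixtureDesign).  In raw mode ``mixture_arm``
    names the quantal dataset of the varied drug administered with the
    adjuncts; it defaults to the design name.
    """

    name: str
    varied: str
    adjuncts: tuple[tuple[str, float], ...]
    additivity_adjuncts: Optional[tuple[tuple[str, float], ...]] = None
    mixture_arm: Optional[str] = None

    @property
    def total_fixed_dose(self) -> float:
        return sum(d for _, d in self.adjuncts)


@dataclass
class StudyConfig:
    """Everything needed to run the study once: mode, inputs, designs, options."""

    mode: str
    designs: tuple[DesignSpec, ...]
    solo_potencies: Optional[dict[str, PotencyEstimate]] = None
    quantal: Optional[dict[str, DoseResponseDataset]] = None
    mixture_summary: Optional[pd.DataFrame] = None
    alpha: float = 0.05
    seed: int = DEFAULT_SEED
    label: str = "study"

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "summary"):
            raise ValueError(f"mode must be 'raw' or 'summary', got {self.mode!r}")
        if self.mode == "summary" and self.solo_potencies is None:
            raise ValueError("summary mode needs solo_potencies")
        if self.mode == "raw" and self.quantal is None:
            raise ValueError("raw mode needs quantal datasets")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Load a study configuration file; relative paths resolve next to it."""
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        base = path.parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        designs = tuple(_design_from_dict(d) for d in cfg.get("designs", []))
        mode = cfg.get("mode", "summary")
        solo = quantal = summary = None
        if "solo_potencies_csv" in cfg:
            solo = read_summary_potencies(_resolve(cfg["solo_potencies_csv"]))
        if "quantal_csv" in cfg:
            quantal = read_quantal_csv(_resolve(cfg["quantal_csv"]))
        if "mixture_summary_csv" in cfg:
            summary = pd.read_csv(_resolve(cfg["mixture_summary_csv"]))
        return cls(
            mode=mode,
            designs=designs,
            solo_potencies=solo,
            quantal=quantal,
            mixture_summary=summary,
            alpha=float(cfg.get("alpha", 0.05)),
            seed=int(cfg.get("seed", DEFAULT_SEED)),
            label=str(cfg.get("label", path.stem)),
        )


def _design_from_dict(d: Mapping) -> DesignSpec:
    def _pairs(items):
        return tuple((str(a["drug"]), float(a["dose_mg_kg"])) for a in items)

    return DesignSpec(
        name=str(d["name"]),
        varied=str(d["varied"]),
        adjuncts=_pairs(d["adjuncts"]),
        additivity_adjuncts=(
            _pairs(d["additivity_adjuncts"]) if "additivity_adjuncts" in d else None
        ),
        mixture_arm=d.get("mixture_arm"),
    )


def significance_marker(p: float) -> str:
    """Footnote markers of printed tables: ``***`` for p < 0.001, ``*`` for p < 0.05."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class StudyReport:
    """Result bundle: potency table, combination table, isobologram coordinates, log."""

    potencies: pd.DataFrame
    combinations: pd.DataFrame
    isobologram: pd.DataFrame
    details: dict

    def write(self, out_dir) -> None:
        """Write CSV tables plus the JSON report (operands and run log) to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.potencies.to_csv(out / "potencies.csv", index=False)
        self.combinations.to_csv(out / "combinations.csv", index=False)
        self.isobologram.to_csv(out / "isobologram.csv", index=False)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(self.details, fh, indent=2, default=_jsonable)
            fh.write("\n")


def _jsonable(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return dataclasses.asdict(x)
    return str(x)


def _potency_record(p: PotencyEstimate) -> dict:
    return {"ed50": p.ed50, "sem": p.sem, "n_probit": p.n_probit}


def _resolve_potency(label: str, potencies: Mapping[str, PotencyEstimate], ctx: str) -> PotencyEstimate:
    try:
        return potencies[label]
    except KeyError:
        raise KeyError(
            f"design {ctx!r}: drug {label!r} has no potency source"
        ) from None


def _build_design(spec: DesignSpec, potencies: Mapping[str, PotencyEstimate]) -> MixtureDesign:
    def _components(pairs):
        return tuple(
            MixtureComponent(drug, dose, _resolve_potency(drug, potencies, spec.name))
            for drug, dose in pairs
        )

    return MixtureDesign(
        varied_drug=spec.varied,
        varied_potency=_resolve_potency(spec.varied, potencies, spec.name),
        adjuncts=_components(spec.adjuncts),
        additivity_adjuncts=(
            _components(spec.additivity_adjuncts)
            if spec.additivity_adjuncts is not None
            else None
        ),
        name=spec.name,
    )


def _summary_experimental(spec: DesignSpec, summary: pd.DataFrame) -> ExperimentalMixturePotency:
    row = summary.loc[summary["combination"] == spec.name]
    if row.empty:
        raise KeyError(f"design {spec.name!r}: no row in the mixture summary table")
    r = row.iloc[0]
    total = float(r["ed50_exp_total"])
    return ExperimentalMixturePotency(
        ed50_exp_total=total,
        ed50_exp_varied=total - spec.total_fixed_dose,
        sem_exp=float(r["sem_exp"]),
        n_exp=int(r["n_exp"]),
    )


def _summary_additive(
    spec: DesignSpec, summary: pd.DataFrame, fixed_dose_eff: float
) -> Optional[AdditivePrediction]:
    row = summary.loc[summary["combination"] == spec.name]
    if row.empty or "ed50_add_total" not in summary.columns:
        return None
    r = row.iloc[0]
    if pd.isna(r["ed50_add_total"]):
        return None
    total = float(r["ed50_add_total"])
    return AdditivePrediction(
        ed50_add_total=total,
        ed50_add_varied=total - fixed_dose_eff,
        sem_add=float(r.get("sem_add", math.nan)),
        n_add=int(r.get("n_add", 0)),
    )


def _fractions_string(fb: FractionBreakdown) -> str:
    terms = " + ".join(f"{v:.2f}" for v in fb.fractions.values())
    return f"{terms} = {fb.fraction_index:.2f}"


def run_study(config: StudyConfig, out_dir=None) -> StudyReport:
    """Run the full analysis: potencies, additive predictions, Welch tests, fractions.

    Per design the report carries the experimental and additive mixture ED50s
    (total mixture dose), the Welch comparison with its classification, the
    per-drug fraction breakdown, the percent change of the varied drug's ED50
    versus its solo value, and two-drug isobologram coordinates.  Every
    derived cell's operands are recorded in the JSON report.
    """
    if config.mode == "raw":
        potencies = {
            drug: fit_log_probit(ds)
            for drug, ds in config.quantal.items()
        }
    else:
        potencies = dict(config.solo_potencies)

    combo_rows = []
    iso_rows = []
    operands = {}
    for spec in config.designs:
        design = _build_design(spec, potencies)
        add_computed = additive_ed50(design)

        if config.mode == "raw":
            arm = spec.mixture_arm or spec.name
            if arm not in potencies:
                raise KeyError(f"design {spec.name!r}: mixture arm {arm!r} not found")
            exp = experimental_mixture_ed50(
                potencies[arm], [dose for _, dose in spec.adjuncts]
            )
            add_used = add_computed
        else:
            if config.mixture_summary is None:
                raise ValueError(
                    f"design {spec.name!r}: summary mode with designs needs a mixture summary table"
                )
            exp = _summary_experimental(spec, config.mixture_summary)
            fixed_eff = sum(c.dose for c in design.effective_adjuncts)
            add_used = _summary_additive(spec, config.mixture_summary, fixed_eff) or add_computed

        result = classify_interaction(exp, add_used, alpha=config.alpha)
        fb = fraction_breakdown(exp, design)
        pct = percent_change(design.varied_potency.ed50, exp.ed50_exp_varied)
        coords = isobologram_coordinates(design, add_used, exp)

        combo_rows.append(
            {
                "combination": spec.name,
                "varied_drug": spec.varied,
                "ed50_exp_total": exp.ed50_exp_total,
                "sem_exp": exp.sem_exp,
                "n_exp": exp.n_exp,
                "ed50_add_total": add_used.ed50_add_total,
                "sem_add": add_used.sem_add,
                "n_add": add_used.n_add,
                "ed50_add_computed": add_computed.ed50_add_total,
                "t": result.t_statistic,
                "df": result.df,
                "p": result.p_value,
                "significance": significance_marker(result.p_value),
                "classification": result.classification,
                "sum_of_fractions": fb.fraction_index,
                "fractions": _fractions_string(fb),
                "pct_change_vs_solo": pct,
            }
        )
        iso_rows.extend(_isobologram_rows(spec.name, coords))
        operands[spec.name] = {
            "varied_solo": _potency_record(design.varied_potency),
            "adjuncts": [
                {"drug": c.drug, "dose_mg_kg": c.dose, **_potency_record(c.potency)}
                for c in design.adjuncts
            ],
            "additivity_adjuncts": [
                {"drug": c.drug, "dose_mg_kg": c.dose, **_potency_record(c.potency)}
                for c in design.effective_adjuncts
            ],
            "experimental": dataclasses.asdict(exp),
            "additive_used": dataclasses.asdict(add_used),
            "additive_computed": dataclasses.asdict(add_computed),
            "welch": {"t": result.t_statistic, "df": result.df, "p": result.p_value},
            "fractions": fb.fractions,
            "fractions_exact": fb.fractions_exact,
        }

    report = StudyReport(
        potencies=potency_table(potencies),
        combinations=pd.DataFrame(combo_rows),
        isobologram=pd.DataFrame(iso_rows, columns=["combination", "series", "x", "y"]),
        details={
            "label": config.label,
            "mode": config.mode,
            "alpha": config.alpha,
            "seed": config.seed,
            "version": __version__,
            "conventions": [
                "mixture ED50s are total mixture dose (varied + fixed adjuncts)",
                "fractions rounded to 2 decimals half-away-from-zero before summing",
                "Welch-Satterthwaite df rounded to nearest integer",
                "provided additive estimates (when present) feed the Welch test; "
                "recomputed additive totals reported alongside",
            ],
            "combinations": operands,
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def _isobologram_rows(name: str, coords: IsobologramCoordinates) -> list[dict]:
    rows = [
        {"combination": name, "series": "additivity_line", "x": 0.0, "y": coords.varied_intercept},
        {"combination": name, "series": "additivity_line", "x": coords.adjunct_intercept, "y": 0.0},
        {"combination": name, "series": "fixed_dose_line", "x": coords.fixed_dose, "y": 0.0},
        {"combination": name, "series": "fixed_dose_line", "x": coords.fixed_dose, "y": coords.varied_intercept},
        {"combination": name, "series": "point_A", "x": coords.point_additive[0], "y": coords.point_additive[1]},
        {"combination": name, "series": "point_E", "x": coords.point_experimental[0], "y": coords.point_experimental[1]},
    ]
    return rows
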