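"""Configuration handling, the shipped drug library, and report generation.

All concentrations in interfaces are uM; all tabular outputs are
tab-delimited text with a header row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .ap_model import APModel, PacingProtocol, build_model, default_model_path, simulate
from .biomarkers import BIOMARKER_NAMES, BiomarkerSet, compute_biomarkers
from .cost_optimizer import (
    CostSpec,
    DoseBounds,
    cost_from_biomarkers,
    factors_for_model,
    make_objective,
    optimize_incremental,
    pairwise_scan,
)
from .drug_model import (
    DrugProfile,
    HillDrugEffect,
    most_affected_current,
    percent_change_table,
)

__all__ = [
    "RunConfig",
    "load_drug_library",
    "save_drug_library",
    "default_library_path",
    "dose_report",
    "biomarker_comparison",
    "run_repair",
]

log = logging.getLogger("aprepair")

_EFFECT_KEYS = {"ec50_uM", "hill", "emax"}


def default_library_path() -> Path:
    """Path of the drug library shipped with the package."""
    return Path(__file__).parent / "data" / "drug_library.yaml"


def load_drug_library(path: str | Path | None = None) -> dict[str, DrugProfile]:
    """Load and validate a drug library (YAML; see data/drug_library.yaml).

    Each drug block maps current ids to ``{ec50_uM, hill, emax[, source]}``;
    validation errors name the offending drug/current/field.
    """
    path = Path(path) if path is not None else default_library_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "drugs" not in raw:
        raise ValueError(f"{path}: drug library must have a top-level 'drugs' map")
    profiles: dict[str, DrugProfile] = {}
    for name, block in raw["drugs"].items():
        if not isinstance(block, dict) or not block:
            raise ValueError(f"{path}: drug {name!r} must map currents to parameters")
        effects = {}
        for cid, entry in block.items():
            missing = _EFFECT_KEYS - set(entry)
            if missing:
                raise ValueError(
                    f"{path}: drug {name!r}, current {cid!r}: missing {sorted(missing)}"
                )
            try:
                effects[cid] = HillDrugEffect(
                    ec50=float(entry["ec50_uM"]),
                    hill=float(entry["hill"]),
                    emax=float(entry["emax"]),
                    source=entry.get("source"),
                )
            except ValueError as err:
                raise ValueError(
                    f"{path}: drug {name!r}, current {cid!r}: {err}"
                ) from err
        profiles[name] = DrugProfile(name=name, effects=effects)
    return profiles


def save_drug_library(profiles: Mapping[str, DrugProfile], path: str | Path) -> None:
    """Serialise a drug library losslessly back to the YAML schema."""
    drugs: dict = {}
    for name, profile in profiles.items():
        drugs[name] = {}
        for cid, eff in profile.effects.items():
            entry = {"ec50_uM": eff.ec50, "hill": eff.hill, "emax": eff.emax}
            if eff.source is not None:
                entry["source"] = eff.source
            drugs[name][cid] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"schema": 1, "concentration_unit": "uM", "drugs": drugs},
            fh, sort_keys=False,
        )


@dataclass
class RunConfig:
    """Everything one end-to-end repair run needs."""

    model_path: str | Path = field(default_factory=default_model_path)
    cell_type: str = "adult-human"
    mutation: str = "N588K"
    library_path: str | Path = field(default_factory=default_library_path)
    drugs: Sequence[str] | None = None  # None = all drugs; () = baseline only
    bounds_mode: str = "saturation-cap"
    max_drugs: int = 2
    run_pairwise: bool = False
    output_dir: str | Path = "aprepair_out"
    protocol: PacingProtocol = field(default_factory=PacingProtocol)
    cost_spec: CostSpec = field(default_factory=CostSpec)
    eval_beats: int = 3

    def __post_init__(self) -> None:
        if not Path(self.model_path).exists():
            raise FileNotFoundError(f"model file not found: {self.model_path}")
        if not Path(self.library_path).exists():
            raise FileNotFoundError(f"drug library not found: {self.library_path}")


def dose_report(
    profiles: Mapping[str, DrugProfile],
    doses: Mapping[str, float],
    currents: Sequence[str] = ("I_Kr", "I_CaL", "I_Na", "I_NaL", "I_f"),
) -> pd.DataFrame:
    """Optimal-dose table: per drug the dose, the saturation of its most
    affected current ("max % of E"), and the combined per-current % change."""
    rows = []
    for name, dose in doses.items():
        cid, frac = most_affected_current(profiles[name], dose)
        rows.append({
            "drug": name,
            "dose_uM": dose,
            "max_pct_of_E": 100.0 * frac,
            "most_affected_current": cid,
        })
    table = pd.DataFrame(rows)
    pct = percent_change_table(profiles, doses, currents)
    for cid in currents:
        table[f"pct_change_{cid}"] = pct[cid]
    return table


def biomarker_comparison(
    wt: BiomarkerSet,
    mutant: BiomarkerSet,
    treated: BiomarkerSet | None = None,
) -> pd.DataFrame:
    """Wild-type vs mutant (vs treated) biomarkers with % deviations from WT."""
    data = {"WT": [wt[n] for n in BIOMARKER_NAMES],
            "mutant": [mutant[n] for n in BIOMARKER_NAMES]}
    frame = pd.DataFrame(data, index=list(BIOMARKER_NAMES))
    frame["mutant_pct_from_WT"] = 100.0 * (frame["mutant"] - frame["WT"]) / frame["WT"].abs()
    if treated is not None:
        frame["treated"] = [treated[n] for n in BIOMARKER_NAMES]
        frame["treated_pct_from_WT"] = (
            100.0 * (frame["treated"] - frame["WT"]) / frame["WT"].abs()
        )
    return frame


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_repair(config: RunConfig) -> int:
    """End-to-end pipeline: baselines, optional pairwise scan, incremental
    optimisation; writes traces, tables and a machine-readable summary.

    Returns 0 on success (exceptions propagate with a logged stage name).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": {
        "cell_type": config.cell_type, "mutation": config.mutation,
        "bounds_mode": config.bounds_mode, "max_drugs": config.max_drugs,
        "drugs": None if config.drugs is None else list(config.drugs),
    }}

    log.info("stage=build model=%s cell_type=%s", config.model_path, config.cell_type)
    wt = build_model(config.model_path, config.cell_type, "WT")
    mutant = build_model(config.model_path, config.cell_type, config.mutation)
    protocol = config.protocol

    log.info("stage=baseline")
    wt_trace = simulate(wt, protocol, record_currents=True)
    mut_trace = simulate(mutant, protocol, record_currents=True)
    wt_bm = compute_biomarkers(wt_trace)
    mut_bm = compute_biomarkers(mut_trace)
    _write(wt_trace.to_frame(), out / "trace_wt.tsv")
    _write(mut_trace.to_frame(), out / "trace_mutant.tsv")
    untreated_cost = cost_from_biomarkers(mut_bm, wt_bm, config.cost_spec)
    summary["untreated_cost"] = untreated_cost

    profiles = load_drug_library(config.library_path)
    selected = list(profiles) if config.drugs is None else list(config.drugs)
    unknown = set(selected) - set(profiles)
    if unknown:
        raise ValueError(f"selected drugs not in library: {sorted(unknown)}")

    if not selected:
        _write(biomarker_comparison(wt_bm, mut_bm), out / "biomarkers.tsv", index=True)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return 0

    bounds_spec = DoseBounds(mode=config.bounds_mode)
    bounds = {name: bounds_spec.resolve(profiles[name]) for name in selected}
    summary["dose_bounds_uM"] = bounds

    log.info("stage=objective eval_beats=%d", config.eval_beats)
    objective = make_objective(
        mutant, wt_bm, profiles, config.cost_spec, protocol,
        eval_beats=config.eval_beats,
    )

    if config.run_pairwise and len(selected) >= 2:
        log.info("stage=pairwise_scan K=%d", len(selected))
        matrix, best_pair = pairwise_scan(selected, bounds, objective)
        _write(matrix, out / "pairwise_costs.tsv", index=True)
        summary["best_pair"] = list(best_pair)

    log.info("stage=incremental max_n=%d", config.max_drugs)
    results = optimize_incremental(
        selected, bounds, objective, max_n=config.max_drugs
    )
    summary["combinations"] = []
    for res in results:
        n = len(res.drugs)
        factors = factors_for_model(mutant, profiles, res.doses)
        treated = simulate(mutant, protocol, factors=factors)
        treated_bm = compute_biomarkers(treated)
        _write(
            biomarker_comparison(wt_bm, mut_bm, treated_bm),
            out / f"biomarkers_n{n}.tsv", index=True,
        )
        _write(dose_report(profiles, res.doses), out / f"doses_n{n}.tsv")
        summary["combinations"].append({
            "n": n, "drugs": list(res.drugs),
            "doses_uM": dict(res.doses), "cost": res.cost,
            "n_evaluations": res.n_evaluations,
        })
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("stage=done out=%s", out)
    return 0
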