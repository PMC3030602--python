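"""End-to-end orchestration: normalize -> call -> pair -> enrich -> summarize.

Every stage reads and writes conventionally-named files inside one
working directory, so the stages compose: running them one at a time
(as the CLI subcommands do) produces byte-identical outputs to
:func:`run_all`.  Each output file carries a provenance header (seed,
thresholds, package version) and the run summary logs row counts in and
out of every filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .data_model import (
    SOURCE_DBS,
    TimePoint,
    read_gmt,
    read_mirna_table,
    read_mrna_table,
    read_target_predictions,
    read_universe,
    validate_in_universe,
    write_mirna_table,
    _write_tsv,
)
from .differential import (
    RULE_BOTH_POOLS,
    RULE_STANDARD,
    call_modulated_genes,
    call_modulated_genes_both_pools,
    call_modulated_mirnas,
    read_modulated_set,
    recurrent_mirnas,
    write_modulated_set,
)
from .enrichment import (
    PermutationConfig,
    overlap_summary,
    run_pathway_analysis,
)
from .normalization import normalize_probe_signals, summarize_mirnas
from .pairing import inverse_pairs, recurrent_pairs
from .synthetic_data import SimulationConfig, simulate_study


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, permutation settings and I/O locations for a run."""

    out_dir: Path
    preset: str | None = "desk"  # "desk", "full", "null" or None (use input_dir)
    input_dir: Path | None = None
    seed: int = 0
    fc_min: float = 1.5
    p_max: float = 0.01
    log_thr: float = 0.6
    target_p_max: float = 0.05
    combined_threshold: float = 0.05
    n_trials: int = 1000
    databases: tuple[str, ...] = SOURCE_DBS

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        for name in ("p_max", "target_p_max", "combined_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.preset is None and self.input_dir is None:
            raise ValueError("either a simulation preset or an input_dir is required")

    def provenance(self) -> str:
        return (
            f"mirpath {__version__} | seed={self.seed} fc_min={self.fc_min} "
            f"p_max={self.p_max} log_thr={self.log_thr} "
            f"target_p_max={self.target_p_max} "
            f"combined_threshold={self.combined_threshold} n_trials={self.n_trials}"
        )


def simulation_config_for(preset: str, seed: int) -> SimulationConfig:
    if preset == "desk":
        return SimulationConfig.desk(seed=seed)
    if preset == "full":
        return SimulationConfig(seed=seed)
    if preset == "null":
        return SimulationConfig.null_enrichment(seed=seed)
    raise ValueError(f"unknown preset {preset!r}; expected desk, full or null")


# ---------------------------------------------------------------------------
# stages (file-based, composable)
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(simulation_config_for(cfg.preset or "desk", cfg.seed))
    study.write(out, header_comment=cfg.provenance())
    return {
        "n_mirnas": study.universe.n_mirnas,
        "n_genes": study.universe.n_genes,
        "n_pathways": len(study.pathways),
    }


def _stage_input_dir(cfg: RunConfig) -> Path:
    return Path(cfg.input_dir) if cfg.input_dir is not None else Path(cfg.out_dir)


def stage_normalize(cfg: RunConfig) -> dict:
    src = _stage_input_dir(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    universe = read_universe(src / "universe.json")
    counts = {}
    for tp in TimePoint:
        signals = pd.read_csv(src / f"probe_signals_{tp.name}.tsv", sep="\t", comment="#")
        ratios = normalize_probe_signals(signals)
        measurements = summarize_mirnas(ratios, tp)
        validate_in_universe(measurements, universe)
        write_mirna_table(
            measurements, out / f"mirna_measurements_{tp.name}.tsv", cfg.provenance()
        )
        counts[tp.name] = {"probe_rows_in": len(signals), "mirnas_out": len(measurements)}
    return counts


def stage_de(cfg: RunConfig) -> dict:
    src = _stage_input_dir(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    for tp in TimePoint:
        measurements = read_mirna_table(out / f"mirna_measurements_{tp.name}.tsv")
        mirna_set = call_modulated_mirnas(measurements, cfg.fc_min, cfg.p_max)
        write_modulated_set(
            mirna_set, out / f"mirna_modulated_{tp.name}.tsv", cfg.provenance()
        )
        probe_ratios = read_mrna_table(src / f"mrna_ratios_{tp.name}.tsv")
        standard = call_modulated_genes(probe_ratios, tp, cfg.log_thr)
        write_modulated_set(
            standard, out / f"mrna_modulated_standard_{tp.name}.tsv", cfg.provenance()
        )
        both = call_modulated_genes_both_pools(probe_ratios, tp, cfg.fc_min)
        write_modulated_set(
            both, out / f"mrna_modulated_bothpools_{tp.name}.tsv", cfg.provenance()
        )
        counts[tp.name] = {
            "measurements_in": len(measurements),
            "mirna_up": len(mirna_set.up),
            "mirna_down": len(mirna_set.down),
            "gene_standard": len(standard.members),
            "gene_both_pools": len(both.members),
        }
    sets = [
        read_modulated_set(out / f"mirna_modulated_{tp.name}.tsv", "mirna", timepoint=tp)
        for tp in TimePoint
    ]
    recurrent = recurrent_mirnas(sets, k=2)
    _write_tsv(recurrent.reset_index(), out / "recurrent_mirnas_k2.tsv", cfg.provenance())
    counts["recurrent_k2"] = len(recurrent)
    return counts


def stage_pair(cfg: RunConfig) -> dict:
    src = _stage_input_dir(cfg)
    out = Path(cfg.out_dir)
    counts = {}
    predictions = {
        db: read_target_predictions(src / f"predictions_{db}.tsv", db)
        for db in cfg.databases
    }
    pairs_by_tp_db: dict[tuple[str, str], pd.DataFrame] = {}
    for tp in TimePoint:
        mirna_set = read_modulated_set(
            out / f"mirna_modulated_{tp.name}.tsv", "mirna", timepoint=tp
        )
        gene_set = read_modulated_set(
            out / f"mrna_modulated_standard_{tp.name}.tsv", "mrna", RULE_STANDARD,
            timepoint=tp,
        )
        for db in cfg.databases:
            pairs = inverse_pairs(mirna_set, gene_set, predictions[db], cfg.target_p_max)
            _write_tsv(pairs, out / f"pairs_{tp.name}_{db}.tsv", cfg.provenance())
            pairs_by_tp_db[(tp.name, db)] = pairs
            counts[f"{tp.name}_{db}"] = len(pairs)
    for db in cfg.databases:
        for a, b in (("ST", "IT"), ("ST", "LT"), ("IT", "LT")):
            rec = recurrent_pairs(pairs_by_tp_db[(a, db)], pairs_by_tp_db[(b, db)])
            _write_tsv(rec, out / f"recurrent_pairs_{a}_{b}_{db}.tsv", cfg.provenance())
            counts[f"recurrent_{a}_{b}_{db}"] = len(rec)
    return counts


def stage_enrich(cfg: RunConfig) -> dict:
    src = _stage_input_dir(cfg)
    out = Path(cfg.out_dir)
    universe = read_universe(src / "universe.json")
    pathways = read_gmt(src / "pathways.gmt")
    predictions = {
        db: read_target_predictions(src / f"predictions_{db}.tsv", db)
        for db in cfg.databases
    }
    mirna_sets = {
        tp: read_modulated_set(
            out / f"mirna_modulated_{tp.name}.tsv", "mirna", timepoint=tp
        )
        for tp in TimePoint
    }
    gene_sets = {
        tp: read_modulated_set(
            out / f"mrna_modulated_bothpools_{tp.name}.tsv", "mrna", RULE_BOTH_POOLS,
            timepoint=tp,
        )
        for tp in TimePoint
    }
    results, selections = run_pathway_analysis(
        pathways,
        mirna_sets,
        gene_sets,
        predictions,
        universe,
        PermutationConfig(n_trials=cfg.n_trials, seed=cfg.seed),
        cfg.combined_threshold,
    )
    _write_tsv(results, out / "enrichment.tsv", cfg.provenance())
    selections_payload = {
        f"{tp}_{db}": sorted(sel) for (tp, db), sel in selections.items()
    }
    with open(out / "selections.json", "w", encoding="utf-8") as fh:
        json.dump(selections_payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    overlaps = {}
    for db in cfg.databases:
        per_tp = {tp: selections[(tp.name, db)] for tp in TimePoint}
        overlaps[db] = overlap_summary(per_tp)
    with open(out / "overlap.json", "w", encoding="utf-8") as fh:
        json.dump(overlaps, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {
        "pathways": len(pathways),
        "selected": {k: len(v) for k, v in sorted(selections_payload.items())},
    }


@dataclass(frozen=True)
class RunResult:
    config: RunConfig
    counts: dict
    out_dir: Path


def run_all(cfg: RunConfig) -> RunResult:
    """Execute every stage in order inside ``cfg.out_dir``."""
    counts: dict = {}
    if cfg.preset is not None and cfg.input_dir is None:
        counts["simulate"] = stage_simulate(cfg)
    counts["normalize"] = stage_normalize(cfg)
    counts["de"] = stage_de(cfg)
    counts["pair"] = stage_pair(cfg)
    counts["enrich"] = stage_enrich(cfg)
    out = Path(cfg.out_dir)
    summary = {
        "provenance": cfg.provenance(),
        "seed": cfg.seed,
        "counts": counts,
    }
    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return RunResult(cfg, counts, out)
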