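"""Differential sets: modulated miRNAs and genes per time point.

Two thresholds from the study design:

* miRNAs: fold induction >= 1.5 (or <= 1/1.5) with raw t-test p < 0.01;
  the fold bound is inclusive, the p bound strict.
* mRNAs, standard rule: mean OVA/PBS log2 ratio over the two treated
  pools above 0.6 or below -0.6 (a 1.52-fold change).  Genes with
  several probe sets count only when every probe agrees in direction
  and at least one probe clears the threshold.
* mRNAs, both-pools rule (feeds the pathway analysis): a >1.5-fold
  change, same sign, in each of the two OVA pools separately.

The two gene rules coexist behind ``rule_tag`` because they feed
different downstream stages: the +-0.6 rule drives the inverse-pair
tables, the both-pools rule the pathway enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import MiRnaMeasurement, ParseError, TimePoint, _write_tsv

RULE_STANDARD = "standard"
RULE_BOTH_POOLS = "both_pools"


@dataclass(frozen=True)
class ModulatedSet:
    """Up/down identifier sets called at one time point under one rule."""

    timepoint: TimePoint
    up: frozenset[str]
    down: frozenset[str]
    kind: str  # "mirna" | "mrna"
    rule_tag: str = RULE_STANDARD
    table: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"ids in both up and down: {sorted(overlap)[:5]}")
        if self.kind not in ("mirna", "mrna"):
            raise ValueError(f"kind must be 'mirna' or 'mrna', got {self.kind!r}")

    @property
    def members(self) -> frozenset[str]:
        return self.up | self.down

    def direction(self, identifier: str) -> str:
        if identifier in self.up:
            return "up"
        if identifier in self.down:
            return "down"
        raise KeyError(identifier)


def call_modulated_mirnas(
    measurements: Sequence[MiRnaMeasurement],
    fc_min: float = 1.5,
    p_max: float = 0.01,
) -> ModulatedSet:
    """Call modulated miRNAs at one time point.

    up: FI >= fc_min and p < p_max; down: FI <= 1/fc_min and p < p_max.
    """
    if fc_min < 1:
        raise ValueError(f"fc_min must be >= 1, got {fc_min}")
    tps = {m.timepoint for m in measurements}
    if len(tps) > 1:
        raise ValueError(f"measurements mix time points: {sorted(t.name for t in tps)}")
    tp = tps.pop() if tps else TimePoint.ST
    rows = []
    for m in measurements:
        if m.p_value >= p_max:
            continue
        if m.fold_induction >= fc_min:
            rows.append((m.mirna_id, "up", m.fold_induction, m.p_value))
        elif m.fold_induction <= 1.0 / fc_min:
            rows.append((m.mirna_id, "down", m.fold_induction, m.p_value))
    table = pd.DataFrame(
        rows, columns=["id", "direction", "fold_induction", "p_value"]
    ).sort_values("id", ignore_index=True)
    return ModulatedSet(
        timepoint=tp,
        up=frozenset(table.loc[table["direction"] == "up", "id"]),
        down=frozenset(table.loc[table["direction"] == "down", "id"]),
        kind="mirna",
        rule_tag=RULE_STANDARD,
        table=table,
    )


def _probe_direction_call(values: np.ndarray, threshold: float) -> str | None:
    """Shared consistency rule: one value per probe, strict sign agreement,
    at least one probe beyond the threshold in the shared direction."""
    if values.size == 0:
        raise ValueError("gene with zero probes")
    if np.all(values > 0) and np.any(values > threshold):
        return "up"
    if np.all(values < 0) and np.any(values < -threshold):
        return "down"
    return None


def call_modulated_genes(
    probe_ratios: pd.DataFrame,
    timepoint: TimePoint,
    log_thr: float = 0.6,
) -> ModulatedSet:
    """Call modulated genes under the +-``log_thr`` mean-log-ratio rule.

    The per-probe statistic is the mean log2 ratio over the two OVA pools;
    multi-probe genes must agree in direction across all probes with at
    least one probe past the threshold.
    """
    if probe_ratios.empty:
        return ModulatedSet(timepoint, frozenset(), frozenset(), "mrna", RULE_STANDARD,
                            pd.DataFrame(columns=["id", "direction", "fold_induction"]))
    mean_ratio = 0.5 * (
        probe_ratios["log_ratio_pool1"].to_numpy(float)
        + probe_ratios["log_ratio_pool2"].to_numpy(float)
    )
    work = pd.DataFrame({"gene_id": probe_ratios["gene_id"].to_numpy(), "m": mean_ratio})
    rows = []
    for gene, grp in work.groupby("gene_id", sort=True):
        call = _probe_direction_call(grp["m"].to_numpy(), log_thr)
        if call is not None:
            fi = float(2.0 ** grp["m"].mean())
            rows.append((gene, call, fi))
    table = pd.DataFrame(rows, columns=["id", "direction", "fold_induction"])
    return ModulatedSet(
        timepoint=timepoint,
        up=frozenset(table.loc[table["direction"] == "up", "id"]),
        down=frozenset(table.loc[table["direction"] == "down", "id"]),
        kind="mrna",
        rule_tag=RULE_STANDARD,
        table=table,
    )


def call_modulated_genes_both_pools(
    probe_ratios: pd.DataFrame,
    timepoint: TimePoint,
    fc_min: float = 1.5,
) -> ModulatedSet:
    """Call genes with a >``fc_min``-fold change, same sign, in both pools.

    "Fold induction greater than 1.5" is read as magnitude in either
    direction (the downstream pathway discussion includes repressed
    genes), i.e. |log2 ratio| > log2(fc_min) with a consistent sign in
    pool 1 and pool 2, aggregating probes with the same consistency rule
    as the standard call.
    """
    thr = math.log2(fc_min)
    if probe_ratios.empty:
        return ModulatedSet(timepoint, frozenset(), frozenset(), "mrna",
                            RULE_BOTH_POOLS,
                            pd.DataFrame(columns=["id", "direction", "fold_induction"]))
    rows = []
    for gene, grp in probe_ratios.groupby("gene_id", sort=True):
        calls = []
        for col in ("log_ratio_pool1", "log_ratio_pool2"):
            calls.append(_probe_direction_call(grp[col].to_numpy(float), thr))
        if calls[0] is not None and calls[0] == calls[1]:
            mean_lr = 0.5 * float(grp["log_ratio_pool1"].mean() + grp["log_ratio_pool2"].mean())
            rows.append((gene, calls[0], float(2.0**mean_lr)))
    table = pd.DataFrame(rows, columns=["id", "direction", "fold_induction"])
    return ModulatedSet(
        timepoint=timepoint,
        up=frozenset(table.loc[table["direction"] == "up", "id"]),
        down=frozenset(table.loc[table["direction"] == "down", "id"]),
        kind="mrna",
        rule_tag=RULE_BOTH_POOLS,
        table=table,
    )


def recurrent_mirnas(
    modulated_sets: Sequence[ModulatedSet], k: int
) -> pd.DataFrame:
    """miRNAs modulated at >= k of the supplied time points.

    Returns a frame indexed by mirna_id with, per time point, the call
    direction and fold induction (empty where not called), plus the
    number of time points at which the miRNA was modulated.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tps = [s.timepoint for s in modulated_sets]
    if len(set(tps)) != len(tps):
        raise ValueError("modulated sets must come from distinct time points")
    order = sorted(range(len(modulated_sets)), key=lambda i: tps[i])
    counts: dict[str, int] = {}
    for s in modulated_sets:
        for m in s.members:
            counts[m] = counts.get(m, 0) + 1
    keep = sorted(m for m, c in counts.items() if c >= k)
    data: dict[str, list] = {}
    for i in order:
        s = modulated_sets[i]
        label = s.timepoint.name
        fi_map: dict[str, float] = {}
        if s.table is not None and len(s.table):
            fi_map = dict(zip(s.table["id"], s.table["fold_induction"]))
        data[f"{label}_direction"] = [
            s.direction(m) if m in s.members else "" for m in keep
        ]
        data[f"{label}_fold_induction"] = [
            fi_map.get(m, np.nan) if m in s.members else np.nan for m in keep
        ]
    out = pd.DataFrame(data, index=pd.Index(keep, name="mirna_id"))
    out["n_timepoints"] = [counts[m] for m in keep]
    return out


def write_modulated_set(
    modulated: ModulatedSet, path: str | Path, header_comment: str | None = None
) -> None:
    """Serialize as TSV: id, timepoint, direction, fold_induction, p_value."""
    if modulated.table is not None and len(modulated.table):
        table = modulated.table.copy()
    else:
        table = pd.DataFrame(
            [(m, modulated.direction(m)) for m in sorted(modulated.members)],
            columns=["id", "direction"],
        )
    table.insert(1, "timepoint", modulated.timepoint.name)
    for col in ("fold_induction", "p_value"):
        if col not in table.columns:
            table[col] = np.nan
    table = table[["id", "timepoint", "direction", "fold_induction", "p_value"]]
    table = table.sort_values("id", ignore_index=True)
    _write_tsv(table, path, header_comment)


def read_modulated_set(
    path: str | Path,
    kind: str,
    rule_tag: str = RULE_STANDARD,
    timepoint: TimePoint | None = None,
) -> ModulatedSet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    required = ["id", "timepoint", "direction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    tps = {TimePoint.parse(t) for t in df["timepoint"].unique()}
    if len(tps) > 1:
        raise ParseError(f"{path}: mixed time points in one modulated set")
    if tps:
        tp = tps.pop()
        if timepoint is not None and tp != timepoint:
            raise ParseError(f"{path}: expected {timepoint.name}, found {tp.name}")
    elif timepoint is not None:
        tp = timepoint
    else:
        raise ParseError(f"{path}: empty set; supply the expected time point")
    table = df.drop(columns=["timepoint"])
    return ModulatedSet(
        timepoint=tp,
        up=frozenset(df.loc[df["direction"] == "up", "id"]),
        down=frozenset(df.loc[df["direction"] == "down", "id"]),
        kind=kind,
        rule_tag=rule_tag,
        table=table,
    )
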