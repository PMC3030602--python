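"""Domain types, identifier normalization and tabular I/O.

The pipeline exchanges four kinds of tables, all UTF-8, tab-separated,
with a mandatory header row (lines starting with ``#`` are provenance
comments and are skipped):

* miRNA measurements — one fold induction (OVA/PBS ratio) and t-test
  p-value per miRNA per time point;
* mRNA probe ratios — probe-level log2 ratios of each of the two
  OVA-treated pools against the PBS control;
* target predictions — sparse (miRNA, gene) edges with a per-prediction
  p-value, from one of two prediction databases;
* pathway gene sets — standard GMT.

Gene identifiers are matched across sources by upper-cased symbol: the
mRNA arrays, the prediction databases and the pathway sets all use gene
symbols but with inconsistent casing, so every reader funnels gene ids
through :func:`normalize_gene_id`.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MICROCOSM = "microcosm"
TARGETSCAN = "targetscan"
SOURCE_DBS = (MICROCOSM, TARGETSCAN)


class InvalidIdentifierError(ValueError):
    """Raised for empty or malformed identifiers."""


class ParseError(ValueError):
    """Raised when a table violates the file contract; names the row."""


class UniverseError(ValueError):
    """Raised when identifiers fall outside the declared chip/array universe."""


class TimePoint(enum.IntEnum):
    """Allergen-exposure time point: short-, intermediate- or long-term.

    The three labels are ordered ST < IT < LT.
    """

    ST = 0
    IT = 1
    LT = 2

    @classmethod
    def parse(cls, label: object) -> "TimePoint":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ParseError(
                f"unknown time point {label!r}; expected one of ST, IT, LT"
            ) from None


def normalize_gene_id(raw: str) -> str:
    """Case-fold a gene symbol to its canonical matching form.

    Upper-cases and strips surrounding whitespace; idempotent.
    """
    if raw is None:
        raise InvalidIdentifierError("gene identifier is None")
    out = str(raw).strip().upper()
    if not out:
        raise InvalidIdentifierError(f"empty gene identifier: {raw!r}")
    return out


def _check_source_db(source_db: str) -> str:
    if source_db not in SOURCE_DBS:
        raise ValueError(f"unknown source_db {source_db!r}; expected one of {SOURCE_DBS}")
    return source_db


@dataclass(frozen=True)
class MiRnaMeasurement:
    """One miRNA at one time point: fold induction (OVA/PBS) and t-test p."""

    mirna_id: str
    timepoint: TimePoint
    fold_induction: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.mirna_id:
            raise InvalidIdentifierError("empty mirna_id")
        if not np.isfinite(self.fold_induction) or self.fold_induction <= 0:
            raise ValueError(
                f"{self.mirna_id}: fold_induction must be a positive finite "
                f"ratio, got {self.fold_induction!r}"
            )
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(
                f"{self.mirna_id}: p_value must lie in [0, 1], got {self.p_value!r}"
            )


@dataclass(frozen=True)
class TargetPrediction:
    """A predicted (miRNA, gene) regulation edge from one database."""

    mirna_id: str
    gene_id: str
    p_value: float
    source_db: str

    def __post_init__(self) -> None:
        if not self.mirna_id:
            raise InvalidIdentifierError("empty mirna_id")
        object.__setattr__(self, "gene_id", normalize_gene_id(self.gene_id))
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(
                f"{self.mirna_id}->{self.gene_id}: p_value must lie in [0, 1]"
            )
        _check_source_db(self.source_db)


@dataclass(frozen=True)
class Pathway:
    """A named gene set (e.g. WP441, the matrix metalloproteinase pathway)."""

    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise InvalidIdentifierError("empty pathway_id")
        if not self.genes:
            raise ValueError(f"{self.pathway_id}: pathway gene set must be non-empty")
        object.__setattr__(
            self, "genes", frozenset(normalize_gene_id(g) for g in self.genes)
        )


@dataclass(frozen=True)
class Universe:
    """The measurement universes: miRNAs on the chip, genes on the array.

    The study design nominally carries 566 miRNAs and 20,461 genes; the
    permutation and hypergeometric nulls are both defined against these
    reference sets, so every measurement identifier must be a member.
    """

    mirna_ids: frozenset[str]
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mirna_ids", frozenset(self.mirna_ids))
        object.__setattr__(
            self, "gene_ids", frozenset(normalize_gene_id(g) for g in self.gene_ids)
        )

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_READ_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _to_float(value: str, what: str, row: int, path: object) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"{path}, row {row}: malformed {what} {value!r}") from None


def read_mirna_table(path: str | Path) -> list[MiRnaMeasurement]:
    """Read a miRNA measurement table.

    Required columns: mirna_id, timepoint, fold_induction, p_value.
    Enforces positive fold inductions, p in [0, 1] and uniqueness of
    (mirna_id, timepoint); errors name the offending data row (1-based).
    """
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, ["mirna_id", "timepoint", "fold_induction", "p_value"], path)
    out: list[MiRnaMeasurement] = []
    seen: set[tuple[str, TimePoint]] = set()
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        tp = TimePoint.parse(rec.timepoint)
        fi = _to_float(rec.fold_induction, "fold_induction", i, path)
        p = _to_float(rec.p_value, "p_value", i, path)
        try:
            m = MiRnaMeasurement(rec.mirna_id, tp, fi, p)
        except ValueError as exc:
            raise ParseError(f"{path}, row {i}: {exc}") from None
        key = (m.mirna_id, m.timepoint)
        if key in seen:
            raise ParseError(f"{path}, row {i}: duplicate (mirna_id, timepoint) {key}")
        seen.add(key)
        out.append(m)
    return out


def measurements_to_frame(measurements: Iterable[MiRnaMeasurement]) -> pd.DataFrame:
    rows = [
        (m.mirna_id, m.timepoint.name, m.fold_induction, m.p_value)
        for m in measurements
    ]
    return pd.DataFrame(
        rows, columns=["mirna_id", "timepoint", "fold_induction", "p_value"]
    )


def write_mirna_table(
    measurements: Iterable[MiRnaMeasurement],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Serialize measurements at full precision (rounding is report-only)."""
    df = measurements_to_frame(measurements)
    _write_tsv(df, path, header_comment)


def read_mrna_table(path: str | Path) -> pd.DataFrame:
    """Read probe-level mRNA log2 ratios (two OVA pools vs the PBS control).

    Required columns: gene_id, probe_id, log_ratio_pool1, log_ratio_pool2.
    Gene ids are normalized; probe ids must be unique; ratios finite.
    """
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(
        df, ["gene_id", "probe_id", "log_ratio_pool1", "log_ratio_pool2"], path
    )
    genes, p1, p2 = [], [], []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            genes.append(normalize_gene_id(rec.gene_id))
        except InvalidIdentifierError as exc:
            raise ParseError(f"{path}, row {i}: {exc}") from None
        a = _to_float(rec.log_ratio_pool1, "log_ratio_pool1", i, path)
        b = _to_float(rec.log_ratio_pool2, "log_ratio_pool2", i, path)
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ParseError(f"{path}, row {i}: non-finite log ratio")
        p1.append(a)
        p2.append(b)
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "probe_id": df["probe_id"].astype(str).to_numpy(),
            "log_ratio_pool1": p1,
            "log_ratio_pool2": p2,
        }
    )
    dup = out["probe_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise ParseError(f"{path}, row {row}: duplicate probe_id {out['probe_id'][dup].iloc[0]!r}")
    return out


def read_target_predictions(path: str | Path, source_db: str) -> pd.DataFrame:
    """Read a target-prediction table (columns mirna_id, gene_id, p_value).

    Gene ids are normalized and duplicate (miRNA, gene) edges are collapsed
    keeping the minimum p-value: the emulated databases list one entry per
    predicted binding site while downstream pairing needs one edge per gene.
    The p < 0.05 target filter is applied at the pairing stage, not here.
    """
    _check_source_db(source_db)
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, ["mirna_id", "gene_id", "p_value"], path)
    genes, ps = [], []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            genes.append(normalize_gene_id(rec.gene_id))
        except InvalidIdentifierError as exc:
            raise ParseError(f"{path}, row {i}: {exc}") from None
        p = _to_float(rec.p_value, "p_value", i, path)
        if not (0.0 <= p <= 1.0):
            raise ParseError(f"{path}, row {i}: p_value {p} outside [0, 1]")
        ps.append(p)
    out = pd.DataFrame(
        {
            "mirna_id": df["mirna_id"].astype(str).to_numpy(),
            "gene_id": genes,
            "p_value": ps,
        }
    )
    out["source_db"] = source_db
    return dedupe_predictions(out)


def dedupe_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (miRNA, gene, db) edges keeping the minimum p."""
    out = (
        predictions.sort_values(["mirna_id", "gene_id", "source_db", "p_value"])
        .drop_duplicates(subset=["mirna_id", "gene_id", "source_db"], keep="first")
        .reset_index(drop=True)
    )
    return out


def read_gmt(path: str | Path) -> list[Pathway]:
    """Read pathways from a GMT file (name <tab> description <tab> gene...)."""
    pathways: list[Pathway] = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}, line {i}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ParseError(f"{path}, line {i}: pathway {name!r} has no genes")
            pathways.append(Pathway(name, desc, frozenset(genes)))
    return pathways


def write_gmt(pathways: Iterable[Pathway], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


def read_universe(path: str | Path) -> Universe:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return Universe(frozenset(payload["mirna_ids"]), frozenset(payload["gene_ids"]))


def write_universe(
    universe: Universe, path: str | Path, provenance: dict | None = None
) -> None:
    payload = {
        "n_mirnas": universe.n_mirnas,
        "n_genes": universe.n_genes,
        "mirna_ids": sorted(universe.mirna_ids),
        "gene_ids": sorted(universe.gene_ids),
    }
    if provenance:
        payload["provenance"] = provenance
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def validate_in_universe(
    measurements: Iterable[MiRnaMeasurement], universe: Universe
) -> None:
    """Raise :class:`UniverseError` if any measurement is off-chip."""
    outside = sorted(
        {m.mirna_id for m in measurements if m.mirna_id not in universe.mirna_ids}
    )
    if outside:
        raise UniverseError(
            f"{len(outside)} miRNA id(s) outside the declared chip universe, "
            f"e.g. {outside[:5]}"
        )


def _write_tsv(
    df: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
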