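"""Pathway enrichment combining miRNA-target and mRNA evidence.

For every pathway, time point and prediction database:

* observed pair count — the number of distinct (miRNA, gene) pairs with
  the miRNA modulated, the gene in the pathway, and a predicted edge
  between them;
* p_mirna — permutation p-value: the proportion of trials (default
  1000) in which a uniform random draw of the same number of miRNAs
  from the chip universe yields a pair count at least as high
  (inclusive tie rule);
* p_mrna — upper-tail hypergeometric probability of the overlap between
  the modulated genes and the pathway, against the array's gene
  universe;
* p_combined — Stouffer's method with equal weights,
  ``1 - Phi((z1 + z2) / sqrt(2))`` with ``z_i = Phi^-1(1 - p_i)``.

Pathways are selected at combined p < 0.05 (no multiplicity correction
is applied for selection; a Benjamini-Hochberg column is emitted for
reference only).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import Pathway, Universe, dedupe_predictions  # noqa: F401
from .differential import ModulatedSet

#: permutation p-values of exactly zero (observed count beyond every trial)
#: are clamped to 1 / (2 * n_trials) before the inverse-normal transform,
#: which would otherwise be infinite; the clamp preserves ranking.
ZERO_CLAMP_FACTOR = 0.5

RESULT_COLUMNS = [
    "pathway_id",
    "timepoint",
    "source_db",
    "observed_pairs",
    "p_mirna",
    "p_mrna",
    "p_combined",
    "p_bh",
    "n_trials",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Number of null trials and the master seed for the permutation test."""

    n_trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def derive_seed(master_seed: int, *labels: str) -> int:
    """Stable per-(timepoint, db) stream seed from the master seed."""
    digest = hashlib.sha256(
        (":".join([str(master_seed), *labels])).encode("utf-8")
    ).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _edge_index(predictions: pd.DataFrame) -> pd.DataFrame:
    preds = dedupe_predictions(predictions)
    return preds[["mirna_id", "gene_id"]]


def count_target_pairs(
    pathway_genes: Iterable[str],
    modulated_mirna_ids: Iterable[str],
    predictions: pd.DataFrame,
) -> int:
    """Count distinct (miRNA, gene) edges from modulated miRNAs into a pathway."""
    genes = set(pathway_genes)
    mirnas = set(modulated_mirna_ids)
    if not genes or not mirnas:
        return 0
    edges = _edge_index(predictions)
    mask = edges["mirna_id"].isin(mirnas) & edges["gene_id"].isin(genes)
    return int(mask.sum())


def _pathway_degrees(
    pathway_gene_sets: Sequence[frozenset[str]],
    universe_mirnas: Sequence[str],
    predictions: pd.DataFrame,
) -> np.ndarray:
    """Matrix D[p, u] = number of predicted targets of miRNA u inside pathway p."""
    edges = _edge_index(predictions)
    mirna_pos = {m: i for i, m in enumerate(universe_mirnas)}
    D = np.zeros((len(pathway_gene_sets), len(universe_mirnas)), dtype=np.int64)
    if not len(edges):
        return D
    membership = pd.DataFrame(
        [
            (g, pi)
            for pi, genes in enumerate(pathway_gene_sets)
            for g in genes
        ],
        columns=["gene_id", "pathway_idx"],
    )
    work = edges[edges["mirna_id"].isin(mirna_pos)].copy()
    work["mirna_idx"] = work["mirna_id"].map(mirna_pos)
    hits = work.merge(membership, on="gene_id")
    if len(hits):
        np.add.at(
            D,
            (hits["pathway_idx"].to_numpy(), hits["mirna_idx"].to_numpy()),
            1,
        )
    return D


def _null_counts(
    degrees: np.ndarray, n_modulated: int, cfg: PermutationConfig
) -> np.ndarray:
    """Null pair counts, shape (n_pathways, n_trials), one shared draw per trial."""
    rng = np.random.default_rng(cfg.seed)
    n_universe = degrees.shape[1]
    if n_modulated == 0:
        return np.zeros((degrees.shape[0], cfg.n_trials), dtype=np.int64)
    # uniform without-replacement subsets via random-key argsort
    keys = rng.random((cfg.n_trials, n_universe))
    idx = np.argsort(keys, axis=1)[:, :n_modulated]
    return degrees[:, idx].sum(axis=2)


def permutation_pvalue(
    pathway_genes: Iterable[str],
    modulated_mirna_ids: Iterable[str],
    universe_mirnas: Iterable[str],
    predictions: pd.DataFrame,
    cfg: PermutationConfig = PermutationConfig(),
) -> tuple[float, int]:
    """Permutation p for one pathway; returns (p_mirna, observed_pairs).

    Each trial draws ``len(modulated)`` miRNAs uniformly without
    replacement from the chip universe and recounts the pairs;
    p = #(trial count >= observed) / n_trials, with an exact zero
    clamped to 1 / (2 n_trials).
    """
    universe = sorted(set(universe_mirnas))
    modulated = sorted(set(modulated_mirna_ids))
    if not set(modulated) <= set(universe):
        raise ValueError("modulated miRNAs must be a subset of the universe")
    genes = frozenset(pathway_genes)
    observed = count_target_pairs(genes, modulated, predictions)
    degrees = _pathway_degrees([genes], universe, predictions)
    null = _null_counts(degrees, len(modulated), cfg)[0]
    p = float(np.mean(null >= observed))
    if p == 0.0:
        p = ZERO_CLAMP_FACTOR / cfg.n_trials
    return p, observed


def hypergeom_pvalue(
    pathway_genes: Iterable[str],
    modulated_gene_ids: Iterable[str],
    gene_universe: Iterable[str],
) -> float:
    """Upper-tail hypergeometric P(X >= k) for pathway/modulated overlap.

    Population = gene universe, successes = modulated genes, draws =
    pathway genes restricted to the universe, observed k = overlap.
    """
    universe = set(gene_universe)
    modulated = set(modulated_gene_ids)
    if not modulated <= universe:
        raise ValueError("modulated genes must be a subset of the gene universe")
    pathway = set(pathway_genes) & universe
    if not pathway:
        warnings.warn(
            "pathway has no genes in the universe; reporting p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    k = len(pathway & modulated)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(modulated), len(pathway)))


def stouffer_combine(p_mirna: float, p_mrna: float) -> float:
    """Combine two p-values with Stouffer's method, equal weights."""
    out = []
    for p in (p_mirna, p_mrna):
        if not (0.0 <= p <= 1.0) or not np.isfinite(p):
            raise ValueError(f"p-value outside [0, 1]: {p!r}")
        out.append(min(max(p, 1e-300), 1.0))
    z = stats.norm.isf(out[0]) + stats.norm.isf(out[1])
    return float(stats.norm.sf(z / np.sqrt(2.0)))


def run_pathway_analysis(
    pathways: Sequence[Pathway],
    modulated_mirnas: Mapping[object, ModulatedSet],
    modulated_genes: Mapping[object, ModulatedSet],
    predictions_by_db: Mapping[str, pd.DataFrame],
    universe: Universe,
    cfg: PermutationConfig = PermutationConfig(),
    select_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict[tuple[str, str], set[str]]]:
    """Full enrichment table plus selections at combined p < threshold.

    ``modulated_mirnas`` / ``modulated_genes`` map each time point to its
    ModulatedSet (up and down members are pooled — modulation in either
    direction counts).  One permutation stream per (timepoint, db),
    derived from the master seed; within a stream the same random miRNA
    subsets score every pathway (statistically identical per pathway and
    cheaper than independent draws).
    """
    universe_mirnas = sorted(universe.mirna_ids)
    gene_universe = universe.gene_ids
    pathway_genes = [frozenset(p.genes & gene_universe) for p in pathways]
    rows = []
    selections: dict[tuple[str, str], set[str]] = {}
    timepoints = sorted(modulated_mirnas.keys())
    for db in sorted(predictions_by_db.keys()):
        predictions = predictions_by_db[db]
        degrees = _pathway_degrees(pathway_genes, universe_mirnas, predictions)
        for tp in timepoints:
            mirna_set = modulated_mirnas[tp]
            gene_set = modulated_genes[tp]
            if not mirna_set.members <= set(universe_mirnas):
                raise ValueError("modulated miRNAs outside the chip universe")
            modulated = sorted(mirna_set.members)
            mirna_pos = {m: i for i, m in enumerate(universe_mirnas)}
            mod_idx = np.array([mirna_pos[m] for m in modulated], dtype=np.int64)
            observed = (
                degrees[:, mod_idx].sum(axis=1)
                if mod_idx.size
                else np.zeros(len(pathways), dtype=np.int64)
            )
            stream = PermutationConfig(
                n_trials=cfg.n_trials,
                seed=derive_seed(cfg.seed, getattr(tp, "name", str(tp)), db),
            )
            null = _null_counts(degrees, len(modulated), stream)
            p_mirna = (null >= observed[:, None]).mean(axis=1)
            p_mirna = np.where(
                p_mirna == 0.0, ZERO_CLAMP_FACTOR / stream.n_trials, p_mirna
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p_mrna = np.array(
                    [
                        hypergeom_pvalue(genes, gene_set.members, gene_universe)
                        if genes
                        else 1.0
                        for genes in pathway_genes
                    ]
                )
            p_combined = np.array(
                [stouffer_combine(a, b) for a, b in zip(p_mirna, p_mrna)]
            )
            p_bh = multipletests(p_combined, method="fdr_bh")[1]
            tp_label = getattr(tp, "name", str(tp))
            for i, pw in enumerate(pathways):
                rows.append(
                    (
                        pw.pathway_id,
                        tp_label,
                        db,
                        int(observed[i]),
                        float(p_mirna[i]),
                        float(p_mrna[i]),
                        float(p_combined[i]),
                        float(p_bh[i]),
                        stream.n_trials,
                    )
                )
            selections[(tp_label, db)] = {
                pathways[i].pathway_id
                for i in range(len(pathways))
                if p_combined[i] < select_threshold
            }
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return results, selections


def overlap_summary(selected_by_timepoint: Mapping[object, Iterable[str]]) -> dict:
    """Partition selected pathways by how many time points selected them."""
    counts: dict[str, int] = {}
    for sel in selected_by_timepoint.values():
        for pid in set(sel):
            counts[pid] = counts.get(pid, 0) + 1
    n_tp = len(selected_by_timepoint)
    summary = {
        f"exactly_{j}": sorted(p for p, c in counts.items() if c == j)
        for j in range(1, n_tp + 1)
    }
    out = {k: len(v) for k, v in summary.items()}
    out["union"] = len(counts)
    out["all_timepoints"] = summary.get(f"exactly_{n_tp}", [])
    return out
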