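"""Inversely-correlated miRNA-mRNA pairs against target predictions.

A pair is emitted when the miRNA and the gene are both modulated at the
same time point in *opposite* directions (miRNA down with its target up,
or the reverse — the expected signature of miRNA-driven repression) and
the prediction database links them with p < 0.05.
"""

from __future__ import annotations

import pandas as pd

from .data_model import dedupe_predictions
from .differential import ModulatedSet

PAIR_COLUMNS = [
    "mirna_id",
    "gene_id",
    "timepoint",
    "mirna_direction",
    "gene_direction",
    "prediction_p",
    "source_db",
]


def inverse_pairs(
    mirna_set: ModulatedSet,
    gene_set: ModulatedSet,
    predictions: pd.DataFrame,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Cross modulated miRNAs and genes through predicted target edges.

    The prediction filter is strict (p < ``p_max``); duplicate edges are
    collapsed to their minimum p first.  Output is sorted by
    (mirna_id, gene_id) and independent of input ordering.
    """
    if mirna_set.timepoint != gene_set.timepoint:
        raise ValueError(
            f"time-point mismatch: miRNAs at {mirna_set.timepoint.name}, "
            f"genes at {gene_set.timepoint.name}"
        )
    preds = dedupe_predictions(predictions)
    preds = preds[preds["p_value"] < p_max]
    rows = []
    mirna_members = mirna_set.members
    gene_members = gene_set.members
    for rec in preds.itertuples(index=False):
        if rec.mirna_id not in mirna_members or rec.gene_id not in gene_members:
            continue
        md = mirna_set.direction(rec.mirna_id)
        gd = gene_set.direction(rec.gene_id)
        if md == gd:
            continue
        rows.append(
            (
                rec.mirna_id,
                rec.gene_id,
                mirna_set.timepoint.name,
                md,
                gd,
                rec.p_value,
                rec.source_db,
            )
        )
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return out.sort_values(["mirna_id", "gene_id", "source_db"], ignore_index=True)


def recurrent_pairs(pairs_a: pd.DataFrame, pairs_b: pd.DataFrame) -> pd.DataFrame:
    """Pairs present (same miRNA, gene, database) at both time points.

    Per-time-point directions are retained — they may flip between time
    points, as for the early-repressed / late-induced miRNAs.
    """
    for df, name in ((pairs_a, "pairs_a"), (pairs_b, "pairs_b")):
        missing = [c for c in PAIR_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{name} missing column(s) {missing}")
    label_a = pairs_a["timepoint"].iloc[0] if len(pairs_a) else "a"
    label_b = pairs_b["timepoint"].iloc[0] if len(pairs_b) else "b"
    merged = pairs_a.merge(
        pairs_b,
        on=["mirna_id", "gene_id", "source_db"],
        suffixes=(f"_{label_a}", f"_{label_b}"),
    )
    return merged.sort_values(["mirna_id", "gene_id", "source_db"], ignore_index=True)
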