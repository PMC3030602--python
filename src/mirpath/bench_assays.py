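"""Bench-assay arithmetic: qPCR 2^-ddCt, platform concordance, reporter assays.

qPCR quantification follows the comparative-Ct convention: each target
assay is normalized against housekeeping references within the same
sample (delta Ct), the group difference OVA - PBS gives delta-delta Ct,
and the fold change is 2 ** -ddCt.  mRNA assays use the mean of two
housekeeping genes (beta-2-microglobulin and HPRT1); miRNA assays use
U6 as the single reference.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CT_MIN, CT_MAX = 0.0, 45.0


def _mean(values: Sequence[float], what: str) -> float:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty {what}")
    return float(arr.mean())


def delta_ct(
    target_cts: Sequence[float],
    reference_cts: Sequence[Sequence[float]],
) -> float:
    """delta Ct = mean(target Ct) - mean of the per-reference mean Cts.

    ``reference_cts`` holds one Ct collection per reference assay; the
    aggregate is the arithmetic mean of the per-assay means (the choice
    is configurable only in the sense that callers may pre-aggregate).
    """
    refs = list(reference_cts)
    if not refs:
        raise ValueError("missing reference assay(s) for delta Ct")
    ref_means = [_mean(r, "reference Ct set") for r in refs]
    return _mean(target_cts, "target Ct set") - float(np.mean(ref_means))


def fold_change_ddct(
    delta_ct_ova: Sequence[float], delta_ct_pbs: Sequence[float]
) -> float:
    """2 ** -(mean dCt OVA - mean dCt PBS)."""
    ddct = _mean(delta_ct_ova, "OVA delta-Ct group") - _mean(
        delta_ct_pbs, "PBS delta-Ct group"
    )
    return float(2.0**-ddct)


def _validate_ct_table(ct: pd.DataFrame) -> None:
    required = ["sample_id", "group", "timepoint", "assay_id", "is_reference", "ct"]
    missing = [c for c in required if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s) {missing}")
    vals = ct["ct"].to_numpy(float)
    bad = ~((vals > CT_MIN) & (vals < CT_MAX))
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} Ct value(s) outside ({CT_MIN}, {CT_MAX}), "
            f"e.g. {vals[bad][0]}"
        )


def delta_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample, target assay) delta Ct from a long Ct table.

    Expects columns sample_id, group, timepoint, assay_id, is_reference,
    ct (one or more technical replicates per row group).  Every sample
    must carry at least one reference assay.
    """
    _validate_ct_table(ct)
    is_ref = ct["is_reference"].astype(bool)
    rows = []
    for sample, sub in ct.groupby("sample_id", sort=True):
        refs = sub[is_ref.loc[sub.index]]
        targets = sub[~is_ref.loc[sub.index]]
        if refs.empty:
            raise ValueError(f"sample {sample!r}: no reference assay")
        ref_cts = [
            grp["ct"].to_numpy(float) for _, grp in refs.groupby("assay_id", sort=True)
        ]
        for assay, grp in targets.groupby("assay_id", sort=True):
            rows.append(
                (
                    sample,
                    grp["group"].iloc[0],
                    grp["timepoint"].iloc[0],
                    assay,
                    delta_ct(grp["ct"].to_numpy(float), ref_cts),
                )
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "timepoint", "assay_id", "delta_ct"]
    )


def fold_changes_from_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Per-(assay, time point) 2^-ddCt fold changes, OVA vs PBS."""
    dct = delta_ct_table(ct)
    rows = []
    for (assay, tp), sub in dct.groupby(["assay_id", "timepoint"], sort=True):
        ova = sub.loc[sub["group"] == "OVA", "delta_ct"].to_numpy(float)
        pbs = sub.loc[sub["group"] == "PBS", "delta_ct"].to_numpy(float)
        rows.append((assay, tp, fold_change_ddct(ova, pbs)))
    return pd.DataFrame(rows, columns=["assay_id", "timepoint", "fold_change"])


def platform_concordance(
    fold_changes: pd.DataFrame, band: float = 1.0
) -> tuple[pd.DataFrame, int]:
    """Flag per-assay concordance between microarray and qPCR fold changes.

    Direction on each platform is up/down by the sign of log(FC); fold
    changes strictly inside (1/band, band) count as "no change".  With
    the default band of 1.0 this reduces to a pure sign rule.  Returns
    the flagged table and the percent concordant, rounded to an integer
    as reported.
    """
    required = ["fc_microarray", "fc_qpcr"]
    missing = [c for c in required if c not in fold_changes.columns]
    if missing:
        raise ValueError(f"fold-change table missing column(s) {missing}")
    if band < 1.0:
        raise ValueError("band must be >= 1.0")
    fa = fold_changes["fc_microarray"].to_numpy(float)
    fb = fold_changes["fc_qpcr"].to_numpy(float)
    if np.any(fa <= 0) or np.any(fb <= 0):
        raise ValueError("fold changes must be positive")

    def direction(fc: np.ndarray) -> np.ndarray:
        d = np.sign(np.log(fc))
        if band > 1.0:
            d[(fc > 1.0 / band) & (fc < band)] = 0.0
        return d

    flags = direction(fa) == direction(fb)
    out = fold_changes.copy()
    out["concordant"] = flags
    percent = int(round(100.0 * flags.mean())) if len(flags) else 0
    return out, percent


def reporter_knockdown(
    activity_with_mirna: float,
    activity_with_control: float,
    protein_with_mirna: float = 1.0,
    protein_with_control: float = 1.0,
) -> float:
    """Protein-normalized luciferase activity as percent of control (=100)."""
    for name, v in (
        ("activity_with_mirna", activity_with_mirna),
        ("activity_with_control", activity_with_control),
        ("protein_with_mirna", protein_with_mirna),
        ("protein_with_control", protein_with_control),
    ):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v!r}")
    specific = activity_with_mirna / protein_with_mirna
    control = activity_with_control / protein_with_control
    return 100.0 * specific / control
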