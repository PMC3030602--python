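"""Two-color miRNA array processing: background, cyclic loess, fold calls.

Raw per-probe intensities from the two channels (Cy3 carrying the
OVA-treated pool, Cy5 the PBS control, two replicate hybridizations)
are background-subtracted, log2-transformed, and normalized with a
cyclic loess filter: for every pair of channel columns a loess curve is
fitted in MA coordinates (A = mean, M = difference of the two columns)
and subtracted symmetrically, iterating over all pairs for a fixed
number of cycles.  Per-miRNA fold inductions are then the anti-log of
the mean per-probe log2 ratio, with a two-sided one-sample t-test of
the log ratios against zero.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_model import MiRnaMeasurement, ParseError, TimePoint

CHANNEL_OVA = "cy3_ova"
CHANNEL_PBS = "cy5_pbs"

#: default floor applied after background subtraction, in intensity units;
#: keeps the subsequent log2 finite on over-subtracted probes.
DEFAULT_FLOOR = 1.0

#: loess span (fraction of points in each local fit) and number of cycles.
#: The filter is conventional MA normalization: span 0.4, locally linear,
#: three full passes over all column pairs.
DEFAULT_SPAN = 0.4
DEFAULT_CYCLES = 3


def subtract_background(
    raw: np.ndarray | Sequence[float],
    background: np.ndarray | Sequence[float],
    floor: float = DEFAULT_FLOOR,
) -> np.ndarray:
    """Background-correct intensities: ``max(raw - background, floor)``.

    The floor (default 1.0 intensity unit) absorbs probes whose local
    background estimate exceeds the foreground, so no error is raised.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if raw.shape != background.shape:
        raise ValueError("raw and background must have identical shapes")
    return np.maximum(raw - background, floor)


def cyclic_loess_normalize(
    matrix: np.ndarray,
    span: float = DEFAULT_SPAN,
    n_cycles: int = DEFAULT_CYCLES,
) -> np.ndarray:
    """Cyclic loess normalization of a probes x channels log2 matrix.

    For each ordered pair of columns (j, k) the loess fit of
    M = col_j - col_k on A = (col_j + col_k) / 2 is split evenly between
    the two columns (col_j loses half the fitted trend, col_k gains it),
    which removes intensity-dependent dye bias while leaving each probe
    row's grand mean unchanged.  Column order is preserved.
    """
    x = np.array(matrix, dtype=float, copy=True)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix entries must be finite")
    if not (0 < span <= 1):
        raise ValueError(f"span must lie in (0, 1], got {span}")
    n = x.shape[0]
    # with very few probes the nominal span may cover <2 points; widen it
    frac = min(1.0, max(span, 3.0 / max(n, 3)))
    for _ in range(int(n_cycles)):
        for j, k in combinations(range(x.shape[1]), 2):
            a = 0.5 * (x[:, j] + x[:, k])
            m = x[:, j] - x[:, k]
            fit = lowess(m, a, frac=frac, return_sorted=False)
            x[:, j] -= 0.5 * fit
            x[:, k] += 0.5 * fit
    return x


def fold_and_pvalue(
    log_ratios: np.ndarray | Sequence[float],
    mirna_id: str,
    timepoint: TimePoint,
) -> MiRnaMeasurement:
    """Summarize normalized per-probe log2 ratios into one measurement.

    fold_induction = 2 ** mean(log2 ratios); p_value is the two-sided
    one-sample t-test of the log ratios against zero.  Degenerate
    zero-variance inputs report p = 1 when the mean is exactly zero and
    p = 0 (with a warning) otherwise, rather than failing.
    """
    r = np.asarray(log_ratios, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError(
            f"{mirna_id}: need >=2 log-ratio observations for a t-test, got {r.size}"
        )
    if not np.all(np.isfinite(r)):
        raise ValueError(f"{mirna_id}: log ratios must be finite")
    mean = float(np.mean(r))
    fi = float(2.0**mean)
    if np.std(r, ddof=1) == 0.0:
        if mean == 0.0:
            p = 1.0
        else:
            warnings.warn(
                f"{mirna_id}: zero-variance log ratios with nonzero mean; "
                "reporting p = 0",
                RuntimeWarning,
                stacklevel=2,
            )
            p = 0.0
    else:
        p = float(stats.ttest_1samp(r, 0.0).pvalue)
    return MiRnaMeasurement(mirna_id, timepoint, fi, p)


def normalize_probe_signals(
    signals: pd.DataFrame,
    floor: float = DEFAULT_FLOOR,
    span: float = DEFAULT_SPAN,
    n_cycles: int = DEFAULT_CYCLES,
) -> pd.DataFrame:
    """Turn a raw probe-signal table into per-probe-per-replicate log2 ratios.

    ``signals`` needs columns mirna_id, probe_index, replicate, channel
    (cy3_ova / cy5_pbs), raw, background.  All channel columns are
    background-corrected, log2-transformed and jointly cyclic-loess
    normalized; the returned frame holds one OVA-vs-PBS log2 ratio per
    (mirna_id, probe_index, replicate).
    """
    required = ["mirna_id", "probe_index", "replicate", "channel", "raw", "background"]
    missing = [c for c in required if c not in signals.columns]
    if missing:
        raise ParseError(f"probe-signal table missing column(s) {missing}")
    channels = set(signals["channel"].unique())
    if not channels <= {CHANNEL_OVA, CHANNEL_PBS}:
        raise ParseError(f"unknown channel label(s) {sorted(channels - {CHANNEL_OVA, CHANNEL_PBS})}")
    corrected = subtract_background(
        signals["raw"].to_numpy(float), signals["background"].to_numpy(float), floor
    )
    work = signals[["mirna_id", "probe_index", "replicate", "channel"]].copy()
    work["log2"] = np.log2(corrected)
    wide = work.pivot_table(
        index=["mirna_id", "probe_index"],
        columns=["replicate", "channel"],
        values="log2",
        aggfunc="first",
        sort=True,
    )
    if wide.isna().any().any():
        raise ParseError("every probe needs both channels in every replicate")
    wide = wide.sort_index(axis=1)
    norm = cyclic_loess_normalize(wide.to_numpy(float), span=span, n_cycles=n_cycles)
    norm = pd.DataFrame(norm, index=wide.index, columns=wide.columns)
    replicates = sorted({rep for rep, _ in wide.columns})
    frames = []
    for rep in replicates:
        ratio = norm[(rep, CHANNEL_OVA)] - norm[(rep, CHANNEL_PBS)]
        frame = ratio.rename("log2_ratio").reset_index()
        frame["replicate"] = rep
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[["mirna_id", "probe_index", "replicate", "log2_ratio"]].sort_values(
        ["mirna_id", "probe_index", "replicate"], ignore_index=True
    )


def summarize_mirnas(
    ratios: pd.DataFrame, timepoint: TimePoint
) -> list[MiRnaMeasurement]:
    """Apply :func:`fold_and_pvalue` per miRNA over all probes x replicates."""
    out = []
    for mirna_id, group in ratios.groupby("mirna_id", sort=True):
        out.append(
            fold_and_pvalue(group["log2_ratio"].to_numpy(float), str(mirna_id), timepoint)
        )
    return out
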