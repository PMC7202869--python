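"""Sliding-window copy-ratio scan between a test and a reference sample.

Reads are binned by leftmost mapped base into windows tiling the scaffold;
each window's test/reference count pair is scored with an exact two-sided
binomial test of the null that the window's share of reads matches the
library-size ratio, log2 ratios are normalised by the two totals (so a
global depth rescaling of either sample cancels), p-values are
Benjamini-Hochberg adjusted over the whole scan, and maximal passing runs
are merged into amplified segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .formats_io import AlignmentRecord, GenomicInterval

DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 5_000


@dataclass(frozen=True)
class AmplifiedSegment:
    interval: GenomicInterval
    mean_log2_ratio: float
    n_windows: int
    min_q: float


def window_counts(
    alignments: Iterable[AlignmentRecord],
    scaffold: str,
    scaffold_length: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Per-window read counts; a read belongs to every window containing
    its leftmost mapped base.  Windows tile [0, scaffold_length) with the
    given step; an empty alignment set yields all-zero windows.
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    starts = np.arange(0, scaffold_length, step)
    ends = np.minimum(starts + window, scaffold_length)
    pos = np.sort(
        np.fromiter(
            (a.pos for a in alignments if a.scaffold == scaffold),
            dtype=np.int64,
        )
    )
    counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
    return pd.DataFrame({"start": starts, "end": ends, "count": counts})


def ratio_test(x: int, y: int, X: int, Y: int) -> tuple[float, float]:
    """Exact binomial window test: (log2 ratio, two-sided p).

    p0 = X/(X+Y) is the null share of the x+y window reads expected in the
    test sample; the log2 ratio is of the total-normalised counts and is
    NaN (flagged undefined) unless both counts are positive.
    """
    if X <= 0 or Y <= 0:
        raise ValueError("totals must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    if x + y == 0:
        return float("nan"), 1.0
    p0 = X / (X + Y)
    p_raw = binomtest(x, x + y, p0, alternative="two-sided").pvalue
    if x > 0 and y > 0:
        log2_ratio = math.log2((x / X) / (y / Y))
    else:
        log2_ratio = float("nan")
    return log2_ratio, float(p_raw)


def scan(
    test: Iterable[AlignmentRecord],
    ref: Iterable[AlignmentRecord],
    scaffold: str,
    scaffold_length: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    test_total: int | None = None,
    ref_total: int | None = None,
    center: bool = True,
) -> pd.DataFrame:
    """WindowRatio table: counts, log2 ratio, raw p and BH q per window.

    Totals default to the number of reads each sample contributes to this
    scaffold; pass library-wide totals to normalise across scaffolds.

    With ``center=True`` (default) log2 ratios are re-centred on the scan's
    median window ratio, the standard diploid-baseline correction: when an
    amplified region contributes a non-negligible share of one library,
    total-count normalisation alone biases every window's ratio, whereas
    the median window is a copy-neutral anchor as long as most of the
    scaffold is copy-neutral.  The uncentred value is kept in
    ``log2_raw``; re-centring does not change which windows are
    significant, only the ratio scale segments are called and reported on.
    """
    test = list(test)
    ref = list(ref)
    wt = window_counts(test, scaffold, scaffold_length, window, step)
    wr = window_counts(ref, scaffold, scaffold_length, window, step)
    X = test_total if test_total is not None else int(wt["count"].sum())
    Y = ref_total if ref_total is not None else int(wr["count"].sum())
    ratios, pvals = [], []
    for x, y in zip(wt["count"], wr["count"]):
        lr, p = ratio_test(int(x), int(y), X, Y)
        ratios.append(lr)
        pvals.append(p)
    ratios = np.asarray(ratios, dtype=float)
    offset = 0.0
    if center and np.isfinite(ratios).any():
        offset = float(np.nanmedian(ratios[np.isfinite(ratios)]))
    df = pd.DataFrame(
        {
            "start": wt["start"],
            "end": wt["end"],
            "x": wt["count"],
            "y": wr["count"],
            "log2_raw": ratios,
            "log2_ratio": ratios - offset,
            "p_raw": pvals,
        }
    )
    # BH over the whole scan, before any segment calling
    df["q"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    df.attrs["scaffold"] = scaffold
    df.attrs["X"] = X
    df.attrs["Y"] = Y
    df.attrs["median_log2"] = offset
    return df


def call_segments(
    windows: pd.DataFrame,
    scaffold: str,
    log2_threshold: float = 0.5,
    q_threshold: float = 0.05,
    max_gap: int = 0,
) -> list[AmplifiedSegment]:
    """Merge maximal runs of amplified windows into segments.

    A window passes when log2_ratio >= log2_threshold and q <= q_threshold;
    runs separated by at most ``max_gap`` failing windows merge.  Segment
    statistics are computed over the passing windows of the run.
    """
    passing = (
        (windows["log2_ratio"].to_numpy() >= log2_threshold)
        & (windows["q"].to_numpy() <= q_threshold)
        & np.isfinite(windows["log2_ratio"].to_numpy())
    )
    segments: list[AmplifiedSegment] = []
    run: list[int] = []
    gap = 0
    for i, ok in enumerate(passing):
        if ok:
            run.append(i)
            gap = 0
        elif run:
            gap += 1
            if gap > max_gap:
                segments.append(_make_segment(windows, run, scaffold))
                run, gap = [], 0
    if run:
        segments.append(_make_segment(windows, run, scaffold))
    return segments


def _make_segment(
    windows: pd.DataFrame, idx: Sequence[int], scaffold: str
) -> AmplifiedSegment:
    sub = windows.iloc[list(idx)]
    return AmplifiedSegment(
        interval=GenomicInterval(scaffold, int(sub["start"].min()), int(sub["end"].max())),
        mean_log2_ratio=float(sub["log2_ratio"].mean()),
        n_windows=len(idx),
        min_q=float(sub["q"].min()),
    )
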