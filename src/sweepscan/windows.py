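"""Non-overlapping window summaries and empirical significance.

Per-SNP (or per-grid-point) statistics are summarized over consecutive
25-kb windows by their maximum. For the haplotype statistic, windows are
binned by SNP count (1-200, 201-400, 401-600, >600) and ranked within the
bin to give an empirical p-value; windows with p < 0.01 (strict) are
candidates. For the composite-likelihood statistic, the top 1% of the
empirical window-maximum distribution is flagged, with the threshold
value reported.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from .datatypes import WindowRecord

DEFAULT_WINDOW_SIZE = 25_000
BIN_WIDTH = 200
BIN_OVERFLOW = 600  # windows with more SNPs than this share one bin


def make_windows(
    scores: list[tuple[str, int, float | None]],
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> list[WindowRecord]:
    """Tile each chromosome with [0,w), [w,2w), ... and take the max score.

    ``scores`` is (chrom, pos, stat) per scored position; positions with an
    undefined statistic still count toward snp_count only if stat is not
    None -- undefined entries are ignored entirely. Windows containing no
    scored positions are dropped (their max is undefined).
    """
    per_window: dict[tuple[str, int], list[float]] = defaultdict(list)
    for chrom, pos, stat in scores:
        if stat is None or (isinstance(stat, float) and math.isnan(stat)):
            continue
        per_window[(chrom, pos // window_size)].append(float(stat))
    out = []
    for (chrom, widx), vals in per_window.items():
        out.append(
            WindowRecord(
                chrom=chrom,
                start=widx * window_size,
                end=(widx + 1) * window_size,
                snp_count=len(vals),
                stat_max=max(vals),
            )
        )
    out.sort(key=lambda w: (w.chrom, w.start))
    return out


def snp_count_bin(snp_count: int, bin_width: int = BIN_WIDTH, overflow: int = BIN_OVERFLOW) -> int:
    """Bin id for a window's SNP count: 1-200 -> 1, 201-400 -> 2,
    401-600 -> 3, >600 -> 4 (upper edges inclusive)."""
    if snp_count < 1:
        raise ValueError("snp_count must be >= 1")
    if snp_count > overflow:
        return overflow // bin_width + 1
    return (snp_count - 1) // bin_width + 1


def bin_by_snp_count(windows: list[WindowRecord]) -> list[WindowRecord]:
    """Assign each window its SNP-count bin (in place; returns the list)."""
    for w in windows:
        w.bin_id = snp_count_bin(w.snp_count)
    return windows


def empirical_pvalues(windows: list[WindowRecord]) -> list[WindowRecord]:
    """Upper-tail rank-based empirical p within each SNP-count bin.

    empirical_p = rank / bin_size with rank 1 for the largest stat_max;
    tied windows all take the worst (largest) rank of the tied set.
    """
    by_bin: dict[int, list[WindowRecord]] = defaultdict(list)
    for w in windows:
        if w.bin_id is None:
            raise ValueError("bins must be assigned before empirical p-values")
        by_bin[w.bin_id].append(w)
    for ws in by_bin.values():
        b = len(ws)
        stats = np.array([w.stat_max for w in ws])
        order = np.argsort(-stats, kind="mergesort")
        # worst rank among ties: count of windows with stat >= this one's
        for i in order:
            ws[i].empirical_p = float(np.sum(stats >= stats[i])) / b
    return windows


def select_significant(
    windows: list[WindowRecord],
    mode: str,
    alpha: float = 0.01,
    top_frac: float = 0.01,
) -> tuple[list[WindowRecord], float | None]:
    """Flag candidate windows.

    xpehh mode: significant iff empirical_p < alpha (strict). xpclr mode:
    threshold is the empirical (1 - top_frac) order statistic of stat_max
    (no interpolation); significant iff stat_max >= threshold. Returns the
    windows and the threshold (None in xpehh mode).
    """
    if mode == "xpehh":
        for w in windows:
            if w.empirical_p is None:
                raise ValueError("empirical p-values must be assigned first")
            w.significant = w.empirical_p < alpha
        return windows, None
    if mode == "xpclr":
        stats = np.sort(np.array([w.stat_max for w in windows]))
        n_top = max(1, math.ceil(top_frac * len(windows)))
        threshold = float(stats[len(stats) - n_top])
        for w in windows:
            w.significant = w.stat_max >= threshold
        return windows, threshold
    raise ValueError(f"unknown mode {mode!r}")


def summarize(
    scores: list[tuple[str, int, float | None]],
    mode: str,
    window_size: int = DEFAULT_WINDOW_SIZE,
    alpha: float = 0.01,
    top_frac: float = 0.01,
) -> tuple[list[WindowRecord], float | None]:
    """make_windows -> bin -> empirical p (xpehh) -> significance flags."""
    ws = make_windows(scores, window_size)
    bin_by_snp_count(ws)
    if mode == "xpehh":
        empirical_pvalues(ws)
    return select_significant(ws, mode, alpha=alpha, top_frac=top_frac)
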