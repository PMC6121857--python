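"""Kernel-smoothed genome tracks and permutation-based outlier windows.

Per-locus statistics (here, calibrated TMRCA estimates) are smoothed along
each chromosome with a Nadaraya-Watson estimator under a Gaussian kernel
whose total support is the window size (sigma = window/6, truncated at
+/- window/2), evaluated on a regular grid.  Outlier windows are grid
points where the observed smoothed value exceeds the chosen quantile
(default 99.9%) of values obtained by permuting the statistic across locus
positions genome-wide; keeping positions fixed controls for the local
density of loci, so sparsely sampled regions get wider permutation
envelopes rather than spurious calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

DEFAULT_WINDOW_BP = 500_000
DEFAULT_GRID_STEP = 10_000
#: grid points whose total kernel weight falls below this are masked
WEIGHT_FLOOR = 1e-8


@dataclass
class ScanTrack:
    """Smoothed genome track with permutation envelope and outlier intervals."""

    chrom: str
    grid: np.ndarray  # bp positions, sorted
    values: np.ndarray  # smoothed statistic, NaN where masked
    window_bp: float = DEFAULT_WINDOW_BP
    upper_envelope: np.ndarray | None = None  # permutation quantile per grid point
    lower_envelope: np.ndarray | None = None
    outliers: list[tuple[int, int]] = field(default_factory=list)  # half-open bp


def _kernel_weights(
    positions: np.ndarray, grid: np.ndarray, window_bp: float
) -> sparse.csr_matrix:
    """Sparse (grid x loci) Gaussian weight matrix, truncated at +/- window/2."""
    sigma = window_bp / 6.0
    half = window_bp / 2.0
    rows, cols, vals = [], [], []
    order = np.argsort(positions)
    pos_sorted = positions[order]
    lo = np.searchsorted(pos_sorted, grid - half, side="left")
    hi = np.searchsorted(pos_sorted, grid + half, side="right")
    for g, (a, b) in enumerate(zip(lo, hi)):
        if a == b:
            continue
        d = pos_sorted[a:b] - grid[g]
        w = np.exp(-0.5 * (d / sigma) ** 2)
        rows.extend([g] * (b - a))
        cols.extend(order[a:b])
        vals.extend(w)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(grid), len(positions))
    )


def make_grid(
    positions: np.ndarray, grid_step: float = DEFAULT_GRID_STEP
) -> np.ndarray:
    start = grid_step * np.floor(positions.min() / grid_step)
    stop = grid_step * np.ceil(positions.max() / grid_step)
    return np.arange(start, stop + grid_step / 2, grid_step)


def kernel_smooth(
    positions,
    values,
    window_bp: float = DEFAULT_WINDOW_BP,
    grid_step: float = DEFAULT_GRID_STEP,
    grid: np.ndarray | None = None,
    chrom: str = "?",
) -> ScanTrack:
    """Gaussian-kernel smoothed track of a per-locus statistic.

    Grid points with total kernel weight below a floor (no locus within the
    truncated window) are masked with NaN.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.size == 0:
        return ScanTrack(chrom=chrom, grid=np.array([]), values=np.array([]), window_bp=window_bp)
    if positions.size != values.size:
        raise ValueError("positions and values must have equal length")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if grid is None:
        grid = make_grid(positions, grid_step)
    W = _kernel_weights(positions, grid, window_bp)
    denom = np.asarray(W.sum(axis=1)).ravel()
    smooth = np.full(len(grid), np.nan)
    ok = denom > WEIGHT_FLOOR
    smooth[ok] = (W @ values)[ok] / denom[ok]
    return ScanTrack(chrom=chrom, grid=grid, values=smooth, window_bp=window_bp)


def _merge_flags(grid: np.ndarray, flags: np.ndarray, grid_step: float) -> list[tuple[int, int]]:
    """Merge runs of flagged grid points into half-open bp intervals."""
    intervals: list[tuple[int, int]] = []
    start = None
    for g, f in zip(grid, flags):
        if f and start is None:
            start = g
        elif not f and start is not None:
            intervals.append((int(start), int(prev + grid_step)))
            start = None
        if f:
            prev = g
    if start is not None:
        intervals.append((int(start), int(prev + grid_step)))
    return intervals


def tmrca_outlier_scan(
    positions,
    values,
    n_perm: int = 1000,
    quantile: float = 0.999,
    seed: int | None = None,
    window_bp: float = DEFAULT_WINDOW_BP,
    grid_step: float = DEFAULT_GRID_STEP,
    two_sided: bool = False,
    chrom: str = "?",
) -> ScanTrack:
    """Permutation outlier scan of a smoothed per-locus statistic.

    Values are permuted across the fixed locus positions genome-wide,
    re-smoothed, and the per-grid-point permutation quantile forms the
    envelope; observed grid points exceeding it are flagged and merged into
    half-open outlier intervals.  With ``two_sided`` both tails are flagged
    at the complementary quantile.
    """
    if n_perm < 1.0 / (1.0 - quantile):
        raise ValueError(
            f"n_perm={n_perm} too small to resolve quantile {quantile}"
        )
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    grid = make_grid(positions, grid_step)
    W = _kernel_weights(positions, grid, window_bp)
    denom = np.asarray(W.sum(axis=1)).ravel()
    ok = denom > WEIGHT_FLOOR
    observed = np.full(len(grid), np.nan)
    observed[ok] = (W @ values)[ok] / denom[ok]

    perm_tracks = np.empty((n_perm, int(ok.sum())))
    for p in range(n_perm):
        perm = rng.permutation(values)
        perm_tracks[p] = (W @ perm)[ok] / denom[ok]
    upper = np.full(len(grid), np.nan)
    upper[ok] = np.quantile(perm_tracks, quantile, axis=0)
    track = ScanTrack(
        chrom=chrom,
        grid=grid,
        values=observed,
        window_bp=window_bp,
        upper_envelope=upper,
    )
    # flag by exact permutation rank: the observed smoothed value must exceed
    # a `quantile` fraction of the permuted values at that grid point
    max_ge = (1.0 - quantile) * n_perm
    flags = np.zeros(len(grid), dtype=bool)
    flags[ok] = (perm_tracks >= observed[ok]).sum(axis=0) <= max_ge
    if two_sided:
        lower = np.full(len(grid), np.nan)
        lower[ok] = np.quantile(perm_tracks, 1.0 - quantile, axis=0)
        track.lower_envelope = lower
        flags[ok] |= (perm_tracks <= observed[ok]).sum(axis=0) <= max_ge
    track.outliers = _merge_flags(grid, flags, grid_step)
    return track


def interval_overlap(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> int:
    """Total bp overlap between two sets of half-open intervals."""
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def remove_and_rescan(
    positions,
    values,
    keep_mask,
    n_perm: int = 1000,
    quantile: float = 0.999,
    seed: int | None = None,
    window_bp: float = DEFAULT_WINDOW_BP,
    grid_step: float = DEFAULT_GRID_STEP,
    chrom: str = "?",
) -> tuple[ScanTrack, ScanTrack, float]:
    """Rerun the outlier scan after dropping flagged loci.

    ``keep_mask`` marks the loci to retain (e.g. excluding reciprocally
    monophyletic loci and loci with marine-freshwater FST above 0.5).
    Returns (full scan, reduced scan, fraction of the full scan's outlier
    span still covered by the reduced scan's outliers).
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    full = tmrca_outlier_scan(
        positions, values, n_perm=n_perm, quantile=quantile, seed=seed,
        window_bp=window_bp, grid_step=grid_step, chrom=chrom,
    )
    if keep_mask.all():
        return full, full, 1.0
    if not keep_mask.any():
        empty = ScanTrack(chrom=chrom, grid=np.array([]), values=np.array([]), window_bp=window_bp)
        return full, empty, 0.0
    reduced = tmrca_outlier_scan(
        positions[keep_mask], values[keep_mask], n_perm=n_perm,
        quantile=quantile, seed=seed, window_bp=window_bp,
        grid_step=grid_step, chrom=chrom,
    )
    full_span = sum(e - s for s, e in full.outliers)
    if full_span == 0:
        return full, reduced, float("nan")
    frac = interval_overlap(full.outliers, reduced.outliers) / full_span
    return full, reduced, frac


def fst_class_keep_mask(
    classes: Sequence[str | None],
    fst_mf: Sequence[float],
    fst_threshold: float = 0.5,
    divergent_class: str = "reciprocal_mono",
) -> np.ndarray:
    """Mask retaining loci that are neither divergent-class nor high-FST."""
    fst = np.asarray(fst_mf, dtype=float)
    cls = np.array([c == divergent_class for c in classes])
    high = np.where(np.isnan(fst), False, fst > fst_threshold)
    return ~(cls | high)
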