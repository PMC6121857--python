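"""Sequence diversity and divergence statistics.

Implements the per-locus statistics of the analysis: nucleotide diversity
(pi, mean per-site pairwise differences within a sample), absolute
divergence (dXY, mean per-site differences using only across-population
pairs), the haplotype-based Hudson FST (1 - Hw/Hb), predicted sampling
variances of pi and dXY for a sequence of length L in samples of size n,
and label-permutation tests for differences in means.

Sites with missing or ambiguous bases are handled by pairwise deletion:
each pair of sequences is compared over the sites where both carry an
unambiguous base, and the per-pair effective length is used as the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class StatResult:
    name: str
    value: float
    groups: tuple[str, ...] = ()
    n_sequences: int = 0
    length: int = 0
    variance: float | None = None
    defined: bool = True


def _encode(sequences) -> np.ndarray:
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must be of equal length")
    return np.frombuffer("".join(sequences).encode(), dtype=np.uint8).reshape(
        len(sequences), L
    )


def _pair_stats(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (#differences, #comparable sites) between row sets a and b."""
    va = np.isin(a, _VALID)
    vb = np.isin(b, _VALID)
    both = va[:, None, :] & vb[None, :, :]
    diffs = ((a[:, None, :] != b[None, :, :]) & both).sum(axis=2)
    return diffs, both.sum(axis=2)


def nucleotide_diversity(sequences) -> float:
    """Nucleotide diversity pi: mean per-site pairwise differences.

    Averaged over all unordered pairs of sequences, with pairwise deletion
    of non-ACGT sites.  Undefined (NaN) for fewer than two sequences.
    """
    if len(sequences) < 2:
        return float("nan")
    arr = _encode(sequences)
    diffs, lens = _pair_stats(arr, arr)
    iu = np.triu_indices(len(sequences), k=1)
    with np.errstate(invalid="ignore"):
        per_pair = diffs[iu] / lens[iu]
    return float(np.mean(per_pair))


def dxy(sequences_x, sequences_y) -> float:
    """Absolute divergence dXY: mean per-site differences across groups only."""
    if not len(sequences_x) or not len(sequences_y):
        return float("nan")
    ax = _encode(list(sequences_x) + list(sequences_y))
    nx = len(sequences_x)
    diffs, lens = _pair_stats(ax[:nx], ax[nx:])
    with np.errstate(invalid="ignore"):
        per_pair = diffs / lens
    return float(np.mean(per_pair))


def hudson_fst(sequences_x, sequences_y) -> float:
    """Haplotype-based Hudson FST = 1 - Hw/Hb.

    Hw is the unweighted mean of the two within-group mean pairwise
    difference counts; Hb is the between-group mean pairwise difference
    count.  NaN when Hb = 0 (no between-group variation) or when either
    group has fewer than two sequences.
    """
    if len(sequences_x) < 2 or len(sequences_y) < 2:
        return float("nan")
    arr = _encode(list(sequences_x) + list(sequences_y))
    nx = len(sequences_x)
    dx, _ = _pair_stats(arr[:nx], arr[:nx])
    dy, _ = _pair_stats(arr[nx:], arr[nx:])
    db, _ = _pair_stats(arr[:nx], arr[nx:])
    iux = np.triu_indices(nx, k=1)
    iuy = np.triu_indices(len(sequences_y), k=1)
    hw = (dx[iux].mean() + dy[iuy].mean()) / 2.0
    hb = db.mean()
    if hb == 0:
        return float("nan")
    return float(1.0 - hw / hb)


def sampling_variance_pi(pi: float, n: int, L: int) -> float:
    """Predicted sampling variance of pi for n sequences of length L.

    The no-recombination variance of mean pairwise nucleotide diversity:

        V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2

    The first term is mutational/site sampling and shrinks with sequence
    length; the second is genealogical and shrinks with sample size.
    """
    if n < 2 or L <= 0:
        raise ValueError("need n >= 2 sequences and L > 0 sites")
    return (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    ) * pi * pi


def sampling_variance_dxy(
    d: float,
    n_x: int,
    n_y: int,
    L: int,
    pi_x: float | None = None,
    pi_y: float | None = None,
) -> float:
    """Predicted sampling variance of dXY between two samples.

    Uses the net-divergence decomposition dXY = dA + (piX + piY)/2: the
    between-population component contributes binomial site-sampling
    variance d(1-d)/L, and each within-population term contributes a
    quarter of the pi sampling variance (defaulting pi to the dXY level
    when within-group diversities are not supplied).
    """
    if n_x < 2 or n_y < 2 or L <= 0:
        raise ValueError("need n >= 2 sequences per group and L > 0 sites")
    pi_x = d if pi_x is None else pi_x
    pi_y = d if pi_y is None else pi_y
    return (
        d * (1.0 - d) / L
        + sampling_variance_pi(pi_x, n_x, L) / 4.0
        + sampling_variance_pi(pi_y, n_y, L) / 4.0
    )


def pooled_pi_decomposition(sequences_x, sequences_y) -> tuple[float, float, float]:
    """Exact identity: pooled pi as the pair-weighted mix of within/between terms.

    Returns (pi_pooled, mean within-pair per-site difference over both
    groups' pairs pooled, mean between-pair per-site difference); pooled pi
    equals (n_w * within + n_b * between) / (n_w + n_b) with n_w, n_b the
    pair counts.
    """
    nx, ny = len(sequences_x), len(sequences_y)
    arr = _encode(list(sequences_x) + list(sequences_y))
    L = arr.shape[1]
    dall, _ = _pair_stats(arr, arr)
    iu = np.triu_indices(nx + ny, k=1)
    pooled = float(np.mean(dall[iu]) / L)
    within_pairs = [
        dall[i, j] for i, j in combinations(range(nx), 2)
    ] + [dall[i, j] for i, j in combinations(range(nx, nx + ny), 2)]
    between_pairs = [dall[i, j] for i in range(nx) for j in range(nx, nx + ny)]
    within = float(np.mean(within_pairs) / L) if within_pairs else float("nan")
    between = float(np.mean(between_pairs) / L)
    return pooled, within, between


def permutation_test(
    values_a,
    values_b,
    n_perm: int = 9999,
    seed: int | None = None,
    two_sided: bool = True,
) -> float:
    """Label-permutation p-value for a difference in group means.

    p = (1 + #{permuted |diff| >= observed |diff|}) / (n_perm + 1), so the
    attainable floor is 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    obs = a.mean() - b.mean()
    stat = abs(obs) if two_sided else obs
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[: a.size].mean() - perm[a.size :].mean()
        if (abs(diff) if two_sided else diff) >= stat - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)
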