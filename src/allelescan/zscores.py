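"""Non-HMM detectors: simple smoothing and expression-binned Z-scores.

Both methods operate on the ordered heterozygous sites of one
individual on one chromosome; homozygous sites are transparent (skipped,
never treated as zeros) and carry no score.

The Z-score method standardizes each het site's allelic log-ratio R
against the mean and standard deviation of R among sites of comparable
total expression E, because measurement noise in R grows as E shrinks.
The het-site E range is cut into equal-width bins (100 by default), and
a site in bin b gets z = (R - mu_b) / sigma_b.  For a run of k
consecutive het sites the regional score is Z = sum(z) / sqrt(k), which
under the null of no imbalance (and independent Gaussian noise) is
standard normal for a *fixed* window.  Scores are then assigned by
repeatedly selecting, among all windows of 1..w_max consecutive
unassigned het sites, the one with the largest |Z|; because each site
inherits the score of the best window containing it, the assigned
scores are no longer Normal(0,1) under the null and are calibrated by
permutation instead.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .data import HET, DataError, SampleMatrix, ScoreTrack, SiteTable


def smooth_scores(r_het: np.ndarray, k: int) -> np.ndarray:
    """Mean of each het site's R with its k het neighbours on each side.

    Windows are truncated at sequence ends so every site is scored;
    k=0 returns R unchanged.
    """
    if k < 0:
        raise DataError("k must be >= 0")
    r = np.asarray(r_het, dtype=float)
    n = len(r)
    if n == 0:
        return r.copy()
    csum = np.concatenate([[0.0], np.cumsum(r)])
    i = np.arange(n)
    lo = np.maximum(i - k, 0)
    hi = np.minimum(i + k, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


@dataclass
class BinStats:
    """Per-expression-bin null mean and sd of R at het sites."""

    edges: np.ndarray  # n_bins + 1 equal-width edges over het-site E
    effective: np.ndarray  # raw bin -> populated bin it was merged into
    mu: np.ndarray  # per raw bin (via effective mapping)
    sigma: np.ndarray
    counts: np.ndarray

    def bin_of(self, e) -> np.ndarray:
        idx = np.searchsorted(self.edges, e, side="right") - 1
        return self.effective[np.clip(idx, 0, len(self.edges) - 2)]


def fit_expression_bins(
    E: np.ndarray,
    R: np.ndarray,
    geno: np.ndarray,
    n_bins: int = 100,
    min_bin_n: int = 50,
    sigma_floor: float = 1e-3,
) -> BinStats:
    """Estimate the E-dependent null distribution of R from het sites.

    All het (site, individual) observations are pooled.  Bins with fewer
    than ``min_bin_n`` observations are merged into the nearest (by bin
    center) populated bin; sigma is floored at ``sigma_floor``.
    """
    het = np.asarray(geno) == HET
    e = np.asarray(E, dtype=float)[het]
    r = np.asarray(R, dtype=float)[het]
    ok = np.isfinite(e) & np.isfinite(r)
    e, r = e[ok], r[ok]
    if e.size == 0:
        raise DataError("no heterozygous sites to fit expression bins")
    lo, hi = float(e.min()), float(e.max())
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    raw = np.clip(np.searchsorted(edges, e, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(raw, minlength=n_bins)

    populated = np.flatnonzero(counts >= min_bin_n)
    if populated.size == 0:
        populated = np.array([int(np.argmax(counts))])
    centers = 0.5 * (edges[:-1] + edges[1:])
    effective = np.empty(n_bins, dtype=np.int64)
    for b in range(n_bins):
        if counts[b] >= min_bin_n and b in populated:
            effective[b] = b
        else:
            effective[b] = populated[
                np.argmin(np.abs(centers[populated] - centers[b]))
            ]

    merged = effective[raw]
    mu = np.zeros(n_bins)
    sigma = np.full(n_bins, sigma_floor)
    mcounts = np.bincount(merged, minlength=n_bins)
    for b in np.unique(merged):
        vals = r[merged == b]
        mu[b] = vals.mean()
        sigma[b] = max(vals.std(ddof=1) if len(vals) > 1 else 0.0, sigma_floor)
    # non-populated raw bins point at their merge target's stats
    mu = mu[effective]
    sigma = sigma[effective]
    return BinStats(edges, effective, mu, sigma, mcounts)


def site_z(R, E, stats: BinStats) -> np.ndarray:
    """Standardize het-site log-ratios against their expression bin."""
    idx = np.searchsorted(stats.edges, np.asarray(E, dtype=float), "right") - 1
    idx = np.clip(idx, 0, len(stats.edges) - 2)
    return (np.asarray(R, dtype=float) - stats.mu[idx]) / stats.sigma[idx]


def regional_z(z: np.ndarray) -> float:
    """Regional score of a run of het-site z values: sum(z)/sqrt(k)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise DataError("regional_z of an empty window")
    return float(z.sum() / np.sqrt(z.size))


def greedy_window_assignment(z: np.ndarray, w_max: int = 25) -> np.ndarray:
    """Assign each het site the regional Z of the best window covering it.

    Iteratively selects, among all windows of 1..w_max consecutive
    not-yet-assigned het sites, the one maximizing |Z| (ties broken
    leftmost, then shortest); every site in the winner receives that
    window's Z.  Deterministic; terminates because length-1 windows
    always remain available.
    """
    if w_max < 1:
        raise DataError("w_max must be >= 1")
    z = np.asarray(z, dtype=float)
    n = len(z)
    out = np.full(n, np.nan)
    if n == 0:
        return out
    csum = np.concatenate([[0.0], np.cumsum(z)])
    heap = []
    for start in range(n):
        for length in range(1, min(w_max, n - start) + 1):
            Z = (csum[start + length] - csum[start]) / np.sqrt(length)
            heap.append((-abs(Z), start, length, Z))
    heapq.heapify(heap)
    assigned = np.zeros(n, dtype=bool)
    n_left = n
    while n_left > 0 and heap:
        _, start, length, Z = heapq.heappop(heap)
        if assigned[start : start + length].any():
            continue
        out[start : start + length] = Z
        assigned[start : start + length] = True
        n_left -= length
    return out


def _per_het_sequences(sites: SiteTable, matrix: SampleMatrix):
    """Yield (chrom slice, individual index, het row indices) triples."""
    for chrom, sl in sites.chrom_slices().items():
        geno = matrix.geno[sl]
        for j in range(matrix.n_individuals):
            het_rows = np.flatnonzero(geno[:, j] == HET) + sl.start
            if het_rows.size:
                yield sl, j, het_rows


def score_smooth(
    sites: SiteTable, matrix: SampleMatrix, k: int = 2
) -> ScoreTrack:
    """Simple-smoothing score track (per individual, per chromosome)."""
    scores = np.full(matrix.geno.shape, np.nan)
    for _, j, rows in _per_het_sequences(sites, matrix):
        scores[rows, j] = smooth_scores(matrix.R[rows, j], k)
    return ScoreTrack(scores, "smooth", list(matrix.individuals))


def score_zscore(
    sites: SiteTable,
    matrix: SampleMatrix,
    n_bins: int = 100,
    w_max: int = 25,
    min_bin_n: int = 50,
    sigma_floor: float = 1e-3,
    stats: BinStats | None = None,
) -> ScoreTrack:
    """Z-score track with greedy non-overlapping window assignment.

    Bin statistics are pooled over all individuals unless ``stats`` is
    supplied (e.g. frozen from the real data when scoring permutations).
    """
    if stats is None:
        stats = fit_expression_bins(
            matrix.E, matrix.R, matrix.geno, n_bins, min_bin_n, sigma_floor
        )
    scores = np.full(matrix.geno.shape, np.nan)
    for _, j, rows in _per_het_sequences(sites, matrix):
        z = site_z(matrix.R[rows, j], matrix.E[rows, j], stats)
        scores[rows, j] = greedy_window_assignment(z, w_max)
    return ScoreTrack(scores, "zscore", list(matrix.individuals))
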