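"""Permutation-based FDR, region calling and downstream summaries.

Because few gold-standard imbalanced regions exist, false-discovery
rates are estimated by a structured permutation: sites are stratified
into (up to) 25 bins — five heterozygosity-frequency levels crossed
with five mean-expression levels — and shuffled only within bins, with
all individuals' columns moving together.  This preserves per-site
heterozygosity and expression structure while destroying the genomic
contiguity that real imbalanced transcripts create.  For a score
threshold t, FDR(t) = N_perm(t) / N_real(t), the ratio of region calls
on permuted versus real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    HET,
    MISSING,
    DataError,
    Region,
    SampleMatrix,
    ScoreTrack,
    SiteTable,
)


@dataclass
class PermutationScheme:
    """Per-site bin ids for the structured permutation."""

    bins: np.ndarray  # (n_sites,) int
    het_level: np.ndarray
    expr_level: np.ndarray


def _quantile_levels(values: np.ndarray, n_levels: int = 5) -> np.ndarray:
    """Split values into quantile levels; ties can collapse levels."""
    qs = np.quantile(values, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.searchsorted(qs, values, side="right")


def assign_permutation_bins(
    matrix: SampleMatrix, n_levels: int = 5
) -> PermutationScheme:
    """Cross of heterozygosity-frequency and mean-expression levels.

    Het count per site (over individuals) and mean E per site (over
    non-missing individuals) are each split into ``n_levels`` quantile
    levels, giving at most n_levels**2 bins.
    """
    if matrix.n_sites == 0:
        raise DataError("empty matrix")
    het_count = (matrix.geno == HET).sum(axis=1)
    obs = matrix.geno != MISSING
    with np.errstate(invalid="ignore"):
        mean_e = np.where(
            obs.any(axis=1),
            np.nansum(np.where(obs, matrix.E, 0.0), axis=1)
            / np.maximum(obs.sum(axis=1), 1),
            0.0,
        )
    het_level = _quantile_levels(het_count.astype(float), n_levels)
    expr_level = _quantile_levels(mean_e, n_levels)
    return PermutationScheme(
        het_level * n_levels + expr_level, het_level, expr_level
    )


def permute_within_bins(
    matrix: SampleMatrix, scheme: PermutationScheme, seed: int
) -> SampleMatrix:
    """Shuffle site rows within bins, all individuals moving jointly.

    Returns a new SampleMatrix; per-site het count and E values travel
    intact, so the permuted data's marginals equal the real data's.
    """
    rng = np.random.default_rng(seed)
    n = matrix.n_sites
    perm = np.arange(n)
    for b in np.unique(scheme.bins):
        idx = np.flatnonzero(scheme.bins == b)
        perm[idx] = idx[rng.permutation(len(idx))]
    return SampleMatrix(
        list(matrix.individuals),
        matrix.geno[perm],
        matrix.E[perm],
        matrix.R[perm],
    )


def call_regions(
    track: ScoreTrack,
    sites: SiteTable,
    threshold: float,
    min_snps: int = 1,
) -> list:
    """Maximal sign-homogeneous runs of scored sites beyond a threshold.

    A region is a run of consecutive scored sites (unscored sites are
    transparent) with S >= t throughout, or S <= -t throughout; a sign
    flip terminates the run.  Runs with fewer than ``min_snps`` scored
    sites are dropped.  Region span is [first site pos - 1, last site
    pos) in 0-based half-open bp.
    """
    if threshold <= 0:
        raise DataError("threshold must be positive")
    regions = []
    chrom_sl = sites.chrom_slices()
    pos_all = sites.pos
    for chrom, sl in chrom_sl.items():
        for j, ind in enumerate(track.individuals):
            s = track.scores[sl, j]
            scored = np.flatnonzero(np.isfinite(s))
            if scored.size == 0:
                continue
            vals = s[scored]
            state = np.where(
                vals >= threshold, 1, np.where(vals <= -threshold, -1, 0)
            )
            start = 0
            for i in range(1, len(state) + 1):
                if i == len(state) or state[i] != state[start]:
                    if state[start] != 0 and i - start >= min_snps:
                        rows = scored[start:i] + sl.start
                        regions.append(
                            Region(
                                chrom=chrom,
                                start=int(pos_all[rows[0]] - 1),
                                end=int(pos_all[rows[-1]]),
                                individual=ind,
                                sign=int(state[start]),
                                mean_score=float(vals[start:i].mean()),
                                n_snps=i - start,
                            )
                        )
                    start = i
    return regions


def count_calls(
    track: ScoreTrack,
    sites: SiteTable,
    threshold: float,
    min_snps: int = 1,
    unit: str = "region",
) -> int:
    """Number of calls at a threshold, pooled over individuals.

    ``unit='region'`` counts regions; ``unit='snp'`` counts the scored
    sites inside them.
    """
    regions = call_regions(track, sites, threshold, min_snps)
    if unit == "region":
        return len(regions)
    if unit == "snp":
        return sum(r.n_snps for r in regions)
    raise DataError(f"unknown counting unit {unit!r}")


@dataclass
class FDRCurve:
    thresholds: np.ndarray
    n_real: np.ndarray
    n_perm: np.ndarray  # mean count per permutation replicate
    fdr: np.ndarray  # NaN where n_real == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_real": self.n_real,
                "n_perm": self.n_perm,
                "fdr": self.fdr,
            }
        )

    def threshold_at_fdr(self, target: float) -> float:
        """Smallest threshold whose FDR is at or below ``target``."""
        ok = np.isfinite(self.fdr) & (self.fdr <= target)
        if not ok.any():
            raise DataError(f"no threshold reaches FDR <= {target}")
        return float(self.thresholds[np.argmax(ok)])


def fdr_curve(
    real_track: ScoreTrack,
    perm_tracks,
    sites: SiteTable,
    thresholds,
    min_snps: int = 1,
    unit: str = "region",
) -> FDRCurve:
    """Permutation FDR at each threshold, counts pooled over individuals.

    ``perm_tracks`` is one ScoreTrack or a list of them (replicates);
    the permuted count is averaged over replicates.
    """
    if isinstance(perm_tracks, ScoreTrack):
        perm_tracks = [perm_tracks]
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    n_real = np.array(
        [count_calls(real_track, sites, t, min_snps, unit) for t in thresholds],
        dtype=float,
    )
    n_perm = np.zeros(len(thresholds))
    for pt in perm_tracks:
        n_perm += [
            count_calls(pt, sites, t, min_snps, unit) for t in thresholds
        ]
    n_perm /= len(perm_tracks)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_real > 0, n_perm / n_real, np.nan)
    return FDRCurve(thresholds, n_real, n_perm, fdr)


def enrichment(pred_sites: set, annot_sites: set, universe: set) -> float:
    """Fold enrichment of predictions in an annotation.

    fold = (|pred & annot| / |pred|) / (|annot| / |universe|), i.e. the
    observed overlap relative to the overlap expected if predictions
    were drawn uniformly from the universe.
    """
    if not annot_sites or not universe:
        raise DataError("annotation and universe must be nonempty")
    if not pred_sites:
        raise DataError("prediction set must be nonempty")
    if not (set(pred_sites) <= set(universe)):
        raise DataError("predictions must be contained in the universe")
    obs = len(set(pred_sites) & set(annot_sites)) / len(pred_sites)
    exp = len(set(annot_sites) & set(universe)) / len(universe)
    return obs / exp


INTERGENIC = "intergenic"
MULTIPLE = "multiple transcripts"
EXACT = "exact transcript"
FIVE_END = "5' end"
THREE_END = "3' end"
INTRONIC = "intronic"
EXT_FIVE = "extended 5'"
EXT_THREE = "extended 3'"


def classify_region(
    region: Region,
    genes: pd.DataFrame,
    delta: int = 20000,
    min_overlap_frac: float = 0.1,
    multi_frac: float = 0.2,
) -> str:
    """Relate a called region to annotated gene boundaries.

    ``genes`` needs chrom/start/end/strand columns (0-based half-open).
    The 20 kb tolerance ``delta`` allows for boundary error in the
    calls.  Cascade: little overlap -> intergenic; two or more genes
    each covering >= 20% of the region -> multiple transcripts; then,
    against the best-overlapping gene: boundaries matching within delta
    -> exact transcript; region running past a gene end by more than
    delta -> extended 5'/3'; region ending near one gene boundary but
    covering only part of the gene -> 5'/3' end; region strictly
    interior -> intronic.  5'/3' orientation follows the gene strand.
    """
    rs, re_ = region.start, region.end
    rlen = re_ - rs
    sub = genes[genes["chrom"] == region.chrom]
    overlaps = []
    for g in sub.itertuples(index=False):
        ov = min(re_, g.end) - max(rs, g.start)
        if ov > 0:
            overlaps.append((ov, g))
    total_ov = 0
    if overlaps:
        # union of gene overlaps with the region
        ivals = sorted(
            (max(rs, g.start), min(re_, g.end)) for _, g in overlaps
        )
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                total_ov += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total_ov += cur_e - cur_s
    if total_ov < min_overlap_frac * rlen:
        return INTERGENIC
    big = [g for ov, g in overlaps if ov >= multi_frac * rlen]
    if len(big) >= 2:
        return MULTIPLE
    ov, g = max(overlaps, key=lambda t: t[0])
    gs, ge = g.start, g.end
    fwd = getattr(g, "strand", "+") != "-"

    def oriented(cat_up, cat_down):
        return cat_up if fwd else cat_down

    near_left = abs(rs - gs) <= delta
    near_right = abs(re_ - ge) <= delta
    if near_left and near_right:
        return EXACT
    ext_left = rs < gs - delta
    ext_right = re_ > ge + delta
    if ext_left and ext_right:
        # extends past both ends; call it by the larger extension
        if (gs - rs) >= (re_ - ge):
            return oriented(EXT_FIVE, EXT_THREE)
        return oriented(EXT_THREE, EXT_FIVE)
    if ext_left:
        return oriented(EXT_FIVE, EXT_THREE)
    if ext_right:
        return oriented(EXT_THREE, EXT_FIVE)
    # region inside the gene (within delta of at most one boundary)
    if near_left:
        return oriented(FIVE_END, THREE_END)
    if near_right:
        return oriented(THREE_END, FIVE_END)
    return INTRONIC


def commonality_counts(calls: np.ndarray) -> dict:
    """Histogram of SNP counts by the number of individuals sharing AI.

    ``calls`` is a boolean (n_sites, n_individuals) array of AI calls
    aligned on shared sites.  Returns {k: number of SNPs with AI in
    exactly k individuals} for k >= 1.
    """
    per_site = np.asarray(calls, dtype=bool).sum(axis=1)
    counts = np.bincount(per_site, minlength=calls.shape[1] + 1)
    return {int(k): int(counts[k]) for k in range(1, len(counts)) if counts[k]}
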