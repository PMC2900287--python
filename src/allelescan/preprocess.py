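"""Derivation of the (E, R) observables and expression deconvolution.

From four probe intensities per site and individual — cDNA and genomic
DNA readouts for each allele — we form two DNA-normalized quantities:

    E = log2((cdnaA + cdnaB + eps) / (gdnaA + gdnaB + eps))
    R = log2(((cdnaA + eps) / (cdnaB + eps)) / ((gdnaA + eps) / (gdnaB + eps)))

E measures total transcript abundance of both alleles; R measures the
fold imbalance between the alleles.  Dividing by the genomic-DNA
readouts, which are balanced at heterozygous sites, cancels probe
sensitivity and sequence biases.  R is meaningful only at heterozygous
sites and is set to missing elsewhere.

The marginal E distribution over genic sites is bimodal because a good
fraction of genes are not transcribed in any one cell type.  Assuming a
fraction p of genic and q of intergenic sites are expressed, the
expressed / non-expressed component distributions are recovered by
per-bin linear unmixing of the genic and intergenic histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .data import HET, MISSING, DataError, SampleMatrix, SiteTable

# density floor used when a histogram is evaluated as a (log-)pdf; keeps
# zero-mass bins from producing -inf emission likelihoods
_DENSITY_FLOOR = 1e-10


@dataclass
class Histogram:
    """A normalized histogram usable as a non-parametric pdf.

    ``edges`` has length n_bins + 1; ``mass`` sums to 1.  Values outside
    the support are clamped to the end bins.
    """

    edges: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if len(self.edges) != len(self.mass) + 1:
            raise DataError("edges must have one more entry than mass")
        if (self.mass < 0).any():
            raise DataError("negative histogram mass")
        tot = self.mass.sum()
        if not np.isclose(tot, 1.0, atol=1e-8):
            raise DataError(f"histogram mass sums to {tot}, expected 1")

    @property
    def n_bins(self) -> int:
        return len(self.mass)

    def bin_of(self, x) -> np.ndarray:
        idx = np.searchsorted(self.edges, x, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)

    def logpdf(self, x) -> np.ndarray:
        widths = np.diff(self.edges)
        dens = self.mass / widths
        return np.log(np.maximum(dens[self.bin_of(x)], _DENSITY_FLOOR))


def compute_expression_and_ratio(
    cdnaA, cdnaB, gdnaA, gdnaB, geno=None, eps: float = 1.0
):
    """Compute (E, R) from four-channel intensities.

    All intensities must be nonnegative; ``eps`` is a pseudocount
    guarding zero channels.  Where all four intensities are zero (and
    eps is 0) both values are missing.  If ``geno`` is given, R is set
    to NaN at non-het entries.
    """
    arrs = [np.asarray(a, dtype=float) for a in (cdnaA, cdnaB, gdnaA, gdnaB)]
    cA, cB, gA, gB = arrs
    for a in arrs:
        if (a < 0).any():
            raise DataError("negative probe intensity")
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.log2(cA + cB + eps) - np.log2(gA + gB + eps)
        R = (np.log2(cA + eps) - np.log2(cB + eps)) - (
            np.log2(gA + eps) - np.log2(gB + eps)
        )
    dead = (cA + cB + gA + gB + eps) == 0
    E = np.where(dead, np.nan, E)
    R = np.where(dead, np.nan, R)
    if geno is not None:
        R = np.where(np.asarray(geno) == HET, R, np.nan)
    return E, R


def expression_histograms(
    sites: SiteTable, matrix: SampleMatrix, n_bins: int = 200
) -> tuple[Histogram, Histogram]:
    """Empirical E histograms over genic and intergenic sites.

    All non-missing (site, individual) observations contribute; both
    histograms share equal-width bin edges spanning the observed E
    range so they can be unmixed bin by bin.
    """
    obs = matrix.geno != MISSING
    genic = sites.genic[:, None] & obs
    inter = ~sites.genic[:, None] & obs
    e_all = matrix.E[obs]
    if e_all.size == 0:
        raise DataError("no observed E values")
    lo, hi = float(np.min(e_all)), float(np.max(e_all))
    if hi <= lo:
        hi = lo + 1e-6
    edges = np.linspace(lo, hi, n_bins + 1)

    def _hist(mask):
        vals = matrix.E[mask]
        if vals.size == 0:
            raise DataError("empty site class for histogram")
        counts, _ = np.histogram(vals, bins=edges)
        return Histogram(edges, counts / counts.sum())

    return _hist(genic), _hist(inter)


def deconvolve_expression(
    hist_genic: Histogram,
    hist_intergenic: Histogram,
    p_genic: float = 0.5,
    p_intergenic: float = 0.1,
) -> tuple[Histogram, Histogram]:
    """Unmix genic/intergenic E histograms into expressed/non-expressed.

    With p = P(expressed | genic) and q = P(expressed | intergenic), the
    observed histograms are mixtures

        f_gen = p f_expr + (1-p) f_nonexpr
        f_int = q f_expr + (1-q) f_nonexpr

    solved bin-wise.  Negative bin masses (possible when the assumed
    mixing fractions are not exact) are clipped to zero and each result
    renormalized, so the outputs remain valid distributions.
    """
    p, q = float(p_genic), float(p_intergenic)
    if p == q:
        raise DataError("p_genic == p_intergenic: singular unmixing")
    if not np.array_equal(hist_genic.edges, hist_intergenic.edges):
        raise DataError("histograms must share bin edges")
    fg, fi = hist_genic.mass, hist_intergenic.mass
    f_expr = ((1 - q) * fg - (1 - p) * fi) / (p - q)
    f_non = (p * fi - q * fg) / (p - q)

    def _norm(f):
        f = np.clip(f, 0.0, None)
        s = f.sum()
        if s == 0:
            raise DataError("deconvolved component has zero total mass")
        return Histogram(hist_genic.edges, f / s)

    return _norm(f_expr), _norm(f_non)


def mask_duplications(
    sites: SiteTable, matrix: SampleMatrix, dup_intervals
) -> tuple[SiteTable, SampleMatrix, int]:
    """Drop sites falling in duplication-prone intervals.

    Probes inside recent segmental duplications cross-hybridize with the
    paralogous transcript and show spurious imbalance shared across
    individuals, so they are removed outright.  ``dup_intervals`` is a
    DataFrame with chrom/start/end in 0-based half-open coordinates
    (BED).  Returns the filtered pair plus the number of sites removed.
    """
    if len(dup_intervals) == 0:
        return sites, matrix, 0
    trees: dict = {}
    for row in dup_intervals.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    keep = np.ones(len(sites), dtype=bool)
    chrom, pos = sites.chrom, sites.pos
    for i in range(len(sites)):
        tree = trees.get(chrom[i])
        # 1-based pos maps to 0-based coordinate pos-1
        if tree is not None and tree.overlaps_point(int(pos[i]) - 1):
            keep[i] = False
    n_removed = int((~keep).sum())
    new_sites = SiteTable(sites.df.loc[keep].reset_index(drop=True))
    return new_sites, matrix.take_sites(keep), n_removed
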