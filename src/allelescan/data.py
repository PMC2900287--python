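"""Core in-memory containers for allelic-expression data.

The data model follows the structure of high-density allelic-expression
assays: a table of polymorphic sites (``SiteTable``) and, aligned to it,
per-individual observations (``SampleMatrix``) consisting of a genotype
class, a total-expression value ``E`` (log2 scale, DNA-normalized) and an
allelic log-ratio ``R`` (log2 allele-A over allele-B, DNA-normalized).
``R`` is only defined at heterozygous sites; homozygous sites carry
expression information but are uninformative about imbalance.

Coordinates are 1-based internally; emitted BED/bedGraph files are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype classes
HOM = 0
HET = 1
MISSING = 2

GENO_LABELS = {HOM: "hom", HET: "het", MISSING: "na"}
GENO_CODES = {v: k for k, v in GENO_LABELS.items()}

SITE_COLUMNS = ["chrom", "pos", "snp_id", "alleleA", "alleleB", "genic"]


class DataError(ValueError):
    """Raised when an input violates the data-model invariants."""


@dataclass
class SiteTable:
    """Ordered table of biallelic polymorphic sites.

    Wraps a DataFrame with columns ``chrom, pos, snp_id, alleleA,
    alleleB, genic``.  Sites are strictly sorted by (chrom, pos) and
    positions are unique per chromosome.  Sites with three or more
    alleles are outside the model and must not be constructed.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"site table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy(dtype=np.int64)

    @property
    def genic(self) -> np.ndarray:
        return self.df["genic"].to_numpy(dtype=bool)

    def validate(self) -> "SiteTable":
        df = self.df
        if df["pos"].le(0).any():
            raise DataError("positions must be 1-based positive integers")
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise DataError(
                f"duplicate position {first['chrom']}:{first['pos']}"
            )
        # strictly sorted within chromosome, chromosomes grouped
        for _, sub in df.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise DataError("sites not sorted by position")
        chroms = df["chrom"].to_numpy()
        seen: list = []
        for c in chroms:
            if not seen or seen[-1] != c:
                if c in seen:
                    raise DataError(f"chromosome {c} not contiguous")
                seen.append(c)
        return self

    def sort(self) -> "SiteTable":
        """Return a copy sorted by (chrom, pos)."""
        order = self.df.sort_values(["chrom", "pos"], kind="mergesort").index
        return SiteTable(self.df.loc[order].reset_index(drop=True))

    def argsort(self) -> np.ndarray:
        return self.df.sort_values(
            ["chrom", "pos"], kind="mergesort"
        ).index.to_numpy()

    def chromosomes(self) -> list:
        out = []
        for c in self.df["chrom"]:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slices(self) -> dict:
        """Map chromosome -> slice of row indices (contiguous by invariant)."""
        out = {}
        chroms = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out


@dataclass
class SampleMatrix:
    """Site x individual observation arrays aligned to a SiteTable.

    ``geno`` holds HOM/HET/MISSING codes; ``E`` is finite wherever the
    genotype is not missing; ``R`` is defined exactly at het sites
    (NaN elsewhere).
    """

    individuals: list
    geno: np.ndarray  # (n_sites, n_ind) int8
    E: np.ndarray  # (n_sites, n_ind) float64, NaN where geno MISSING
    R: np.ndarray  # (n_sites, n_ind) float64, NaN where geno != HET

    @property
    def n_sites(self) -> int:
        return self.geno.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.geno.shape[1]

    def validate(self, sites: SiteTable | None = None) -> "SampleMatrix":
        if not (self.geno.shape == self.E.shape == self.R.shape):
            raise DataError("geno/E/R shape mismatch")
        if len(self.individuals) != self.geno.shape[1]:
            raise DataError("individual list does not match array width")
        if sites is not None and len(sites) != self.geno.shape[0]:
            raise DataError("matrix length does not match site table")
        het = self.geno == HET
        bad = np.isfinite(self.R) & ~het
        if bad.any():
            i, j = np.argwhere(bad)[0]
            name = self.individuals[j]
            raise DataError(
                f"R present at non-het site (row {i}, individual {name})"
            )
        obs = self.geno != MISSING
        if not np.isfinite(self.E[obs]).all():
            raise DataError("non-finite E at a non-missing genotype")
        return self

    def take_sites(self, idx) -> "SampleMatrix":
        return SampleMatrix(
            list(self.individuals), self.geno[idx], self.E[idx], self.R[idx]
        )


@dataclass
class ScoreTrack:
    """Per-site, per-individual AI score S for one scoring method.

    NaN marks sites where the method defines no score (e.g. homozygous
    sites for het-only methods).
    """

    scores: np.ndarray  # (n_sites, n_ind)
    method: str
    individuals: list = field(default_factory=list)

    @property
    def shape(self):
        return self.scores.shape


@dataclass
class Region:
    """A contiguous run of sites called as allelically imbalanced.

    ``start``/``end`` are 0-based half-open bp coordinates; ``sign`` is
    +1 for excess of allele A, -1 for allele B; ``n_snps`` counts the
    scored sites supporting the call.
    """

    chrom: str
    start: int
    end: int
    individual: str
    sign: int
    mean_score: float
    n_snps: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"degenerate region {self.start}-{self.end}")
        if self.sign not in (-1, 1):
            raise DataError("sign must be +1 or -1")
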