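"""Readers and writers for the tab-delimited interchange formats.

Two TSV files carry a dataset: a site table (chrom, pos, snp_id,
alleleA, alleleB, genic) and a sample matrix with one row per site and
three columns per individual (``<ind>.geno``, ``<ind>.E``, ``<ind>.R``).
Scores go out as one bedGraph per individual, region calls as BED6 with
the imbalance sign in the strand column.  Internal coordinates are
1-based; all emitted interval files are 0-based half-open.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    GENO_CODES,
    GENO_LABELS,
    HET,
    MISSING,
    DataError,
    Region,
    SampleMatrix,
    ScoreTrack,
    SiteTable,
)

_FLOAT_FMT = "%.6g"


def write_dataset(
    sites: SiteTable, matrix: SampleMatrix, site_path, matrix_path
) -> None:
    """Write a (SiteTable, SampleMatrix) pair as two TSV files."""
    df = sites.df.copy()
    df["genic"] = df["genic"].astype(int)
    df.to_csv(site_path, sep="\t", index=False)

    cols = {"snp_id": sites.df["snp_id"].to_numpy()}
    for j, ind in enumerate(matrix.individuals):
        cols[f"{ind}.geno"] = [GENO_LABELS[g] for g in matrix.geno[:, j]]
        cols[f"{ind}.E"] = matrix.E[:, j]
        cols[f"{ind}.R"] = matrix.R[:, j]
    pd.DataFrame(cols).to_csv(
        matrix_path, sep="\t", index=False, float_format="%.6g", na_rep="NA"
    )


def read_dataset(site_path, matrix_path) -> tuple[SiteTable, SampleMatrix]:
    """Read and validate a dataset; rows are returned sorted by (chrom, pos).

    Duplicate positions and R values at non-het sites are hard errors.
    """
    sdf = pd.read_csv(
        site_path, sep="\t", dtype={"chrom": str, "snp_id": str}
    )
    sdf["genic"] = sdf["genic"].astype(bool)
    sites = SiteTable(sdf)
    order = sites.argsort()
    sites = SiteTable(sdf.loc[order].reset_index(drop=True)).validate()

    mdf = pd.read_csv(matrix_path, sep="\t", na_values=["NA"])
    if len(mdf) != len(sites):
        raise DataError("matrix row count does not match site table")
    mdf = mdf.iloc[order].reset_index(drop=True)
    inds = [c[:-5] for c in mdf.columns if c.endswith(".geno")]
    n, k = len(mdf), len(inds)
    geno = np.empty((n, k), dtype=np.int8)
    E = np.empty((n, k))
    R = np.empty((n, k))
    for j, ind in enumerate(inds):
        try:
            geno[:, j] = [GENO_CODES[g] for g in mdf[f"{ind}.geno"]]
        except KeyError as exc:
            raise DataError(f"unknown genotype label {exc}") from exc
        E[:, j] = mdf[f"{ind}.E"].to_numpy(dtype=float)
        R[:, j] = mdf[f"{ind}.R"].to_numpy(dtype=float)
    matrix = SampleMatrix(inds, geno, E, R)
    matrix.validate(sites)
    return sites, matrix


def write_scores(track: ScoreTrack, sites: SiteTable, prefix) -> list:
    """Write one bedGraph per individual; returns the paths written.

    Missing (NaN) scores are omitted.  Files are named
    ``<prefix>.<individual>.bedGraph``.
    """
    if track.scores.shape[0] != len(sites):
        raise DataError("score track length does not match site table")
    prefix = str(prefix)
    chrom = sites.chrom
    pos = sites.pos
    paths = []
    for j, ind in enumerate(track.individuals):
        path = f"{prefix}.{ind}.bedGraph"
        s = track.scores[:, j]
        keep = np.isfinite(s)
        with open(path, "w") as fh:
            fh.write(
                f"track type=bedGraph name={track.method}.{ind}\n"
            )
            for i in np.flatnonzero(keep):
                fh.write(
                    f"{chrom[i]}\t{pos[i] - 1}\t{pos[i]}\t"
                    f"{_FLOAT_FMT % s[i]}\n"
                )
        paths.append(path)
    return paths


def read_scores(paths, sites: SiteTable, method: str) -> ScoreTrack:
    """Re-assemble a ScoreTrack from per-individual bedGraph files."""
    key = {
        (c, p): i for i, (c, p) in enumerate(zip(sites.chrom, sites.pos))
    }
    inds = []
    cols = []
    for path in paths:
        name = Path(path).name
        ind = name.split(".")[-2] if name.endswith(".bedGraph") else name
        inds.append(ind)
        col = np.full(len(sites), np.nan)
        with open(path) as fh:
            for line in fh:
                if line.startswith(("track", "#")) or not line.strip():
                    continue
                c, s, e, v = line.split("\t")
                col[key[(c, int(s) + 1)]] = float(v)
        cols.append(col)
    return ScoreTrack(np.column_stack(cols), method, inds)


def write_regions(regions: list, path) -> None:
    """Write region calls as BED6; strand encodes the imbalance sign.

    The name field is ``<individual>:<n_snps>`` so that a round trip
    preserves the SNP support count.  Overlapping regions for one
    individual violate the model and raise.
    """
    by_ind: dict = {}
    for r in regions:
        by_ind.setdefault((r.individual, r.chrom), []).append(r)
    for (ind, chrom), rs in by_ind.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise DataError(
                    f"overlapping regions for {ind} on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
    with open(path, "w") as fh:
        for r in regions:
            strand = "+" if r.sign > 0 else "-"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t"
                f"{r.individual}:{r.n_snps}\t"
                f"{_FLOAT_FMT % r.mean_score}\t{strand}\n"
            )


def read_regions(path) -> list:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split(
                "\t"
            )
            ind, n_snps = name.rsplit(":", 1)
            regions.append(
                Region(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    individual=ind,
                    sign=1 if strand == "+" else -1,
                    mean_score=float(score),
                    n_snps=int(n_snps),
                )
            )
    return regions


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ intervals (0-based half-open); strand kept if present."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            row = {
                "chrom": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
            }
            if len(parts) >= 4:
                row["name"] = parts[3]
            if len(parts) >= 6:
                row["strand"] = parts[5]
            rows.append(row)
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "strand"]
    )


def write_histogram(edges: np.ndarray, mass: np.ndarray, path) -> None:
    """Serialize a histogram as two-column TSV (bin_left_edge, mass).

    A final row carries the right edge of the last bin with zero mass so
    the full support round-trips.
    """
    with open(path, "w") as fh:
        fh.write("bin_left_edge\tmass\n")
        for e, m in zip(edges[:-1], mass):
            fh.write(f"{e!r}\t{m!r}\n")
        fh.write(f"{edges[-1]!r}\t0.0\n")


def read_histogram(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    edges = df["bin_left_edge"].to_numpy(dtype=float)
    mass = df["mass"].to_numpy(dtype=float)[:-1]
    return edges, mass
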