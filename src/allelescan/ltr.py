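"""Multi-sample left-to-right HMM with per-gap transition matrices.

Each genomic site carries its own copy of the ergodic state set, and
transitions only run between states of neighbouring sites, left to
right (a profile-HMM-like layout).  All copies of a state share the
ergodic model's emissions.  What is position-specific is the transition
matrix A_i for each inter-site gap; this lets the model learn, from all
individuals jointly, where in the genome entries into (and exits from)
imbalanced states are common, and then decode each individual
separately with that shared prior knowledge.

Training is two-stage.  Stage one trains the ergodic model on all
individuals (see :mod:`allelescan.ergodic`).  Stage two runs EM over
the per-gap matrices only, treating each individual's sequence as an
independent run of the HMM, with the distance-corrected ergodic
transitions P_i = T^(d_i/D) as a pseudocount prior:

    A_i(s,t) = (sum_j xi_j,i(s,t) + w * P_i(s,t))
               / (sum_j gamma_j,i(s) + w)

where j ranges over individuals and w is the pseudocount weight.  With
w -> infinity the model reduces exactly to the distance-corrected
ergodic decoder; with w = 0 and one individual it is unregularized
per-gap EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._hmmcore import forward_backward_kernel, viterbi_kernel
from .data import DataError, SampleMatrix, ScoreTrack, SiteTable
from .ergodic import (
    ErgodicModel,
    _scaled_emissions,
    emission_loglik,
    posterior_expected_logratio,
)

_TINY = 1e-300


def build_priors(ergodic: ErgodicModel, positions: np.ndarray) -> np.ndarray:
    """Per-gap prior matrices P_i = T^(d_i/D) for one chromosome."""
    positions = np.asarray(positions, dtype=np.int64)
    gaps = np.diff(positions)
    if (gaps <= 0).any():
        raise DataError("positions must be strictly increasing (gap > 0)")
    A, idx = ergodic.kernel().stack_for_gaps(gaps)
    return A[idx]


@dataclass
class LTRModel:
    """Per-chromosome per-gap transitions tied to an ergodic prior."""

    ergodic: ErgodicModel
    chrom_positions: dict  # chrom -> (n,) positions
    A: dict  # chrom -> (n-1, S, S) trained per-gap transitions
    P: dict  # chrom -> (n-1, S, S) priors
    w: float
    pi: np.ndarray
    loglik_history: list = field(default_factory=list)


def train_ltr(
    sites: SiteTable,
    matrix: SampleMatrix,
    ergodic: ErgodicModel,
    w: float = 10.0,
    max_iter: int = 200,
    abs_tol: float = 1e-4,
    rel_tol: float = 0.01,
) -> LTRModel:
    """Stage-two EM over per-gap transitions, emissions fixed.

    The joint log-likelihood (summed over individuals) is checked to be
    non-decreasing at every iteration.  Initial A_i = P_i.
    """
    if w < 0:
        raise DataError("pseudocount weight w must be >= 0")
    pi = ergodic.pi.copy()
    chrom_positions = {}
    A_all = {}
    P_all = {}
    history = []
    for chrom, sl in sites.chrom_slices().items():
        pos = sites.pos[sl]
        chrom_positions[chrom] = pos
        n = len(pos)
        P = build_priors(ergodic, pos)
        A = P.copy()
        # emissions never change in stage two: precompute per individual
        Bs = []
        for j in range(matrix.n_individuals):
            L = emission_loglik(
                ergodic, matrix.E[sl, j], matrix.R[sl, j], matrix.geno[sl, j]
            )
            Bs.append(_scaled_emissions(L))
        gap_idx = np.arange(n - 1, dtype=np.int64)
        hist = []
        for it in range(max_iter):
            ll = 0.0
            xi_sum = np.zeros_like(A)
            gamma_sum = np.zeros((n - 1, A.shape[1]))
            for B, off in Bs:
                gamma, xi, log_c = forward_backward_kernel(
                    pi, A, gap_idx, B
                )
                ll += float(log_c + off)
                xi_sum += xi
                gamma_sum += gamma[:-1]
            if hist and ll < hist[-1] - (1e-8 + 1e-9 * abs(hist[-1])):
                raise RuntimeError(
                    f"LTR EM log-likelihood decreased at iteration {it} "
                    f"on {chrom}: {hist[-1]} -> {ll}"
                )
            hist.append(ll)
            A_new = (xi_sum + w * P) / (gamma_sum[:, :, None] + w)
            delta = np.abs(A_new - A)
            A = A_new
            if np.all(delta < np.maximum(abs_tol, rel_tol * np.abs(A))):
                break
        A_all[chrom] = A
        P_all[chrom] = P
        history.append(hist)
    return LTRModel(
        ergodic, chrom_positions, A_all, P_all, w, pi, history
    )


def decode_ltr(
    model: LTRModel,
    chrom,
    E,
    R,
    geno,
    mode: str = "posterior",
):
    """Decode one individual's sequence on one chromosome.

    ``mode='posterior'`` returns (gamma, loglik); ``mode='viterbi'``
    returns the state path.  The sequence must align with the model's
    site list for that chromosome.
    """
    if chrom not in model.A:
        raise DataError(f"no trained transitions for chromosome {chrom}")
    A = model.A[chrom]
    n = len(model.chrom_positions[chrom])
    E = np.asarray(E, dtype=float)
    if len(E) != n:
        raise DataError(
            f"sequence length {len(E)} does not match model sites {n}"
        )
    L = emission_loglik(model.ergodic, E, R, geno)
    gap_idx = np.arange(n - 1, dtype=np.int64)
    if mode == "viterbi":
        path, _ = viterbi_kernel(
            np.log(np.maximum(model.pi, _TINY)),
            np.log(np.maximum(A, _TINY)),
            gap_idx,
            L,
        )
        return path
    B, off = _scaled_emissions(L)
    gamma, _, log_c = forward_backward_kernel(model.pi, A, gap_idx, B)
    return gamma, float(log_c + off)


def score_ltr(
    sites: SiteTable, matrix: SampleMatrix, model: LTRModel
) -> ScoreTrack:
    """Posterior expected log-ratio track from the left-to-right model."""
    scores = np.full(matrix.geno.shape, np.nan)
    mu = model.ergodic.score_mu()
    for chrom, sl in sites.chrom_slices().items():
        for j in range(matrix.n_individuals):
            gamma, _ = decode_ltr(
                model,
                chrom,
                matrix.E[sl, j],
                matrix.R[sl, j],
                matrix.geno[sl, j],
            )
            scores[sl, j] = gamma @ mu
    return ScoreTrack(scores, "ltr", list(matrix.individuals))


def viterbi_calls_ltr(
    sites: SiteTable, matrix: SampleMatrix, model: LTRModel
) -> np.ndarray:
    """Boolean AI calls from per-individual Viterbi paths."""
    calls = np.zeros(matrix.geno.shape, dtype=bool)
    erg = model.ergodic
    S = erg.n_states
    balanced = erg.m + 1
    ai_states = np.array(
        [s for s in range(1, S) if s != balanced], dtype=np.int64
    )
    for chrom, sl in sites.chrom_slices().items():
        for j in range(matrix.n_individuals):
            path = decode_ltr(
                model,
                chrom,
                matrix.E[sl, j],
                matrix.R[sl, j],
                matrix.geno[sl, j],
                mode="viterbi",
            )
            calls[sl, j] = np.isin(path, ai_states)
    return calls
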