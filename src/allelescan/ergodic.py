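"""Single-sample ergodic HMM over (E, R) observations.

The model has 2m+2 states: N (not transcribed), and 2m+1 expressed
states spanning m levels of negative imbalance, balance, and m levels
of positive imbalance (m=3 gives the default 8-state model).  Each
expressed state emits E from a shared, fixed "expressed" histogram and
R from a state-specific normal(mu_s, sigma_s); N emits E from the fixed
"non-expressed" histogram and R from a broad fixed zero-mean normal, so
classification of non-expressed sites is driven by expression alone.
At homozygous sites R is unobserved and all states are scored on E
only, which lets homozygous SNPs help delineate expressed regions.

Baum-Welch trains mu_s, sigma_s, the homogeneous transition matrix T
and the initial distribution pi on the pooled sequences of all
individuals; the expression emissions stay fixed.  After training, a
per-base-pair "unit" kernel T1 = T^(1/D) (D = mean inter-SNP gap, bp)
is taken via eigendecomposition, and decoding uses T(d) = T1^d for each
actual gap d, so state persistence decays with genomic distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._hmmcore import forward_backward_kernel, viterbi_kernel
from .data import HET, MISSING, DataError, SampleMatrix, ScoreTrack, SiteTable
from .preprocess import Histogram

_LOG_2PI = float(np.log(2.0 * np.pi))
_TINY = 1e-300


def state_labels(m: int) -> list:
    """State labels, index 0 = N, expressed states ordered by mean R."""
    return (
        ["N"]
        + [f"M{i}" for i in range(m, 0, -1)]
        + ["B"]
        + [f"P{i}" for i in range(1, m + 1)]
    )


def _project_stochastic(M: np.ndarray) -> np.ndarray:
    M = np.clip(M, 0.0, None)
    rows = M.sum(axis=1, keepdims=True)
    if (rows <= 0).any():
        raise DataError("transition row collapsed to zero mass")
    return M / rows


class TransitionKernel:
    """Distance-dependent transitions from a trained homogeneous matrix.

    Caches the eigendecomposition of T; ``at_distance(d)`` returns
    T^(d/D) projected back to a stochastic matrix (tiny negative
    entries from rounding clipped, rows renormalized).
    """

    def __init__(self, T: np.ndarray, D: float, imag_tol: float = 1e-8):
        if D <= 0:
            raise DataError("mean inter-SNP distance D must be positive")
        T = np.asarray(T, dtype=float)
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("T rows must sum to 1")
        self.T = T
        self.D = float(D)
        self.imag_tol = imag_tol
        w, V = scipy.linalg.eig(T)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > 1e12:
            raise DataError(
                "transition matrix is near-defective; jitter it slightly "
                "before taking fractional powers"
            )
        # a trained T occasionally carries a tiny negative real
        # eigenvalue; its mode decays within one step, but a principal
        # fractional power would be complex, so floor it at a small
        # positive value (complex-conjugate pairs are fine as they
        # cancel in the reconstruction)
        real_neg = (np.abs(w.imag) < 1e-10) & (w.real < 1e-6)
        w = np.where(real_neg, 1e-6 + 0j, w)
        self.eigvals = w
        self.V = V
        self.Vinv = np.linalg.inv(V)

    def power_raw(self, exponent: float) -> np.ndarray:
        """T**exponent via principal-branch eigenvalue powers, un-projected."""
        lam = np.power(self.eigvals.astype(complex), exponent)
        M = (self.V * lam) @ self.Vinv
        if np.abs(M.imag).max() > self.imag_tol:
            raise DataError(
                "fractional matrix power has a non-negligible imaginary "
                "part (negative or complex eigenvalue); jitter T"
            )
        return M.real

    def at_distance(self, d: float) -> np.ndarray:
        """Stochastic T(d) = T^(d/D); T(0) is the identity."""
        if d < 0:
            raise DataError("distance must be nonnegative")
        if d == 0:
            return np.eye(len(self.T))
        return _project_stochastic(self.power_raw(d / self.D))

    def unit(self) -> np.ndarray:
        """Per-base-pair transition matrix T1 = T^(1/D)."""
        return _project_stochastic(self.power_raw(1.0 / self.D))

    def stack_for_gaps(self, gaps: np.ndarray):
        """(A stack, gap index) for an array of inter-site gaps in bp."""
        gaps = np.asarray(gaps)
        uniq, idx = np.unique(gaps, return_inverse=True)
        S = len(self.T)
        A = np.empty((len(uniq), S, S))
        for g, d in enumerate(uniq):
            A[g] = self.at_distance(float(d))
        return A, idx.astype(np.int64)


def unit_transition(T: np.ndarray, D: float) -> np.ndarray:
    """D-th root of a row-stochastic matrix, projected to stochastic."""
    return TransitionKernel(T, D).unit()


def transition_at_distance(T1: np.ndarray, d: float) -> np.ndarray:
    """Power a unit (per-bp) kernel up to distance d."""
    return TransitionKernel(T1, 1.0).at_distance(d)


@dataclass
class ErgodicModel:
    m: int
    mu: np.ndarray  # (S,) mean R per state; mu[0] (N) fixed at 0
    sigma: np.ndarray  # (S,) sd of R; sigma[0] is the fixed broad sd for N
    hist_expressed: Histogram
    hist_nonexpressed: Histogram
    T: np.ndarray  # (S,S) homogeneous trained transitions
    pi: np.ndarray  # (S,)
    D: float  # mean inter-SNP gap (bp)
    loglik_history: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return 2 * self.m + 2

    @property
    def labels(self) -> list:
        return state_labels(self.m)

    def kernel(self) -> TransitionKernel:
        return TransitionKernel(self.T, self.D)

    def score_mu(self) -> np.ndarray:
        """State means used for the posterior expected log-ratio (N -> 0)."""
        mu = self.mu.copy()
        mu[0] = 0.0
        return mu

    def validate(self) -> "ErgodicModel":
        S = self.n_states
        if not (len(self.mu) == len(self.sigma) == S):
            raise DataError("state parameter length mismatch")
        if (self.sigma <= 0).any():
            raise DataError("sigma must be positive")
        if not np.all(np.diff(self.mu[1:]) >= 0):
            raise DataError("expressed-state means must be ordered")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise DataError("pi must sum to 1")
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("T rows must sum to 1")
        return self

    def to_json(self, path=None) -> str:
        obj = {
            "m": self.m,
            "labels": self.labels,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "T": self.T.tolist(),
            "pi": self.pi.tolist(),
            "D": self.D,
            "hist_expressed": {
                "edges": self.hist_expressed.edges.tolist(),
                "mass": self.hist_expressed.mass.tolist(),
            },
            "hist_nonexpressed": {
                "edges": self.hist_nonexpressed.edges.tolist(),
                "mass": self.hist_nonexpressed.mass.tolist(),
            },
        }
        text = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ErgodicModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith(
            "{"
        ):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            m=obj["m"],
            mu=np.array(obj["mu"]),
            sigma=np.array(obj["sigma"]),
            hist_expressed=Histogram(
                np.array(obj["hist_expressed"]["edges"]),
                np.array(obj["hist_expressed"]["mass"]),
            ),
            hist_nonexpressed=Histogram(
                np.array(obj["hist_nonexpressed"]["edges"]),
                np.array(obj["hist_nonexpressed"]["mass"]),
            ),
            T=np.array(obj["T"]),
            pi=np.array(obj["pi"]),
            D=obj["D"],
        )


def make_initial_model(
    m: int,
    hist_expressed: Histogram,
    hist_nonexpressed: Histogram,
    D: float,
    sigma0: float = 0.5,
    sigma_N: float = 2.0,
    self_loop: float = 0.9,
) -> ErgodicModel:
    """Initial model: mu grid 0, +/-0.5, +/-1, +/-2, ... (doubling levels).

    Training refines mu/sigma; the ordering constraint applied after
    each M-step keeps state identities stable.
    """
    mags = 0.5 * 2.0 ** np.arange(m)
    mu_expr = np.concatenate([-mags[::-1], [0.0], mags])
    S = 2 * m + 2
    mu = np.concatenate([[0.0], mu_expr])
    sigma = np.concatenate([[sigma_N], np.full(2 * m + 1, sigma0)])
    T = np.full((S, S), (1.0 - self_loop) / (S - 1))
    np.fill_diagonal(T, self_loop)
    pi = np.full(S, 1.0 / S)
    return ErgodicModel(
        m, mu, sigma, hist_expressed, hist_nonexpressed, T, pi, D
    )


def emission_loglik(
    model: ErgodicModel, E: np.ndarray, R: np.ndarray, geno: np.ndarray
) -> np.ndarray:
    """Per-site, per-state log-likelihood matrix (n, S).

    Het sites combine the E histogram term with the state's normal over
    R; at hom sites R is marginalized out (no R term for any state);
    missing-genotype sites contribute nothing to any state.
    """
    E = np.asarray(E, dtype=float)
    R = np.asarray(R, dtype=float)
    geno = np.asarray(geno)
    n = len(E)
    S = model.n_states
    L = np.zeros((n, S))
    obs = geno != MISSING
    if obs.any():
        L[obs, 0] = model.hist_nonexpressed.logpdf(E[obs])
        L[obs, 1:] = model.hist_expressed.logpdf(E[obs])[:, None]
    het = geno == HET
    if het.any():
        r = R[het][:, None]
        mu = model.mu[None, :]
        sd = model.sigma[None, :]
        L[het] += (
            -0.5 * _LOG_2PI - np.log(sd) - 0.5 * ((r - mu) / sd) ** 2
        )
    return L


def _scaled_emissions(L: np.ndarray):
    off = L.max(axis=1)
    return np.exp(L - off[:, None]), float(off.sum())


def forward_backward(
    model: ErgodicModel,
    E,
    R,
    geno,
    positions=None,
):
    """Posterior decode one sequence.

    With ``positions`` given, transitions are distance-corrected per
    gap via the unit kernel; otherwise the homogeneous T is used for
    every gap.  Returns (gamma, xi, loglik).
    """
    L = emission_loglik(model, E, R, geno)
    B, off = _scaled_emissions(L)
    n = len(B)
    if n == 1:
        g = model.pi * B[0]
        tot = g.sum()
        if tot <= 0:
            raise DataError("zero emission likelihood at site 0")
        gamma = (g / tot)[None, :]
        return gamma, np.empty((0, model.n_states, model.n_states)), float(
            np.log(tot) + off
        )
    A, gap_idx = _transition_stack(model, n, positions)
    gamma, xi, log_c = forward_backward_kernel(
        model.pi, A, gap_idx, B
    )
    return gamma, xi, float(log_c + off)


def _transition_stack(model: ErgodicModel, n: int, positions):
    if positions is None:
        A = model.T[None, :, :].copy()
        gap_idx = np.zeros(n - 1, dtype=np.int64)
    else:
        positions = np.asarray(positions, dtype=np.int64)
        gaps = np.diff(positions)
        if (gaps <= 0).any():
            raise DataError("positions must be strictly increasing")
        A, gap_idx = model.kernel().stack_for_gaps(gaps)
    return A, gap_idx


def viterbi(model: ErgodicModel, E, R, geno, positions=None) -> np.ndarray:
    """Most probable state path (ties toward lower state index)."""
    L = emission_loglik(model, E, R, geno)
    n = len(L)
    if n == 1:
        v = np.log(np.maximum(model.pi, _TINY)) + L[0]
        return np.array([int(np.argmax(v))])
    A, gap_idx = _transition_stack(model, n, positions)
    path, _ = viterbi_kernel(
        np.log(np.maximum(model.pi, _TINY)),
        np.log(np.maximum(A, _TINY)),
        gap_idx,
        L,
    )
    return path


def posterior_expected_logratio(
    gamma: np.ndarray, model: ErgodicModel
) -> np.ndarray:
    """Summary score per site: sum_s P(state s | data) * mu_s, mu_N = 0."""
    return gamma @ model.score_mu()


def baum_welch_train(
    sequences,
    init: ErgodicModel,
    max_iter: int = 200,
    abs_tol: float = 1e-4,
    rel_tol: float = 0.01,
    min_sigma: float = 0.01,
    verbose: bool = False,
) -> ErgodicModel:
    """Pooled Baum-Welch over multiple (E, R, geno) sequences.

    Trains mu_s and sigma_s of the expressed states, T and pi; the E
    emissions (histograms) and the N state's R distribution stay fixed.
    Convergence is declared when no parameter moved by more than
    ``abs_tol`` or ``rel_tol`` (1%) of its previous value.  Expressed
    states are re-sorted by mu after every M-step (with T and pi
    permuted consistently), preventing label switching.  The total
    log-likelihood is checked to be non-decreasing every iteration.
    """
    model = ErgodicModel(
        init.m,
        init.mu.copy(),
        init.sigma.copy(),
        init.hist_expressed,
        init.hist_nonexpressed,
        init.T.copy(),
        init.pi.copy(),
        init.D,
    )
    S = model.n_states
    history: list = []

    # E-part of emissions and het masks never change across iterations
    prepped = []
    for E, R, geno in sequences:
        E = np.asarray(E, dtype=float)
        R = np.asarray(R, dtype=float)
        geno = np.asarray(geno)
        Lfix = np.zeros((len(E), S))
        obs = geno != MISSING
        Lfix[obs, 0] = model.hist_nonexpressed.logpdf(E[obs])
        Lfix[obs, 1:] = model.hist_expressed.logpdf(E[obs])[:, None]
        het = geno == HET
        prepped.append((Lfix, het, R))

    for it in range(max_iter):
        old = np.concatenate(
            [model.mu[1:], model.sigma[1:], model.T.ravel(), model.pi]
        )
        ll = 0.0
        trans = np.zeros((S, S))
        pi_acc = np.zeros(S)
        wsum = np.zeros(S)
        wx = np.zeros(S)
        wx2 = np.zeros(S)
        for Lfix, het, R in prepped:
            L = Lfix.copy()
            if het.any():
                r = R[het][:, None]
                mu = model.mu[None, :]
                sd = model.sigma[None, :]
                L[het] += (
                    -0.5 * _LOG_2PI
                    - np.log(sd)
                    - 0.5 * ((r - mu) / sd) ** 2
                )
            B, off = _scaled_emissions(L)
            n = len(B)
            if n == 1:
                g = model.pi * B[0]
                tot = g.sum()
                gamma = (g / tot)[None, :]
                ll += float(np.log(tot) + off)
                pi_acc += gamma[0]
            else:
                A = model.T[None, :, :].copy()
                gap_idx = np.zeros(n - 1, dtype=np.int64)
                gamma, xi, log_c = forward_backward_kernel(
                    model.pi, A, gap_idx, B
                )
                ll += float(log_c + off)
                trans += xi.sum(axis=0)
                pi_acc += gamma[0]
            gh = gamma[het]
            rh = R[het]
            wsum += gh.sum(axis=0)
            wx += gh.T @ rh
            wx2 += gh.T @ (rh * rh)

        if history and ll < history[-1] - (1e-8 + 1e-9 * abs(history[-1])):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{history[-1]} -> {ll}"
            )
        history.append(ll)
        if verbose:
            print(f"iter {it}: loglik {ll:.4f}")

        # M-step: expressed-state normals over R (het sites only)
        for s in range(1, S):
            if wsum[s] > 1e-8:
                m_new = wx[s] / wsum[s]
                v_new = wx2[s] / wsum[s] - m_new * m_new
                model.mu[s] = m_new
                model.sigma[s] = max(np.sqrt(max(v_new, 0.0)), min_sigma)
        rows = trans.sum(axis=1)
        nz = rows > 0
        model.T[nz] = trans[nz] / rows[nz, None]
        model.pi = pi_acc / pi_acc.sum()

        # enforce mu ordering of expressed states (label permutation;
        # does not change the likelihood)
        order = np.argsort(model.mu[1:], kind="stable")
        perm = np.concatenate([[0], 1 + order])
        model.mu = model.mu[perm]
        model.sigma = model.sigma[perm]
        model.T = model.T[np.ix_(perm, perm)]
        model.pi = model.pi[perm]

        new = np.concatenate(
            [model.mu[1:], model.sigma[1:], model.T.ravel(), model.pi]
        )
        delta = np.abs(new - old)
        if np.all(delta < np.maximum(abs_tol, rel_tol * np.abs(old))):
            break

    model.loglik_history = history
    return model


def sequences_from_dataset(sites: SiteTable, matrix: SampleMatrix):
    """Per-chromosome, per-individual (E, R, geno) training sequences."""
    seqs = []
    for chrom, sl in sites.chrom_slices().items():
        for j in range(matrix.n_individuals):
            seqs.append(
                (matrix.E[sl, j], matrix.R[sl, j], matrix.geno[sl, j])
            )
    return seqs


def mean_gap(sites: SiteTable) -> float:
    """Average distance in bp between consecutive SNPs, pooled."""
    gaps = []
    for chrom, sl in sites.chrom_slices().items():
        p = sites.pos[sl]
        if len(p) > 1:
            gaps.append(np.diff(p))
    if not gaps:
        raise DataError("need at least two sites on one chromosome")
    return float(np.concatenate(gaps).mean())


def fit_ergodic(
    sites: SiteTable,
    matrix: SampleMatrix,
    m: int = 3,
    n_bins: int = 200,
    p_genic_expressed: float = 0.5,
    p_intergenic_expressed: float = 0.1,
    **train_opts,
) -> ErgodicModel:
    """End-to-end stage-one fit on a dataset.

    Builds genic/intergenic E histograms, deconvolves them into the
    fixed expressed/non-expressed emission distributions, and runs
    pooled Baum-Welch over all individuals and chromosomes.
    """
    from .preprocess import deconvolve_expression, expression_histograms

    hg, hi = expression_histograms(sites, matrix, n_bins=n_bins)
    h_expr, h_non = deconvolve_expression(
        hg, hi, p_genic_expressed, p_intergenic_expressed
    )
    init = make_initial_model(m, h_expr, h_non, mean_gap(sites))
    return baum_welch_train(
        sequences_from_dataset(sites, matrix), init, **train_opts
    )


def score_ergodic(
    sites: SiteTable, matrix: SampleMatrix, model: ErgodicModel
) -> ScoreTrack:
    """Posterior expected log-ratio track with distance-corrected decoding."""
    scores = np.full(matrix.geno.shape, np.nan)
    mu = model.score_mu()
    for chrom, sl in sites.chrom_slices().items():
        pos = sites.pos[sl]
        for j in range(matrix.n_individuals):
            gamma, _, _ = forward_backward(
                model,
                matrix.E[sl, j],
                matrix.R[sl, j],
                matrix.geno[sl, j],
                positions=pos,
            )
            scores[sl, j] = gamma @ mu
    return ScoreTrack(scores, "ergodic", list(matrix.individuals))


def viterbi_calls(
    sites: SiteTable, matrix: SampleMatrix, model: ErgodicModel
) -> np.ndarray:
    """Boolean (n_sites, n_ind) AI calls: Viterbi state is imbalanced.

    Imbalanced means an expressed state other than the balanced one
    (the middle expressed state, whose trained mean sits nearest zero).
    """
    calls = np.zeros(matrix.geno.shape, dtype=bool)
    S = model.n_states
    balanced = model.m + 1  # expressed states 1..S-1 sorted by mu
    ai_states = np.array(
        [s for s in range(1, S) if s != balanced], dtype=np.int64
    )
    for chrom, sl in sites.chrom_slices().items():
        pos = sites.pos[sl]
        for j in range(matrix.n_individuals):
            path = viterbi(
                model,
                matrix.E[sl, j],
                matrix.R[sl, j],
                matrix.geno[sl, j],
                positions=pos,
            )
            calls[sl, j] = np.isin(path, ai_states)
    return calls
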