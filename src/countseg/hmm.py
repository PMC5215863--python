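"""HMM over binned count tracks: initialization, forward-backward, Baum-Welch.

The hidden state of each genomic bin is a chromatin state; each state emits
the D track counts independently from its per-track emission distribution
(see :mod:`countseg.emissions`). Recursions run in log space and are
numba-compiled so genome-scale sequences fit comfortably in memory and time.

Initialization follows the thresholding/k-means scheme common for sparse
sequencing signals: per-track Poisson-tail thresholds zero out noise-level
counts, bins with no remaining signal form a background cluster, and k-means
on log counts partitions the rest into K-1 clusters whose moments seed the
emission parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats
from sklearn.cluster import KMeans

from countseg.emissions import (
    EmissionGrid,
    GroupedCounts,
    NegBinomParams,
    PoilogParams,
    SIGMA_MIN,
    MU_FLOOR,
    fit_emission,
    group_counts,
)
from countseg.io_binning import CountMatrix, SizeFactors

MODEL_FORMAT_VERSION = 1


@dataclass
class HMMModel:
    initial_probs: np.ndarray     # pi, length K
    transitions: np.ndarray       # A, K x K row-stochastic
    emissions: EmissionGrid
    track_names: tuple[str, ...]
    bin_width: int

    def __post_init__(self):
        pi = np.asarray(self.initial_probs, dtype=float)
        A = np.asarray(self.transitions, dtype=float)
        K = len(pi)
        if K < 1:
            raise ValueError("need at least one state")
        if A.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if np.any(pi < 0) or np.any(A < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("initial probabilities must sum to 1")
        if np.max(np.abs(A.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition rows must sum to 1")
        if self.emissions.n_states != K:
            raise ValueError("emission grid state count mismatch")
        if self.emissions.n_tracks != len(self.track_names):
            raise ValueError("emission grid track count mismatch")
        self.initial_probs = pi
        self.transitions = A
        self.track_names = tuple(self.track_names)

    @property
    def n_states(self) -> int:
        return len(self.initial_probs)

    @property
    def family(self) -> str:
        return self.emissions.family


@dataclass
class PosteriorMatrix:
    gamma: np.ndarray        # (T, K), rows sum to 1
    log_likelihood: float


@dataclass
class FitTrace:
    log_likelihoods: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def poisson_threshold(lambda_d: float, tail: float = 1e-4) -> int:
    """Smallest n > 0 with Pr(X > n) < tail for X ~ Poisson(lambda_d)."""
    if lambda_d < 0:
        raise ValueError("lambda must be non-negative")
    n = 1
    while stats.poisson.sf(n, lambda_d) >= tail:
        n += 1
    return n


# ---------------------------------------------------------------------------
# numba log-space recursions

@njit(cache=True)
def _logsumexp_vec(v):
    m = v[0]
    for i in range(1, v.shape[0]):
        if v[i] > m:
            m = v[i]
    if m == -np.inf:
        return -np.inf
    acc = 0.0
    for i in range(v.shape[0]):
        acc += np.exp(v[i] - m)
    return m + np.log(acc)


@njit(cache=True)
def _forward_log(log_pi, log_A, log_B):
    T, K = log_B.shape
    la = np.empty((T, K))
    for k in range(K):
        la[0, k] = log_pi[k] + log_B[0, k]
    tmp = np.empty(K)
    for t in range(1, T):
        for j in range(K):
            for i in range(K):
                tmp[i] = la[t - 1, i] + log_A[i, j]
            la[t, j] = _logsumexp_vec(tmp) + log_B[t, j]
    return la, _logsumexp_vec(la[T - 1])


@njit(cache=True)
def _backward_log(log_A, log_B):
    T, K = log_B.shape
    lb = np.empty((T, K))
    for k in range(K):
        lb[T - 1, k] = 0.0
    tmp = np.empty(K)
    for t in range(T - 2, -1, -1):
        for i in range(K):
            for j in range(K):
                tmp[j] = log_A[i, j] + log_B[t + 1, j] + lb[t + 1, j]
            lb[t, i] = _logsumexp_vec(tmp)
    return lb


@njit(cache=True)
def _xi_sum(la, lb, log_A, log_B, loglik):
    T, K = log_B.shape
    xi = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi[i, j] += np.exp(la[t, i] + log_A[i, j]
                                   + log_B[t + 1, j] + lb[t + 1, j] - loglik)
    return xi


@njit(cache=True)
def _viterbi_log(log_pi, log_A, log_B):
    T, K = log_B.shape
    delta = np.empty((T, K))
    back = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + log_B[0, k]
    for t in range(1, T):
        for j in range(K):
            best_i = 0
            best = delta[t - 1, 0] + log_A[0, j]
            for i in range(1, K):
                v = delta[t - 1, i] + log_A[i, j]
                if v > best:  # strict: ties stay at the lower index
                    best = v
                    best_i = i
            delta[t, j] = best + log_B[t, j]
            back[t, j] = best_i
    path = np.empty(T, dtype=np.int64)
    best_k = 0
    best = delta[T - 1, 0]
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            best_k = k
    path[T - 1] = best_k
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path, best


# ---------------------------------------------------------------------------

_PROB_FLOOR = 1e-300


def _size_vector(model: HMMModel, counts: CountMatrix, size_factors) -> np.ndarray:
    if size_factors is None:
        return np.ones(len(model.track_names))
    if isinstance(size_factors, SizeFactors):
        # stored factors normalize counts to the mean library; the emission
        # mean of a cell type scales with its relative depth, i.e. 1/s
        return size_factors.mean_scaling(counts.cell_type or
                                         size_factors.factors.columns[0],
                                         model.track_names)
    return np.asarray(size_factors, dtype=float)


def _check_tracks(model: HMMModel, counts: CountMatrix) -> None:
    if tuple(counts.track_names) != model.track_names:
        raise ValueError(f"count tracks {counts.track_names} do not match "
                         f"model tracks {model.track_names}")


def _log_pi_A(model):
    with np.errstate(divide="ignore"):
        return (np.log(np.maximum(model.initial_probs, _PROB_FLOOR)),
                np.log(np.maximum(model.transitions, _PROB_FLOOR)))


def forward_backward(model: HMMModel, counts: CountMatrix,
                     size_factors=None) -> PosteriorMatrix:
    """Posterior state probabilities Pr(s_t = i | O) and log Pr(O)."""
    _check_tracks(model, counts)
    s = _size_vector(model, counts, size_factors)
    log_B = model.emissions.log_emission_matrix(counts.counts, s)
    log_pi, log_A = _log_pi_A(model)
    la, loglik = _forward_log(log_pi, log_A, log_B)
    lb = _backward_log(log_A, log_B)
    if not np.isfinite(loglik):
        raise FloatingPointError("non-finite log-likelihood")
    lg = la + lb - loglik
    gamma = np.exp(lg)
    gamma /= gamma.sum(axis=1, keepdims=True)
    return PosteriorMatrix(gamma=gamma, log_likelihood=float(loglik))


def _e_step(model, counts, size_factors):
    _check_tracks(model, counts)
    s = _size_vector(model, counts, size_factors)
    log_B = model.emissions.log_emission_matrix(counts.counts, s)
    log_pi, log_A = _log_pi_A(model)
    la, loglik = _forward_log(log_pi, log_A, log_B)
    lb = _backward_log(log_A, log_B)
    gamma = np.exp(la + lb - loglik)
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = _xi_sum(la, lb, log_A, log_B, loglik)
    return gamma, xi, float(loglik), s


def baum_welch(model: HMMModel, sequences, size_factors=None,
               max_iter: int = 100, tol: float = 1e-6,
               seed: int = 0) -> tuple[HMMModel, FitTrace]:
    """EM fit of pi, A and the emission grid on one or more count sequences.

    The emission M-step pools posterior weights across sequences and groups
    them by unique (count, size factor) per state and track before numerical
    maximization, so its cost scales with the number of distinct counts, not
    with genome size.
    """
    if isinstance(sequences, CountMatrix):
        sequences = [sequences]
    if not sequences:
        raise ValueError("need at least one sequence")
    trace = FitTrace()
    prev_ll = None
    for it in range(max_iter):
        gammas, xis, lls, svecs = [], [], [], []
        for cm in sequences:
            gamma, xi, ll, s = _e_step(model, cm, size_factors)
            if not np.isfinite(ll):
                raise FloatingPointError(f"non-finite likelihood at iteration {it}")
            gammas.append(gamma)
            xis.append(xi)
            lls.append(ll)
            svecs.append(s)
        total_ll = float(sum(lls))
        trace.log_likelihoods.append(total_ll)
        trace.iterations = it + 1
        if prev_ll is not None and total_ll - prev_ll < tol * abs(prev_ll):
            trace.converged = True
            break
        prev_ll = total_ll

        K = model.n_states
        pi = sum(g[0] for g in gammas)
        pi = np.maximum(pi, _PROB_FLOOR)
        pi /= pi.sum()
        A = sum(xis)
        A = np.maximum(A, _PROB_FLOOR)
        A /= A.sum(axis=1, keepdims=True)
        new_params = []
        for k in range(K):
            row = []
            for d in range(len(model.track_names)):
                col = np.concatenate([cm.counts[:, d] for cm in sequences])
                w = np.concatenate([g[:, k] for g in gammas])
                sfac = np.concatenate([np.full(cm.counts.shape[0], sv[d])
                                       for cm, sv in zip(sequences, svecs)])
                grouped = group_counts(col, w, sfac)
                row.append(fit_emission(grouped, model.family,
                                        init=model.emissions.params[k][d],
                                        seed=seed + 1000 * k + d))
            new_params.append(row)
        model = HMMModel(initial_probs=pi, transitions=A,
                         emissions=EmissionGrid(model.family, new_params),
                         track_names=model.track_names,
                         bin_width=model.bin_width)
    return model, trace


def viterbi(model: HMMModel, counts: CountMatrix, size_factors=None) -> np.ndarray:
    """Exact maximum-probability state path; ties break to the lower index."""
    _check_tracks(model, counts)
    s = _size_vector(model, counts, size_factors)
    log_B = model.emissions.log_emission_matrix(counts.counts, s)
    log_pi, log_A = _log_pi_A(model)
    path, _ = _viterbi_log(log_pi, log_A, log_B)
    return path


def posterior_decode(posterior: PosteriorMatrix) -> np.ndarray:
    """Per-bin argmax of the posterior; ties break to the lower state index."""
    return np.argmax(posterior.gamma, axis=1)


# ---------------------------------------------------------------------------
# initialization

def _moment_params(family: str, cluster_counts: np.ndarray):
    """Method-of-moments emission parameters for one cluster, one track."""
    m = float(cluster_counts.mean()) if cluster_counts.size else 0.0
    v = float(cluster_counts.var()) if cluster_counts.size else 0.0
    m = max(m, MU_FLOOR)
    if family == "negbinom":
        if v > m:
            r = m * m / (v - m)
        else:
            r = 1e4
        return NegBinomParams(mu=m, size=float(np.clip(r, 1e-2, 1e4)))
    # poilog: match mean and variance of the Poisson-lognormal
    # mean = exp(mu + s^2/2), var = mean + mean^2 (e^{s^2} - 1)
    if v > m:
        sig2 = float(np.log1p((v - m) / (m * m)))
    else:
        sig2 = SIGMA_MIN ** 2
    sig2 = float(np.clip(sig2, SIGMA_MIN ** 2, 16.0))
    return PoilogParams(mu_log=float(np.log(m) - sig2 / 2.0),
                        sigma=float(np.sqrt(sig2)))


def initialize(counts, K: int, seed: int = 0, family: str = "negbinom",
               pseudocount: float = 1.0) -> HMMModel:
    """Threshold/k-means initialization of a K-state model.

    Per track, counts below the Poisson tail threshold n_d (track mean rate,
    Pr(X > n_d) < 1e-4) are zeroed; bins left all-zero form the background
    cluster; k-means with K-1 clusters on log(count + pseudocount) partitions
    the rest. Cluster moments seed the emissions; pi and A start uniform.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if isinstance(counts, CountMatrix):
        counts = [counts]
    track_names = counts[0].track_names
    bin_width = counts[0].genome.bin_width
    pooled = np.vstack([cm.counts for cm in counts])
    T, D = pooled.shape
    lam = pooled.mean(axis=0)
    n_d = np.array([poisson_threshold(l) for l in lam])
    work = pooled.copy()
    work[work < n_d[None, :]] = 0
    background = (work == 0).all(axis=1)
    signal = work[~background]
    if len(np.unique(signal, axis=0)) < K - 1:
        raise ValueError(f"insufficient signal for {K} states: fewer than "
                         f"{K - 1} distinct non-background bins")
    km = KMeans(n_clusters=K - 1, n_init=10, random_state=seed)
    labels = km.fit_predict(np.log(signal + pseudocount))
    # reseed empty clusters from the farthest points (rare with n_init=10)
    for c in range(K - 1):
        if not (labels == c).any():
            dist = km.transform(np.log(signal + pseudocount)).min(axis=1)
            labels[np.argmax(dist)] = c
    # deterministic state order: background first, clusters by mean total count
    order = np.argsort([signal[labels == c].sum(axis=1).mean()
                        for c in range(K - 1)], kind="stable")
    raw_signal = pooled[~background]
    params = [[_moment_params(family, pooled[background][:, d]) for d in range(D)]]
    for c in order:
        sel = raw_signal[labels == c]
        params.append([_moment_params(family, sel[:, d]) for d in range(D)])
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 1.0 / K)
    return HMMModel(initial_probs=pi, transitions=A,
                    emissions=EmissionGrid(family, params),
                    track_names=track_names, bin_width=bin_width)


# ---------------------------------------------------------------------------
# model file

def save_model(model: HMMModel, path) -> None:
    if model.family == "negbinom":
        grid = [[{"mu": p.mu, "size": p.size} for p in row]
                for row in model.emissions.params]
    else:
        grid = [[{"mu_log": p.mu_log, "sigma": p.sigma} for p in row]
                for row in model.emissions.params]
    doc = {
        "format": "countseg_model",
        "version": MODEL_FORMAT_VERSION,
        "n_states": model.n_states,
        "family": model.family,
        "initial_probs": model.initial_probs.tolist(),
        "transitions": model.transitions.tolist(),
        "emissions": grid,
        "track_names": list(model.track_names),
        "bin_width": model.bin_width,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path) -> HMMModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: corrupted model file") from exc
    if doc.get("format") != "countseg_model":
        raise ValueError(f"{path}: not a countseg model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model version {doc.get('version')}")
    family = doc["family"]
    if family == "negbinom":
        grid = [[NegBinomParams(**p) for p in row] for row in doc["emissions"]]
    else:
        grid = [[PoilogParams(**p) for p in row] for row in doc["emissions"]]
    return HMMModel(initial_probs=np.array(doc["initial_probs"]),
                    transitions=np.array(doc["transitions"]),
                    emissions=EmissionGrid(family, grid),
                    track_names=tuple(doc["track_names"]),
                    bin_width=int(doc["bin_width"]))
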