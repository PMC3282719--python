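"""Gene-unit chromatin-state hidden Markov model.

Each gene is one chain step (one chain per chromosome, genes in genomic
order).  The hidden variable is the chromatin state; the emission is the
5-dimensional vector of gene-level mark scores, modeled as a multivariate
Gaussian with diagonal covariance.  The workflow is:

1. choose the number of states K with the gap statistic on the pooled score
   vectors (k-means within-cluster dispersion against uniform reference sets);
2. fit a K-state model per cell line by EM on a training chromosome;
3. semantically align the per-line models (active / non-active / null) and
   average them into one common model;
4. Viterbi-decode every cell line genome-wide with the common model.

Scores are log(1+x)-transformed by default before clustering and EM, since
Gaussian emissions fit the skewed non-negative scores poorly on the raw scale.

State integer codes follow the convention 1 = null, 2 = non-active, 3 = active.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .simulate import STATE_CODES, GeneScoreArray

SD_FLOOR = 1e-3
ACTIVE_MARKS = ("H3K4me3", "H3K9ac", "H3K36me3", "H3K4me1")
REPRESSIVE_MARK = "H3K27me3"

CANONICAL_ORDER = ("null", "nonactive", "active")


class ModelError(ValueError):
    pass


@dataclass
class StateHMM:
    """K-state diagonal-Gaussian HMM over gene-level mark scores."""

    means: np.ndarray               # K x M
    sds: np.ndarray                 # K x M, floored at SD_FLOOR
    transition: np.ndarray          # K x K row-stochastic
    initial: np.ndarray             # length K
    marks: list
    labels: list | None = None      # semantic state names, len K
    transform: str = "log1p"        # transform applied to scores before use

    def __post_init__(self):
        self.means = np.asarray(self.means, float)
        self.sds = np.maximum(np.asarray(self.sds, float), SD_FLOOR)
        self.transition = np.asarray(self.transition, float)
        self.initial = np.asarray(self.initial, float)
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ModelError("transition rows must sum to 1")

    @property
    def K(self) -> int:
        return self.means.shape[0]

    def transform_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if self.transform == "log1p":
            return np.log1p(X)
        if self.transform == "none":
            return X
        raise ModelError(f"unknown transform {self.transform!r}")

    def log_emission(self, X_t: np.ndarray) -> np.ndarray:
        """n x K log densities for already-transformed observations."""
        X_t = np.atleast_2d(X_t)
        diff = X_t[:, None, :] - self.means[None, :, :]        # n x K x M
        var = self.sds[None, :, :] ** 2
        ll = -0.5 * np.sum(diff * diff / var + np.log(2 * np.pi * var), axis=2)
        return ll

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        w, v = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def state_codes(self) -> np.ndarray:
        """Map state index -> integer code (1 null, 2 nonactive, 3 active)."""
        if self.labels is None:
            raise ModelError("model is unlabeled; call label_states first")
        return np.array([STATE_CODES[l] for l in self.labels])

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "marks": list(self.marks),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "labels": self.labels,
            "transform": self.transform,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "StateHMM":
        return cls(
            means=np.asarray(d["means"], float),
            sds=np.asarray(d["sds"], float),
            transition=np.asarray(d["transition"], float),
            initial=np.asarray(d["initial"], float),
            marks=list(d["marks"]),
            labels=d.get("labels"),
            transform=d.get("transform", "log1p"),
        )

    @classmethod
    def from_json(cls, path) -> "StateHMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------

@dataclass
class GapResult:
    k_range: list
    log_w_obs: np.ndarray
    log_w_ref_mean: np.ndarray
    gap: np.ndarray = field(init=False)
    chosen_k: int = field(init=False)

    def __post_init__(self):
        self.gap = self.log_w_ref_mean - self.log_w_obs
        self.chosen_k = int(self.k_range[int(np.argmax(self.gap))])


def _within_ss(X: np.ndarray, k: int, seed: int) -> float:
    if k == 1:
        return float(np.sum((X - X.mean(axis=0)) ** 2))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    return float(km.inertia_)


def gap_select_k(X: np.ndarray, k_range=range(1, 9), B: int = 100,
                 seed: int = 0, transform: str = "log1p") -> GapResult:
    """Choose the number of clusters by the gap statistic.

    Gap(k) = E[log W*_k] - log W_k, where W_k is the k-means within-cluster
    sum of squares of the data and the expectation is the mean over ``B``
    reference datasets drawn uniformly over each feature's observed range.
    The chosen K maximizes Gap(k).  Degenerate data (all points identical)
    yields K = 1.
    """
    X = np.asarray(X, float)
    if transform == "log1p":
        X = np.log1p(X)
    k_range = list(k_range)
    if np.allclose(X, X[0]):
        n = len(k_range)
        return GapResult(k_range=[1], log_w_obs=np.zeros(1), log_w_ref_mean=np.zeros(1))
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    eps = 1e-12
    log_w_obs = np.array([np.log(_within_ss(X, k, seed) + eps) for k in k_range])
    log_w_ref = np.zeros((B, len(k_range)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        for j, k in enumerate(k_range):
            log_w_ref[b, j] = np.log(_within_ss(ref, k, ref_seed) + eps)
    return GapResult(k_range=k_range, log_w_obs=log_w_obs,
                     log_w_ref_mean=log_w_ref.mean(axis=0))


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _forward_backward(model: StateHMM, logB: np.ndarray):
    """Log-space forward-backward for one sequence.

    Returns (log alpha, log beta, sequence log-likelihood).
    """
    n, K = logB.shape
    log_pi = np.log(model.initial + 1e-300)
    log_A = np.log(model.transition + 1e-300)
    la = np.empty((n, K))
    lb = np.zeros((n, K))
    la[0] = log_pi + logB[0]
    for t in range(1, n):
        la[t] = logB[t] + logsumexp(la[t - 1][:, None] + log_A, axis=0)
    for t in range(n - 2, -1, -1):
        lb[t] = logsumexp(log_A + (logB[t + 1] + lb[t + 1])[None, :], axis=1)
    ll = float(logsumexp(la[-1]))
    return la, lb, ll


def fit_hmm_em(X: np.ndarray, chroms: np.ndarray | None = None, K: int = 3,
               tol: float = 1e-6, max_iter: int = 200, seed: int = 0,
               marks=None, transform: str = "log1p",
               self_loop: float = 0.8):
    """Fit a K-state diagonal-Gaussian HMM by EM.

    ``X`` is the n_genes x n_marks score matrix for one cell line on the
    training chromosome(s), position-ordered; ``chroms`` optionally splits the
    rows into independent chains (one per chromosome).  Initialization: means
    from k-means centroids, per-cluster sds, uniform initial distribution and
    a transition matrix with ``self_loop`` on the diagonal.

    Returns ``(model, loglik_trace)``; the trace is non-decreasing.
    """
    X = np.asarray(X, float)
    if X.size == 0:
        raise ModelError("empty training data")
    if X.shape[0] < 10 * K:
        raise ModelError(f"need at least {10 * K} training genes for K={K}")
    marks = list(marks) if marks is not None else [f"m{j}" for j in range(X.shape[1])]
    Xt = np.log1p(X) if transform == "log1p" else X
    if chroms is None:
        chroms = np.zeros(len(Xt), dtype=int)
    chroms = np.asarray(chroms)
    seqs = [np.flatnonzero(chroms == c) for c in pd.unique(chroms)]

    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(Xt)
    means = km.cluster_centers_.copy()
    sds = np.empty_like(means)
    for k in range(K):
        pts = Xt[km.labels_ == k]
        sds[k] = pts.std(axis=0) if len(pts) > 1 else Xt.std(axis=0)
    sds = np.maximum(sds, SD_FLOOR)
    A = np.full((K, K), (1 - self_loop) / max(K - 1, 1))
    np.fill_diagonal(A, self_loop if K > 1 else 1.0)
    pi = np.full(K, 1.0 / K)
    model = StateHMM(means, sds, A, pi, marks, transform=transform)

    trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        logB = model.log_emission(Xt)
        total_ll = 0.0
        gamma = np.zeros((len(Xt), K))
        xi_sum = np.zeros((K, K))
        pi_new = np.zeros(K)
        log_A = np.log(model.transition + 1e-300)
        for idx in seqs:
            la, lb, ll = _forward_backward(model, logB[idx])
            total_ll += ll
            g = la + lb - ll
            gamma[idx] = np.exp(g)
            pi_new += gamma[idx[0]]
            if len(idx) > 1:
                lx = (la[:-1, :, None] + log_A[None, :, :]
                      + (logB[idx[1:]] + lb[1:])[:, None, :] - ll)
                xi_sum += np.exp(lx).sum(axis=0)
        trace.append(total_ll)
        if total_ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = total_ll
        # M-step
        w = gamma.sum(axis=0)
        means = (gamma.T @ Xt) / w[:, None]
        var = (gamma.T @ (Xt**2)) / w[:, None] - means**2
        sds = np.sqrt(np.maximum(var, SD_FLOOR**2))
        if np.any(var < SD_FLOOR**2):
            warnings.warn("emission variance collapsed; sd floored")
        A = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
        if K == 1:
            A = np.ones((1, 1))
        pi = pi_new / pi_new.sum()
        model = StateHMM(means, sds, A, pi, marks, transform=transform)
    return model, np.asarray(trace)


# ---------------------------------------------------------------------------
# labeling and averaging
# ---------------------------------------------------------------------------

def label_states(model: StateHMM) -> list:
    """Assign semantic labels (null / nonactive / active) to a 3-state model.

    The non-active state has the highest H3K27me3 emission mean; among the
    remaining two, the active state has the highest mean over the active
    marks; the leftover is null.  Ties break deterministically toward the
    lower state index (with a warning).
    """
    if model.K != 3:
        raise ModelError("semantic labeling is defined for K=3")
    marks = list(model.marks)
    k27 = marks.index(REPRESSIVE_MARK)
    active_cols = [marks.index(m) for m in ACTIVE_MARKS if m in marks]
    col = model.means[:, k27]
    if np.count_nonzero(col == col.max()) > 1:
        warnings.warn("tie while labeling the non-active state; breaking by index")
    nonactive = int(np.argmax(col))
    rest = [k for k in range(3) if k != nonactive]
    act_score = model.means[rest][:, active_cols].mean(axis=1)
    if act_score[0] == act_score[1]:
        warnings.warn("tie while labeling the active state; breaking by index")
    active = rest[int(np.argmax(act_score))]
    null = next(k for k in rest if k != active)
    labels = [""] * 3
    labels[null], labels[nonactive], labels[active] = "null", "nonactive", "active"
    model.labels = labels
    return labels


def _canonical_perm(model: StateHMM) -> np.ndarray:
    labels = model.labels if model.labels else label_states(model)
    if sorted(labels) != sorted(CANONICAL_ORDER):
        raise ModelError(f"label collision: {labels}")
    return np.array([labels.index(name) for name in CANONICAL_ORDER])


def align_and_average(models: list) -> StateHMM:
    """Average per-cell-line models into one common model.

    Each model's states are first matched by semantic label (label switching
    across independently fitted models would otherwise make element-wise
    averaging meaningless), reordered canonically (null, nonactive, active),
    then means, sds, initial and transition are averaged element-wise and the
    transition rows renormalized.
    """
    if not models:
        raise ModelError("no models to average")
    K = models[0].K
    marks = list(models[0].marks)
    for m in models:
        if m.K != K or list(m.marks) != marks or m.transform != models[0].transform:
            raise ModelError("models disagree in K, mark order or transform")
    perms = [_canonical_perm(m) for m in models]
    means = np.mean([m.means[p] for m, p in zip(models, perms)], axis=0)
    sds = np.mean([m.sds[p] for m, p in zip(models, perms)], axis=0)
    init = np.mean([m.initial[p] for m, p in zip(models, perms)], axis=0)
    init = init / init.sum()
    trans = np.mean([m.transition[np.ix_(p, p)] for m, p in zip(models, perms)], axis=0)
    trans = trans / trans.sum(axis=1, keepdims=True)
    avg = StateHMM(means, sds, trans, init, marks,
                   labels=list(CANONICAL_ORDER), transform=models[0].transform)
    return avg


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def viterbi_path(model: StateHMM, logB: np.ndarray) -> np.ndarray:
    """Maximum-probability state path for one chain (log-space)."""
    n, K = logB.shape
    log_pi = np.log(model.initial + 1e-300)
    log_A = np.log(model.transition + 1e-300)
    delta = np.empty((n, K))
    back = np.zeros((n, K), dtype=int)
    delta[0] = log_pi + logB[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + log_A
        back[t] = np.argmax(cand, axis=0)
        delta[t] = logB[t] + np.max(cand, axis=0)
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def viterbi_decode(model: StateHMM, X: np.ndarray,
                   chroms: np.ndarray | None = None) -> np.ndarray:
    """Decode one cell line's genes into integer state codes.

    ``X`` is genes x marks (raw scale; the model's transform is applied),
    position-ordered; ``chroms`` splits it into independent per-chromosome
    chains.  Returns codes per the 1=null / 2=nonactive / 3=active convention.
    """
    if model.labels is None:
        raise ModelError("decode requires a labeled model")
    X = np.asarray(X, float)
    if X.shape[1] != len(model.marks):
        raise ModelError("score matrix mark dimension does not match model")
    if np.isnan(X).any():
        raise ModelError("scores contain missing values")
    Xt = model.transform_scores(X)
    logB = model.log_emission(Xt)
    if chroms is None:
        chroms = np.zeros(len(X), dtype=int)
    chroms = np.asarray(chroms)
    codes = model.state_codes()
    out = np.empty(len(X), dtype=np.int64)
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        out[idx] = codes[viterbi_path(model, logB[idx])]
    return out


def decode_states(model: StateHMM, scores: GeneScoreArray,
                  annotation: pd.DataFrame) -> pd.DataFrame:
    """Genome-wide StateMatrix (genes x cell lines, integer codes) for all lines."""
    chrom_map = annotation.set_index("gene_id")["chrom"]
    chroms = chrom_map.loc[scores.genes].to_numpy()
    cols = {}
    for line in scores.cell_lines:
        cols[line] = viterbi_decode(model, scores.line_matrix(line), chroms)
    return pd.DataFrame(cols, index=scores.genes)


def fit_common_model(scores: GeneScoreArray, annotation: pd.DataFrame,
                     training_chrom: str = "chr1", K: int = 3, seed: int = 0,
                     transform: str = "log1p", tol: float = 1e-6,
                     max_iter: int = 200) -> StateHMM:
    """Per-line EM on the training chromosome, then align and average."""
    chrom_map = annotation.set_index("gene_id")["chrom"]
    chroms = chrom_map.loc[scores.genes].to_numpy()
    train = np.flatnonzero(chroms == training_chrom)
    if train.size == 0:
        raise ModelError(f"training chromosome {training_chrom!r} has no genes")
    models = []
    for i, line in enumerate(scores.cell_lines):
        m, _ = fit_hmm_em(scores.line_matrix(line)[train], K=K, seed=seed + i,
                          marks=scores.marks, transform=transform,
                          tol=tol, max_iter=max_iter)
        label_states(m)
        models.append(m)
    return align_and_average(models)
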