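"""Permutation one-way ANOVA across differentiation classes, with FDR control.

Features (bins, gene-level mark scores, or integer-coded chromatin states) are
tested for systematic differences across the P / M / U-D cell-lineage groups
with the classical one-way F statistic.  Because state codes are ordinal
rather than Gaussian, p-values come from a permutation null: group labels are
permuted jointly across all features (preserving cross-feature dependence)
and p = (1 + #{permuted F >= observed F}) / (1 + n_perm).  Selection is by
Benjamini-Hochberg at FDR 0.05.  Genes selected at the chromatin-state level
are the "hotspot" genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .simulate import STATE_NAMES


def _group_indicator(labels) -> np.ndarray:
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    G = np.stack([(labels == g).astype(float) for g in groups], axis=1)  # n x g
    if not np.any(G.sum(axis=0) >= 2):
        raise ValueError("at least one group needs two or more members")
    return G


def f_statistic(values: np.ndarray, labels) -> np.ndarray:
    """One-way ANOVA F per feature row.

    ``values`` is features x samples (a single feature vector is accepted).
    Degenerate features with zero between- and within-group variance get
    F = 0; zero within-group variance with real between-group differences
    gives +inf.
    """
    X = np.atleast_2d(np.asarray(values, float))
    G = _group_indicator(labels)
    return _f_from_indicator(X, G)[0] if np.asarray(values).ndim == 1 else _f_from_indicator(X, G)


def _f_from_indicator(X: np.ndarray, G: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    g = G.shape[1]
    sizes = G.sum(axis=0)                           # g
    group_sums = X @ G                              # features x g
    grand = X.sum(axis=1, keepdims=True)
    ssb = np.sum(group_sums**2 / sizes[None, :], axis=1) - (grand[:, 0] ** 2) / n
    sst = np.sum(X**2, axis=1) - (grand[:, 0] ** 2) / n
    ssw = sst - ssb
    ssb = np.maximum(ssb, 0.0)
    ssw = np.maximum(ssw, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (g - 1)) / (ssw / (n - g))
    F = np.where(ssb <= 1e-12, 0.0, F)              # no signal at all -> 0
    F = np.where((ssw <= 1e-12) & (ssb > 1e-12), np.inf, F)
    return F


def permutation_pvalues(matrix: np.ndarray, labels, n_perm: int = 100_000,
                        seed: int = 0, permutations: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values for the per-feature F statistics.

    One label permutation per iteration is shared across all features.  An
    explicit ``permutations`` array (n_perm x n_samples of column indices)
    overrides the random draws, e.g. for exhaustive or diagnostic nulls.
    Returns ``(F_observed, p)`` with the +1-corrected estimator
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    X = np.atleast_2d(np.asarray(matrix, float))
    labels = np.asarray(labels)
    if permutations is None:
        if n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        rng = np.random.default_rng(seed)
        permutations = np.stack([rng.permutation(len(labels)) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations)
        n_perm = len(permutations)
    G = _group_indicator(labels)
    F_obs = _f_from_indicator(X, G)
    count = np.zeros(X.shape[0], dtype=np.int64)
    for perm in permutations:
        Fp = _f_from_indicator(X, G[perm])
        count += Fp >= F_obs
    p = (1 + count) / (1 + n_perm)
    return F_obs, p


def fdr_select(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (significant mask, q-values)."""
    reject, qvals, _, _ = multipletests(np.asarray(pvalues), alpha=q, method="fdr_bh")
    return reject, qvals


def differential_features(matrix: np.ndarray, labels, feature_ids=None,
                          n_perm: int = 100_000, q: float = 0.05,
                          seed: int = 0) -> pd.DataFrame:
    """Full permutation-ANOVA table: F, permutation p, BH q, significance flag."""
    F, p = permutation_pvalues(matrix, labels, n_perm=n_perm, seed=seed)
    sig, qvals = fdr_select(p, q=q)
    idx = feature_ids if feature_ids is not None else np.arange(len(F))
    return pd.DataFrame({"F": F, "p": p, "q": qvals, "significant": sig}, index=idx)


def hotspot_genes(state_matrix: pd.DataFrame, labels, n_perm: int = 10_000,
                  q: float = 0.05, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes whose integer-coded chromatin state differs across classes.

    Only the labeled normal lines should be passed (cancer lines are held
    out of all differential analyses).  Returns the differential table and,
    for the significant genes, the modal state name per class.
    """
    X = state_matrix.to_numpy(float)
    table = differential_features(X, labels, feature_ids=state_matrix.index,
                                  n_perm=n_perm, q=q, seed=seed)
    hot = table[table["significant"]].index
    labels = np.asarray(labels)
    rows = {}
    for cls in pd.unique(labels):
        sub = state_matrix.loc[hot, state_matrix.columns[labels == cls]]
        if len(hot) == 0:
            rows[cls] = pd.Series(dtype=object)
            continue
        modal = sub.mode(axis=1)[0].astype(int)
        rows[cls] = modal.map(STATE_NAMES)
    summary = pd.DataFrame(rows, index=hot)
    return table, summary
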