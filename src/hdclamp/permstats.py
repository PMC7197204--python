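"""Paired sign-flip permutation inference with FWER and FDR control.

For paired data (two conditions per participant) the null hypothesis of
no condition difference is exchanged by flipping the sign of each
participant's difference. The test statistic is the one-sample t of the
differences per feature. Exhaustive mode enumerates all 2^n sign
assignments (the identity assignment is always among them, so p > 0);
Monte-Carlo mode draws random assignments and includes the identity.
Family-wise error is controlled either by the permutation distribution
of the maximum |t| over features (max-stat) or by adjacency-defined
cluster mass; feature-wise maps can instead be corrected with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermSpec",
    "Cluster",
    "TestResult",
    "paired_t",
    "sign_flip_test",
    "cluster_test",
    "fdr_bh",
    "n_sign_flips",
    "iter_sign_chunks",
    "chain_adjacency",
    "adjacency_from_edges",
]

#: Exhaustive enumeration is refused above this exponent.
MAX_EXHAUSTIVE_EXPONENT = 26

#: Sign-pattern chunk size for exhaustive enumeration.
_CHUNK = 1 << 13


@dataclass(frozen=True)
class PermSpec:
    """How to build the permutation null."""

    mode: str = "exhaustive"
    n_perm: int = 10000
    seed: Optional[int] = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exhaustive", "monte-carlo"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "monte-carlo" and self.n_perm < 1:
            raise ValueError("n_perm must be positive")


@dataclass(frozen=True)
class Cluster:
    """A connected supra-threshold set of features."""

    features: Tuple[int, ...]
    mass: float
    sign: int
    p_value: float


@dataclass(frozen=True)
class TestResult:
    t: np.ndarray
    p_uncorrected: np.ndarray
    p_maxstat: Optional[np.ndarray] = None
    clusters: Tuple[Cluster, ...] = ()
    n_permutations: int = 0


def _as_diffs(samples: np.ndarray) -> np.ndarray:
    """Accept (n, features) paired differences or (n, 2, features) values."""
    a = np.asarray(samples, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim == 3:
        if a.shape[1] != 2:
            raise ValueError("expected exactly 2 conditions")
        a = a[:, 0, :] - a[:, 1, :]
    if a.ndim != 2:
        raise ValueError("samples must be (n,), (n, features) or "
                         "(n, 2, features)")
    if not np.all(np.isfinite(a)):
        raise ValueError("samples contain non-finite values")
    return a


def _t_from_signs(signs: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """t statistics for a batch of sign assignments.

    Sign flips leave each difference's square unchanged, so only the mean
    changes: t = m / sqrt((ss/n - m^2) / (n - 1) / n) with ss fixed.
    signs: (P, n), diffs: (n, F) -> (P, F).
    """
    n = diffs.shape[0]
    ss = np.sum(diffs ** 2, axis=0)  # (F,)
    m = signs @ diffs / n  # (P, F)
    var = (ss[None, :] - n * m ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return m / np.sqrt(var / n)


def paired_t(samples: np.ndarray) -> np.ndarray:
    """One-sample t of paired differences per feature (df = n - 1).

    Zero-variance features yield NaN (flagged as missing, not infinite).
    """
    diffs = _as_diffs(samples)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    t = _t_from_signs(np.ones((1, n)), diffs)[0]
    sd = diffs.std(axis=0, ddof=1)
    t[sd == 0.0] = np.nan
    return t


def n_sign_flips(n: int) -> int:
    """Size of the exhaustive sign-flip permutation group."""
    return 1 << n


def iter_sign_chunks(n: int, spec: PermSpec = PermSpec(),
                     chunk: int = _CHUNK) -> Iterator[np.ndarray]:
    """Yield (P, n) blocks of +/-1 sign assignments.

    Exhaustive mode enumerates all 2^n assignments lazily (the first row
    of the first block is the identity, all +1); Monte-Carlo mode yields
    the identity followed by spec.n_perm random assignments.
    """
    if spec.mode == "exhaustive":
        if n > MAX_EXHAUSTIVE_EXPONENT:
            raise ValueError(
                f"exhaustive enumeration of 2^{n} permutations is "
                f"infeasible (guard 2^{MAX_EXHAUSTIVE_EXPONENT}); use "
                "monte-carlo mode"
            )
        total = 1 << n
        bits = np.arange(n, dtype=np.uint64)
        for start in range(0, total, chunk):
            codes = np.arange(start, min(start + chunk, total),
                              dtype=np.uint64)
            # bit k of the code decides participant k's sign; code 0 = identity
            mat = ((codes[:, None] >> bits[None, :]) & 1).astype(float)
            yield 1.0 - 2.0 * mat
    else:
        rng = np.random.default_rng(spec.seed)
        yield np.ones((1, n))
        remaining = spec.n_perm
        while remaining > 0:
            k = min(chunk, remaining)
            yield rng.choice([-1.0, 1.0], size=(k, n))
            remaining -= k


def sign_flip_test(samples: np.ndarray,
                   spec: PermSpec = PermSpec()) -> TestResult:
    """Two-tailed paired sign-flip permutation test per feature.

    p_uncorrected[f] = fraction of permutations with |t_perm[f]| >=
    |t_obs[f]|; p_maxstat[f] uses the permutation distribution of
    max_f |t| (family-wise error control). The identity permutation is
    always counted, so p values are never 0.
    """
    diffs = _as_diffs(samples)
    n, n_feat = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    t_obs = paired_t(diffs)
    abs_obs = np.abs(np.nan_to_num(t_obs, nan=np.inf))

    count_unc = np.zeros(n_feat)
    count_max = np.zeros(n_feat)
    total = 0
    for signs in iter_sign_chunks(n, spec):
        t_perm = np.abs(_t_from_signs(signs, diffs))
        t_perm = np.nan_to_num(t_perm, nan=0.0)
        count_unc += np.sum(t_perm >= abs_obs[None, :] - 1e-12, axis=0)
        tmax = t_perm.max(axis=1)
        count_max += np.sum(tmax[:, None] >= abs_obs[None, :] - 1e-12,
                            axis=0)
        total += signs.shape[0]

    p_unc = count_unc / total
    p_max = count_max / total
    nan_mask = ~np.isfinite(t_obs)
    p_unc[nan_mask] = np.nan
    p_max[nan_mask] = np.nan
    return TestResult(t=t_obs, p_uncorrected=p_unc, p_maxstat=p_max,
                      n_permutations=total)


def chain_adjacency(n: int) -> sparse.csr_matrix:
    """1-2-3-...-n chain neighbor relation (features on a line)."""
    i = np.arange(n - 1)
    m = sparse.coo_matrix(
        (np.ones(2 * (n - 1)), (np.r_[i, i + 1], np.r_[i + 1, i])),
        shape=(n, n),
    )
    return m.tocsr()


def adjacency_from_edges(edges: Sequence[Tuple[int, int]],
                         n_features: int) -> sparse.csr_matrix:
    """Symmetric adjacency from an (i, j) edge list; self-edges rejected."""
    edges = np.asarray(edges, dtype=int)
    if edges.size and np.any(edges[:, 0] == edges[:, 1]):
        raise ValueError("adjacency must be irreflexive (no self-edges)")
    i, j = (edges[:, 0], edges[:, 1]) if edges.size else ([], [])
    m = sparse.coo_matrix(
        (np.ones(2 * len(edges)), (np.r_[i, j], np.r_[j, i])),
        shape=(n_features, n_features),
    )
    m = m.tocsr()
    m.data[:] = 1.0
    return m


def _check_adjacency(adj: sparse.spmatrix, n_feat: int) -> sparse.csr_matrix:
    adj = sparse.csr_matrix(adj)
    if adj.shape != (n_feat, n_feat):
        raise ValueError(
            f"adjacency shape {adj.shape} does not cover {n_feat} features"
        )
    if (adj != adj.T).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    if adj.diagonal().any():
        raise ValueError("adjacency must be irreflexive")
    return adj


def _clusters_from_map(t_map: np.ndarray, thresh: float,
                       adj: sparse.csr_matrix
                       ) -> List[Tuple[np.ndarray, float, int]]:
    """Connected supra-threshold sets, separately per sign."""
    out = []
    for sign in (1, -1):
        mask = (sign * t_map) > thresh
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        sub = adj[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            feats = idx[labels == c]
            out.append((feats, float(np.sum(np.abs(t_map[feats]))), sign))
    return out


def _max_chain_cluster_stat(t_perm: np.ndarray, thresh: float,
                            statistic: str) -> np.ndarray:
    """Max cluster statistic per permutation row under chain adjacency.

    On a chain, clusters are runs of consecutive supra-threshold
    features, so all rows can be labeled at once by flattening with a
    separator column between rows.
    """
    P, F = t_perm.shape
    best = np.zeros(P)
    for sign in (1.0, -1.0):
        mask = (sign * t_perm) > thresh
        padded = np.concatenate(
            [mask, np.zeros((P, 1), dtype=bool)], axis=1
        ).ravel()
        if not padded.any():
            continue
        labels, n_lab = ndimage.label(padded)
        weights = (np.abs(t_perm) if statistic == "mass"
                   else np.ones_like(t_perm))
        wpad = np.concatenate([weights, np.zeros((P, 1))], axis=1).ravel()
        masses = np.bincount(labels, weights=wpad)[1:]
        starts = np.nonzero(np.diff(np.concatenate([[0], labels])) > 0)[0]
        rows = starts // (F + 1)
        np.maximum.at(best, rows, masses)
    return best


def cluster_test(samples: np.ndarray, adjacency: sparse.spmatrix,
                 cluster_alpha: float = 0.05,
                 spec: PermSpec = PermSpec(),
                 statistic: str = "mass") -> TestResult:
    """Cluster-based sign-flip permutation test.

    Features whose |t| exceeds the two-tailed parametric t quantile at
    cluster_alpha form candidate clusters (positive and negative
    separately) connected under the adjacency. The cluster statistic is
    the mass sum(|t|) (or the size, statistic="size"); its null is the
    permutation distribution of the maximum cluster statistic.
    """
    diffs = _as_diffs(samples)
    n, n_feat = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    adj = _check_adjacency(adjacency, n_feat)
    if statistic not in ("mass", "size"):
        raise ValueError(f"unknown cluster statistic {statistic!r}")
    thresh = float(t_dist.ppf(1.0 - cluster_alpha / 2.0, n - 1))

    t_obs = paired_t(diffs)
    if not np.all(np.isfinite(t_obs)):
        raise ValueError("t map contains non-finite values")
    obs_clusters = _clusters_from_map(t_obs, thresh, adj)

    def stat(feats: np.ndarray, mass: float) -> float:
        return float(len(feats)) if statistic == "size" else mass

    is_chain = (n_feat > 1
                and (adj != chain_adjacency(n_feat)).nnz == 0)
    null_max = []
    total = 0
    for signs in iter_sign_chunks(n, spec):
        t_perm = _t_from_signs(signs, diffs)
        t_perm = np.nan_to_num(t_perm, nan=0.0)
        if is_chain:
            null_max.append(_max_chain_cluster_stat(t_perm, thresh,
                                                    statistic))
        else:
            null_max.append(np.array([
                max((stat(f, m) for f, m, _ in
                     _clusters_from_map(row, thresh, adj)), default=0.0)
                for row in t_perm
            ]))
        total += signs.shape[0]
    null_max = np.concatenate(null_max)

    clusters = tuple(
        Cluster(
            features=tuple(int(f) for f in feats),
            mass=mass,
            sign=sign,
            p_value=float(np.mean(null_max >= stat(feats, mass) - 1e-12)),
        )
        for feats, mass, sign in obs_clusters
    )
    p_unc = 2.0 * t_dist.sf(np.abs(t_obs), n - 1)
    return TestResult(t=t_obs, p_uncorrected=p_unc, clusters=clusters,
                      n_permutations=total)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)
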