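"""Permutation inference for dyadic and node-level data.

Dyadic observations are not independent: both cells involving individual A
share A's idiosyncrasies.  Quadratic-assignment (QAP) tests respect this by
building the null distribution from *node-label permutations* — permuting
rows and columns of a matrix simultaneously — which preserves the dyadic
dependence structure exactly.

Three tests are provided:

* :func:`mrqap_dsp` — multiple regression of one dyadic matrix on others
  with double semi-partialling: for each predictor, the residual of that
  predictor on the remaining predictors is node-permuted and substituted
  back into the model, which makes the test robust to collinearity among
  predictors and to skew.  The permuted statistic is the standardized
  coefficient (a t-ratio option is exposed).
* :func:`node_regression` — node-level OLS with significance from random
  permutation of the outcome vector across individuals.
* :func:`geary_c` — network autocorrelation between a node attribute and a
  dyadic network; the statistic's null expectation is exactly 1, values
  below 1 indicate positive association, above 1 negative.

p-values from sampled permutations use the ``(hits + 1) / (n_perm + 1)``
convention (the observed arrangement counts as one permutation), so the
smallest attainable p is ``1/(n_perm + 1)`` and p is never 0.  Ties with
the observed statistic count toward the tail.  :func:`mrqap_exhaustive`
enumerates the full permutation group (n <= 7) as an exact oracle; there
p is the fraction of the n! permutations (identity included) at least as
extreme as observed.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError, LabelMismatchError, SizeError
from .matrices import DyadicMatrix, offdiag_indices

__all__ = [
    "MRQAPResult",
    "NodeRegressionResult",
    "GearyResult",
    "vectorize_offdiag",
    "offdiag_to_matrix",
    "ols_standardized",
    "qap_node_permutation",
    "mrqap_dsp",
    "mrqap_exhaustive",
    "geary_c",
    "node_regression",
]

_TIE_TOL = 1e-12


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class _RegressionResult:
    outcome_name: str
    predictor_names: tuple[str, ...]
    beta: tuple[float, ...]
    r_squared: float
    p: tuple[float, ...]
    n_perm: int
    seed: int | None
    engine: str = "sampled"

    def __post_init__(self) -> None:
        if not (len(self.beta) == len(self.p) == len(self.predictor_names)):
            raise InputError("beta, p and predictor_names must have equal length")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise InputError(f"r_squared out of [0, 1]: {self.r_squared}")

    def to_dict(self) -> dict:
        return asdict(self) | {
            "predictor_names": list(self.predictor_names),
            "beta": list(self.beta),
            "p": list(self.p),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predictor": self.predictor_names, "beta": self.beta, "p": self.p}
        ).assign(r_squared=self.r_squared, n_perm=self.n_perm, seed=self.seed,
                 outcome=self.outcome_name)


@dataclass(frozen=True)
class MRQAPResult(_RegressionResult):
    n_dyads: int = 0


@dataclass(frozen=True)
class NodeRegressionResult(_RegressionResult):
    n_nodes: int = 0


@dataclass(frozen=True)
class GearyResult:
    """Geary's C with a permutation p-value.

    ``c_perm_mean`` is the Monte-Carlo mean of C over the permutation null,
    which should sit at the theoretical null expectation of 1.0.
    """

    c: float
    p: float
    n_perm: int
    seed: int | None
    null_expectation: float = 1.0
    c_perm_mean: float = float("nan")
    weights: str = "binary"

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# plumbing


def vectorize_offdiag(matrices: Sequence[DyadicMatrix]) -> np.ndarray:
    """Stack matrices into aligned off-diagonal columns (n(n-1) x k).

    Cells are in row-major, diagonal-skipped order; all matrices must share
    the same ordered label set.
    """
    if not matrices:
        raise InputError("need at least one matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise LabelMismatchError(
                f"label mismatch: {m.name or '<unnamed>'} does not align with "
                f"{matrices[0].name or '<unnamed>'}"
            )
    return np.column_stack([m.offdiag_values() for m in matrices])


def offdiag_to_matrix(vec: np.ndarray, labels: Sequence[str], **kwargs) -> DyadicMatrix:
    """Inverse of :func:`vectorize_offdiag` for a single column."""
    n = len(labels)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n * (n - 1),):
        raise InputError(f"expected {n * (n - 1)} off-diagonal cells, got {vec.shape}")
    vals = np.full((n, n), np.nan)
    rows, cols = offdiag_indices(n)
    vals[rows, cols] = vec
    return DyadicMatrix(labels=tuple(labels), values=vals, **kwargs)


def _zscore_columns(X: np.ndarray, names: Sequence[str]) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    sd = X.std(axis=0)
    for k, s in enumerate(sd):
        if s == 0 or len(np.unique(X[:, k])) < 2:
            raise DegenerateInputError(f"column {names[k]!r} is constant")
    return (X - X.mean(axis=0)) / sd


def ols_standardized(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str] | None = None,
    allow_rank_deficient: bool = False,
) -> tuple[np.ndarray, float]:
    """Least squares on z-scored columns: standardized betas and r-squared.

    After z-scoring, no intercept is needed.  Rank-deficient designs raise
    unless ``allow_rank_deficient``, in which case the minimum-norm solution
    is returned (saturated node-level models are legitimate here: a model
    with as many predictors as individuals fits exactly, r^2 = 1, and the
    permutation test still discriminates).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = list(names) if names is not None else [f"x{k + 1}" for k in range(X.shape[1])]
    yz = _zscore_columns(np.asarray(y, dtype=float).reshape(-1, 1), ["y"])[:, 0]
    Xz = _zscore_columns(X, names)
    rank = np.linalg.matrix_rank(Xz)
    if rank < Xz.shape[1] and not allow_rank_deficient:
        raise DegenerateInputError(
            f"collinear predictors (rank {rank} < {Xz.shape[1]}): {names}"
        )
    beta, *_ = np.linalg.lstsq(Xz, yz, rcond=None)
    resid = yz - Xz @ beta
    r2 = 1.0 - (resid @ resid) / (yz @ yz)
    return beta, float(min(max(r2, 0.0), 1.0))


def qap_node_permutation(
    matrix: DyadicMatrix, perm: Mapping[str, str] | Sequence[int]
) -> DyadicMatrix:
    """Apply one node-label permutation to rows and columns simultaneously.

    ``perm`` is either a bijective mapping old-label -> new-label, or an
    index array ``p`` such that output cell (i, j) = input cell (p[i], p[j]).
    """
    n = matrix.n
    if isinstance(perm, Mapping):
        if set(perm) != set(matrix.labels) or set(perm.values()) != set(matrix.labels):
            raise InputError("perm must be a bijection on the matrix's label set")
        inv = {v: k for k, v in perm.items()}
        p = np.array([matrix.index(inv[l]) for l in matrix.labels])
    else:
        p = np.asarray(perm, dtype=int)
        if sorted(p.tolist()) != list(range(n)):
            raise InputError("perm indices must be a permutation of 0..n-1")
    return matrix.with_values(matrix.values[np.ix_(p, p)])


# ---------------------------------------------------------------------------
# MRQAP double semi-partialling


def _names_for(matrices: Sequence[DyadicMatrix], given: Sequence[str] | None) -> list[str]:
    if given is not None:
        return list(given)
    return [m.name or f"x{k + 1}" for k, m in enumerate(matrices)]


def _dsp_pieces(yz: np.ndarray, Xz: np.ndarray, n: int):
    """Precompute, per predictor k: residual e_k of X_k on the others, the
    projector pieces for partialling, and e_k reshaped to matrix form."""
    m, kdim = Xz.shape
    rows, cols = offdiag_indices(n)
    pieces = []
    for k in range(kdim):
        others = [j for j in range(kdim) if j != k]
        if others:
            Q, _ = np.linalg.qr(Xz[:, others])
            e = Xz[:, k] - Q @ (Q.T @ Xz[:, k])
            my = yz - Q @ (Q.T @ yz)
        else:
            Q = np.zeros((m, 0))
            e = Xz[:, k].copy()
            my = yz.copy()
        ss_e = float(e @ e)
        if ss_e <= _TIE_TOL:
            raise DegenerateInputError(
                f"predictor {k} is collinear with the remaining predictors"
            )
        E = np.zeros((n, n))
        E[rows, cols] = e
        pieces.append((E, Q, my, ss_e))
    return pieces, rows, cols


def _dsp_betas(E, Q, my, ss_e, P, rows, cols, *, tstat: bool, m: int, kdim: int):
    """Semi-partialled statistic for a batch of node permutations P (B x n)."""
    Estar = E[P[:, rows], P[:, cols]]          # (B, m) permuted residual vectors
    num = Estar @ my
    if Q.shape[1]:
        den = ss_e - np.einsum("bj,bj->b", Estar @ Q, Estar @ Q)
    else:
        den = np.full(len(P), ss_e)
    den = np.maximum(den, _TIE_TOL)
    beta = num / den
    if not tstat:
        return beta
    rss = np.maximum(my @ my - num * num / den, _TIE_TOL)
    df = max(m - kdim, 1)
    return num / np.sqrt(den) / np.sqrt(rss / df)


def _observed_stats(yz, Xz, names):
    rank = np.linalg.matrix_rank(Xz)
    if rank < Xz.shape[1]:
        raise DegenerateInputError(f"collinear predictors (rank deficient): {names}")
    beta, *_ = np.linalg.lstsq(Xz, yz, rcond=None)
    resid = yz - Xz @ beta
    r2 = 1.0 - (resid @ resid) / (yz @ yz)
    return beta, float(min(max(r2, 0.0), 1.0))


def _mrqap_core(
    Y: DyadicMatrix,
    Xs: Sequence[DyadicMatrix],
    P: np.ndarray,
    names: list[str],
    *,
    sampled: bool,
    seed: int | None,
    permute_stat: str,
    outcome_name: str | None,
) -> MRQAPResult:
    n = Y.n
    cols_all = vectorize_offdiag([Y, *Xs])
    all_names = ["y"] + names
    Z = _zscore_columns(cols_all, all_names)
    yz, Xz = Z[:, 0], Z[:, 1:]
    m, kdim = Xz.shape
    beta_obs, r2 = _observed_stats(yz, Xz, names)
    tstat = permute_stat == "tstat"
    pieces, rows, cols = _dsp_pieces(yz, Xz, n)

    pvals = []
    for k, (E, Q, my, ss_e) in enumerate(pieces):
        ident = np.arange(n)[None, :]
        obs = _dsp_betas(E, Q, my, ss_e, ident, rows, cols, tstat=tstat, m=m, kdim=kdim)[0]
        stats = _dsp_betas(E, Q, my, ss_e, P, rows, cols, tstat=tstat, m=m, kdim=kdim)
        hits = int(np.sum(np.abs(stats) >= abs(obs) - _TIE_TOL * max(1.0, abs(obs))))
        if sampled:
            pvals.append((hits + 1) / (len(P) + 1))
        else:
            pvals.append(hits / len(P))
    return MRQAPResult(
        outcome_name=outcome_name or Y.name or "y",
        predictor_names=tuple(names),
        beta=tuple(float(b) for b in beta_obs),
        r_squared=r2,
        p=tuple(float(p) for p in pvals),
        n_perm=len(P),
        seed=seed,
        engine="sampled" if sampled else "exhaustive",
        n_dyads=m,
    )


def mrqap_dsp(
    Y: DyadicMatrix,
    Xs: Sequence[DyadicMatrix],
    n_perm: int = 2000,
    seed=None,
    predictor_names: Sequence[str] | None = None,
    outcome_name: str | None = None,
    permute_stat: str = "beta",
) -> MRQAPResult:
    """MRQAP with double semi-partialling (sampled node permutations).

    For each predictor, its residual on the remaining predictors is reshaped
    to a matrix, node-permuted ``n_perm`` times (uniform with replacement,
    identity allowed), substituted back into the design, and the refit
    coefficient recorded; the two-tailed p compares |beta*| against the
    observed |beta|.
    """
    if Y.n < 4:
        raise SizeError("MRQAP needs at least 4 individuals")
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    if permute_stat not in ("beta", "tstat"):
        raise InputError(f"permute_stat must be 'beta' or 'tstat', got {permute_stat!r}")
    names = _names_for(Xs, predictor_names)
    rng = _rng(seed)
    P = np.stack([rng.permutation(Y.n) for _ in range(n_perm)])
    return _mrqap_core(
        Y, Xs, P, names, sampled=True,
        seed=seed if isinstance(seed, int) else None,
        permute_stat=permute_stat, outcome_name=outcome_name,
    )


def mrqap_exhaustive(
    Y: DyadicMatrix,
    Xs: Sequence[DyadicMatrix],
    predictor_names: Sequence[str] | None = None,
    outcome_name: str | None = None,
    permute_stat: str = "beta",
) -> MRQAPResult:
    """Exact MRQAP: enumerate every node permutation once (requires n <= 7).

    p is the fraction of the full permutation group (identity included)
    whose semi-partialled statistic is at least as extreme as observed.
    """
    n = Y.n
    if n > 7:
        raise SizeError(f"exhaustive enumeration refuses n={n} (> 7; {math.factorial(n)} perms)")
    names = _names_for(Xs, predictor_names)
    P = np.array(list(permutations(range(n))))
    return _mrqap_core(
        Y, Xs, P, names, sampled=False, seed=None,
        permute_stat=permute_stat, outcome_name=outcome_name,
    )


# ---------------------------------------------------------------------------
# Geary's C


def _geary_stat(x: np.ndarray, w_off: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> float:
    n = len(x)
    ss = float(((x - x.mean()) ** 2).sum())
    W = float(w_off.sum())
    num = float((w_off * (x[rows] - x[cols]) ** 2).sum())
    return (n - 1) * num / (2.0 * W * ss)


def geary_c(
    attribute,
    network: DyadicMatrix,
    n_perm: int = 10000,
    seed=None,
    weights: str = "binary",
) -> GearyResult:
    """Geary's C between a node attribute and a dyadic network.

    ``C = (N-1) sum_ij w_ij (x_i - x_j)^2 / (2 W sum_i (x_i - xbar)^2)``
    over off-diagonal cells.  With ``weights='binary'`` (default) any
    positive cell contributes weight 1; ``'weighted'`` uses cell values.
    The two-sided p doubles the smaller tail of the permutation null
    obtained by shuffling attribute values across individuals.
    """
    if weights not in ("binary", "weighted"):
        raise InputError(f"weights must be 'binary' or 'weighted', got {weights!r}")
    if isinstance(attribute, Mapping):
        x = np.array([attribute[l] for l in network.labels], dtype=float)
    elif isinstance(attribute, pd.Series):
        x = attribute.reindex(list(network.labels)).to_numpy(dtype=float)
        if np.isnan(x).any():
            raise InputError("attribute series is missing values for some individuals")
    else:
        x = np.asarray(attribute, dtype=float)
        if x.shape != (network.n,):
            raise InputError(f"attribute must have one value per individual ({network.n})")
    if x.std() == 0:
        raise DegenerateInputError("attribute is constant; Geary's C is undefined")

    rows, cols = offdiag_indices(network.n)
    w_off = network.values[rows, cols].copy()
    w_off = np.nan_to_num(w_off, nan=0.0)
    if (w_off < 0).any():
        raise InputError("network weights must be nonnegative")
    if weights == "binary":
        w_off = (w_off > 0).astype(float)
    if w_off.sum() == 0:
        raise InputError("network has no positive off-diagonal weights")

    c_obs = _geary_stat(x, w_off, rows, cols)
    rng = _rng(seed)
    n = network.n
    P = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Xp = x[P]  # (n_perm, n)
    diffs = (Xp[:, rows] - Xp[:, cols]) ** 2
    ss = float(((x - x.mean()) ** 2).sum())
    W = float(w_off.sum())
    c_star = (n - 1) * (diffs @ w_off) / (2.0 * W * ss)
    tol = _TIE_TOL * max(1.0, abs(c_obs))
    p_lo = (int(np.sum(c_star <= c_obs + tol)) + 1) / (n_perm + 1)
    p_hi = (int(np.sum(c_star >= c_obs - tol)) + 1) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return GearyResult(
        c=float(c_obs), p=float(p), n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
        c_perm_mean=float(c_star.mean()), weights=weights,
    )


# ---------------------------------------------------------------------------
# node-level permutation regression


def node_regression(
    y,
    X,
    n_perm: int = 10000,
    seed=None,
    predictor_names: Sequence[str] | None = None,
    outcome_name: str = "y",
    allow_rank_deficient: bool = True,
) -> NodeRegressionResult:
    """Node-level OLS with significance from permuting the outcome vector.

    Standardized coefficients are fit on z-scored columns; the null refits
    the model after each of ``n_perm`` random shuffles of y across
    individuals, and the two-tailed p compares |beta*| with |beta|.
    Saturated designs (p >= n, as when regressing degree on many degree
    covariates in a small community) use the minimum-norm solution.
    """
    if isinstance(X, pd.DataFrame):
        if predictor_names is None:
            predictor_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if isinstance(y, pd.Series):
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise SizeError("node regression needs at least 4 individuals")
    if X.shape[0] != n:
        raise InputError("y and X must have the same number of individuals")
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    names = list(predictor_names) if predictor_names is not None else [
        f"x{k + 1}" for k in range(X.shape[1])
    ]
    yz = _zscore_columns(y.reshape(-1, 1), ["y"])[:, 0]
    Xz = _zscore_columns(X, names)
    rank = np.linalg.matrix_rank(Xz)
    if rank < Xz.shape[1] and not allow_rank_deficient:
        raise DegenerateInputError(f"collinear predictors (rank deficient): {names}")
    pinv = np.linalg.pinv(Xz)
    beta = pinv @ yz
    resid = yz - Xz @ beta
    r2 = float(min(max(1.0 - (resid @ resid) / (yz @ yz), 0.0), 1.0))

    rng = _rng(seed)
    P = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Bstar = pinv @ yz[P].T  # (k, n_perm)
    tol = _TIE_TOL
    pvals = [
        (int(np.sum(np.abs(Bstar[k]) >= abs(beta[k]) - tol * max(1.0, abs(beta[k])))) + 1)
        / (n_perm + 1)
        for k in range(Xz.shape[1])
    ]
    return NodeRegressionResult(
        outcome_name=outcome_name,
        predictor_names=tuple(names),
        beta=tuple(float(b) for b in beta),
        r_squared=r2,
        p=tuple(float(p) for p in pvals),
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
        n_nodes=n,
    )
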