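"""Bray-Curtis dissimilarity and permutational multivariate ANOVA.

The PERMANOVA here is written from first principles: the squared-distance
matrix is Gower-centered into an inner-product matrix ``G``; sums of squares
for each design term are obtained sequentially (Type-I) by projecting onto an
orthonormal basis of the accumulated design columns, so
``SS_term = tr(H_k G) - tr(H_{k-1} G)``.  The pseudo-F statistic is
``(SS_term/df_term) / (SS_res/df_res)`` and its p-value comes from permuting
sample labels, optionally restricted within strata (e.g. within subjects for
a paired design).  With a single term, ``R2_term + R2_residual = 1``.

The permutation p-value uses the add-one estimator
``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` so it is never exactly 0;
an exhaustive mode (``n_permutations="all"``) enumerates every label
permutation for small n and reports the exact proportion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis, pdist, squareform

from .errors import DesignError, UndefinedStatisticError
from .qc import RelAbundanceTable

_RANK_TOL = 1e-8


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` between two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if x.sum() <= 0 and y.sum() <= 0:
        raise UndefinedStatisticError("Bray-Curtis is undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with sample ids and a metric tag."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def reorder(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(
            tuple(sample_ids), self.values[np.ix_(idx, idx)], self.metric
        )


def distance_matrix(rel: RelAbundanceTable, metric: str = "braycurtis") -> DistanceMatrix:
    """All pairwise dissimilarities of a relative-abundance table."""
    if rel.data.shape[0] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    condensed = pdist(rel.data.to_numpy(dtype=float), metric=metric)
    return DistanceMatrix(tuple(rel.sample_ids), squareform(condensed), metric)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def _design_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    if term not in design.columns:
        raise DesignError(f"term {term!r} not in design columns {list(design.columns)}")
    col = design[term]
    if col.nunique() < 2:
        raise DesignError(f"term {term!r} is constant")
    if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
        return col.to_numpy(dtype=float).reshape(-1, 1)
    dummies = pd.get_dummies(col.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _orthonormal_basis(columns: list[np.ndarray], n: int) -> tuple[np.ndarray, list[int]]:
    """Incremental Gram-Schmidt; returns basis and df (rank gain) per block."""
    basis: list[np.ndarray] = []
    dfs: list[int] = []
    for block in columns:
        gained = 0
        for j in range(block.shape[1]):
            v = block[:, j].astype(float)
            for q in basis:
                v = v - (q @ v) * q
            norm = np.linalg.norm(v)
            if norm > _RANK_TOL * math.sqrt(n):
                basis.append(v / norm)
                gained += 1
        dfs.append(gained)
    q = np.column_stack(basis) if basis else np.zeros((n, 0))
    return q, dfs


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str],
    n_permutations: int | str = 999,
    seed: int | None = None,
    strata: str | None = None,
) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA on a distance matrix.

    Parameters
    ----------
    dist, design
        ``design`` rows must align with ``dist.sample_ids`` (a ``sample_id``
        column or index is used to reorder when present).
    terms
        Ordered model terms (columns of ``design``); with one term the
        decomposition is the familiar single-factor PERMANOVA.
    n_permutations
        Number of random label permutations, or ``"all"`` to enumerate every
        permutation (n <= 8 only) for exact p-values.
    strata
        Optional design column; permutations are then restricted to shuffle
        samples only within each stratum.

    Returns a table with one row per term plus Residual and Total rows;
    columns: term, df, sum_sq, pseudo_F, R2, p_value.  Attributes
    ``attrs["n_permutations"]`` and ``attrs["seed"]`` record the setup.
    """
    design = design.copy()
    if "sample_id" in design.columns:
        design = design.set_index("sample_id")
    if set(design.index) == set(dist.sample_ids):
        design = design.loc[list(dist.sample_ids)]
    elif len(design) != dist.n:
        raise DesignError("design rows do not align with distance matrix samples")
    n = dist.n
    g = _gower_center(dist.values)
    ss_total = float(np.trace(g))

    blocks = [np.ones((n, 1))] + [_design_columns(design, t) for t in terms]
    q, dfs = _orthonormal_basis(blocks, n)
    term_dfs = dfs[1:]
    for t, df_t in zip(terms, term_dfs):
        if df_t == 0:
            raise DesignError(f"term {t!r} is confounded with earlier terms")
    df_model = sum(term_dfs)
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise DesignError("zero residual degrees of freedom: model is saturated")

    # boundaries[k] = number of basis columns consumed up to and incl. term k
    boundaries = np.cumsum(dfs)

    def seq_ss(g_mat: np.ndarray) -> tuple[np.ndarray, float]:
        contrib = np.einsum("ij,ij->j", q, g_mat @ q)  # q_j' G q_j per basis vector
        cum = np.concatenate([[0.0], np.cumsum(contrib)])
        per_block = cum[boundaries] - cum[np.concatenate([[0], boundaries[:-1]])]
        ss_terms = per_block[1:]  # drop intercept block
        ss_res = float(np.trace(g_mat)) - float(cum[boundaries[-1]])
        return ss_terms, ss_res

    ss_terms, ss_res = seq_ss(g)
    ms_res = ss_res / df_res
    f_obs = (ss_terms / np.asarray(term_dfs)) / ms_res

    # permutation null
    if strata is not None:
        if strata not in design.columns:
            raise DesignError(f"strata column {strata!r} not in design")
        groups = [
            np.flatnonzero((design[strata] == level).to_numpy())
            for level in design[strata].unique()
        ]
    else:
        groups = [np.arange(n)]

    def f_for(perm: np.ndarray) -> np.ndarray:
        gp = g[np.ix_(perm, perm)]
        ss_t, ss_r = seq_ss(gp)
        return (ss_t / np.asarray(term_dfs)) / (ss_r / df_res)

    # relative tie tolerance: permutations reproducing the observed grouping
    # must count as >= despite floating-point noise in the projection route
    tol = 1e-8 * np.maximum(1.0, np.abs(f_obs))
    if n_permutations == "all":
        if strata is not None:
            raise ValueError("exhaustive permutation does not support strata")
        if n > 8:
            raise ValueError("exhaustive permutation supported for n <= 8 only")
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            fp = f_for(np.asarray(perm))
            count += fp >= f_obs - tol
            total += 1
        p_values = count / total
        n_perm_used: int | str = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(int(n_permutations)):
            perm = np.arange(n)
            for idx in groups:
                perm[idx] = idx[rng.permutation(len(idx))]
            fp = f_for(perm)
            count += fp >= f_obs - tol
        p_values = (1.0 + count) / (1.0 + int(n_permutations))
        n_perm_used = int(n_permutations)

    rows = []
    for t, df_t, ss_t, f_t, p_t in zip(terms, term_dfs, ss_terms, f_obs, p_values):
        rows.append(
            dict(term=t, df=df_t, sum_sq=float(ss_t), pseudo_F=float(f_t),
                 R2=float(ss_t / ss_total), p_value=float(p_t))
        )
    rows.append(dict(term="Residual", df=df_res, sum_sq=float(ss_res),
                     pseudo_F=np.nan, R2=float(ss_res / ss_total), p_value=np.nan))
    rows.append(dict(term="Total", df=n - 1, sum_sq=ss_total,
                     pseudo_F=np.nan, R2=1.0, p_value=np.nan))
    out = pd.DataFrame(rows)
    out.attrs["n_permutations"] = n_perm_used
    out.attrs["seed"] = seed
    out.attrs["strata"] = strata
    return out


def single_term_permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 999,
    seed: int | None = None,
    strata: str | None = None,
) -> pd.DataFrame:
    """Fit each term alone in its own single-variable model (per-variable R2).

    Mirrors reporting each explanatory variable's marginal share separately;
    returns the concatenated per-term rows.
    """
    frames = []
    for i, term in enumerate(terms):
        tab = permanova(
            dist, design, [term], n_permutations=n_permutations,
            seed=None if seed is None else seed + i, strata=strata,
        )
        frames.append(tab[tab["term"] == term])
    return pd.concat(frames, ignore_index=True)
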