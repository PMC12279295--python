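"""Compositional-geometry primitives.

A composition is a vector of nonnegative proportions that sums to one (a
point on a simplex); zeros are allowed and meaningful.  A samples-by-features
table of compositions is held in a :class:`CompositionTable`.  A regression
coefficient matrix mapping one simplex into another is a rectangular Markov
matrix (nonnegative, columns summing to one), held in
:class:`CoefficientMatrix`.

All heavy lifting is plain NumPy; these classes are thin validated wrappers
so that downstream code can rely on the simplex/Markov invariants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance on "sums to one" checks
SUM_TOL = 1e-8


def close(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Renormalize nonnegative vectors so they sum to one (the closure map)."""
    values = np.asarray(values, dtype=float)
    total = values.sum(axis=axis, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("cannot close a vector with nonpositive total")
    return values / total


def _as_composition(values, name: str = "composition") -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"{name} must be a vector of length >= 2")
    if np.any(v < 0):
        raise ValueError(f"{name} has negative entries")
    s = v.sum()
    if abs(s - 1.0) > SUM_TOL:
        if s <= 0:
            raise ValueError(f"{name} has nonpositive total")
        logger.warning("%s sums to %.6g; renormalizing", name, s)
        v = v / s
    return v


@dataclass
class CompositionTable:
    """An ``n x d`` stack of compositions with sample and feature labels.

    Rows off the simplex by more than ``SUM_TOL`` are renormalized with a
    warning rather than rejected — sequencing proportions rarely sum exactly
    to one after rounding.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if np.any(v < 0):
            raise ValueError("compositions cannot have negative entries")
        totals = v.sum(axis=1)
        if np.any(totals <= 0):
            bad = np.nonzero(totals <= 0)[0]
            raise ValueError(f"rows with nonpositive total: {bad.tolist()}")
        if np.any(np.abs(totals - 1.0) > SUM_TOL):
            logger.warning(
                "%d row(s) do not sum to 1 within %g; renormalizing",
                int(np.sum(np.abs(totals - 1.0) > SUM_TOL)), SUM_TOL,
            )
            v = v / totals[:, None]
        self.values = v
        n, d = v.shape
        if self.sample_ids is None:
            self.sample_ids = [f"S{i+1}" for i in range(n)]
        if self.feature_ids is None:
            self.feature_ids = [f"F{j+1}" for j in range(d)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids length does not match column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "CompositionTable":
        return cls(
            frame.to_numpy(dtype=float),
            sample_ids=[str(i) for i in frame.index],
            feature_ids=[str(c) for c in frame.columns],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def __getitem__(self, rows) -> "CompositionTable":
        idx = np.arange(self.n_samples)[rows]
        return CompositionTable(
            self.values[idx],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
            feature_ids=list(self.feature_ids),
        )


@dataclass
class CoefficientMatrix:
    """A ``q x p`` rectangular Markov matrix: entries >= 0, columns sum to 1.

    Maps the predictor simplex ``S^p`` into the response simplex ``S^q`` via
    ``x -> B x``.  The barycenter matrix ``B0`` (all entries ``1/q``) is the
    no-association null element; the centered matrix ``B - 1/q`` is what the
    group-sparsity penalty acts on.
    """

    entries: np.ndarray
    row_ids: list[str] = field(default=None)  # type: ignore[assignment]
    col_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        b = np.atleast_2d(np.asarray(self.entries, dtype=float))
        if np.any(b < 0):
            raise ValueError("coefficient matrix has negative entries")
        sums = b.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > SUM_TOL):
            bad = np.nonzero(np.abs(sums - 1.0) > SUM_TOL)[0]
            raise ValueError(
                f"columns {bad.tolist()} do not sum to 1 within {SUM_TOL:g}"
            )
        self.entries = b
        q, p = b.shape
        if self.row_ids is None:
            self.row_ids = [f"R{k+1}" for k in range(q)]
        if self.col_ids is None:
            self.col_ids = [f"C{j+1}" for j in range(p)]
        if len(self.row_ids) != q or len(self.col_ids) != p:
            raise ValueError("label lengths do not match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    @property
    def q(self) -> int:
        return self.entries.shape[0]

    @property
    def p(self) -> int:
        return self.entries.shape[1]

    @classmethod
    def barycenter(cls, q: int, p: int, **labels) -> "CoefficientMatrix":
        """The null matrix B0 with every entry 1/q (no association)."""
        return cls(np.full((q, p), 1.0 / q), **labels)

    def centered(self) -> np.ndarray:
        """Column-centered deviations ``B - 1/q`` (each column sums to 0)."""
        return self.entries - 1.0 / self.q

    def to_dataframe(self, centered: bool = False) -> pd.DataFrame:
        vals = self.centered() if centered else self.entries
        return pd.DataFrame(vals, index=self.row_ids, columns=self.col_ids)


# ---------------------------------------------------------------------------
# operations


def kld(observed, expected, zero_expected: str = "error") -> float:
    """Kullback-Leibler divergence between stacks of compositions.

    Computes ``-sum_i sum_k y_ik * log(yhat_ik / y_ik)`` with the convention
    ``0 * log 0 = 0``.  Nonnegative, and zero iff the tables agree on the
    support of ``observed``.

    Parameters
    ----------
    observed, expected
        Arrays or CompositionTables of identical shape.
    zero_expected
        What to do when an expected entry is 0 where the observed entry is
        positive: ``"error"`` raises, ``"inf"`` returns ``+inf`` (useful to
        mark infeasible points during optimization).
    """
    y = observed.values if isinstance(observed, CompositionTable) else np.atleast_2d(np.asarray(observed, float))
    yhat = expected.values if isinstance(expected, CompositionTable) else np.atleast_2d(np.asarray(expected, float))
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: observed {y.shape} vs expected {yhat.shape}")
    support = y > 0
    if np.any(yhat[support] <= 0):
        if zero_expected == "inf":
            return float("inf")
        raise ValueError(
            "expected composition is 0 on the support of the observed one; "
            "KLD is undefined (pass zero_expected='inf' to get +inf)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(support, y * np.log(np.where(support, y / np.where(yhat > 0, yhat, 1.0), 1.0)), 0.0)
    return float(max(terms.sum(), 0.0))


def predict(B, x) -> np.ndarray:
    """Conditional-mean responses ``E(y|x) = B x`` for each row of ``x``.

    Returns an ``n x q`` array; rows are valid compositions by construction
    because B is column-stochastic.
    """
    b = B.entries if isinstance(B, CoefficientMatrix) else np.asarray(B, float)
    xv = x.values if isinstance(x, CompositionTable) else np.atleast_2d(np.asarray(x, float))
    if xv.shape[1] != b.shape[1]:
        raise ValueError(f"predictor dimension {xv.shape[1]} does not match B columns {b.shape[1]}")
    return xv @ b.T


def perturb(a, b) -> np.ndarray:
    """Aitchison perturbation: elementwise product, renormalized."""
    av, bv = np.asarray(a, float), np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError("dimension mismatch")
    return close(av * bv)


def inverse_perturb(a, b) -> np.ndarray:
    """Aitchison inverse perturbation ``a (-) b``: elementwise ratio, renormalized.

    Requires every entry of ``b`` to be strictly positive; callers working
    with sparse data should smooth first (see the bootstrap test).
    """
    av, bv = np.asarray(a, float), np.asarray(b, float)
    if av.shape != bv.shape:
        raise ValueError("dimension mismatch")
    if np.any(bv <= 0):
        raise ValueError(
            "inverse perturbation needs strictly positive denominator entries; "
            "smooth zeros first (e.g. add a pseudocount and renormalize)"
        )
    return close(av / bv)


def contrast_effect(B, j: int, j_prime: int, delta: float) -> np.ndarray:
    """Effect on E(y|x) of moving ``delta`` mass from predictor j' to j.

    Because columns of a compositional regression matrix carry only relative
    information, effects are defined pairwise: increasing ``x_j`` by delta at
    the expense of ``x_j'`` shifts the mean response by
    ``delta * (B[:, j] - B[:, j'])``, a vector summing to zero.
    """
    b = B.entries if isinstance(B, CoefficientMatrix) else np.asarray(B, float)
    p = b.shape[1]
    if not (0 <= j < p and 0 <= j_prime < p):
        raise IndexError(f"column index out of range for p={p}")
    if abs(delta) > 1:
        raise ValueError("|delta| must be <= 1 for a compositional shift")
    return delta * (b[:, j] - b[:, j_prime])


def pairwise_column_distances(B) -> np.ndarray:
    """Squared Euclidean distances ``||B_.j - B_.j'||_2^2`` between all column pairs.

    Symmetric with zero diagonal; the largest entry flags the predictor pair
    whose joint swap has the largest impact on the response.
    """
    b = B.entries if isinstance(B, CoefficientMatrix) else np.asarray(B, float)
    sq = np.sum(b * b, axis=0)
    d = sq[:, None] + sq[None, :] - 2.0 * (b.T @ b)
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def argmax_column_pair(B) -> tuple[int, int]:
    """Indices (j, j') of the most-separated pair of coefficient columns."""
    d = pairwise_column_distances(B)
    j, jp = np.unravel_index(np.argmax(d), d.shape)
    return int(j), int(jp)
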