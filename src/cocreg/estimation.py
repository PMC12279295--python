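"""Fitting the composition-on-composition regression model.

The model is ``E(y|x) = B x`` with ``B`` a q x p column-stochastic matrix.
Estimation minimizes the Kullback-Leibler divergence between observed and
fitted compositions; in high dimensions a group penalty shrinks whole
columns of ``B`` toward the barycenter column ``(1/q, ..., 1/q)``, the null
element of the response simplex:

    minimize_{B in F}  -sum_{ik} y_ik log( sum_j x_ij B_kj )
                       + lambda * sum_j || B_.j - 1/q ||_2

The unpenalized problem is solved by a multiplicative EM update (each unit
of response mass y_ik is attributed to a latent predictor source j with
posterior weight proportional to x_ij B_kj); the update preserves
nonnegativity and unit column sums and never increases the objective.  The
penalized problem interleaves one EM update with a group soft-threshold of
every column toward the barycenter, with backtracking on the true penalized
objective so descent is monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simplex import CompositionTable, CoefficientMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12  # floor inside logs during iteration only


@dataclass
class FitConfig:
    """Solver and tuning settings.

    Parameters
    ----------
    lam
        Penalty weight ``lambda >= 0``, or ``"auto"`` for cross-validated
        selection over ``lambda_grid``.
    max_iter, tol
        Outer-iteration cap and relative-objective-change convergence
        tolerance.
    lambda_grid
        Candidate penalty weights for CV; ``None`` builds a log-spaced grid
        from the data-driven full-shrinkage threshold ``lambda_max`` down to
        ``lambda_max * grid_floor``, plus 0.
    n_grid, grid_floor
        Size and lower relative bound of the automatic grid.
    cv_folds
        Folds for ``"auto"`` selection (>= 2).
    cv_rule
        ``"1se"`` (default): the largest lambda whose CV score is within one
        standard error of the minimum — the usual conservative choice for
        sparsity tuning, which resolves the near-flat region of the CV curve
        toward more shrinkage.  ``"min"``: the exact minimizer, ties broken
        toward the larger lambda.
    seed
        Seed for the CV fold shuffle and random initialization.
    init
        ``"barycenter"`` (deterministic null start) or ``"random"``
        (Dirichlet(1_q) columns, seeded) for multistart checks.
    """

    lam: float | str = "auto"
    max_iter: int = 5000
    tol: float = 1e-8
    lambda_grid: list[float] | None = None
    n_grid: int = 25
    grid_floor: float = 1e-4
    cv_folds: int = 5
    cv_rule: str = "1se"
    seed: int = 0
    init: str = "barycenter"
    cv_max_iter: int | None = None  # lighter cap for inner CV fits

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.lam == "auto" and self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2 for automatic lambda selection")
        if isinstance(self.lam, str) and self.lam != "auto":
            raise ValueError("lam must be a nonnegative number or 'auto'")
        if not isinstance(self.lam, str) and self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.cv_rule not in ("1se", "min"):
            raise ValueError("cv_rule must be '1se' or 'min'")


@dataclass
class FitResult:
    """Outcome of one solver run (array level)."""

    B_hat: CoefficientMatrix
    lambda_used: float
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    cv_table: list[tuple[float, float]] | None = None
    dropped_columns: list[int] = field(default_factory=list)

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


# ---------------------------------------------------------------------------
# objective pieces


def penalty(B) -> float:
    """Group (L2,1) penalty: sum over columns of ||B_.j - 1/q||_2.

    Zero exactly when B is the barycenter matrix B0.
    """
    b = B.entries if isinstance(B, CoefficientMatrix) else np.asarray(B, float)
    dev = b - 1.0 / b.shape[0]
    return float(np.sqrt((dev * dev).sum(axis=0)).sum())


def objective(B, x, y, lam: float) -> float:
    """Penalized fit criterion: negative log-fit term plus lam * penalty.

    The fit term ``-sum y_ik log(yhat_ik)`` equals the KL divergence between
    observed and fitted compositions up to the B-free constant
    ``sum y_ik log y_ik``; minimizers coincide.  Returns +inf at an
    infeasible point (a fitted zero where the observed entry is positive).
    """
    b = B.entries if isinstance(B, CoefficientMatrix) else np.asarray(B, float)
    xv = x.values if isinstance(x, CompositionTable) else np.asarray(x, float)
    yv = y.values if isinstance(y, CompositionTable) else np.asarray(y, float)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    yhat = xv @ b.T
    support = yv > 0
    if np.any(yhat[support] <= 0):
        return float("inf")
    fit = -float(np.sum(yv[support] * np.log(yhat[support])))
    return fit + lam * penalty(b)


# ---------------------------------------------------------------------------
# solver internals


def _coerce(x, y):
    xv = x.values if isinstance(x, CompositionTable) else np.atleast_2d(np.asarray(x, float))
    yv = y.values if isinstance(y, CompositionTable) else np.atleast_2d(np.asarray(y, float))
    if xv.shape[0] != yv.shape[0]:
        raise ValueError(f"x has {xv.shape[0]} rows but y has {yv.shape[0]}")
    if xv.shape[0] < 2:
        raise ValueError("need at least two samples")
    if xv.shape[1] < 2 or yv.shape[1] < 2:
        raise ValueError("need at least two predictor and two response components")
    return xv, yv


def _initial_B(q: int, p: int, init: str, seed: int) -> np.ndarray:
    if init == "barycenter":
        return np.full((q, p), 1.0 / q)
    if init == "random":
        rng = np.random.default_rng(seed)
        cols = rng.dirichlet(np.ones(q), size=p).T
        return cols
    raise ValueError(f"unknown init {init!r}")


def _em_candidate(B: np.ndarray, xv: np.ndarray, yv: np.ndarray,
                  active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative EM update.

    Returns the candidate matrix and the per-column posterior masses
    ``m_j = sum_{ik} y_ik w_ijk`` (these sum to n over active columns and
    scale the strength of evidence about column j).
    """
    yhat = np.maximum(xv @ B.T, _EPS)
    ratio = np.where(yv > 0, yv / yhat, 0.0)        # n x q
    M = xv.T @ ratio                                # p x q: sum_i x_ij y_ik / yhat_ik
    N = B * M.T                                     # q x p
    mass = N.sum(axis=0)                            # column masses
    C = B.copy()
    ok = active & (mass > 0)
    C[:, ok] = N[:, ok] / mass[ok]
    return C, mass


def _group_soft_threshold(C: np.ndarray, thresholds: np.ndarray,
                          active: np.ndarray) -> np.ndarray:
    """Shrink each column of C toward the barycenter by its group threshold.

    The shrunk column is a convex combination of the EM candidate and the
    barycenter, so nonnegativity and unit column sums are preserved without
    any projection.
    """
    q = C.shape[0]
    V = C - 1.0 / q
    norms = np.sqrt((V * V).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(norms > 0, np.maximum(0.0, 1.0 - thresholds / np.maximum(norms, _EPS)), 0.0)
    factor = np.where(active, factor, 0.0)  # inactive columns pinned at 1/q
    return 1.0 / q + V * factor


def fit_coc_arrays(xv: np.ndarray, yv: np.ndarray, lam: float,
                   config: FitConfig | None = None,
                   B_init: np.ndarray | None = None,
                   max_iter: int | None = None) -> FitResult:
    """Penalized (or, with lam=0, plain EM) fit at a fixed penalty weight."""
    config = config or FitConfig(lam=lam)
    xv = np.asarray(xv, float)
    yv = np.asarray(yv, float)
    n, p = xv.shape
    q = yv.shape[1]
    max_iter = max_iter if max_iter is not None else config.max_iter

    col_mass = xv.sum(axis=0)
    active = col_mass > 0
    dropped = np.nonzero(~active)[0].tolist()
    if dropped:
        logger.warning(
            "predictor column(s) %s never observed; fixing their coefficients "
            "at the barycenter and excluding them from the penalty", dropped)

    B = B_init.copy() if B_init is not None else _initial_B(q, p, config.init, config.seed)
    B[:, ~active] = 1.0 / q

    obj = objective(B, xv, yv, lam)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C, mass = _em_candidate(B, xv, yv, active)
        if lam == 0:
            B_new = C
            new_obj = objective(B_new, xv, yv, lam)
            # EM descent can only stall from the log floor; clamp defensively
            if new_obj > obj + 1e-9:
                B_new, new_obj = B, obj
        else:
            # group soft-threshold scaled by column evidence, with
            # backtracking on the true penalized objective
            safe_mass = np.maximum(mass, _EPS)
            step = 1.0
            B_new, new_obj = B, obj
            for _ in range(30):
                thr = step * lam / safe_mass
                cand = _group_soft_threshold(C, thr, active)
                cand_obj = objective(cand, xv, yv, lam)
                if cand_obj <= obj + 1e-12:
                    B_new, new_obj = cand, cand_obj
                    break
                step *= 0.5
            else:
                # even vanishing shrinkage fails: keep the current iterate
                B_new, new_obj = B, obj
        rel = abs(obj - new_obj) / max(abs(obj), 1.0)
        B, obj = B_new, new_obj
        trace.append(obj)
        if rel < config.tol:
            converged = True
            break

    B_hat = CoefficientMatrix(B)
    return FitResult(
        B_hat=B_hat,
        lambda_used=float(lam),
        objective_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
        dropped_columns=dropped,
    )


def lambda_max(xv: np.ndarray, yv: np.ndarray) -> float:
    """Smallest penalty weight at which a fit started from B0 stays at B0.

    From the barycenter start, one EM pass produces candidate columns c_j
    with evidence masses m_j; the first proximal step keeps B = B0 exactly
    iff ``lambda >= m_j * ||c_j - 1/q||`` for every column, which then makes
    B0 a fixed point of the iteration.
    """
    xv = np.asarray(xv, float)
    yv = np.asarray(yv, float)
    q = yv.shape[1]
    p = xv.shape[1]
    active = xv.sum(axis=0) > 0
    B0 = np.full((q, p), 1.0 / q)
    C, mass = _em_candidate(B0, xv, yv, active)
    dev = np.sqrt(((C - 1.0 / q) ** 2).sum(axis=0))
    val = float(np.max(mass * dev, initial=0.0))
    return max(val, _EPS)


def default_lambda_grid(xv: np.ndarray, yv: np.ndarray,
                        config: FitConfig) -> np.ndarray:
    """Log-spaced grid from lambda_max down to lambda_max*grid_floor, plus 0."""
    lmax = lambda_max(xv, yv)
    grid = np.geomspace(lmax, lmax * config.grid_floor, config.n_grid)
    return np.concatenate([grid, [0.0]])


def _heldout_kld(B: np.ndarray, xv: np.ndarray, yv: np.ndarray) -> float:
    """Mean per-sample KLD on held-out data, with a floor inside the log so a
    single structurally-zero prediction does not void the whole fold."""
    yhat = np.maximum(xv @ B.T, _EPS)
    support = yv > 0
    terms = np.where(support, yv * (np.log(np.where(support, yv, 1.0)) - np.log(yhat)), 0.0)
    return float(terms.sum()) / xv.shape[0]


def select_lambda(x, y, config: FitConfig | None = None):
    """Cross-validated choice of the penalty weight.

    K-fold CV on the mean held-out KLD.  Under the default ``cv_rule="1se"``
    the selected lambda is the largest one whose score is within one
    standard error (across folds) of the minimum; under ``"min"`` it is the
    exact minimizer with ties broken toward the larger lambda (more
    shrinkage).  Fits along the grid are warm-started from the previous
    (larger) lambda's solution.

    Returns ``(lambda, cv_table)`` where cv_table lists (lambda, score).
    """
    config = config or FitConfig()
    xv, yv = _coerce(x, y)
    n = xv.shape[0]
    if config.cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if n < config.cv_folds:
        raise ValueError(f"cannot make {config.cv_folds} folds from {n} samples")
    grid = (np.asarray(config.lambda_grid, float) if config.lambda_grid is not None
            else default_lambda_grid(xv, yv, config))
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    grid = np.sort(np.unique(grid))[::-1]  # descending: warm-start a path

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, config.cv_folds)
    if min(len(f) for f in folds) < 1 or n - min(len(f) for f in folds) < 2:
        raise ValueError("a CV fold would leave fewer than two training samples")

    inner_iter = config.cv_max_iter if config.cv_max_iter is not None else config.max_iter
    fold_scores = np.zeros((grid.size, len(folds)))
    weights = np.array([len(f) for f in folds], float)
    for fi, fold in enumerate(folds):
        mask = np.ones(n, bool)
        mask[fold] = False
        x_tr, y_tr = xv[mask], yv[mask]
        x_te, y_te = xv[fold], yv[fold]
        B_warm = None
        for gi, lam in enumerate(grid):
            res = fit_coc_arrays(x_tr, y_tr, lam, config, B_init=B_warm,
                                 max_iter=inner_iter)
            B_warm = res.B_hat.entries
            fold_scores[gi, fi] = _heldout_kld(B_warm, x_te, y_te)
    scores = fold_scores @ weights / weights.sum()

    best_idx = int(np.nonzero(scores <= scores.min() + 1e-12)[0][0])
    if config.cv_rule == "1se":
        se = float(fold_scores[best_idx].std(ddof=1) / np.sqrt(len(folds)))
        # descending grid: first index within one SE is the largest lambda
        pick = int(np.nonzero(scores <= scores[best_idx] + se)[0][0])
    else:
        pick = best_idx
    cv_table = list(zip(grid.tolist(), scores.tolist()))
    return float(grid[pick]), cv_table


def fit_dr(x, y, config: FitConfig | None = None) -> FitResult:
    """Unpenalized KLD-minimizing EM fit (the low-dimensional DR baseline)."""
    config = config or FitConfig(lam=0.0)
    xv, yv = _coerce(x, y)
    return fit_coc_arrays(xv, yv, 0.0, config)


def fit_coc(x, y, config: FitConfig | None = None) -> FitResult:
    """Penalized COC fit; lam='auto' runs cross-validated selection first."""
    config = config or FitConfig()
    xv, yv = _coerce(x, y)
    cv_table = None
    lam = config.lam
    if lam == "auto":
        lam, cv_table = select_lambda(xv, yv, config)
    res = fit_coc_arrays(xv, yv, float(lam), config)
    res.cv_table = cv_table
    return res
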