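"""Resampling inference and conformal prediction for COC regression.

Hypothesis testing targets the global null of no association,
``H0: B = B0`` with ``B0`` the all-``1/q`` barycenter matrix.  Two tests
are provided:

* a residual bootstrap on the simplex: compositional residuals
  ``e_i = y_i (-) yhat_i`` (Aitchison inverse perturbation against the
  fitted values) are resampled with replacement and applied to the null
  fitted value (the barycenter, since ``B0 x`` is constant) to synthesize
  responses under H0; the statistic is ``T = ||Bhat - B0||_F``;
* a permutation test that breaks the pairing between predictor and
  response rows, the classical approach for this null.

Prediction uncertainty uses conformal inference with the KL divergence as
the conformity score: the full-conformal p-value refits the model on the
augmented dataset for each candidate response, while the split-conformal
region needs a single fit and is a KLD ball of radius ``c`` (a data-driven
calibration quantile) around the predicted composition.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .estimation import FitConfig, fit_coc_arrays, select_lambda
from .simplex import CoefficientMatrix, CompositionTable, close

_EPS = 1e-12


def rowwise_kld(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    """Per-row KL divergence between stacks of compositions.

    Rows where the prediction is zero on the observed support get +inf.
    """
    y = np.atleast_2d(np.asarray(y, float))
    yhat = np.atleast_2d(np.asarray(yhat, float))
    support = y > 0
    out = np.empty(y.shape[0])
    bad = np.any(support & (yhat <= 0), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(support, y * (np.log(np.where(support, y, 1.0))
                                       - np.log(np.where(yhat > 0, yhat, 1.0))), 0.0)
    out[:] = np.maximum(terms.sum(axis=1), 0.0)
    out[bad] = np.inf
    return out


def smooth_zeros(values: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Pseudocount smoothing: add eps to every coordinate and renormalize.

    Used only where the Aitchison inverse perturbation needs strictly
    positive entries; reported divergences are never smoothed.
    """
    return close(np.asarray(values, float) + eps)


def _values(t) -> np.ndarray:
    return t.values if isinstance(t, CompositionTable) else np.atleast_2d(np.asarray(t, float))


@dataclass
class TestResult:
    """Outcome of a resampling test of H0: B = B0."""

    statistic_observed: float
    statistics_null: np.ndarray
    p_value: float
    method: str
    n_resamples: int
    seed: int
    lambda_used: float

    def to_json(self) -> str:
        return json.dumps({
            "method": self.method,
            "statistic_observed": self.statistic_observed,
            "p_value": self.p_value,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "lambda_used": self.lambda_used,
        })


def _add_one_pvalue(t_obs: float, t_null: np.ndarray) -> float:
    """(1 + #{null >= observed}) / (1 + n): never zero, exact ties count."""
    return float((1 + np.sum(t_null >= t_obs)) / (1 + t_null.size))


def _resolve_lambda(xv, yv, config: FitConfig):
    lam = config.lam
    if lam == "auto":
        lam, _ = select_lambda(xv, yv, config)
    return float(lam)


def bootstrap_test(x, y, config: FitConfig | None = None, n_boot: int = 200,
                   seed: int = 0, smooth_eps: float = 1e-6,
                   refit_max_iter: int | None = None) -> TestResult:
    """Residual bootstrap test of H0: B = B0.

    The penalty weight is selected once on the observed data and held fixed
    across resamples.  Responses and fitted values are pseudocount-smoothed
    (``smooth_eps``) before forming compositional residuals, since the
    inverse perturbation requires strictly positive denominators.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    config = config or FitConfig()
    xv, yv = _values(x), _values(y)
    n, q = yv.shape
    lam = _resolve_lambda(xv, yv, config)
    fit = fit_coc_arrays(xv, yv, lam, config)
    B_hat = fit.B_hat.entries
    t_obs = float(np.linalg.norm(B_hat - 1.0 / q))

    # compositional residuals against the fitted values; under H0 the fitted
    # value B0 x is the barycenter, and barycenter (+) e = e, so the null
    # responses are simply resampled residuals
    yhat = np.maximum(xv @ B_hat.T, 0.0)
    e = smooth_zeros(yv, smooth_eps) / smooth_zeros(yhat, smooth_eps)
    e = close(e)

    rng = np.random.default_rng(seed)
    B0 = np.full_like(B_hat, 1.0 / q)
    t_null = np.empty(n_boot)
    cap = refit_max_iter if refit_max_iter is not None else config.max_iter
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        refit = fit_coc_arrays(xv, e[idx], lam, config, B_init=B0, max_iter=cap)
        t_null[b] = np.linalg.norm(refit.B_hat.entries - 1.0 / q)

    return TestResult(
        statistic_observed=t_obs,
        statistics_null=t_null,
        p_value=_add_one_pvalue(t_obs, t_null),
        method="bootstrap",
        n_resamples=n_boot,
        seed=seed,
        lambda_used=lam,
    )


def permutation_test(x, y, config: FitConfig | None = None, n_perm: int = 200,
                     seed: int = 0, statistic: str = "dr",
                     refit_max_iter: int | None = None) -> TestResult:
    """Permutation test of H0: B = B0 by breaking the (x, y) row pairing.

    ``statistic`` chooses the fitted model for ``T = ||Bhat - B0||_F``:
    ``"dr"`` (unpenalized EM) or ``"coc"`` (penalized, weight selected once
    on the observed pairing and reused for every permutation).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    config = config or FitConfig()
    xv, yv = _values(x), _values(y)
    n, q = yv.shape
    if statistic == "dr":
        lam = 0.0
    elif statistic == "coc":
        lam = _resolve_lambda(xv, yv, config)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    cap = refit_max_iter if refit_max_iter is not None else config.max_iter
    fit = fit_coc_arrays(xv, yv, lam, config, max_iter=cap)
    t_obs = float(np.linalg.norm(fit.B_hat.entries - 1.0 / q))

    rng = np.random.default_rng(seed)
    t_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        refit = fit_coc_arrays(xv, yv[perm], lam, config, max_iter=cap)
        t_null[b] = np.linalg.norm(refit.B_hat.entries - 1.0 / q)

    return TestResult(
        statistic_observed=t_obs,
        statistics_null=t_null,
        p_value=_add_one_pvalue(t_obs, t_null),
        method="permutation",
        n_resamples=n_perm,
        seed=seed,
        lambda_used=float(lam),
    )


# ---------------------------------------------------------------------------
# conformal prediction


def full_conformal_pvalue(x, y, x_new, y_cand,
                          config: FitConfig | None = None) -> float:
    """Conformal p-value of a candidate response at a new predictor.

    Refits the model on the dataset augmented with ``(x_new, y_cand)`` and
    ranks the candidate's conformity score ``R = KLD(y, yhat)`` among all
    n+1 scores: ``pi = (1/(n+1)) sum_i I(R_i <= R_{n+1})``.  The candidate
    lies in the level-(1-alpha) region iff
    ``(n+1) pi <= ceil((1-alpha)(n+1))``.

    Exploring a whole region this way needs a candidate lattice over S^q,
    which is only tractable for small q; for larger responses use the split
    conformal region.
    """
    config = config or FitConfig()
    xv, yv = _values(x), _values(y)
    q = yv.shape[1]
    if q > 10:
        raise ValueError(
            f"full conformal candidate search is intractable for q={q} > 10; "
            "use split_conformal_calibrate instead")
    x_aug = np.vstack([xv, np.asarray(x_new, float)[None, :]])
    y_aug = np.vstack([yv, np.asarray(y_cand, float)[None, :]])
    lam = _resolve_lambda(x_aug, y_aug, config)
    fit = fit_coc_arrays(x_aug, y_aug, lam, config)
    scores = rowwise_kld(y_aug, x_aug @ fit.B_hat.entries.T)
    return float(np.mean(scores <= scores[-1] + _EPS))


def full_conformal_contains(pi: float, n: int, alpha: float) -> bool:
    """Region membership from a full-conformal p-value on n training pairs."""
    return (n + 1) * pi <= math.ceil((1 - alpha) * (n + 1)) + _EPS


@dataclass
class ConformalCalibration:
    """A calibrated split-conformal region: a KLD ball around predictions.

    ``cutoff_c`` is the ``ceil((n2+1)(1-alpha))``-th smallest calibration
    score; when that rank exceeds the calibration size the cutoff is +inf
    and the region is the whole simplex (``whole_simplex`` flag).
    """

    B_hat: CoefficientMatrix
    scores: np.ndarray
    cutoff_c: float
    alpha: float
    split_seed: int
    lambda_used: float
    train_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    calibration_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def whole_simplex(self) -> bool:
        return not np.isfinite(self.cutoff_c)


def split_conformal_calibrate(x, y, alpha: float,
                              config: FitConfig | None = None,
                              seed: int = 0) -> ConformalCalibration:
    """Calibrate a split-conformal prediction region at level 1 - alpha.

    The sample is split at random into a training half (the larger half for
    odd n) used to fit the model and a calibration half whose conformity
    scores ``R_i = KLD(y_i, Bhat x_i)`` set the cutoff.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    config = config or FitConfig()
    xv, yv = _values(x), _values(y)
    n = xv.shape[0]
    if n < 4:
        raise ValueError("need at least four samples to split and calibrate")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = math.ceil(n / 2)
    idx_train, idx_cal = perm[:n_train], perm[n_train:]

    lam = _resolve_lambda(xv[idx_train], yv[idx_train], config)
    fit = fit_coc_arrays(xv[idx_train], yv[idx_train], lam, config)
    scores = rowwise_kld(yv[idx_cal], xv[idx_cal] @ fit.B_hat.entries.T)

    n2 = idx_cal.size
    rank = math.ceil((n2 + 1) * (1 - alpha))
    if rank > n2:
        cutoff = float("inf")
    else:
        cutoff = float(np.sort(scores)[rank - 1])
    return ConformalCalibration(
        B_hat=fit.B_hat,
        scores=scores,
        cutoff_c=cutoff,
        alpha=alpha,
        split_seed=seed,
        lambda_used=lam,
        train_index=idx_train,
        calibration_index=idx_cal,
    )


def split_conformal_contains(cal: ConformalCalibration, x_new, y_cand) -> bool:
    """True iff KLD(y_cand, Bhat x_new) <= cutoff.

    A candidate supported where the prediction is zero has infinite
    divergence and is never inside a finite region.
    """
    x_new = np.asarray(x_new, float).ravel()
    y_cand = np.asarray(y_cand, float).ravel()
    yhat = cal.B_hat.entries @ x_new
    score = rowwise_kld(y_cand[None, :], yhat[None, :])[0]
    return bool(score <= cal.cutoff_c)


def conformal_projection_grid(cal: ConformalCalibration, x_new,
                              resolution: int = 50) -> pd.DataFrame:
    """Membership flags over 2-D projections of the response simplex.

    For every coordinate pair (k, k') a barycentric lattice of candidates is
    built: the pair takes masses (u, v) with u + v <= 1 and the remaining
    mass is spread uniformly over the other q - 2 coordinates.  Returns a
    long-format frame with columns (k, k_prime, u, v, inside), ready for
    faceted plotting of the prediction region.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    x_new = np.asarray(x_new, float).ravel()
    q = cal.B_hat.q
    yhat = cal.B_hat.entries @ x_new
    ticks = np.linspace(0.0, 1.0, resolution)
    records = []
    for k, kp in itertools.combinations(range(q), 2):
        for u in ticks:
            for v in ticks:
                if u + v > 1.0 + 1e-12:
                    continue
                cand = np.zeros(q)
                cand[k], cand[kp] = u, v
                rest = 1.0 - u - v
                if q > 2:
                    others = np.ones(q, bool)
                    others[[k, kp]] = False
                    cand[others] = rest / (q - 2)
                elif rest > 1e-12:
                    continue  # q == 2: only the u + v = 1 edge exists
                score = rowwise_kld(cand[None, :], yhat[None, :])[0]
                records.append((k, kp, float(u), float(v), bool(score <= cal.cutoff_c)))
    return pd.DataFrame(records, columns=["k", "k_prime", "u", "v", "inside"])
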