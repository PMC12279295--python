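"""Synthetic-data generators and benchmark runners.

The generators emulate paired relative-abundance surveys: a predictor
composition (e.g. bacterial genera) drives the conditional mean of a
response composition (e.g. fungal classes) through a column-stochastic
coefficient matrix, and responses are Dirichlet-distributed around that
mean.  Two predictor designs are provided:

* ``homogeneous``   — rows i.i.d. Dirichlet(1_p): exchangeable components.
* ``heterogeneous`` — softmax of latent Gaussian rows N_p(theta, Sigma)
  with ``theta_j = log(0.5 p)`` for the first five components (which then
  dominate the composition) and an AR(1) correlation
  ``Sigma_ij = rho^|i-j|``.

Coefficient matrices carry a configurable fraction of "signal" columns
drawn from Dirichlet(1_q); the remaining columns sit at the barycenter
(no association).  Responses are drawn as ``y_i ~ Dirichlet(c * B x_i)``
with concentration ``c`` (default 10), so smaller conditional means both
shrink a component and make it noisier — the zero-inflated flavour of
sequencing data.

The benchmark runners measure estimation error (Frobenius norm), leave-
one-out predictive KL divergence, test rejection rates, and split-conformal
coverage on these designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .estimation import FitConfig, fit_coc_arrays, select_lambda
from .simplex import CoefficientMatrix, CompositionTable, close
from . import inference

logger = logging.getLogger(__name__)

SIGNAL_FRACTIONS = {
    "null": 0.0,
    "extremely_sparse": 0.01,
    "sparse": 0.05,
    "dense": 1.0,
}


@dataclass
class Scenario:
    """One simulation condition.

    ``signal`` controls the fraction of non-barycenter coefficient columns:
    1% (extremely_sparse), 5% (sparse), all (dense) or none (null).  A
    non-integer count rounds, with a floor of one column so that every
    non-null scenario carries some signal.
    """

    p: int
    q: int
    n: int
    predictor_design: str = "homogeneous"
    signal: str = "dense"
    concentration: float = 10.0
    rho: float = 0.5
    n_dominant: int = 5
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.predictor_design not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown predictor design {self.predictor_design!r}")
        if self.signal not in SIGNAL_FRACTIONS:
            raise ValueError(f"unknown signal type {self.signal!r}")
        if min(self.p, self.q) < 2 or self.n < 2:
            raise ValueError("p, q must be >= 2 and n >= 2")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")

    @property
    def n_signal_columns(self) -> int:
        frac = SIGNAL_FRACTIONS[self.signal]
        if frac == 0.0:
            return 0
        return max(1, round(frac * self.p))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent substream for one replicate, reproducible in isolation."""
    return np.random.default_rng([int(seed) % (2**31), int(replicate)])


def gen_predictors(scenario: Scenario, seed=None) -> CompositionTable:
    """Draw the n x p predictor composition table for a scenario."""
    rng = _rng(scenario.seed if seed is None else seed)
    n, p = scenario.n, scenario.p
    if scenario.predictor_design == "homogeneous":
        x = rng.dirichlet(np.ones(p), size=n)
    else:
        theta = np.zeros(p)
        k = min(scenario.n_dominant, p)
        theta[:k] = np.log(0.5 * p)
        # AR(1) latent field: exact recursion for Sigma_ij = rho^|i-j|
        rho = scenario.rho
        eps = rng.standard_normal((n, p))
        w = np.empty((n, p))
        w[:, 0] = eps[:, 0]
        c = np.sqrt(1.0 - rho * rho)
        for j in range(1, p):
            w[:, j] = rho * w[:, j - 1] + c * eps[:, j]
        w += theta
        w -= w.max(axis=1, keepdims=True)
        x = close(np.exp(w))
    return CompositionTable(x)


def gen_coefficients(scenario: Scenario, seed=None) -> CoefficientMatrix:
    """Draw the true q x p coefficient matrix for a scenario.

    Signal columns (chosen uniformly without replacement) are Dirichlet(1_q);
    all other columns are exactly the barycenter column (1/q, ..., 1/q).
    """
    rng = _rng(scenario.seed if seed is None else seed)
    p, q = scenario.p, scenario.q
    B = np.full((q, p), 1.0 / q)
    m = scenario.n_signal_columns
    if m:
        idx = rng.choice(p, size=m, replace=False)
        B[:, idx] = rng.dirichlet(np.ones(q), size=m).T
    return CoefficientMatrix(B)


def gen_responses(x, B, concentration: float = 10.0, seed=None) -> CompositionTable:
    """Draw responses ``y_i ~ Dirichlet(concentration * B x_i)``.

    A zero conditional-mean coordinate yields a Dirichlet parameter of zero
    and hence an exactly-zero response coordinate (degenerate-Dirichlet
    convention, realized through gamma draws with shape zero).
    """
    rng = _rng(seed)
    xv = x.values if isinstance(x, CompositionTable) else np.asarray(x, float)
    b = B.entries if isinstance(B, CoefficientMatrix) else np.asarray(B, float)
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    mu = xv @ b.T
    totals = mu.sum(axis=1)
    if np.any(totals <= 0):
        raise RuntimeError("a conditional mean row is entirely zero; B is not column-stochastic")
    g = rng.gamma(np.maximum(concentration * mu, 0.0), 1.0)
    row_sums = g.sum(axis=1)
    # shape parameters can underflow the gamma sampler to all-zero rows only
    # in pathological cases; redraw those rows from the exact mean instead
    bad = row_sums <= 0
    if np.any(bad):
        g[bad] = mu[bad]
    return CompositionTable(close(g))


def simulate_dataset(scenario: Scenario, seed=None):
    """Generate one (x, B, y) triple; returns (CompositionTable, CoefficientMatrix, CompositionTable)."""
    rng = _rng(scenario.seed if seed is None else seed)
    x = gen_predictors(scenario, rng)
    B = gen_coefficients(scenario, rng)
    y = gen_responses(x, B, scenario.concentration, rng)
    return x, B, y


def null_distance(m: int, q: int) -> float:
    """Expected squared Frobenius distance ||B - B0||_F^2 of m Dirichlet(1_q)
    signal columns is m(q-1)/(q(q+1)); returns its square root."""
    return float(np.sqrt(m * (q - 1) / (q * (q + 1))))


# ---------------------------------------------------------------------------
# benchmark runners


def _fit_method(method: str, xv, yv, config: FitConfig):
    if method == "dr":
        return fit_coc_arrays(xv, yv, 0.0, config)
    if method == "coc":
        lam = config.lam
        if lam == "auto":
            lam, _ = select_lambda(xv, yv, config)
        return fit_coc_arrays(xv, yv, float(lam), config)
    raise ValueError(f"unknown method {method!r}")


def run_estimation_benchmark(scenario: Scenario, methods=("coc", "dr"),
                             config: FitConfig | None = None) -> pd.DataFrame:
    """Mean Frobenius-norm error ||Bhat - B||_F per method over replicates."""
    config = config or FitConfig()
    errors: dict[str, list[float]] = {m: [] for m in methods}
    completed = 0
    for r in range(scenario.n_replicates):
        rng = replicate_rng(scenario.seed, r)
        try:
            x, B, y = simulate_dataset(scenario, rng)
            for m in methods:
                res = _fit_method(m, x.values, y.values, replace(config, seed=int(rng.integers(2**31))))
                errors[m].append(float(np.linalg.norm(res.B_hat.entries - B.entries)))
            completed += 1
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("replicate %d aborted: %s", r, exc)
    rows = []
    for m in methods:
        e = np.asarray(errors[m])
        rows.append({
            "method": m,
            "mean_frobenius_error": e.mean(),
            "se": e.std(ddof=1) / np.sqrt(len(e)) if len(e) > 1 else np.nan,
            "n_replicates": completed,
        })
    return pd.DataFrame(rows)


def run_prediction_benchmark(scenario: Scenario, methods=("coc", "dr"),
                             config: FitConfig | None = None) -> pd.DataFrame:
    """Mean leave-one-out KL divergence per method over replicates.

    For the penalized method the penalty weight is selected once per
    replicate on the full data and held fixed across the n leave-one-out
    refits, which are warm-started from the full-data solution.
    """
    config = config or FitConfig()
    scores: dict[str, list[float]] = {m: [] for m in methods}
    completed = 0
    for r in range(scenario.n_replicates):
        rng = replicate_rng(scenario.seed, r)
        try:
            x, B, y = simulate_dataset(scenario, rng)
            xv, yv = x.values, y.values
            n = xv.shape[0]
            for m in methods:
                cfg = replace(config, seed=int(rng.integers(2**31)))
                if m == "dr":
                    lam = 0.0
                else:
                    lam = cfg.lam
                    if lam == "auto":
                        lam, _ = select_lambda(xv, yv, cfg)
                    lam = float(lam)
                warm = fit_coc_arrays(xv, yv, lam, cfg).B_hat.entries
                klds = []
                for i in range(n):
                    mask = np.ones(n, bool)
                    mask[i] = False
                    res = fit_coc_arrays(xv[mask], yv[mask], lam, cfg, B_init=warm)
                    yhat = xv[i] @ res.B_hat.entries.T
                    klds.append(inference.rowwise_kld(yv[i][None, :], yhat[None, :])[0])
                scores[m].append(float(np.mean(klds)))
            completed += 1
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("replicate %d aborted: %s", r, exc)
    rows = []
    for m in methods:
        s = np.asarray(scores[m])
        rows.append({
            "method": m,
            "mean_loo_kld": s.mean(),
            "se": s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan,
            "n_replicates": completed,
        })
    return pd.DataFrame(rows)


def run_test_benchmark(scenario: Scenario, alpha: float = 0.05,
                       method: str = "bootstrap", n_resamples: int = 200,
                       config: FitConfig | None = None,
                       refit_max_iter: int | None = None) -> pd.DataFrame:
    """Empirical rejection rate of H0: B = B0 over replicates.

    With a null scenario this is the Type-I error rate; with signal it is
    the power.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    config = config or FitConfig()
    pvals = []
    for r in range(scenario.n_replicates):
        rng = replicate_rng(scenario.seed, r)
        x, _, y = simulate_dataset(scenario, rng)
        test_seed = int(rng.integers(2**31))
        cfg = replace(config, seed=test_seed)
        if method == "bootstrap":
            tr = inference.bootstrap_test(x, y, config=cfg, n_boot=n_resamples,
                                          seed=test_seed, refit_max_iter=refit_max_iter)
        elif method == "permutation":
            tr = inference.permutation_test(x, y, config=cfg, n_perm=n_resamples,
                                            seed=test_seed, refit_max_iter=refit_max_iter)
        else:
            raise ValueError(f"unknown test method {method!r}")
        pvals.append(tr.p_value)
    pvals = np.asarray(pvals)
    return pd.DataFrame([{
        "method": method,
        "alpha": alpha,
        "rejection_rate": float(np.mean(pvals <= alpha)),
        "n_replicates": scenario.n_replicates,
        "n_resamples": n_resamples,
    }])


def center_perturbed_point(p: int, j: int, delta: float) -> np.ndarray:
    """The simplex center with delta added to coordinate j, renormalized."""
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    v = np.full(p, 1.0 / p)
    v[j] += delta
    return close(v)


def run_coverage_benchmark(scenario: Scenario, alpha: float = 0.05,
                           delta: float = 0.01, n_points: int | None = None,
                           n_repeats: int = 50,
                           config: FitConfig | None = None) -> pd.DataFrame:
    """Split-conformal coverage for new predictors near the simplex center.

    For each evaluation point (the center of S^p with ``delta`` added to one
    coordinate, renormalized) a fresh dataset of size n plus the new pair is
    simulated, the split-conformal region calibrated (penalty weight
    cross-validated on the training half when ``config.lam == "auto"``), and
    membership of the true new response recorded.  Returns per-point
    coverage plus the grand average in the last row.
    """
    config = config or FitConfig()
    p = scenario.p
    points = range(p) if n_points is None else range(min(n_points, p))

    rows = []
    hits_all = []
    for j in points:
        x_new = center_perturbed_point(p, j, delta)
        hits = []
        for rep in range(n_repeats):
            rng = replicate_rng(scenario.seed, j * 100003 + rep)
            x, B, y = simulate_dataset(scenario, rng)
            y_new = gen_responses(x_new[None, :], B, scenario.concentration, rng).values[0]
            cal = inference.split_conformal_calibrate(
                x, y, alpha,
                config=replace(config, seed=int(rng.integers(2**31))),
                seed=int(rng.integers(2**31)))
            hits.append(inference.split_conformal_contains(cal, x_new, y_new))
        cov = float(np.mean(hits))
        hits_all.extend(hits)
        rows.append({"point": j, "delta": delta, "coverage": cov, "n_repeats": n_repeats})
    rows.append({"point": "average", "delta": delta,
                 "coverage": float(np.mean(hits_all)), "n_repeats": n_repeats})
    return pd.DataFrame(rows)
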