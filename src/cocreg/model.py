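"""Model/Results interface for composition-on-composition regression.

Follows the statsmodels idiom: :class:`COCRegression` is constructed from
data (``endog`` = response compositions, ``exog`` = predictor compositions),
``fit()`` returns a :class:`COCResults` carrying the estimated coefficient
matrix, tuning information and diagnostics, and inference (resampling tests,
conformal prediction) hangs off the model and results objects.

Example
-------
>>> model = COCRegression(y_table, x_table)
>>> res = model.fit(lam="auto")
>>> res.params.shape
(q, p)
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import inference
from .estimation import FitConfig, FitResult, fit_coc_arrays, select_lambda
from .simplex import (CoefficientMatrix, CompositionTable, contrast_effect,
                      kld, pairwise_column_distances, predict)


def _as_table(data, role: str) -> CompositionTable:
    if isinstance(data, CompositionTable):
        return data
    if isinstance(data, pd.DataFrame):
        return CompositionTable.from_dataframe(data)
    return CompositionTable(np.asarray(data, float))


class COCRegression:
    """Composition-on-composition regression E(y|x) = B x.

    Parameters
    ----------
    endog
        Response compositions, n x q (array, DataFrame or CompositionTable).
    exog
        Predictor compositions, n x p.

    Both inputs are renormalized row-wise if slightly off the simplex.  The
    coefficient matrix B is a q x p rectangular Markov matrix (nonnegative,
    columns summing to one), so predictions are always valid compositions.
    """

    def __init__(self, endog, exog):
        self.endog_table = _as_table(endog, "endog")
        self.exog_table = _as_table(exog, "exog")
        if self.endog_table.n_samples != self.exog_table.n_samples:
            raise ValueError(
                f"endog has {self.endog_table.n_samples} rows but exog has "
                f"{self.exog_table.n_samples}; align the tables first")
        self.endog = self.endog_table.values
        self.exog = self.exog_table.values

    @classmethod
    def from_dataframes(cls, endog: pd.DataFrame, exog: pd.DataFrame) -> "COCRegression":
        """Build a model from two frames, inner-joining on their indexes."""
        from .io import align_tables
        y, x = align_tables(CompositionTable.from_dataframe(endog),
                            CompositionTable.from_dataframe(exog))
        return cls(y, x)

    @property
    def nobs(self) -> int:
        return self.endog.shape[0]

    @property
    def p(self) -> int:
        return self.exog.shape[1]

    @property
    def q(self) -> int:
        return self.endog.shape[1]

    def _config(self, lam, **kwargs) -> FitConfig:
        return FitConfig(lam=lam, **kwargs)

    def fit(self, method: str = "coc", lam="auto", **config_kwargs) -> "COCResults":
        """Estimate B.

        ``method="coc"`` minimizes the penalized KL criterion with weight
        ``lam`` (``"auto"`` selects it by cross-validation on held-out KLD);
        ``method="dr"`` is the unpenalized KLD-EM baseline.
        """
        if method == "dr":
            lam = 0.0
        elif method != "coc":
            raise ValueError(f"unknown method {method!r}")
        config = self._config(lam, **config_kwargs)
        cv_table = None
        lam_val = config.lam
        if lam_val == "auto":
            lam_val, cv_table = select_lambda(self.exog, self.endog, config)
        result = fit_coc_arrays(self.exog, self.endog, float(lam_val), config)
        result.cv_table = cv_table
        return COCResults(self, result, method=method, config=config)

    def select_lambda(self, **config_kwargs):
        """Cross-validated penalty-weight selection; returns (lam, cv_table)."""
        return select_lambda(self.exog, self.endog, self._config("auto", **config_kwargs))

    def bootstrap_test(self, n_boot: int = 200, seed: int = 0, lam="auto",
                       **config_kwargs) -> inference.TestResult:
        """Residual-bootstrap test of the no-association null H0: B = B0."""
        return inference.bootstrap_test(self.exog_table, self.endog_table,
                                        config=self._config(lam, **config_kwargs),
                                        n_boot=n_boot, seed=seed)

    def permutation_test(self, n_perm: int = 200, seed: int = 0,
                         statistic: str = "dr", lam="auto",
                         **config_kwargs) -> inference.TestResult:
        """Permutation test of H0: B = B0 (row-pairing broken)."""
        return inference.permutation_test(self.exog_table, self.endog_table,
                                          config=self._config(lam, **config_kwargs),
                                          n_perm=n_perm, seed=seed,
                                          statistic=statistic)

    def split_conformal(self, alpha: float = 0.05, seed: int = 0, lam="auto",
                        **config_kwargs) -> inference.ConformalCalibration:
        """Calibrate a split-conformal prediction region at level 1 - alpha."""
        return inference.split_conformal_calibrate(
            self.exog_table, self.endog_table, alpha,
            config=self._config(lam, **config_kwargs), seed=seed)

    def full_conformal_pvalue(self, x_new, y_cand, lam="auto",
                              **config_kwargs) -> float:
        """Full-conformal p-value for a candidate response at a new predictor."""
        return inference.full_conformal_pvalue(
            self.exog_table, self.endog_table, x_new, y_cand,
            config=self._config(lam, **config_kwargs))


class COCResults:
    """Fit results: estimated coefficients, diagnostics and predictions."""

    def __init__(self, model: COCRegression, result: FitResult, method: str,
                 config: FitConfig):
        self.model = model
        self._result = result
        self.method = method
        self.config = config
        self.coefficients = CoefficientMatrix(
            result.B_hat.entries,
            row_ids=list(model.endog_table.feature_ids),
            col_ids=list(model.exog_table.feature_ids),
        )

    # -- statsmodels-flavoured accessors ------------------------------------
    @property
    def params(self) -> np.ndarray:
        """Estimated q x p coefficient matrix."""
        return self.coefficients.entries

    @property
    def lambda_(self) -> float:
        return self._result.lambda_used

    @property
    def cv_table(self):
        return self._result.cv_table

    @property
    def objective_trace(self) -> np.ndarray:
        return self._result.objective_trace

    @property
    def n_iter(self) -> int:
        return self._result.n_iter

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def fittedvalues(self) -> np.ndarray:
        return predict(self.params, self.model.exog)

    def predict(self, exog=None) -> np.ndarray:
        """Predicted response compositions for new (or training) predictors."""
        x = self.model.exog if exog is None else exog
        x = x.values if isinstance(x, CompositionTable) else np.atleast_2d(np.asarray(x, float))
        return predict(self.params, x)

    def kld(self) -> float:
        """In-sample KL divergence between observed and fitted compositions."""
        return kld(self.model.endog, self.fittedvalues, zero_expected="inf")

    def contrast(self, j: int, j_prime: int, delta: float = 1.0) -> np.ndarray:
        """Mean-response effect of moving delta mass from predictor j' to j."""
        return contrast_effect(self.params, j, j_prime, delta)

    def column_distances(self) -> pd.DataFrame:
        """Pairwise squared distances between coefficient columns."""
        ids = self.coefficients.col_ids
        return pd.DataFrame(pairwise_column_distances(self.params),
                            index=ids, columns=ids)

    def top_contrast_pair(self) -> tuple[str, str]:
        """Predictor pair whose joint swap most moves the mean response."""
        d = pairwise_column_distances(self.params)
        j, jp = np.unravel_index(np.argmax(d), d.shape)
        ids = self.coefficients.col_ids
        return ids[int(j)], ids[int(jp)]

    def n_null_columns(self, tol: float = 1e-10) -> int:
        """Number of coefficient columns shrunk exactly to the barycenter."""
        dev = np.abs(self.params - 1.0 / self.model.q)
        return int(np.sum(dev.max(axis=0) <= tol))

    # -- inference ----------------------------------------------------------
    def bootstrap_test(self, n_boot: int = 200, seed: int = 0) -> inference.TestResult:
        """Bootstrap test of H0: B = B0 reusing this fit's penalty weight."""
        return inference.bootstrap_test(self.model.exog_table, self.model.endog_table,
                                        config=replace_lam(self.config, self.lambda_),
                                        n_boot=n_boot, seed=seed)

    def split_conformal(self, alpha: float = 0.05, seed: int = 0) -> inference.ConformalCalibration:
        """Split-conformal region reusing this fit's penalty weight."""
        return self.model.split_conformal(alpha=alpha, seed=seed, lam=self.lambda_)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        q, p = self.params.shape
        pen = float(np.sqrt(((self.params - 1.0 / q) ** 2).sum(axis=0)).sum())
        top = self.top_contrast_pair()
        lines = [
            "Composition-on-Composition Regression Results",
            "=" * 53,
            f"Method:               {self.method.upper()}",
            f"No. samples:          {self.model.nobs}",
            f"Predictor dim (p):    {p}",
            f"Response dim (q):     {q}",
            f"Penalty weight:       {self.lambda_:.6g}",
            f"Converged:            {self.converged} ({self.n_iter} iterations)",
            f"Final objective:      {self.objective_trace[-1]:.6g}",
            f"In-sample KLD:        {self.kld():.6g}",
            f"Group penalty ||B~||: {pen:.6g}",
            f"Barycenter columns:   {self.n_null_columns()} / {p}",
            f"Top contrast pair:    {top[0]} vs {top[1]}",
            "=" * 53,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<COCResults method={self.method} shape={self.params.shape} "
                f"lambda={self.lambda_:.4g} converged={self.converged}>")


def replace_lam(config: FitConfig, lam: float) -> FitConfig:
    from dataclasses import replace
    return replace(config, lam=lam)
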