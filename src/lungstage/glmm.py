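"""Mixed-effects logistic model for reading correctness.

The reader study produces one binary correctness outcome per reading
and TNM category (three rows per reading: T, N, M).  Readings are
cross-classified by case (image study) and reader, so correctness is
modelled as a logistic GLMM with fixed effects for reporting method
(reference: FTR) and category (reference: M) and crossed random
intercepts for case and reader:

    logit P(correct) = b0 + b_SR * [method=SR] + b_N * [cat=N]
                       + b_T * [cat=T] + u_case + v_reader,
    u_case ~ N(0, s_case^2),  v_reader ~ N(0, s_reader^2).

No method x category interaction is included: with near-ceiling M
correctness the interaction model is singular on realistic data.

Estimation is maximum likelihood under the Laplace approximation — the
random-intercept vector is profiled out by an inner Newton solve and
the marginal log-likelihood is maximized over fixed effects and log
standard deviations.  This is the same approximation lme4's ``glmer``
uses by default; no pre-installed Python package fits crossed-random-
effect binomial GLMMs by ML, so the Laplace machinery is implemented
here directly.  Wald standard errors come from the numerical Hessian
of the Laplace log-likelihood in the fixed effects at the optimum.

The usual entry points are statsmodels-style::

    model = ReaderCorrectnessModel.from_scored(scored)
    res = model.fit()
    print(res.summary())

or the convenience wrapper :func:`fit_correctness_glmm`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .evaluation import latent_icc, sidak_adjust

__all__ = ["ReaderCorrectnessModel", "ReaderCorrectnessResults", "fit_correctness_glmm"]

PARAM_NAMES = ("Intercept", "method[SR]", "category[N]", "category[T]")
_LOG_SD_LOWER = -6.0  # sd floor exp(-6) ~ 0.0025: the singular boundary
_LOG_SD_UPPER = 3.0


def _scored_to_long(scored: pd.DataFrame) -> pd.DataFrame:
    """Melt a scored reader-study table into one row per category outcome."""
    required = {"reader_id", "case_id", "method", "t_correct", "n_correct", "m_correct"}
    missing = required - set(scored.columns)
    if missing:
        raise ValueError(f"scored table is missing columns: {sorted(missing)}")
    frames = []
    for cat, col in (("T", "t_correct"), ("N", "n_correct"), ("M", "m_correct")):
        frames.append(
            pd.DataFrame(
                {
                    "reader_id": scored["reader_id"].astype(str),
                    "case_id": scored["case_id"].astype(str),
                    "method": scored["method"].astype(str),
                    "category": cat,
                    "correct": scored[col].astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class ReaderCorrectnessModel:
    """Logistic GLMM for per-category reading correctness.

    Parameters
    ----------
    data
        Long-format DataFrame with columns ``correct`` (0/1),
        ``method`` ("SR"/"FTR"), ``category`` ("T"/"N"/"M"),
        ``case_id`` and ``reader_id``.
    """

    def __init__(self, data: pd.DataFrame):
        for col in ("correct", "method", "category", "case_id", "reader_id"):
            if col not in data.columns:
                raise ValueError(f"missing column {col!r}")
        if set(data["method"].unique()) - {"SR", "FTR"}:
            raise ValueError("method must be SR or FTR")
        if set(data["category"].unique()) - {"T", "N", "M"}:
            raise ValueError("category must be T, N, or M")
        if data["reader_id"].nunique() < 2 or data["case_id"].nunique() < 2:
            raise ValueError("the GLMM needs >=2 readers and >=2 cases")
        self.data = data.reset_index(drop=True)
        self.endog = data["correct"].to_numpy(dtype=float)
        self.exog = np.column_stack(
            [
                np.ones(len(data)),
                (data["method"] == "SR").to_numpy(dtype=float),
                (data["category"] == "N").to_numpy(dtype=float),
                (data["category"] == "T").to_numpy(dtype=float),
            ]
        )
        self.case_codes, self.case_levels = pd.factorize(data["case_id"], sort=True)
        self.reader_codes, self.reader_levels = pd.factorize(data["reader_id"], sort=True)
        self.n_case = len(self.case_levels)
        self.n_reader = len(self.reader_levels)
        q = self.n_case + self.n_reader
        n = len(self.endog)
        Z = np.zeros((n, q))
        Z[np.arange(n), self.case_codes] = 1.0
        Z[np.arange(n), self.n_case + self.reader_codes] = 1.0
        self._Z = Z

    @classmethod
    def from_scored(cls, scored: pd.DataFrame) -> "ReaderCorrectnessModel":
        """Build the model from a :func:`lungstage.evaluation.score_records` table."""
        return cls(_scored_to_long(scored))

    # -- Laplace machinery -------------------------------------------------

    def _penalized_mode(self, beta: np.ndarray, dinv: np.ndarray, u0: np.ndarray):
        """Inner Newton solve for the random-effect mode (concave problem)."""
        X, Z, y = self.exog, self._Z, self.endog

        def pen(u: np.ndarray) -> float:
            eta = X @ beta + Z @ u
            return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (dinv * u * u).sum())

        u = u0.copy()
        H = None
        for _ in range(100):
            eta = X @ beta + Z @ u
            p = 1.0 / (1.0 + np.exp(-eta))
            grad = Z.T @ (y - p) - dinv * u
            W = p * (1.0 - p)
            H = (Z.T * W) @ Z + np.diag(dinv)
            step = np.linalg.solve(H, grad)
            if np.abs(grad).max() < 1e-9:
                break
            f0, t = pen(u), 1.0
            while t > 1e-6 and pen(u + t * step) < f0:
                t /= 2.0
            u = u + t * step
        return u, H

    def _laplace_loglike(self, params: np.ndarray, u_state: list) -> float:
        beta, log_sd = params[:4], params[4:]
        sd = np.exp(log_sd)
        dinv = np.concatenate(
            [np.full(self.n_case, sd[0] ** -2), np.full(self.n_reader, sd[1] ** -2)]
        )
        u, H = self._penalized_mode(beta, dinv, u_state[0])
        u_state[0] = u
        eta = self.exog @ beta + self._Z @ u
        lpen = float(self.endog @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (dinv * u * u).sum())
        log_det_d = -float(np.log(dinv).sum())
        _, log_det_h = np.linalg.slogdet(H)
        return lpen - 0.5 * log_det_d - 0.5 * log_det_h

    def fit(self, start_params: Optional[np.ndarray] = None) -> "ReaderCorrectnessResults":
        """Maximize the Laplace marginal likelihood; never raises on a
        difficult dataset — non-convergence and degeneracy are flags on
        the result."""
        degenerate = bool(self.endog.min() == self.endog.max())
        q = self.n_case + self.n_reader
        u_state = [np.zeros(q)]

        def nll(params: np.ndarray) -> float:
            try:
                return -self._laplace_loglike(params, u_state)
            except np.linalg.LinAlgError:
                return 1e12

        x0 = np.zeros(6) if start_params is None else np.asarray(start_params, dtype=float)
        bounds = [(None, None)] * 4 + [(_LOG_SD_LOWER, _LOG_SD_UPPER)] * 2
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        beta = res.x[:4]
        log_sd = res.x[4:]
        sds = np.exp(log_sd)
        singular = bool(np.any(log_sd <= _LOG_SD_LOWER + 1e-6))
        cov = self._beta_covariance(res.x, u_state)
        converged = bool(res.success) and np.all(np.isfinite(cov)) and not degenerate
        return ReaderCorrectnessResults(
            model=self,
            params=pd.Series(beta, index=list(PARAM_NAMES)),
            cov_params_=pd.DataFrame(cov, index=list(PARAM_NAMES), columns=list(PARAM_NAMES)),
            vc_sd={"case": float(sds[0]), "reader": float(sds[1])},
            loglike=-float(res.fun),
            converged=converged,
            degenerate=degenerate,
            singular=singular,
            n_obs=len(self.endog),
        )

    def _beta_covariance(self, x_opt: np.ndarray, u_state: list) -> np.ndarray:
        """Numerical Hessian of the Laplace log-likelihood in the fixed
        effects (variance parameters held at their estimates), inverted
        to a Wald covariance — mirroring the conditional Wald covariance
        mixed-model software reports."""
        k = 4
        h = 1e-4 * np.maximum(1.0, np.abs(x_opt[:k]))
        H = np.zeros((k, k))

        def f(beta: np.ndarray) -> float:
            p = x_opt.copy()
            p[:k] = beta
            return self._laplace_loglike(p, u_state)

        b0 = x_opt[:k].copy()
        f0 = f(b0)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k)
                ej = np.zeros(k)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    val = (f(b0 + ei) - 2 * f0 + f(b0 - ei)) / (h[i] * h[i])
                else:
                    val = (
                        f(b0 + ei + ej) - f(b0 + ei - ej) - f(b0 - ei + ej) + f(b0 - ei - ej)
                    ) / (4 * h[i] * h[j])
                H[i, j] = H[j, i] = val
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return np.full((k, k), np.nan)


@dataclass
class ReaderCorrectnessResults:
    """Fitted correctness GLMM: estimates, uncertainties, diagnostics.

    ``params`` are log-odds coefficients; ``odds_ratios`` exponentiates
    them.  ``vc`` holds random-intercept variances for case and reader,
    and ``icc`` their latent-scale intraclass correlations (logistic
    residual variance pi^2/3).
    """

    model: ReaderCorrectnessModel
    params: pd.Series
    cov_params_: pd.DataFrame
    vc_sd: Mapping[str, float]
    loglike: float
    converged: bool
    degenerate: bool
    singular: bool
    n_obs: int

    # -- fixed effects -----------------------------------------------------

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params_.to_numpy())), index=self.params.index)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.tvalues)), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return self.cov_params_

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald confidence bounds on the odds-ratio scale."""
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"lower": lo, "upper": hi})

    # -- random effects ----------------------------------------------------

    @property
    def vc(self) -> dict[str, float]:
        return {k: float(v) ** 2 for k, v in self.vc_sd.items()}

    @property
    def icc(self) -> dict[str, float]:
        return latent_icc(self.vc)

    # -- contrasts ---------------------------------------------------------

    def pairwise_category_contrasts(self) -> pd.DataFrame:
        """Pairwise category contrasts (M vs N, M vs T, N vs T) on the
        log-odds scale, exponentiated, with Sidak-adjusted (family of 3)
        confidence intervals and p-values."""
        if not self.converged:
            raise ValueError("pairwise contrasts require a converged fit")
        beta = self.params.to_numpy()
        cov = self.cov_params_.to_numpy()
        # coefficient order: Intercept, method, category N, category T
        contrasts = {
            "M vs N": np.array([0.0, 0.0, -1.0, 0.0]),
            "M vs T": np.array([0.0, 0.0, 0.0, -1.0]),
            "N vs T": np.array([0.0, 0.0, 1.0, -1.0]),
        }
        m = len(contrasts)
        alpha_sidak = 1.0 - (1.0 - 0.05) ** (1.0 / m)
        z_crit = stats.norm.ppf(1.0 - alpha_sidak / 2.0)
        rows = []
        for name, c in contrasts.items():
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            p_raw = float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else (0.0 if est else 1.0)
            rows.append(
                {
                    "contrast": name,
                    "odds_ratio": math.exp(est),
                    "ci_lower": math.exp(est - z_crit * se),
                    "ci_upper": math.exp(est + z_crit * se),
                    "p_sidak": sidak_adjust([p_raw], m=m)[0],
                }
            )
        return pd.DataFrame(rows).set_index("contrast")

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Reading-correctness logistic GLMM (Laplace ML)",
            f"  observations: {self.n_obs}   cases: {self.model.n_case}   readers: {self.model.n_reader}",
            f"  log-likelihood: {self.loglike:.3f}   converged: {self.converged}"
            + ("   [singular fit]" if self.singular else "")
            + ("   [degenerate outcome]" if self.degenerate else ""),
            "",
            f"  {'term':<14}{'OR':>9}{'2.5% CI':>10}{'97.5% CI':>10}{'p-value':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<14}{self.odds_ratios[name]:>9.3f}"
                f"{ci.loc[name, 'lower']:>10.3f}{ci.loc[name, 'upper']:>10.3f}"
                f"{self.pvalues[name]:>10.4f}"
            )
        lines.append("")
        lines.append(f"  {'grouping':<14}{'variance':>10}{'std.dev':>10}{'ICC':>8}")
        iccs = self.icc
        for g, var in self.vc.items():
            lines.append(f"  {g:<14}{var:>10.3f}{self.vc_sd[g]:>10.3f}{iccs[g]:>8.3f}")
        return "\n".join(lines)


def fit_correctness_glmm(scored: pd.DataFrame) -> ReaderCorrectnessResults:
    """Fit the correctness GLMM directly from a scored reader-study table."""
    return ReaderCorrectnessModel.from_scored(scored).fit()
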