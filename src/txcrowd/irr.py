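"""Individual-level count models for crowdfunding outcomes.

Outcomes (amount raised in whole dollars, success rate in percent, average
donation in dollars) are regressed on race/ethnicity (White baseline) and
campaign/state covariates with a log link.  The family is negative binomial
(NB2) or Poisson according to a Cameron-Trivedi overdispersion test; success
rate is fitted by Poisson pseudo-likelihood on the percent scale.  Standard
errors are sandwich estimates clustered on state (CR1 small-sample scaling),
and coefficients are reported as incidence rate ratios, IRR = exp(beta).

The module is organised statsmodels-style: :class:`IRRModel` is built from a
DataFrame and its :meth:`~IRRModel.fit` returns :class:`IRRResults` carrying
estimates, cluster-robust uncertainty, diagnostics and a ``summary()`` table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial

from .constants import RACE_BASELINE, RACE_LEVELS

#: default adjusted specification (race dummies are added automatically).
DEFAULT_COVARIATES = [
    "year_2016", "year_2017", "year_2018", "year_2019",
    "shares", "shares_sq", "organizer_not_beneficiary", "high_fraud",
    "solid_organ", "q4_wla", "q4_unins", "medicaid_expansion",
]

CAMPAIGN_COVARIATES = [
    "year_2016", "year_2017", "year_2018", "year_2019",
    "shares", "shares_sq", "organizer_not_beneficiary", "high_fraud", "solid_organ",
]

YEAR_COVARIATES = ["year_2016", "year_2017", "year_2018", "year_2019"]


class EstimationError(RuntimeError):
    """Model could not be estimated (rank deficiency, separation, no convergence)."""


@dataclass(frozen=True)
class OverdispersionTest:
    """Cameron-Trivedi auxiliary regression test of Var > Mean.

    Under NB2, ((y - mu)^2 - y)/mu = alpha * mu + noise; the one-sided t-test
    of alpha > 0 in a no-intercept OLS on the Poisson fitted means decides
    the family (negbin when p < threshold).
    """

    statistic: float
    pvalue: float
    alpha: float
    family: str
    threshold: float = 0.05


def overdispersion_test(y, X, threshold: float = 0.05) -> OverdispersionTest:
    """Run the overdispersion test and recommend a model family."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("outcome and design must be finite")
    if np.any(y < 0):
        raise ValueError("count outcome must be non-negative")
    if np.ptp(y) == 0:
        raise EstimationError("outcome is constant; dispersion is degenerate")
    mu = sm.GLM(y, X, family=sm.families.Poisson()).fit().mu
    z = ((y - mu) ** 2 - y) / mu
    aux = sm.OLS(z, mu).fit()
    t = float(aux.tvalues[0])
    p = float(stats.t.sf(t, df=aux.df_resid))
    alpha = max(float(aux.params[0]), 0.0)
    family = "negbin" if p < threshold else "poisson"
    return OverdispersionTest(statistic=t, pvalue=p, alpha=alpha, family=family,
                              threshold=threshold)


@dataclass
class ModelSpec:
    """Outcome, covariate list, cluster variable, and family choice."""

    outcome: str
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    cluster: str = "state"
    family: str = "auto"  # auto | poisson | negbin


def _race_dummies(race: pd.Series) -> pd.DataFrame:
    levels = [r for r in RACE_LEVELS if r != RACE_BASELINE]
    out = pd.DataFrame(index=race.index)
    for lvl in levels:
        out[f"race_{lvl}"] = (race == lvl).astype(float)
    return out


class IRRModel:
    """Log-link count regression of a crowdfunding outcome on race + covariates.

    ``data`` must contain the outcome column, a ``race`` column with the four
    categories, every covariate column, and the cluster column.  Rows are
    canonically ordered internally so estimates are exactly invariant to the
    input row order.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        required = [spec.outcome, "race", spec.cluster, *spec.covariates]
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns: {missing}")
        df = data[required].dropna(subset=[spec.outcome]).copy()
        # canonical row order: permutation-invariant, reproducible estimates
        df = df.sort_values(by=[spec.cluster, spec.outcome, *spec.covariates],
                            kind="mergesort").reset_index(drop=True)
        self.data = df
        exog = pd.concat([_race_dummies(df["race"]), df[spec.covariates].astype(float)], axis=1)
        exog.insert(0, "const", 1.0)
        self.exog = exog
        self.endog = df[spec.outcome].to_numpy(dtype=float)
        self.groups = df[spec.cluster].to_numpy()
        self._check_design()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        covariates: list[str] | None = None,
        cluster: str = "state",
        family: str = "auto",
    ) -> "IRRModel":
        spec = ModelSpec(outcome=outcome,
                         covariates=list(covariates) if covariates is not None else list(DEFAULT_COVARIATES),
                         cluster=cluster, family=family)
        return cls(data, spec)

    def _check_design(self) -> None:
        if len(np.unique(self.groups)) < 2:
            raise EstimationError("need at least 2 clusters for cluster-robust errors")
        X = self.exog.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            offenders = [
                c for c in self.exog.columns
                if c != "const" and np.ptp(self.exog[c].to_numpy()) == 0
            ]
            raise EstimationError(
                f"design is rank deficient (rank {rank} < {X.shape[1]}); "
                f"constant columns: {offenders or 'collinear set not constant'}"
            )

    def fit(self, threshold: float = 0.05, maxiter: int = 200,
            alpha: float | None = None) -> "IRRResults":
        """Estimate the model; family resolved by the dispersion test if auto.

        ``alpha`` fixes the NB2 dispersion instead of estimating it by MLE
        (e.g. alpha -> 0 reproduces the Poisson fit).
        """
        y = self.endog
        X = self.exog
        disp = None
        family = self.spec.family
        if family == "auto":
            disp = overdispersion_test(np.round(y), X.to_numpy(), threshold=threshold)
            family = disp.family

        cov_kwds = {"groups": self.groups}
        if family == "poisson":
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(
                cov_type="cluster", cov_kwds=cov_kwds
            )
            alpha = None
            converged = res.converged
        elif family == "negbin" and alpha is not None:
            res = sm.GLM(np.round(y), X,
                         family=sm.families.NegativeBinomial(alpha=alpha)).fit(
                cov_type="cluster", cov_kwds=cov_kwds
            )
            converged = res.converged
        elif family == "negbin":
            y_int = np.round(y)
            if disp is None:
                disp = overdispersion_test(y_int, X.to_numpy(), threshold=threshold)
            start_pois = sm.GLM(y_int, X, family=sm.families.Poisson()).fit().params
            start = np.append(np.asarray(start_pois), max(disp.alpha, 0.01))
            model = NegativeBinomial(y_int, X, loglike_method="nb2")
            try:
                res = model.fit(start_params=start, method="newton", maxiter=maxiter,
                                disp=0, cov_type="cluster", cov_kwds=cov_kwds)
            except Exception:
                res = model.fit(start_params=start, method="bfgs", maxiter=5 * maxiter,
                                disp=0, cov_type="cluster", cov_kwds=cov_kwds)
            converged = bool(res.mle_retvals.get("converged", True))
            # optimizers can flag precision loss at a stationary point; accept
            # the fit when the score is numerically zero
            if not converged:
                grad = np.asarray(
                    res.mle_retvals.get("score", res.mle_retvals.get("gopt", [np.inf]))
                )
                if np.max(np.abs(grad)) < 1e-3:
                    converged = True
                else:
                    raise EstimationError(
                        f"negative binomial fit did not converge: {res.mle_retvals}"
                    )
            alpha = float(np.asarray(res.params)[-1])
        else:
            raise ValueError(f"unknown family {family!r}")
        return IRRResults(model=self, _res=res, family=family, alpha=alpha,
                          dispersion=disp, converged=converged)


class IRRResults:
    """Fitted IRR model: coefficients, cluster-robust CIs, diagnostics."""

    def __init__(self, model: IRRModel, _res, family: str, alpha: float | None,
                 dispersion: OverdispersionTest | None, converged: bool):
        self.model = model
        self._res = _res
        self.family = family
        self.alpha = alpha
        self.dispersion = dispersion
        self.converged = converged
        self.term_names = list(model.exog.columns)
        k = len(self.term_names)
        params = np.asarray(_res.params, dtype=float)[:k]
        bse = np.asarray(_res.bse, dtype=float)[:k]
        ci = np.asarray(_res.conf_int(), dtype=float)[:k]
        pvals = np.asarray(_res.pvalues, dtype=float)[:k]
        self.params = pd.Series(params, index=self.term_names)
        self.bse = pd.Series(bse, index=self.term_names)
        self.pvalues = pd.Series(pvals, index=self.term_names)
        self._ci = pd.DataFrame(ci, index=self.term_names, columns=["low", "high"])
        self.nobs = int(len(model.endog))
        self.n_clusters = int(len(np.unique(model.groups)))

    @property
    def irr(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self) -> pd.DataFrame:
        """95% CI on the log (coefficient) scale."""
        return self._ci.copy()

    def conf_int_irr(self) -> pd.DataFrame:
        """95% CI on the IRR scale: exactly exp of the log-scale CI."""
        return np.exp(self._ci)

    def to_frame(self) -> pd.DataFrame:
        ci = self._ci
        irr_ci = self.conf_int_irr()
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.params.to_numpy(),
                "irr": self.irr.to_numpy(),
                "stderr": self.bse.to_numpy(),
                "ci_low": ci["low"].to_numpy(),
                "ci_high": ci["high"].to_numpy(),
                "irr_ci_low": irr_ci["low"].to_numpy(),
                "irr_ci_high": irr_ci["high"].to_numpy(),
                "pvalue": self.pvalues.to_numpy(),
                "family": self.family,
                "n": self.nobs,
                "n_clusters": self.n_clusters,
            }
        )

    def summary(self) -> str:
        lines = [
            f"IRR model: {self.model.spec.outcome} ~ race + {len(self.model.spec.covariates)} covariates",
            f"family: {self.family}"
            + (f" (alpha = {self.alpha:.3f})" if self.alpha is not None else ""),
            f"n = {self.nobs}, clusters({self.model.spec.cluster}) = {self.n_clusters}",
        ]
        if self.dispersion is not None:
            lines.append(
                f"overdispersion: t = {self.dispersion.statistic:.2f}, "
                f"p = {self.dispersion.pvalue:.3g} -> {self.dispersion.family}"
            )
        lines.append(f"{'term':<28}{'IRR':>8}{'95% CI':>20}{'p':>10}")
        irr_ci = self.conf_int_irr()
        for term in self.term_names:
            lines.append(
                f"{term:<28}{self.irr[term]:>8.3f}"
                f"{irr_ci.loc[term, 'low']:>9.3f} -{irr_ci.loc[term, 'high']:>9.3f}"
                f"{self.pvalues[term]:>10.3g}"
            )
        return "\n".join(lines)


#: spec-facing alias: a fitted count model is the "IRRFit" of the pipeline.
IRRFit = IRRResults


def fit_model(spec: ModelSpec, data: pd.DataFrame, threshold: float = 0.05) -> IRRResults:
    """Functional wrapper: build :class:`IRRModel` and fit it."""
    return IRRModel(data, spec).fit(threshold=threshold)


def quartile_flags(panel: pd.DataFrame, variable: str, race_col: str = "race") -> pd.DataFrame:
    """Per-(state, race) fourth-quartile indicator for a panel variable.

    The indicator is 1 iff the state's race-specific value is >= the 75th
    percentile (inclusive linear interpolation) across states within that
    race group.  Requires at least 4 states per group.
    """
    rows = []
    for race, grp in panel.groupby(race_col, sort=True):
        vals = grp.groupby("state")[variable].mean()
        if len(vals) < 4:
            raise ValueError(f"quartile_flags needs >= 4 states per race (got {len(vals)} for {race})")
        q3 = np.percentile(vals.to_numpy(dtype=float), 75)
        for state, v in vals.items():
            rows.append({"state": state, "race": race, variable: float(v), "q4": bool(v >= q3)})
    return pd.DataFrame(rows)


SENSITIVITY_RUNS = [
    "base", "solid_only", "exclude_2019", "concordant_only", "high_certainty",
    "race_year_only", "race_year_campaign",
]


def run_sensitivities(
    data: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    cluster: str = "state",
    family: str = "auto",
    min_n: int = 50,
) -> pd.DataFrame:
    """Base fit plus the four subset sensitivities and two reduced specifications.

    Subsets: solid-organ campaigns only; excluding 2019; weighted/max
    concordant classifications only; certainty score above the threshold.
    Reduced specifications: race + year; race + year + campaign
    characteristics.  ``data`` must carry ``creation_year``, ``concordant``
    and ``passes_threshold`` columns for the subset rules.  Runs whose subset
    is too small are reported as not estimable; the others proceed.
    """
    covs = list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    subsets = {
        "base": (data, covs),
        "solid_only": (data[data["solid_organ"] == 1], [c for c in covs if c != "solid_organ"]),
        "exclude_2019": (data[data["creation_year"] != 2019],
                         [c for c in covs if c != "year_2019"]),
        "concordant_only": (data[data["concordant"].astype(bool)], covs),
        "high_certainty": (data[data["passes_threshold"].astype(bool)], covs),
        "race_year_only": (data, [c for c in covs if c in YEAR_COVARIATES]),
        "race_year_campaign": (data, [c for c in covs if c in CAMPAIGN_COVARIATES]),
    }
    frames = []
    for run, (sub, run_covs) in subsets.items():
        if len(sub) < min_n:
            frames.append(pd.DataFrame([{"run": run, "term": None, "estimable": False,
                                         "n": len(sub)}]))
            continue
        try:
            res = IRRModel.from_dataframe(sub, outcome, run_covs, cluster, family).fit()
        except EstimationError as err:
            frames.append(pd.DataFrame([{"run": run, "term": None, "estimable": False,
                                         "n": len(sub), "error": str(err)}]))
            continue
        tab = res.to_frame()
        tab.insert(0, "run", run)
        tab["estimable"] = True
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
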