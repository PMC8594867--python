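"""Explanatory statistical layer for the benchmark observations.

The unit of analysis is one protein x fold x strategy observation.  Two
model families describe the results:

- the predicted active ratio r_pred is modeled, per strategy, with a
  quasibinomial logistic regression on r_training, r_test (numeric in
  [0, 1]), n_int, n_seq (numeric) and k_fold (categorical); each
  observation is weighted by its per-protein test count (the ratio's
  denominator) and a free Pearson-X2 dispersion absorbs overdispersion;
- each performance metric (raw, baseline, or baseline-adjusted) is modeled
  with a linear regression on strategy (categorical, 4 levels), n_int,
  n_seq and k_fold.

Reference categories are ``no_resampling`` for strategy and 0 for fold.
The strategy term is tested with a type-3 (marginal) ANOVA — with main
effects only this is the joint Wald F-test of the strategy coefficients
given all other terms, identical under any contrast coding.  A metric is
called *imbalance-sensitive* when the strategy term is significant in the
random baseline's metric model.  Pairwise strategy contrasts are adjusted
with Tukey's studentized-range method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from pcmbench.strategies import StrategyName

STRATEGY_ORDER = [s.value for s in StrategyName]
REFERENCE_STRATEGY = StrategyName.no_resampling.value
REFERENCE_FOLD = 0


@dataclass
class ExplanatoryFit:
    """A fitted explanatory model plus the metadata needed downstream."""

    formula: str
    result: object  # statsmodels results
    kind: str  # "quasibinomial" | "ols"
    dispersion: float | None = None
    strategy_levels: list[str] = field(default_factory=list)
    n_obs: int = 0
    separation_flagged: bool = False

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def bse(self) -> pd.Series:
        return self.result.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.result.pvalues

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.result.conf_int(alpha)

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "p": self.pvalues,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )


_EQ1_COLUMNS = ["r_pred", "r_training", "r_test", "n_int", "n_seq", "k_fold", "n_test"]


def fit_predicted_ratio_model(
    observations: pd.DataFrame, strategy: StrategyName | str
) -> ExplanatoryFit:
    """Quasibinomial logistic model of the predicted active ratio.

    Not defined for ``resampling_after_clustering``, whose balance (hence
    predicted ratio target) is enforced by construction.
    """
    strategy = StrategyName(strategy)
    if strategy is StrategyName.resampling_after_clustering:
        raise ValueError(
            "the predicted-ratio model is not fitted for "
            "resampling_after_clustering: its data balance is enforced"
        )
    data = observations[observations["strategy"] == strategy.value]
    if data.empty:
        raise ValueError(f"no observations for strategy {strategy.value}")
    data = data.dropna(subset=_EQ1_COLUMNS).copy()
    formula = (
        "r_pred ~ r_training + r_test + n_int + n_seq "
        f"+ C(k_fold, Treatment({REFERENCE_FOLD}))"
    )
    model = smf.glm(
        formula,
        data=data,
        family=sm.families.Binomial(),
        var_weights=np.asarray(data["n_test"], dtype=float),
    )
    try:
        result = model.fit(scale="X2")
    except ValueError:
        # zero Pearson residual variance (e.g. constant response): the
        # dispersion is not estimable, fall back to the binomial scale
        result = model.fit()
    separation = bool(np.any(np.abs(result.params) > 15))
    if separation:
        import logging

        logging.getLogger(__name__).warning(
            "possible separation in predicted-ratio model: |coef| > 15"
        )
    return ExplanatoryFit(
        formula=formula,
        result=result,
        kind="quasibinomial",
        dispersion=float(result.scale),
        n_obs=len(data),
        separation_flagged=separation,
    )


def fit_metric_model(observations: pd.DataFrame, response: str) -> ExplanatoryFit:
    """Linear model of a (possibly baseline-adjusted) metric.

    ``response`` names a column of the observation table, e.g. ``mcc``,
    ``baseline_auroc`` or ``adjusted_macro_f1``.  Undefined (NaN) responses
    are excluded; the response must remain observed for >= 2 strategies.
    """
    if response not in observations:
        raise ValueError(f"unknown response column {response!r}")
    data = observations.dropna(subset=[response, "n_int", "n_seq"]).copy()
    if data.empty:
        raise ValueError(f"response {response!r} is undefined everywhere")
    levels = [s for s in STRATEGY_ORDER if s in set(data["strategy"])]
    if len(levels) < 2:
        raise ValueError(f"response {response!r} observed for < 2 strategies")
    formula = (
        f"Q('{response}') ~ C(strategy, Treatment('{REFERENCE_STRATEGY}')) "
        f"+ n_int + n_seq + C(k_fold, Treatment({REFERENCE_FOLD}))"
    )
    result = smf.ols(formula, data=data).fit()
    return ExplanatoryFit(
        formula=formula,
        result=result,
        kind="ols",
        strategy_levels=levels,
        n_obs=len(data),
    )


def _term_names(fit: ExplanatoryFit, term: str) -> list[str]:
    return [name for name in fit.params.index if name.startswith(f"C({term}")]


def anova_strategy(fit: ExplanatoryFit) -> float:
    """Type-3 p-value for the strategy term (joint test given all others)."""
    names = _term_names(fit, "strategy")
    if not names:
        raise ValueError("fit contains no strategy term")
    index = list(fit.params.index)
    R = np.zeros((len(names), len(index)))
    for row, name in enumerate(names):
        R[row, index.index(name)] = 1.0
    test = fit.result.f_test(R)
    return float(test.pvalue)


def classify_metric_sensitivity(
    baseline_fits: dict[str, ExplanatoryFit], alpha: float = 0.05
) -> dict[str, str]:
    """Label each metric by whether the baseline shifts across strategies.

    ``imbalance_sensitive`` iff the strategy term is significant (at
    ``alpha``) in the random baseline's metric model; such metrics are then
    analysed on the baseline-adjusted scale.
    """
    out = {}
    for metric, fit in baseline_fits.items():
        p = anova_strategy(fit)
        out[metric] = (
            "imbalance_sensitive" if p < alpha else "imbalance_insensitive"
        )
    return out


def tukey_pairwise(fit: ExplanatoryFit) -> pd.DataFrame:
    """All pairwise strategy contrasts with Tukey-adjusted p-values.

    Contrasts are differences of the strategy coefficients (reference
    level = 0); the familywise adjustment uses the studentized-range
    distribution with k = number of levels and the fit's residual degrees
    of freedom, as in standard post-hoc pairwise-comparison machinery.
    """
    names = _term_names(fit, "strategy")
    if not names:
        raise ValueError("fit contains no strategy term")
    levels = list(fit.strategy_levels) or STRATEGY_ORDER
    if len(levels) < 2:
        raise ValueError("need >= 2 strategy levels")
    coef_of = {REFERENCE_STRATEGY: None}
    for name in names:
        level = name.split("T.")[-1].rstrip("]")
        coef_of[level] = name
    params = fit.params
    cov = fit.result.cov_params()
    df_resid = float(fit.result.df_resid)
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            vec = pd.Series(0.0, index=params.index)
            if coef_of.get(a) is not None:
                vec[coef_of[a]] = 1.0
            if coef_of.get(b) is not None:
                vec[coef_of[b]] -= 1.0
            est = float(vec @ params)
            se = float(np.sqrt(vec @ cov @ vec))
            t = est / se if se > 0 else np.nan
            p_raw = 2 * stats.t.sf(abs(t), df_resid) if se > 0 else np.nan
            p_adj = (
                float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df_resid))
                if se > 0
                else np.nan
            )
            rows.append(
                {
                    "contrast": f"{a} - {b}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_raw": p_raw,
                    "p_tukey": min(p_adj, 1.0) if np.isfinite(p_adj) else p_adj,
                }
            )
    return pd.DataFrame(rows)


def pearson_ci(x, y, alpha: float = 0.05) -> dict[str, float]:
    """Pearson correlation with a Fisher-z confidence interval and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(1 - alpha)
    return {
        "r": float(res.statistic),
        "p": float(res.pvalue),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "n": int(len(x)),
    }


def expected_performance(fit: ExplanatoryFit) -> dict[str, float]:
    """Model-expected response per strategy at covariate means, fold-averaged.

    Because the design is additive, the shared covariate/fold contribution
    cancels in comparisons; it is included so the values are interpretable
    on the response scale.
    """
    params = fit.params
    names = _term_names(fit, "strategy")
    coef_of = {REFERENCE_STRATEGY: 0.0}
    for name in names:
        level = name.split("T.")[-1].rstrip("]")
        coef_of[level] = float(params[name])
    base = float(params.get("Intercept", 0.0))
    data = fit.result.model.data.frame
    for cov_name in ("n_int", "n_seq"):
        if cov_name in params.index:
            base += float(params[cov_name]) * float(data[cov_name].mean())
    fold_names = _term_names(fit, "k_fold")
    n_folds = len(fold_names) + 1
    base += sum(float(params[n]) for n in fold_names) / n_folds
    return {level: base + c for level, c in coef_of.items()}


def rank_strategies(
    fits: dict[str, ExplanatoryFit], higher_is_better: bool = True
) -> pd.DataFrame:
    """Per-metric strategy ranking, 1 (best) to 4 (worst).

    Strategies are ordered by model-expected performance; exact ties break
    by strategy enumeration order and are flagged.
    """
    rows = []
    for metric, fit in fits.items():
        expect = expected_performance(fit)
        levels = [s for s in STRATEGY_ORDER if s in expect]
        order = sorted(
            levels,
            key=lambda s: (-expect[s] if higher_is_better else expect[s],
                           STRATEGY_ORDER.index(s)),
        )
        values = [expect[s] for s in levels]
        tied = len(set(np.round(values, 12))) < len(values)
        for rank, s in enumerate(order, start=1):
            rows.append(
                {
                    "metric": metric,
                    "strategy": s,
                    "rank": rank,
                    "expected": expect[s],
                    "tied": tied,
                }
            )
    return pd.DataFrame(rows)
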