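"""Ordinary-least-squares regressions relating total BAT glucose uptake to
thermography and MRI measurements.

The study design is seven simple regressions (one per IRT/MRI measurement)
and four pre-specified multiple regressions, each reporting coefficients,
intercept, adjusted R-squared, two-sided coefficient p-values and
significance (p < 0.05) / trend (p < 0.10) flags.  An all-pairs table of
simple regressions between every pair of continuous variables is also
provided.  p-values are unadjusted for multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "fit_ols",
    "run_study_regressions",
    "all_pairs_regressions",
    "RESPONSE",
    "SIMPLE_PREDICTORS",
    "MULTIPLE_PREDICTOR_SETS",
    "P_SIGNIFICANT",
    "P_TREND",
]

RESPONSE = "total_bat_gur_umol_min"

SIMPLE_PREDICTORS: tuple[str, ...] = (
    "scf_neutral_c",
    "scf_cold_c",
    "pnr_neutral_c",
    "pnr_cold_c",
    "bat_ff2e_pct",
    "bat_ff15e_pct",
    "bat_r2s_s1",
)

MULTIPLE_PREDICTOR_SETS: tuple[tuple[str, ...], ...] = (
    ("scf_neutral_c", "pnr_neutral_c"),
    ("scf_neutral_c", "scf_cold_c"),
    ("scf_cold_c", "pnr_cold_c"),
    ("bat_ff15e_pct", "bat_r2s_s1"),
)

P_SIGNIFICANT = 0.05
P_TREND = 0.10


@dataclass
class RegressionResult:
    """One fitted OLS model."""

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    adj_r2: float
    r2: float
    pvalues: dict[str, float]
    n: int
    significant: dict[str, bool] = field(default_factory=dict)
    trend: dict[str, bool] = field(default_factory=dict)
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        model = "+".join(self.predictors)
        rows = []
        for p in self.predictors:
            rows.append(
                {
                    "model": model,
                    "predictor": p,
                    "beta": self.coefficients[p],
                    "intercept": self.intercept,
                    "adj_r2": self.adj_r2,
                    "p_value": self.pvalues[p],
                    "significant": self.significant[p],
                    "trend": self.trend[p],
                    "n": self.n,
                }
            )
        return rows


def fit_ols(table: pd.DataFrame, response: str, predictors: list[str] | tuple[str, ...]) -> RegressionResult:
    """Ordinary least squares of ``response`` on ``predictors`` with intercept.

    Adjusted R2 is ``1 - (1-R2)(n-1)/(n-p-1)``; p-values are two-sided
    t-tests on the coefficients.
    """
    predictors = tuple(predictors)
    missing = [c for c in (response, *predictors) if c not in table.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    n = len(table)
    if n <= len(predictors) + 1:
        raise ValueError(
            f"need more than {len(predictors) + 1} subjects for {len(predictors)} "
            f"predictor(s); got {n}"
        )
    y = table[response].to_numpy(dtype=float)
    x = table[list(predictors)].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in design or response")
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(f"rank-deficient design for predictors {predictors}")
    fit = sm.OLS(y, design).fit()
    coefs = dict(zip(predictors, fit.params[1:]))
    pvals = dict(zip(predictors, fit.pvalues[1:]))
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        response=response,
        predictors=predictors,
        coefficients=coefs,
        intercept=float(fit.params[0]),
        adj_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        pvalues=pvals,
        n=n,
        significant={p: pvals[p] < P_SIGNIFICANT for p in predictors},
        trend={p: pvals[p] < P_TREND for p in predictors},
        conf_int={p: (float(ci[i + 1, 0]), float(ci[i + 1, 1])) for i, p in enumerate(predictors)},
    )


def run_study_regressions(table: pd.DataFrame, response: str = RESPONSE) -> pd.DataFrame:
    """Fit the pre-specified 7 simple + 4 multiple regressions.

    Returns a long-format table (one row per predictor per model) with beta,
    intercept, adjusted R2, p-value and significance/trend flags.
    """
    missing = [c for c in SIMPLE_PREDICTORS if c not in table.columns]
    if missing:
        raise KeyError(f"cohort table lacks predictor columns: {missing}")
    rows: list[dict] = []
    for pred in SIMPLE_PREDICTORS:
        rows.extend(fit_ols(table, response, (pred,)).to_rows())
    for preds in MULTIPLE_PREDICTOR_SETS:
        rows.extend(fit_ols(table, response, preds).to_rows())
    out = pd.DataFrame(rows)
    out.insert(0, "kind", np.where(out["model"].str.contains(r"\+"), "multiple", "simple"))
    return out


def all_pairs_regressions(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Simple regressions of every ordered pair of continuous columns.

    R2 is symmetric in the pair; the slopes depend on direction and satisfy
    ``slope(y~x) * slope(x~y) = R2``.
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c != "subject" and pd.api.types.is_numeric_dtype(table[c])
        ]
    if len(columns) < 2:
        raise ValueError("need at least two continuous columns")
    rows = []
    for resp in columns:
        for pred in columns:
            if resp == pred:
                continue
            res = fit_ols(table, resp, (pred,))
            rows.append(
                {
                    "response": resp,
                    "predictor": pred,
                    "beta": res.coefficients[pred],
                    "intercept": res.intercept,
                    "r2": res.r2,
                    "adj_r2": res.adj_r2,
                    "p_value": res.pvalues[pred],
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
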