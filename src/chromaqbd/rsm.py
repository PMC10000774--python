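"""Response-surface models for critical method attributes (CMAs).

Fits polynomial models in coded factor units to designed-experiment data
and produces the classical ANOVA decomposition: per-term sums of squares,
residual, lack-of-fit vs pure error (from replicate groups), an optional
center-point curvature row, and the usual fit statistics (R^2, adjusted
R^2, CV%, adequate precision).

On a two-level design pure quadratic terms are not estimable; the default
term set is the intercept, all main effects and all two-factor
interactions, with the three-factor interaction optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .designs import DesignMatrix, code_levels

__all__ = [
    "CMA_NAMES",
    "ResponseTable",
    "FittedModel",
    "default_terms",
    "fit_response_model",
    "anova_table",
    "fit_statistics",
    "predict",
]

CMA_NAMES = (
    "RS1",
    "RS2",
    "RT_CMN",
    "RT_DMCMN",
    "RT_BDMCMN",
    "TP_CMN",
    "TP_DMCMN",
    "TP_BDMCMN",
)


@dataclass
class ResponseTable:
    """A design joined to its measured CMA responses.

    ``responses`` has one column per CMA, one row per design run, aligned
    with ``design.coded``.
    """

    design: DesignMatrix
    responses: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.responses) != self.design.n_runs:
            raise ValueError(
                f"responses have {len(self.responses)} rows but the design "
                f"has {self.design.n_runs} runs"
            )

    @property
    def cma_names(self) -> list[str]:
        return list(self.responses.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.design.to_frame(), self.responses.reset_index(drop=True)], axis=1
        )


@dataclass
class FittedModel:
    """A least-squares polynomial fit for one CMA, in coded units."""

    cma: str
    terms: list[str]
    coefficients: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    mse: float
    df_resid: int
    factors: list = field(repr=False, default_factory=list)
    anova: pd.DataFrame | None = field(repr=False, default=None)
    stats: dict | None = None
    lack_of_fit_available: bool = True

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


def default_terms(factor_names: list[str], three_way: bool = False) -> list[str]:
    """Main effects plus all two-factor interactions (optionally the 3-way)."""
    terms = list(factor_names)
    k = len(factor_names)
    for i in range(k):
        for j in range(i + 1, k):
            terms.append(f"{factor_names[i]}:{factor_names[j]}")
    if three_way and k >= 3:
        from itertools import combinations

        for combo in combinations(factor_names, 3):
            terms.append(":".join(combo))
    return terms


def _term_column(coded: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    unknown = [p for p in parts if p not in coded.columns]
    if unknown:
        raise KeyError(f"unknown factor name(s) in term {term!r}: {unknown}")
    col = np.ones(len(coded))
    for p in parts:
        col = col * coded[p].to_numpy()
    return col


def _model_matrix(design: DesignMatrix, terms: list[str]) -> pd.DataFrame:
    coded = pd.DataFrame(design.coded, columns=design.factor_names)
    X = pd.DataFrame({"Intercept": np.ones(design.n_runs)})
    for t in terms:
        X[t] = _term_column(coded, t)
    return X


def fit_response_model(
    data: ResponseTable,
    cma: str,
    term_spec: list[str] | None = None,
) -> FittedModel:
    """Fit a polynomial model (in coded units) for one CMA.

    Raises ``ValueError`` naming the unestimable terms if the requested
    model matrix is rank deficient (e.g. pure quadratic terms on a
    two-level design).
    """
    if cma not in data.responses.columns:
        raise KeyError(f"no response column named {cma!r}")
    terms = (
        list(term_spec)
        if term_spec is not None
        else default_terms(data.design.factor_names)
    )
    X = _model_matrix(data.design, terms)
    y = data.responses[cma].to_numpy(dtype=float)

    # Incremental rank check so the error can name the offending terms.
    bad: list[str] = []
    rank = 0
    kept = np.empty((len(X), 0))
    for name in X.columns:
        cand = np.column_stack([kept, X[name].to_numpy()])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            bad.append(name)
    if bad:
        raise ValueError(
            f"model for {cma!r} is rank deficient; unestimable terms: {bad} "
            "(pure quadratic terms are aliased with the intercept on a "
            "two-level design)"
        )

    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    return FittedModel(
        cma=cma,
        terms=terms,
        coefficients=res.params,
        se=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        conf_int=ci,
        mse=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        df_resid=int(res.df_resid),
        factors=list(data.design.factors),
    )


def _replicate_groups(design: DesignMatrix) -> np.ndarray:
    """Integer labels grouping rows with identical coded settings."""
    _, labels = np.unique(design.coded, axis=0, return_inverse=True)
    return labels


def anova_table(model: FittedModel, data: ResponseTable) -> FittedModel:
    """Populate ``model.anova`` with the full decomposition.

    Sequential (Type I) per-term sums of squares via QR; on orthogonal
    coded designs these coincide with partial SS.  When replicate groups
    exist the residual is split into lack-of-fit and pure error; when
    center points exist a single-df curvature contrast (factorial mean vs
    center mean) is reported as an additional informational row (it is a
    component of lack-of-fit, not added to the decomposition sum).
    """
    X = _model_matrix(data.design, model.terms)
    y = data.responses[model.cma].to_numpy(dtype=float)
    n = len(y)
    p = X.shape[1]

    Q, R = np.linalg.qr(X.to_numpy())
    effects = Q.T @ y
    # effects[0] captures the intercept/grand mean; term SS are single-df.
    term_ss = effects[1:] ** 2
    fitted = X.to_numpy() @ np.linalg.solve(R, effects)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_resid = float(np.sum((y - fitted) ** 2))
    ss_model = float(np.sum(term_ss))
    df_model = p - 1
    df_resid = n - p
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    rows: list[dict] = []

    def add(source, ss, df, against_ms=None, against_df=None):
        ms = ss / df if df > 0 else np.nan
        F = p_ = np.nan
        if against_ms is not None and df > 0 and against_df and against_ms > 0:
            F = ms / against_ms
            p_ = float(stats.f.sf(F, df, against_df))
        rows.append(
            {"source": source, "SS": ss, "df": df, "MS": ms, "F": F, "p": p_}
        )

    add("model", ss_model, df_model, ms_resid, df_resid)
    for name, ss in zip(model.terms, term_ss):
        add(name, float(ss), 1, ms_resid, df_resid)

    # Residual split: pure error from replicate groups.
    labels = _replicate_groups(data.design)
    ss_pe = 0.0
    df_pe = 0
    for g in np.unique(labels):
        yg = y[labels == g]
        if len(yg) > 1:
            ss_pe += float(np.sum((yg - yg.mean()) ** 2))
            df_pe += len(yg) - 1
    has_reps = df_pe > 0

    add("residual", ss_resid, df_resid)
    lof_available = has_reps and df_resid - df_pe > 0
    if lof_available:
        ss_lof = ss_resid - ss_pe
        df_lof = df_resid - df_pe
        ms_pe = ss_pe / df_pe
        add("lack-of-fit", max(ss_lof, 0.0), df_lof, ms_pe if ms_pe > 0 else None, df_pe)
        add("pure error", ss_pe, df_pe)

    # Curvature: factorial corners vs center points, one df.
    is_c = data.design.is_center
    n_c = int(is_c.sum())
    n_f = n - n_c
    if 0 < n_c < n:
        diff = y[~is_c].mean() - y[is_c].mean()
        ss_curv = (n_f * n_c / (n_f + n_c)) * diff**2
        if has_reps:
            add("curvature", float(ss_curv), 1, ss_pe / df_pe if ss_pe > 0 else None, df_pe)
        else:
            add("curvature", float(ss_curv), 1, ms_resid, df_resid)

    add("total", ss_total, n - 1)

    model.anova = pd.DataFrame(rows)
    model.lack_of_fit_available = lof_available
    return model


def fit_statistics(model: FittedModel, data: ResponseTable) -> dict:
    """R^2, adjusted R^2, CV%, adequate precision and MSE.

    Adequate precision is the Design-Expert-style signal-to-noise ratio
    (max(yhat) - min(yhat)) / sqrt(p * MSE / n) over the design points.
    """
    if model.anova is None:
        anova_table(model, data)
    an = model.anova.set_index("source")
    ss_total = float(an.loc["total", "SS"])
    ss_resid = float(an.loc["residual", "SS"])
    df_resid = int(an.loc["residual", "df"])
    df_total = int(an.loc["total", "df"])
    n = data.design.n_runs
    p = model.n_params

    y = data.responses[model.cma].to_numpy(dtype=float)
    ybar = y.mean()
    if ybar == 0:
        raise ZeroDivisionError("CV%% undefined: mean response is zero")

    mse = ss_resid / df_resid if df_resid > 0 else 0.0
    r2 = 1.0 - ss_resid / ss_total if ss_total > 0 else 1.0
    adj_r2 = (
        1.0 - (ss_resid / df_resid) / (ss_total / df_total)
        if df_resid > 0 and ss_total > 0
        else r2
    )
    yhat = predict(model, data.design.to_frame()[data.design.factor_names])
    if mse > 0:
        adeq = float((yhat.max() - yhat.min()) / np.sqrt(p * mse / n))
    else:
        adeq = np.inf

    stats_rec = {
        "R2": r2,
        "adj_R2": adj_r2,
        "CV_pct": 100.0 * np.sqrt(mse) / ybar,
        "adeq_precision": adeq,
        "MSE": mse,
    }
    model.stats = stats_rec
    return stats_rec


def predict(model: FittedModel, points: pd.DataFrame | dict) -> np.ndarray:
    """Predict the CMA at natural-unit factor settings.

    ``points`` maps factor names to values (a dict of scalars/arrays or a
    DataFrame with one column per factor); values are coded internally.
    """
    if isinstance(points, dict):
        points = pd.DataFrame(
            {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in points.items()}
        )
    coded = pd.DataFrame(index=points.index)
    by_name = {f.name: f for f in model.factors}
    for name in points.columns:
        if name not in by_name:
            raise KeyError(f"unknown factor name {name!r}")
        coded[name] = code_levels(by_name[name], points[name].to_numpy())
    out = np.full(len(points), model.coefficients["Intercept"], dtype=float)
    for t in model.terms:
        out += model.coefficients[t] * _term_column(coded, t)
    return out
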