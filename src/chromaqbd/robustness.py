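"""Plackett-Burman effect estimation and robustness significance tests.

An effect is the classical two-level contrast: mean response at the high
level minus mean response at the low level, computed over the non-center
rows.  Standard errors can come from a main-effects regression residual
(default — it works for any printed two-level plan), from unassigned
dummy columns of a standard PB geometry, or from center-point pure error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import Factor
from .rsm import ResponseTable

__all__ = ["EffectEstimate", "pb_effects", "pb_significance"]


@dataclass
class EffectEstimate:
    factor: str
    cma: str
    effect: float
    se: float | None = None
    t: float | None = None
    df: int | None = None
    p: float | None = None
    significant: bool | None = None


def _two_level_columns(data: ResponseTable, factors: list[Factor]):
    """Non-center rows, natural settings and responses, per-factor hi/lo."""
    keep = ~data.design.is_center
    nat = data.design.natural[keep]
    resp = data.responses.loc[keep].reset_index(drop=True)
    names = data.design.factor_names
    cols = {}
    for f in factors:
        j = names.index(f.name)
        x = nat[:, j]
        levels = np.unique(x)
        if len(levels) != 2:
            raise ValueError(
                f"factor {f.name!r} does not have exactly two levels in the "
                f"non-center rows (found {levels})"
            )
        cols[f.name] = x == levels.max()  # True at the high level
    return cols, resp


def pb_effects(data: ResponseTable, factors: list[Factor]) -> list[EffectEstimate]:
    """High-minus-low mean effects for every factor x CMA pair.

    Center rows are excluded from the contrasts.  Unbalanced columns
    (unequal high/low counts) are computed from the level means with a
    warning.
    """
    cols, resp = _two_level_columns(data, factors)
    out = []
    for name, hi in cols.items():
        if hi.sum() != (~hi).sum():
            warnings.warn(
                f"factor {name!r} is unbalanced ({int(hi.sum())} high vs "
                f"{int((~hi).sum())} low); effect uses level means",
                stacklevel=2,
            )
        for cma in resp.columns:
            y = resp[cma].to_numpy(dtype=float)
            out.append(
                EffectEstimate(
                    factor=name,
                    cma=cma,
                    effect=float(y[hi].mean() - y[~hi].mean()),
                )
            )
    return out


def pb_significance(
    data: ResponseTable,
    effects: list[EffectEstimate],
    method: str = "regression_residual",
    alpha: float = 0.05,
) -> list[EffectEstimate]:
    """Attach SE, t, df and two-sided p to each effect estimate.

    methods
    -------
    regression_residual
        Fit intercept + coded main effects on the two-level rows; the
        residual MS gives Var(effect) = 4 * MSE / n (balanced case, each
        effect being twice a coded slope).
    dummy_columns
        Root-mean-square of the unassigned PB column effects as the
        effect SE, df = number of dummy columns.
    center_points
        Pure-error variance from center replicates;
        Var(effect) = s^2 (1/n_hi + 1/n_lo), df = n_center - 1.
    """
    cols, resp = _two_level_columns(data, factors=[
        f for f in data.design.factors if f.name in {e.factor for e in effects}
    ])
    n = len(resp)
    k = len(cols)

    if method == "regression_residual":
        X = np.column_stack(
            [np.ones(n)] + [np.where(hi, 1.0, -1.0) for hi in cols.values()]
        )
        df = n - k - 1
        if df < 1:
            raise ValueError("regression residual df < 1")
        xtx_inv_diag = np.diag(np.linalg.pinv(X.T @ X))
        factor_idx = {name: 1 + i for i, name in enumerate(cols)}
        se_by = {}
        for cma in resp.columns:
            y = resp[cma].to_numpy(dtype=float)
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            mse = float(np.sum((y - X @ beta) ** 2)) / df
            for name, j in factor_idx.items():
                # effect = 2 * coded slope, so Var(effect) = 4 MSE (X'X)^-1_jj
                se_by[(name, cma)] = 2.0 * np.sqrt(mse * xtx_inv_diag[j])
        se_of = lambda e: (se_by[(e.factor, e.cma)], df)
    elif method == "dummy_columns":
        if data.design.dummy is None or data.design.dummy.shape[1] == 0:
            raise ValueError("design carries no dummy columns")
        keep = ~data.design.is_center
        dmy = data.design.dummy[keep]
        m = dmy.shape[1]
        se_by_cma = {}
        for cma in resp.columns:
            y = resp[cma].to_numpy(dtype=float)
            d_eff = np.array(
                [y[dmy[:, j] > 0].mean() - y[dmy[:, j] < 0].mean() for j in range(m)]
            )
            se_by_cma[cma] = float(np.sqrt(np.mean(d_eff**2)))
        se_of = lambda e: (se_by_cma[e.cma], m)
    elif method == "center_points":
        is_c = data.design.is_center
        nc = int(is_c.sum())
        if nc < 2:
            raise ValueError("center_points method needs >= 2 center rows")
        df = nc - 1
        se_of = None  # built per effect below
        s2_by_cma = {
            cma: float(np.var(data.responses.loc[is_c, cma].to_numpy(), ddof=1))
            for cma in resp.columns
        }
    else:
        raise ValueError(f"unknown method {method!r}")

    out = []
    for e in effects:
        hi = cols[e.factor]
        if method == "center_points":
            s2 = s2_by_cma[e.cma]
            se = float(np.sqrt(s2 * (1.0 / hi.sum() + 1.0 / (~hi).sum())))
            dof = int(is_c.sum()) - 1
        else:
            se, dof = se_of(e)
        if se > 0:
            t = e.effect / se
            p = float(2.0 * stats.t.sf(abs(t), dof))
        else:
            t, p = np.inf if e.effect != 0 else 0.0, 0.0 if e.effect != 0 else 1.0
        out.append(
            EffectEstimate(
                factor=e.factor,
                cma=e.cma,
                effect=e.effect,
                se=se,
                t=float(t),
                df=dof,
                p=p,
                significant=bool(p < alpha),
            )
        )
    return out


def effects_frame(effects: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy table of effect estimates (one row per factor x CMA)."""
    return pd.DataFrame([vars(e) for e in effects])
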