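"""Monte Carlo propagation of method-parameter uncertainty and Cpk.

Factor settings are drawn from per-parameter distributions (uniform,
normal or triangular, truncated to the factor range), pushed through the
fitted CMA models — optionally with residual model noise — and each CMA
distribution is summarized against its specification window by the
process-capability index Cpk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modr import SpecWindow
from .rsm import FittedModel, predict

__all__ = ["CMPDistribution", "MCConfig", "MCResult", "cpk", "simulate_capability"]

_KINDS = ("uniform", "normal", "triangular")


@dataclass(frozen=True)
class CMPDistribution:
    """Sampling distribution for one method parameter, in natural units.

    uniform: params (low, high); normal: (mean, sd); triangular:
    (left, mode, right).  Draws are truncated (by resampling) to
    [trunc_low, trunc_high] when given.
    """

    name: str
    kind: str
    params: tuple
    trunc_low: float | None = None
    trunc_high: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        def raw(m):
            if self.kind == "uniform":
                lo, hi = self.params
                return rng.uniform(lo, hi, m)
            if self.kind == "normal":
                mu, sd = self.params
                return rng.normal(mu, sd, m)
            left, mode, right = self.params
            return rng.triangular(left, mode, right, m)

        x = raw(n)
        lo = -np.inf if self.trunc_low is None else self.trunc_low
        hi = np.inf if self.trunc_high is None else self.trunc_high
        for _ in range(1000):
            bad = (x < lo) | (x > hi)
            if not bad.any():
                break
            x[bad] = raw(int(bad.sum()))
        else:
            raise RuntimeError(
                f"{self.name}: truncation region has negligible mass"
            )
        return x


@dataclass
class MCConfig:
    distributions: list[CMPDistribution]
    n_draws: int = 100_000
    seed: int = 0
    include_residual_noise: bool = True
    n_bins: int = 30

    def __post_init__(self) -> None:
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")


@dataclass
class MCResult:
    per_cma: pd.DataFrame                    # cma, mean, sd, cpk, frac_out
    histograms: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    n_draws: int = 0
    seed: int = 0


def cpk(mean: float, sd: float, window: SpecWindow) -> float:
    """Process-capability index against a one- or two-sided window.

    Two-sided: min((USL-mean)/(3 sd), (mean-LSL)/(3 sd)); one-sided uses
    the single finite term.  ``sd`` must be positive (a degenerate
    zero-spread sample is reported as +inf by the simulator, not here).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    parts = []
    if window.usl is not None:
        parts.append((window.usl - mean) / (3.0 * sd))
    if window.lsl is not None:
        parts.append((mean - window.lsl) / (3.0 * sd))
    return float(min(parts))


def simulate_capability(
    models: dict[str, FittedModel],
    windows: list[SpecWindow],
    config: MCConfig,
) -> MCResult:
    """Draw CMP vectors, predict every CMA, and summarize capability.

    With ``include_residual_noise`` each prediction gets independent
    N(0, sqrt(MSE)) noise from the corresponding model fit.  A zero
    sample SD (point-mass inputs, noise off) yields Cpk = +inf and an
    out-of-spec fraction of exactly 0 or 1.  Bit-identical output for
    identical seeds.
    """
    missing = [w.cma for w in windows if w.cma not in models]
    if missing:
        raise KeyError(f"no fitted model for window CMA(s): {missing}")
    rng = np.random.default_rng(config.seed)
    pts = pd.DataFrame(
        {d.name: d.draw(config.n_draws, rng) for d in config.distributions}
    )

    rows = []
    hists: dict[str, pd.DataFrame] = {}
    for w in windows:
        m = models[w.cma]
        y = predict(m, pts)
        if config.include_residual_noise and m.mse > 0:
            y = y + rng.normal(0.0, np.sqrt(m.mse), config.n_draws)
        mean, sd = float(y.mean()), float(y.std(ddof=1))
        frac_out = float(1.0 - w.contains(y).mean())
        cpk_val = cpk(mean, sd, w) if sd > 0 else np.inf
        rows.append(
            {"cma": w.cma, "mean": mean, "sd": sd, "cpk": cpk_val, "frac_out": frac_out}
        )
        counts, edges = np.histogram(y, bins=config.n_bins)
        hists[w.cma] = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )
    return MCResult(
        per_cma=pd.DataFrame(rows),
        histograms=hists,
        n_draws=config.n_draws,
        seed=config.seed,
    )
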