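"""Design-space overlay and Method Operable Design Region extraction.

Predicted CMAs are evaluated on a factor lattice and compared against
their specification windows; a lattice point is feasible iff every CMA
lies inside its (closed) window.  The MODR is the maximum-volume
axis-aligned lattice box whose points are all feasible — found by exact
enumeration for up to three factors, and by a grow-from-seed heuristic
for higher-dimensional overlays.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import Factor
from .rsm import FittedModel, predict

__all__ = ["SpecWindow", "OverlayResult", "overlay_feasibility", "extract_modr"]


@dataclass(frozen=True)
class SpecWindow:
    """Acceptance window for one CMA; one of LSL/USL may be open."""

    cma: str
    lsl: float | None = None
    usl: float | None = None

    def __post_init__(self) -> None:
        if self.lsl is None and self.usl is None:
            raise ValueError(f"{self.cma}: at least one of LSL/USL is required")
        if self.lsl is not None and self.usl is not None and not self.lsl < self.usl:
            raise ValueError(f"{self.cma}: LSL must be < USL")

    def contains(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        ok = np.ones(y.shape, dtype=bool)
        if self.lsl is not None:
            ok &= y >= self.lsl
        if self.usl is not None:
            ok &= y <= self.usl
        return ok


@dataclass
class OverlayResult:
    factors: list[Factor]
    axes: list[np.ndarray]          # natural-unit grid points per factor
    feasible: np.ndarray            # boolean mask, shape = grid per factor
    modr: dict[str, tuple[float, float]] | None = None

    @property
    def coverage(self) -> float:
        return float(self.feasible.mean())

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per lattice point + feasible flag."""
        mesh = np.array(list(itertools.product(*self.axes)))
        out = pd.DataFrame(mesh, columns=[f.name for f in self.factors])
        out["feasible"] = self.feasible.ravel().astype(int)
        return out


def overlay_feasibility(
    models: dict[str, FittedModel],
    windows: list[SpecWindow],
    ranges: list[Factor],
    grid: int = 21,
) -> OverlayResult:
    """Evaluate joint feasibility of all spec windows on a factor lattice."""
    missing = [w.cma for w in windows if w.cma not in models]
    if missing:
        raise KeyError(f"no fitted model for window CMA(s): {missing}")
    axes = [np.linspace(f.low, f.high, grid) for f in ranges]
    names = [f.name for f in ranges]
    mesh = np.array(list(itertools.product(*axes)))
    pts = pd.DataFrame(mesh, columns=names)
    ok = np.ones(len(pts), dtype=bool)
    for w in windows:
        ok &= w.contains(predict(models[w.cma], pts))
    shape = tuple(len(a) for a in axes)
    return OverlayResult(factors=list(ranges), axes=axes, feasible=ok.reshape(shape))


def _max_box_exact(mask: np.ndarray) -> tuple[tuple[int, int], ...] | None:
    """Maximum-lattice-point axis-aligned all-True box, exact enumeration.

    Returns per-axis (start, stop) inclusive index intervals, or None when
    no point is feasible.  Complexity O(prod(g_i^2)) over the leading axes
    with a linear max-run scan on the last — fine for <= 3 axes at g <= 51.
    """
    if not mask.any():
        return None
    nd = mask.ndim
    shapes = mask.shape
    best = None
    best_size = 0

    lead_axes = [range(s) for s in shapes[:-1]]
    lead_intervals = [
        [(i, j) for i in rng for j in rng if i <= j] for rng in lead_axes
    ]

    for combo in itertools.product(*lead_intervals):
        sl = tuple(slice(i, j + 1) for i, j in combo)
        line = mask[sl].all(axis=tuple(range(nd - 1))) if nd > 1 else mask
        lead_count = int(np.prod([j - i + 1 for i, j in combo])) if combo else 1
        # longest all-True run on the last axis
        run = 0
        for idx in range(len(line)):
            if line[idx]:
                run += 1
                if run * lead_count > best_size:
                    best_size = run * lead_count
                    best = combo + ((idx - run + 1, idx),)
            else:
                run = 0
    return best


def _max_box_greedy(mask: np.ndarray, rng: np.random.Generator):
    """Grow a box axis-by-axis from random feasible seeds (heuristic)."""
    feas = np.argwhere(mask)
    if len(feas) == 0:
        return None
    best = None
    best_size = 0
    seeds = feas[rng.permutation(len(feas))[: min(50, len(feas))]]
    for seed_pt in seeds:
        box = [(int(c), int(c)) for c in seed_pt]
        grew = True
        while grew:
            grew = False
            for ax in range(mask.ndim):
                for direction in (-1, +1):
                    lo, hi = box[ax]
                    nlo, nhi = (lo - 1, hi) if direction < 0 else (lo, hi + 1)
                    if nlo < 0 or nhi >= mask.shape[ax]:
                        continue
                    trial = box.copy()
                    trial[ax] = (nlo, nhi)
                    sl = tuple(slice(a, b + 1) for a, b in trial)
                    if mask[sl].all():
                        box = trial
                        grew = True
        size = int(np.prod([b - a + 1 for a, b in box]))
        if size > best_size:
            best_size = size
            best = tuple(box)
    return best


def extract_modr(overlay: OverlayResult, seed: int = 0) -> dict[str, tuple[float, float]]:
    """Extract the MODR: the largest all-feasible axis-aligned lattice box.

    "Largest" counts lattice points (product over axes), so a single
    feasible point yields a degenerate box at that point.  Exact search
    for <= 3 factors; a seeded greedy heuristic above that.  An empty
    feasible set returns an empty dict with a warning.
    """
    mask = overlay.feasible
    if mask.ndim <= 3:
        box = _max_box_exact(mask)
    else:
        box = _max_box_greedy(mask, np.random.default_rng(seed))
    if box is None:
        warnings.warn("no feasible lattice point; MODR is empty", stacklevel=2)
        overlay.modr = {}
        return {}
    modr = {
        f.name: (float(ax[i]), float(ax[j]))
        for f, ax, (i, j) in zip(overlay.factors, overlay.axes, box)
    }
    overlay.modr = modr
    return modr
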