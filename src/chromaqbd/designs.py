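"""Two-level experimental designs with coded (-1/0/+1) variables.

Supports the two designs used in chromatographic method screening and
robustness work: a two-level full factorial with center points, and the
12-run Plackett-Burman design with center points.  Factor levels are kept
both in natural units (pH, %ACN, degC, mM) and in the usual coded units,
where -1/+1 are the low/high ends of each factor's range and 0 is the
midpoint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignMatrix",
    "full_factorial",
    "plackett_burman",
    "code_levels",
    "decode_levels",
    "PB12_GENERATOR",
]

# First row of the cyclic 12-run Plackett-Burman generator; rows 2-11 are
# cyclic right-shifts and row 12 is all minus.
PB12_GENERATOR = (+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1)


@dataclass(frozen=True)
class Factor:
    """A controllable method parameter with its natural-unit range."""

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("factor name must be non-empty")
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    @property
    def mid(self) -> float:
        return (self.low + self.high) / 2.0

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0


def code_levels(factor: Factor, natural):
    """Map natural units to coded units: -1 at ``low``, +1 at ``high``.

    Values outside [low, high] are mapped linearly (|coded| > 1).
    """
    return (np.asarray(natural, dtype=float) - factor.mid) / factor.half_range


def decode_levels(factor: Factor, coded):
    """Inverse of :func:`code_levels` (exact linear inverse)."""
    return factor.mid + np.asarray(coded, dtype=float) * factor.half_range


@dataclass
class DesignMatrix:
    """An experimental plan: coded rows plus run metadata.

    Attributes
    ----------
    factors : list of Factor
        Ordered factors; column ``i`` of ``coded`` belongs to ``factors[i]``.
    coded : ndarray of shape (n_runs, k)
        Coded settings, each cell in {-1, 0, +1}.
    is_center : ndarray of bool
        True for center-point rows (all coded levels 0).
    replicate : ndarray of int
        1-based replicate index of each row.
    run_order : ndarray of int
        Randomized execution order (a permutation of 1..n_runs).
    dummy : ndarray or None
        For Plackett-Burman designs, the unassigned +/-1 columns kept for
        error estimation; None otherwise (center rows carry 0).
    """

    factors: list[Factor]
    coded: np.ndarray
    is_center: np.ndarray
    replicate: np.ndarray
    run_order: np.ndarray
    dummy: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names: {names}")
        self.coded = np.asarray(self.coded, dtype=float)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factors):
            raise ValueError("coded matrix shape does not match factor list")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def natural(self) -> np.ndarray:
        """Natural-unit settings, row by row (midpoint + coded * half-range)."""
        mids = np.array([f.mid for f in self.factors])
        halves = np.array([f.half_range for f in self.factors])
        return mids + self.coded * halves

    def to_frame(self) -> pd.DataFrame:
        """Design as a tidy table: run_order, is_center, replicate, factors."""
        out = pd.DataFrame(
            {
                "run_order": self.run_order,
                "is_center": self.is_center.astype(int),
                "replicate": self.replicate,
            }
        )
        nat = self.natural
        for j, f in enumerate(self.factors):
            out[f.name] = nat[:, j]
        return out


def _randomize(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.permutation(n) + 1


def full_factorial(
    factors: list[Factor],
    n_center: int = 0,
    n_replicates: int = 1,
    seed: int = 0,
) -> DesignMatrix:
    """Two-level full factorial (2^k runs) plus center points.

    Every distinct row — the 2^k factorial corners and each of the
    ``n_center`` center points — is replicated ``n_replicates`` times,
    giving (2^k + n_center) * n_replicates rows in total.  Only the run
    order is randomized (by ``seed``); level assignment is fixed.
    """
    if not factors:
        raise ValueError("empty factor list")
    k = len(factors)
    if not 1 <= k <= 8:
        raise ValueError(f"full factorial supports 1..8 factors, got {k}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")

    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    base = np.vstack([corners, np.zeros((n_center, k))])
    center_flag = np.r_[np.zeros(2**k, dtype=bool), np.ones(n_center, dtype=bool)]

    coded = np.repeat(base, n_replicates, axis=0)
    is_center = np.repeat(center_flag, n_replicates)
    replicate = np.tile(np.arange(1, n_replicates + 1), base.shape[0])

    return DesignMatrix(
        factors=list(factors),
        coded=coded,
        is_center=is_center,
        replicate=replicate,
        run_order=_randomize(coded.shape[0], seed),
    )


def plackett_burman(
    factors: list[Factor],
    n_center: int = 0,
    seed: int = 0,
) -> DesignMatrix:
    """12-run Plackett-Burman screening design plus center points.

    The 12 two-level rows come from the textbook cyclic generator; the
    first k of the 11 orthogonal columns are assigned to ``factors`` and
    the remaining 11-k columns are retained as dummy columns for error
    estimation.
    """
    if not factors:
        raise ValueError("empty factor list")
    k = len(factors)
    if k > 11:
        raise ValueError(f"12-run Plackett-Burman supports at most 11 factors, got {k}")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")

    gen = np.array(PB12_GENERATOR, dtype=float)
    rows = [np.roll(gen, shift) for shift in range(11)]
    rows.append(-np.ones(11))
    full = np.array(rows)  # 12 x 11, orthogonal

    coded = np.vstack([full[:, :k], np.zeros((n_center, k))])
    dummy = np.vstack([full[:, k:], np.zeros((n_center, 11 - k))])
    is_center = np.r_[np.zeros(12, dtype=bool), np.ones(n_center, dtype=bool)]
    replicate = np.r_[np.ones(12, dtype=int), np.arange(1, n_center + 1)]

    return DesignMatrix(
        factors=list(factors),
        coded=coded,
        is_center=is_center,
        replicate=replicate,
        run_order=_randomize(coded.shape[0], seed),
        dummy=dummy,
    )
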