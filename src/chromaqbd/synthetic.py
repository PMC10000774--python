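"""Synthetic chromatographic data with the structure the pipeline assumes.

The generator emulates an isocratic reversed-phase separation of the
three curcuminoids (curcumin CMN, demethoxycurcumin DMCMN,
bisdemethoxycurcumin BDMCMN) under three controllable method parameters:
mobile-phase pH, % acetonitrile and column temperature (plus an optional
buffer-concentration factor for robustness plans).

Retention follows a linear-solvent-strength-style log-linear law,
ln k = ln k0 + b_phi (phi - phi0) + b_pH (pH - pH0) + b_T (T - T0),
with RT = t0 (1 + k); plate counts are linear in temperature and solvent;
the resolution between an adjacent peak pair is the fundamental relation
Rs = (sqrt(Nbar)/4) ((alpha - 1)/alpha) (k2/(1 + k2)) with
alpha = k2/k1.  Signs default to the qualitative behavior expected of
such a system: retention increases with pH and decreases with organic
fraction and temperature.  Noise is multiplicative Gaussian per CMA
family.

The module also ships verbatim fixture transcriptions of the printed
design/goal/window/robustness/calibration/content tables, addressable by
name via :func:`fixtures`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .designs import DesignMatrix, Factor, full_factorial
from .rsm import ResponseTable
from .validation import PeakTable

__all__ = [
    "SyntheticTruth",
    "make_truth",
    "simulate_responses",
    "simulate_calibration",
    "simulate_degradation",
    "fixtures",
    "fixture_names",
    "ANALYTES",
]

# Elution order at the reference condition: BDMCMN first, CMN last.
ANALYTES = ("BDMCMN", "DMCMN", "CMN")

_REFERENCE = {"ACN": 54.0, "pH": 2.7, "Temperature": 33.0, "Buffer": 10.0}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth retention/plate model for the synthetic separation."""

    analytes: tuple[str, ...] = ANALYTES          # in elution order
    lnk0: dict = field(
        default_factory=lambda: {"BDMCMN": 1.35, "DMCMN": 1.48, "CMN": 1.61}
    )
    beta_phi: dict = field(
        default_factory=lambda: {a: -0.030 for a in ANALYTES}
    )  # per % ACN
    beta_ph: dict = field(default_factory=lambda: {a: 0.05 for a in ANALYTES})
    beta_t: dict = field(
        default_factory=lambda: {a: -0.010 for a in ANALYTES}
    )  # per degC
    beta_buffer: dict = field(
        default_factory=lambda: {a: -0.0005 for a in ANALYTES}
    )  # per mM
    t0: float = 1.0                                # dead time, minutes
    n0: dict = field(
        default_factory=lambda: {"BDMCMN": 4806.0, "DMCMN": 3970.0, "CMN": 4915.0}
    )
    n_per_degc: float = 40.0
    n_per_pct_acn: float = -25.0
    noise_rel: dict = field(
        default_factory=lambda: {"RT": 0.01, "RS": 0.02, "TP": 0.03}
    )
    slope_true: dict = field(
        default_factory=lambda: {
            "CMN": 2.22e6, "DMCMN": 3.46e6, "BDMCMN": 1.08e6,
        }
    )  # detector area per (ug/mL)
    intercept_true: dict = field(
        default_factory=lambda: {"CMN": 5.0e5, "DMCMN": -4.1e5, "BDMCMN": -1.3e5}
    )
    parent_areas: dict = field(
        default_factory=lambda: {"CMN": 5.0e6, "DMCMN": 3.0e6, "BDMCMN": 1.0e6}
    )
    seed: int = 0

    def ln_k(self, analyte: str, acn, ph, temp, buffer=None) -> np.ndarray:
        out = (
            self.lnk0[analyte]
            + self.beta_phi[analyte] * (np.asarray(acn, float) - _REFERENCE["ACN"])
            + self.beta_ph[analyte] * (np.asarray(ph, float) - _REFERENCE["pH"])
            + self.beta_t[analyte] * (np.asarray(temp, float) - _REFERENCE["Temperature"])
        )
        if buffer is not None:
            out = out + self.beta_buffer[analyte] * (
                np.asarray(buffer, float) - _REFERENCE["Buffer"]
            )
        return out

    def retention_time(self, analyte, acn, ph, temp, buffer=None) -> np.ndarray:
        return self.t0 * (1.0 + np.exp(self.ln_k(analyte, acn, ph, temp, buffer)))

    def plates(self, analyte, acn, temp) -> np.ndarray:
        return (
            self.n0[analyte]
            + self.n_per_degc * (np.asarray(temp, float) - _REFERENCE["Temperature"])
            + self.n_per_pct_acn * (np.asarray(acn, float) - _REFERENCE["ACN"])
        )


def make_truth(seed: int = 0, overrides: dict | None = None) -> SyntheticTruth:
    """Build the ground truth, optionally overriding any field.

    Deterministic: the same seed (and overrides) always yields the same
    truth.  Defaults place all three analytes inside the 2-7 min
    retention window with plate counts above 2000 at the reference
    operating point (54% ACN, pH 2.7, 33 degC).
    """
    truth = SyntheticTruth(seed=seed)
    if overrides:
        truth = replace(truth, **overrides)
    if truth.t0 <= 0:
        raise ValueError("dead time t0 must be positive")
    if any(v < 0 for v in truth.noise_rel.values()):
        raise ValueError("noise SDs must be non-negative")
    # Plate counts must stay positive across the usual screening region.
    for a in truth.analytes:
        for acn in (50.0, 70.0):
            for temp in (25.0, 35.0):
                if truth.plates(a, acn, temp) <= 0:
                    raise ValueError(
                        f"plate model for {a} non-positive at ACN={acn}, T={temp}"
                    )
    return truth


def _design_columns(design: DesignMatrix) -> dict[str, np.ndarray]:
    nat = design.natural
    cols = {f.name: nat[:, j] for j, f in enumerate(design.factors)}
    for required in ("pH", "ACN", "Temperature"):
        if required not in cols:
            raise KeyError(f"design is missing required factor {required!r}")
    return cols


def simulate_responses(
    truth: SyntheticTruth, design: DesignMatrix, seed: int = 0
) -> ResponseTable:
    """Simulate all eight CMAs for every run of a design.

    Requires factors named pH, ACN and Temperature (Buffer optional).
    Multiplicative Gaussian noise with the truth's per-family relative
    SDs; deterministic for a given seed.
    """
    if len(truth.analytes) < 2:
        raise ValueError("need at least two analytes to compute resolutions")
    cols = _design_columns(design)
    buf = cols.get("Buffer")
    rng = np.random.default_rng(seed)
    n = design.n_runs

    k = {
        a: np.exp(truth.ln_k(a, cols["ACN"], cols["pH"], cols["Temperature"], buf))
        for a in truth.analytes
    }
    rt = {a: truth.t0 * (1.0 + k[a]) for a in truth.analytes}
    tp = {a: truth.plates(a, cols["ACN"], cols["Temperature"]) for a in truth.analytes}

    def resolution(a1: str, a2: str) -> np.ndarray:
        k1, k2 = k[a1], k[a2]
        nbar = (tp[a1] + tp[a2]) / 2.0
        alpha = k2 / k1
        return (np.sqrt(nbar) / 4.0) * ((alpha - 1.0) / alpha) * (k2 / (1.0 + k2))

    order = truth.analytes  # elution order, first to last
    out = pd.DataFrame(index=range(n))
    # RS1 separates the last pair (CMN from DMCMN), RS2 the first pair.
    out["RS1"] = resolution(order[-2], order[-1])
    out["RS2"] = resolution(order[0], order[1])
    for a in truth.analytes:
        out[f"RT_{a}"] = rt[a]
    for a in truth.analytes:
        out[f"TP_{a}"] = tp[a]

    for col in out.columns:
        fam = col.split("_")[0]
        rel = truth.noise_rel.get(fam, 0.0)
        if rel > 0:
            out[col] = out[col] * (1.0 + rel * rng.standard_normal(n))

    order_cols = ["RS1", "RS2"] + [f"RT_{a}" for a in ("CMN", "DMCMN", "BDMCMN") if a in truth.analytes]
    order_cols += [f"TP_{a}" for a in ("CMN", "DMCMN", "BDMCMN") if a in truth.analytes]
    extra = [c for c in out.columns if c not in order_cols]
    return ResponseTable(design=design, responses=out[order_cols + extra])


def simulate_calibration(
    truth: SyntheticTruth,
    analyte: str,
    levels,
    relative_noise: float = 0.005,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration rows (analyte, concentration, response) with noise.

    The response is slope_true * conc + intercept_true plus Gaussian noise
    whose SD is ``relative_noise`` times the signal magnitude.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("concentration levels must be positive")
    rng = np.random.default_rng(seed)
    signal = truth.slope_true[analyte] * levels + truth.intercept_true[analyte]
    noise = relative_noise * np.abs(truth.slope_true[analyte] * levels)
    resp = signal + noise * rng.standard_normal(len(levels))
    return pd.DataFrame(
        {"analyte": analyte, "concentration": levels, "response": resp}
    )


def simulate_degradation(
    truth: SyntheticTruth,
    condition: str,
    extent: float,
    n_degradants: int = 2,
    seed: int = 0,
) -> tuple[PeakTable, PeakTable]:
    """Reference and stressed peak tables with a known degradation extent.

    The stressed parents lose exactly ``extent`` of the total reference
    parent area (with per-peak jitter that sums to zero), and the lost
    mass reappears as ``n_degradants`` early-eluting degradant peaks —
    all placed before the first parent peak, as expected for the more
    polar cleavage products.
    """
    if not 0.0 <= extent <= 1.0:
        raise ValueError("extent must be in [0, 1]")
    rng = np.random.default_rng(seed)

    ref_point = _REFERENCE
    parents = sorted(
        truth.analytes,
        key=lambda a: float(
            truth.retention_time(a, ref_point["ACN"], ref_point["pH"], ref_point["Temperature"])
        ),
    )
    rt_parent = np.array(
        [
            float(truth.retention_time(a, ref_point["ACN"], ref_point["pH"], ref_point["Temperature"]))
            for a in parents
        ]
    )
    area_parent = np.array([truth.parent_areas[a] for a in parents])
    reference = PeakTable(
        condition="none",
        rt=rt_parent,
        area=area_parent,
        parent=np.ones(len(parents), dtype=bool),
    )

    # Per-peak losses: proportional to area, plus a zero-sum jitter kept
    # small enough that every stressed area stays non-negative.
    lost = extent * area_parent.copy()
    if extent > 0 and len(parents) > 1:
        jitter = rng.uniform(-1.0, 1.0, len(parents))
        jitter -= jitter.mean()
        headroom = np.minimum(lost, area_parent - lost)
        scale = 0.25 * headroom.min() / max(np.abs(jitter).max(), 1e-12)
        lost = lost + scale * jitter
    stressed_area = area_parent - lost

    if extent > 0 and n_degradants > 0:
        first_parent = rt_parent.min()
        lo = truth.t0 * 1.2
        hi = first_parent - 0.3
        rt_deg = np.sort(rng.uniform(lo, hi, n_degradants))
        while len(np.unique(rt_deg)) < n_degradants:
            rt_deg = np.sort(rng.uniform(lo, hi, n_degradants))
        w = rng.dirichlet(np.ones(n_degradants))
        area_deg = w * lost.sum()
    else:
        rt_deg = np.empty(0)
        area_deg = np.empty(0)

    rt_all = np.concatenate([rt_deg, rt_parent])
    area_all = np.concatenate([area_deg, stressed_area])
    parent_all = np.concatenate(
        [np.zeros(len(rt_deg), dtype=bool), np.ones(len(parents), dtype=bool)]
    )
    stressed = PeakTable(
        condition=condition, rt=rt_all, area=area_all, parent=parent_all
    )
    return reference, stressed


_FIXTURES = {
    "table1": "table1_factors.csv",
    "table3": "table3_goals.csv",
    "table4_windows": "table4_windows.csv",
    "table4_cmp_ranges": "table4_cmp_ranges.csv",
    "table5": "table5_pb.csv",
    "table6": "table6_calibration.csv",
    "table8": "table8_content.csv",
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixtures(name: str | None = None):
    """Packaged verbatim transcriptions of the printed tables.

    With ``name`` returns that table as a DataFrame; otherwise a dict of
    all of them.  Numeric columns are parsed; empty cells become NaN.
    """
    def load(fname: str) -> pd.DataFrame:
        path = resources.files("chromaqbd.data").joinpath(fname)
        with path.open("r") as fh:
            return pd.read_csv(fh)

    if name is not None:
        if name not in _FIXTURES:
            raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")
        return load(_FIXTURES[name])
    return {key: load(fname) for key, fname in _FIXTURES.items()}


def screening_factors() -> list[Factor]:
    """The three screening factors with their printed natural ranges."""
    t1 = fixtures("table1")
    return [
        Factor(name=r["name"], low=float(r["low"]), high=float(r["high"]),
               units=str(r["units"]) if pd.notna(r["units"]) else "")
        for r in t1.to_dict("records")
    ]


def robustness_factors() -> list[Factor]:
    """The four robustness factors with their narrow perturbation ranges."""
    t4 = fixtures("table4_cmp_ranges")
    out = [
        Factor(name=r["name"], low=float(r["low"]), high=float(r["high"]),
               units=str(r["units"]) if pd.notna(r["units"]) else "")
        for r in t4.to_dict("records")
    ]
    out.append(Factor(name="Buffer", low=8.0, high=12.0, units="mM"))
    # Canonical order of the printed robustness plan.
    order = {"pH": 0, "ACN": 1, "Temperature": 2, "Buffer": 3}
    return sorted(out, key=lambda f: order.get(f.name, 99))


def modr_factors() -> list[Factor]:
    """The operable-region factor ranges (the reported MODR box)."""
    t4 = fixtures("table4_cmp_ranges")
    out = [
        Factor(name=r["name"], low=float(r["low"]), high=float(r["high"]),
               units=str(r["units"]) if pd.notna(r["units"]) else "")
        for r in t4.to_dict("records")
    ]
    order = {"pH": 0, "ACN": 1, "Temperature": 2}
    return sorted(out, key=lambda f: order.get(f.name, 99))


def spec_windows():
    """The printed CMA acceptance windows as SpecWindow objects."""
    from .io import windows_from_records

    return windows_from_records(fixtures("table4_windows").to_dict("records"))


def optimization_goals():
    """The printed optimization goals mapped to desirability ramps.

    One-sided ">x" goals become at_least ramps with the printed observed
    maximum as the saturation point; Maximize/Minimize/In range use the
    printed observed range as the ramp span.
    """
    from .desirability import DesirabilityGoal

    kind_map = {"maximize": "maximize", "minimize": "minimize", "in range": "in_range"}
    out = []
    for r in fixtures("table3").to_dict("records"):
        raw = str(r["goal"]).strip()
        hi = float(r["upper_limit"])
        lo = float(r["lower_limit"])
        if raw.startswith(">"):
            thr = float(raw[1:])
            out.append(
                DesirabilityGoal(cma=r["cma"], goal="at_least", lower=thr, upper=hi)
            )
        else:
            out.append(
                DesirabilityGoal(cma=r["cma"], goal=kind_map[raw.lower()], lower=lo, upper=hi)
            )
    return out


def table5_response_table() -> ResponseTable:
    """The printed robustness plan and responses, ready for analysis."""
    from .io import response_table_from_frame

    return response_table_from_frame(
        fixtures("table5"), robustness_factors(), where="table5 fixture"
    )


def demo_response_table(
    n_center: int = 3, n_replicates: int = 1, seed: int = 0
) -> ResponseTable:
    """A ready-to-model synthetic screening study on the printed ranges."""
    design = full_factorial(
        screening_factors(), n_center=n_center, n_replicates=n_replicates, seed=seed
    )
    return simulate_responses(make_truth(seed), design, seed=seed + 1)
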