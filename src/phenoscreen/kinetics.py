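"""Culture-side computations for phenol-degrading strains.

Covers the quantitative steps of a typical phenol-degradation culture
study: modified Gompertz fits of OD580 growth curves, FACS-calibrated
proportions of a GFP-tagged strain in a two-member mixed culture,
Beer-Lambert absorbance-to-concentration conversion for ring-cleavage
intermediates, dioxygenase specific activities, and growth/no-growth
summaries of phenol dose-response plates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

log = logging.getLogger(__name__)


class GompertzFitError(RuntimeError):
    """Raised when the growth model cannot be fitted to a curve."""


@dataclass(frozen=True)
class GrowthCurve:
    times: np.ndarray      # hours, strictly increasing
    od580: np.ndarray
    strain: str = ""
    temperature_C: float | None = None
    phenol_mM: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od580, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od580", y)
        if t.size != y.size:
            raise ValueError("times and od580 differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("od580 must be non-negative")


@dataclass(frozen=True)
class GompertzFit:
    """Zwietering-form modified Gompertz parameters.

    A is the asymptotic OD rise above the baseline y0, mu_m the maximum
    specific growth rate (h^-1, the slope at the inflection), lam the lag
    time (h, where the inflection tangent crosses the baseline).
    """

    y0: float
    A: float
    mu_m: float
    lam: float
    rss: float


def gompertz(t, y0: float, A: float, mu_m: float, lam: float):
    """y(t) = y0 + A * exp(-exp(mu_m*e/A * (lam - t) + 1))."""
    t = np.asarray(t, dtype=float)
    return y0 + A * np.exp(-np.exp(mu_m * math.e / A * (lam - t) + 1.0))


def fit_gompertz(
    curve: GrowthCurve, *, on_log: bool = False, min_points: int = 6
) -> GompertzFit:
    """Nonlinear least-squares Gompertz fit with multi-start initialization.

    Lag starts are placed at 0 / 25 / 50% of the observed time span, mu_m
    at the largest finite-difference slope and A at the observed OD rise.
    With on_log=True the model is fitted to ln(OD/OD_0) instead of OD
    (both conventions exist for the modified Gompertz model).  Raises
    GompertzFitError when no start converges.
    """
    t = curve.times
    y = curve.od580
    if t.size < min_points:
        raise ValueError(f"need >={min_points} points, got {t.size}")
    if on_log:
        if y[0] <= 0:
            raise ValueError("on_log requires positive initial OD")
        y = np.log(np.maximum(y, 1e-9) / y[0])
    if np.all(np.diff(y) <= 0) and y[-1] < y[0]:
        raise ValueError("monotone-decreasing curve: no growth to fit")

    span = t[-1] - t[0]
    slopes = np.diff(y) / np.diff(t)
    mu0 = max(float(np.max(slopes)), 1e-3)
    A0 = max(float(np.max(y) - np.min(y)), 1e-3)
    y00 = float(np.min(y))
    lower = [min(y00, -1.0) if on_log else 0.0, 1e-6, 1e-6, 0.0]
    upper = [np.inf, np.inf, np.inf, float(t[-1])]

    def residuals(p):
        return gompertz(t, *p) - y

    best = None
    for frac in (0.0, 0.25, 0.5):
        p0 = [y00, A0, mu0, t[0] + frac * span]
        p0 = np.clip(p0, lower, upper)
        try:
            sol = least_squares(
                residuals, p0, bounds=(lower, upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise GompertzFitError(
            f"Gompertz fit did not converge for strain {curve.strain!r}"
        )
    rss, (y0_, A_, mu_, lam_) = best
    return GompertzFit(y0=float(y0_), A=float(A_), mu_m=float(mu_),
                       lam=float(lam_), rss=rss)


@dataclass(frozen=True)
class FACSSample:
    """One flow-cytometry measurement of a GFP/non-GFP two-strain mixture.

    N: total events recorded (30,000 per measurement in the assay this
       models); F: fluorescent events; f: fluorescent fraction of the
       GFP-tagged strain in pure culture (the calibration ratio).
    """

    N: int = 30000
    F: int = 0
    f: float = 1.0

    def __post_init__(self):
        if not (0 <= self.F <= self.N):
            raise ValueError("need 0 <= F <= N")
        if not (0.0 < self.f <= 1.0):
            raise ValueError("calibration fraction f must be in (0, 1]")


def mixture_proportions(
    sample: FACSSample, clip_tolerance: float = 0.02
) -> tuple[float, float]:
    """(p_gfp_strain, p_other) corrected for incomplete GFP expression.

    The GFP strain's true event count is estimated as F / f; estimates
    beyond N signal a calibration inconsistency and are clipped with a
    warning when the excess exceeds `clip_tolerance` of N.
    """
    est = sample.F / sample.f
    if est > sample.N * (1.0 + clip_tolerance):
        log.warning(
            "FACS estimate %.0f exceeds total events %d; clipping "
            "(calibration fraction f=%.3f likely too low)",
            est, sample.N, sample.f,
        )
    p_gfp = min(max(est, 0.0), float(sample.N)) / sample.N
    return p_gfp, 1.0 - p_gfp


def absorbance_to_conc(A: float, epsilon: float, path_cm: float = 1.0) -> float:
    """Beer-Lambert concentration c = A / (epsilon * l), in mol/L."""
    if A < 0:
        raise ValueError("absorbance must be non-negative")
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    return A / (epsilon * path_cm)


def conc_to_absorbance(c: float, epsilon: float, path_cm: float = 1.0) -> float:
    """Inverse of absorbance_to_conc (round-trip identity)."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    return c * epsilon * path_cm


@dataclass(frozen=True)
class EnzymeAssay:
    """Continuous spectrophotometric dioxygenase assay.

    slope: absorbance change per minute at the product's wavelength
    (260 nm for cis,cis-muconate from C12O, 375 nm for HMS from C23O);
    epsilon: product molar absorptivity (M^-1 cm^-1, supplied by config —
    never hard-coded); path_cm: cuvette path; volume_L: assay volume;
    protein_mg: protein in the assay.
    """

    slope: float
    epsilon: float
    path_cm: float = 1.0
    volume_L: float = 0.001
    protein_mg: float = 1.0

    def __post_init__(self):
        if min(self.epsilon, self.path_cm, self.volume_L) <= 0:
            raise ValueError("epsilon, path and volume must be positive")
        if self.protein_mg <= 0:
            raise ValueError("protein mass must be positive")


def specific_activity(assay: EnzymeAssay) -> float:
    """Specific activity in umol product min^-1 (mg protein)^-1.

    rate = (slope / (epsilon * l)) * V * 1e6 / m_protein: the Beer-Lambert
    rate in M/min times assay volume gives mol/min, scaled to umol per mg.
    """
    molar_per_min = assay.slope / (assay.epsilon * assay.path_cm)
    return molar_per_min * assay.volume_L * 1e6 / assay.protein_mg


def dose_response_summary(
    table: pd.DataFrame, growth_delta: float = 0.05
) -> tuple[pd.DataFrame, dict[float, float | None]]:
    """Growth/no-growth calls on a phenol dose-response plate.

    `table` columns: conc_mM, timepoint_h, replicate, od580; the 0 mM rows
    are the blank.  A (concentration, timepoint) cell shows growth iff its
    mean OD exceeds the same timepoint's blank mean by more than
    growth_delta (strict).  Returns the per-cell flag table and, per
    timepoint, the highest concentration with growth (None if none); gaps
    in the concentration series are reported as-is, not smoothed.
    """
    required = {"conc_mM", "timepoint_h", "replicate", "od580"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    if not (table["conc_mM"] == 0).any():
        raise ValueError("plate has no 0 mM blank/control wells")
    cells = (
        table.groupby(["timepoint_h", "conc_mM"])["od580"]
        .mean()
        .rename("mean_od")
        .reset_index()
    )
    blanks = (
        cells[cells["conc_mM"] == 0]
        .set_index("timepoint_h")["mean_od"]
        .to_dict()
    )
    for tp in cells["timepoint_h"].unique():
        if tp not in blanks:
            raise ValueError(f"no 0 mM blank for timepoint {tp} h")
    cells["blank_od"] = cells["timepoint_h"].map(blanks)
    cells["growth"] = (cells["mean_od"] - cells["blank_od"]) > growth_delta
    summary: dict[float, float | None] = {}
    for tp, grp in cells.groupby("timepoint_h"):
        grown = grp.loc[grp["growth"], "conc_mM"]
        summary[float(tp)] = float(grown.max()) if len(grown) else None
    return cells, summary
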