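"""Antigen dose-response calibration: stimulus mapping, Hill curves, time factors.

This module is the quantitative bridge between cytometry summaries and the
spatial model.  Antigen doses (µg of antigen used for immunization) are mapped
onto a normalized stimulus A ∈ [0, 1].  The producer fraction φ(A) of Th cells
and the receptor (CD25) capacity curves γ_pop(A) are monotone Hill-type
functions of A, fitted from per-dose condition summaries.  Deterministic time
factors describe the rise and fall of IL-2 secretion (T_sec, peak 9 h, gone by
18 h) and CD25 expression (T_rec, peak 18 h, gone by 30 h) after immunization;
IL-2 secretion precedes receptor expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StimulusMapping",
    "HillCurve",
    "HillFit",
    "StimulusProfiles",
    "secretion_time_profile",
    "receptor_time_profile",
    "positivity_time_window",
    "fit_stimulus_curve",
    "build_profiles",
    "default_profiles",
    "DEFAULT_PHI",
    "DEFAULT_GAMMA",
]


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative (hours post-immunization)")
    return t


def secretion_time_profile(t_hours):
    """IL-2 secretion time factor T_sec(t) ∈ [0, 1].

    Piecewise linear: 0 at t=0, rises to 1 at t=9 h, falls back to 0 at
    t=18 h and stays 0 afterwards.
    """
    t = _check_times(t_hours)
    out = np.interp(t, [0.0, 9.0, 18.0], [0.0, 1.0, 0.0])
    return float(out) if np.isscalar(t_hours) else out


def receptor_time_profile(t_hours):
    """CD25 expression time factor T_rec(t) ∈ [0, 1]: peak at 18 h, 0 from 30 h."""
    t = _check_times(t_hours)
    out = np.interp(t, [0.0, 18.0, 30.0], [0.0, 1.0, 0.0])
    return float(out) if np.isscalar(t_hours) else out


def positivity_time_window(t_hours):
    """Time weighting of the *measured* marker-positive fraction.

    A secretion-assay or phospho-stain readout scores a cell positive if it is
    actively expressing around the sampling time; the positive fraction
    plateaus while expression is ongoing (roughly 6-18 h) rather than tracking
    the instantaneous secretion rate.  Trapezoid: ramp 0-6 h, plateau 6-18 h,
    decay to 0 at 24 h.
    """
    t = _check_times(t_hours)
    out = np.interp(t, [0.0, 6.0, 18.0, 24.0], [0.0, 1.0, 1.0, 0.0])
    return float(out) if np.isscalar(t_hours) else out


@dataclass(frozen=True)
class StimulusMapping:
    """Linear map from antigen dose (µg) to normalized stimulus A ∈ [0, 1]."""

    dose_max: float = 2000.0

    def __post_init__(self):
        if self.dose_max <= 0:
            raise ValueError("dose_max must be positive")

    def stimulus(self, dose_ug):
        dose = np.asarray(dose_ug, dtype=float)
        if np.any(dose < 0):
            raise ValueError("doses must be non-negative")
        out = np.clip(dose / self.dose_max, 0.0, 1.0)
        return float(out) if np.isscalar(dose_ug) else out

    __call__ = stimulus


@dataclass(frozen=True)
class HillCurve:
    """Monotone saturating dose-response curve on the unit stimulus interval.

    value(A) = floor + (ceiling - floor) * w(A) with the rescaled Hill weight

        w(A) = A^h (1 + A50^h) / (A^h + A50^h),

    so that w(0) = 0 and w(1) = 1 exactly: the ceiling is attained at full
    stimulus.  ``a50`` is the half-point on the A scale (w(a50) ≈ 1/2 for
    small a50) and ``h`` the steepness coefficient.
    """

    floor: float
    ceiling: float
    a50: float
    h: float

    def __post_init__(self):
        if self.ceiling < self.floor:
            raise ValueError("ceiling must be >= floor")
        if not (0.0 < self.a50 <= 1.0):
            raise ValueError("a50 must lie in (0, 1]")
        if self.h <= 0:
            raise ValueError("Hill coefficient must be positive")

    def weight(self, a):
        a = np.asarray(a, dtype=float)
        ah = np.power(np.clip(a, 0.0, 1.0), self.h)
        kh = self.a50 ** self.h
        return ah * (1.0 + kh) / (ah + kh + 1e-300)

    def value(self, a):
        out = self.floor + (self.ceiling - self.floor) * self.weight(a)
        return float(out) if np.isscalar(a) else out

    __call__ = value

    def weight_quantile(self, q: float) -> float:
        """Stimulus A at which the normalized weight equals q ∈ (0, 1)."""
        if not (0.0 < q < 1.0):
            raise ValueError("q must be in (0, 1)")
        kh = self.a50 ** self.h
        return float((q * kh / (1.0 + kh - q)) ** (1.0 / self.h))

    def linear_range_width(self, lo: float = 0.1, hi: float = 0.9) -> float:
        """Width of the A interval over which the curve runs from lo to hi
        of its dynamic range (default 10-90%): a measure of gradedness."""
        return self.weight_quantile(hi) - self.weight_quantile(lo)

    def to_dict(self) -> dict:
        return {"floor": self.floor, "ceiling": self.ceiling,
                "a50": self.a50, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "HillCurve":
        return cls(**d)


#: Default producer-fraction curve: up to 75% of antigen-specific Th cells
#: secrete IL-2 at the maximal dose; half-point at A=0.0625 (125 µg of 2 mg).
DEFAULT_PHI = HillCurve(floor=0.0, ceiling=0.75, a50=0.0625, h=1.0)

#: Default CD25 capacity curves.  Treg cells express CD25 constitutively
#: (high floor) while Th cells acquire it only upon antigen stimulation.
DEFAULT_GAMMA: Dict[str, HillCurve] = {
    "Th": HillCurve(floor=0.05, ceiling=1.0, a50=0.0625, h=1.0),
    "Treg": HillCurve(floor=0.80, ceiling=1.0, a50=0.0625, h=1.0),
}


@dataclass
class HillFit:
    curve: HillCurve
    rss: float
    degenerate: bool = False
    monotone_warning: bool = False


def fit_stimulus_curve(doses_ug, values, mapping: StimulusMapping | None = None,
                       fix_floor: Optional[float] = None) -> HillFit:
    """Least-squares Hill fit of per-dose summaries on the A scale.

    ``values`` may be positive fractions, percentages or MFI-derived levels;
    the fitted floor/ceiling adopt their scale.  Requires ≥4 dose points
    including dose 0 and the maximal dose.  A non-monotone-beyond-noise input
    is flagged (fit proceeds); a flat input yields a degenerate fit flag.
    """
    mapping = mapping or StimulusMapping()
    doses = np.asarray(doses_ug, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(doses) != len(y):
        raise ValueError("doses and values must have equal length")
    if len(doses) < 4:
        raise ValueError("need at least 4 dose points for a Hill fit")
    if not np.any(doses == 0):
        raise ValueError("dose grid must include the unimmunized anchor (0)")
    if not np.any(doses >= mapping.dose_max):
        raise ValueError("dose grid must include the maximal dose")
    order = np.argsort(doses)
    doses, y = doses[order], y[order]
    a = mapping.stimulus(doses)

    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1.0)
    if span < 1e-9 * scale:
        # flat input: h unidentifiable
        curve = HillCurve(floor=float(y.mean()), ceiling=float(y.mean()) + 1e-12,
                          a50=0.5, h=1.0)
        return HillFit(curve=curve, rss=float(np.sum((y - y.mean()) ** 2)),
                       degenerate=True)
    # monotonicity check against a noise allowance of 10% of the span
    monotone_warning = bool(np.any(np.diff(y) < -0.1 * span))

    def model(aa, floor, ceiling, a50, h):
        return HillCurve(floor, max(ceiling, floor), np.clip(a50, 1e-6, 1.0),
                         max(h, 1e-6)).value(aa)

    if fix_floor is None:
        p0 = [float(y[0]), float(y[-1]), 0.1, 1.0]
        bounds = ([-np.inf, -np.inf, 1e-6, 1e-3], [np.inf, np.inf, 1.0, 20.0])
        popt, _ = curve_fit(model, a, y, p0=p0, bounds=bounds, maxfev=20000)
        floor, ceiling, a50, h = popt
    else:
        def model_ff(aa, ceiling, a50, h):
            return model(aa, fix_floor, ceiling, a50, h)
        p0 = [float(y[-1]), 0.1, 1.0]
        bounds = ([-np.inf, 1e-6, 1e-3], [np.inf, 1.0, 20.0])
        popt, _ = curve_fit(model_ff, a, y, p0=p0, bounds=bounds, maxfev=20000)
        ceiling, a50, h = popt
        floor = fix_floor
    curve = HillCurve(float(floor), float(max(ceiling, floor)),
                      float(np.clip(a50, 1e-6, 1.0)), float(max(h, 1e-6)))
    rss = float(np.sum((curve.value(a) - y) ** 2))
    return HillFit(curve=curve, rss=rss, monotone_warning=monotone_warning)


@dataclass
class StimulusProfiles:
    """Bundle of calibrated stimulus/time factors used by the spatial model.

    f(A, t) for secretion is scenario-dependent (see the spatial model): the
    producer fraction φ(A) enters either as the fraction of secreting cells
    (binary) or as a per-producer rate scale (graded), multiplied by T_sec(t).
    g(A, t) = γ_pop(A)·T_rec(t) scales receptor-mediated uptake.
    """

    phi: HillCurve = field(default_factory=lambda: DEFAULT_PHI)
    gamma: Dict[str, HillCurve] = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    mapping: StimulusMapping = field(default_factory=StimulusMapping)

    def __post_init__(self):
        for pop in ("Th", "Treg"):
            if pop not in self.gamma:
                raise ValueError(f"missing CD25 capacity curve for population {pop!r}")
        if not self.gamma["Treg"].value(0.0) > self.gamma["Th"].value(0.0):
            raise ValueError("Treg CD25 capacity must exceed Th at zero stimulus")

    t_sec = staticmethod(secretion_time_profile)
    t_rec = staticmethod(receptor_time_profile)

    @property
    def p_max(self) -> float:
        """Maximal producer fraction φ(1)."""
        return float(self.phi.value(1.0))

    def secretion_factor(self, a, t_hours):
        """f(A, t) = φ(A)·T_sec(t): population-mean secretion factor."""
        return self.phi.value(a) * secretion_time_profile(t_hours)

    def receptor_factor(self, population: str, a, t_hours):
        """g(A, t) = γ_pop(A)·T_rec(t)."""
        return self.gamma[population].value(a) * receptor_time_profile(t_hours)

    def to_dict(self) -> dict:
        return {
            "phi": self.phi.to_dict(),
            "gamma": {k: v.to_dict() for k, v in self.gamma.items()},
            "dose_max": self.mapping.dose_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProfiles":
        return cls(phi=HillCurve.from_dict(d["phi"]),
                   gamma={k: HillCurve.from_dict(v) for k, v in d["gamma"].items()},
                   mapping=StimulusMapping(d.get("dose_max", 2000.0)))

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StimulusProfiles":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_profiles(il2_curve: HillCurve, cd25_curves: Dict[str, HillCurve],
                   mapping: StimulusMapping | None = None) -> StimulusProfiles:
    """Bundle fitted curves into :class:`StimulusProfiles` (validating Treg > Th
    baseline CD25)."""
    return StimulusProfiles(phi=il2_curve, gamma=dict(cd25_curves),
                            mapping=mapping or StimulusMapping())


def default_profiles() -> StimulusProfiles:
    """Profiles built from the default (text-anchored) calibration."""
    return StimulusProfiles()
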