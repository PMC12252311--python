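"""Regression metrics and intensity-zone-stratified error analysis.

Prediction quality is summarised with RMSE, MAE and the coefficient of
determination R², all in the label's units (L/min for VO₂).  Errors are
additionally stratified into ACSM exercise-intensity zones — low, moderate
and high — defined either by absolute VO₂ cutoffs (1.80 and 2.51 L/min) or
relative to the individual's VO₂max (46% and 64%), since prediction error
is known to concentrate in the high-intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ZONES = ("low", "moderate", "high")

#: Absolute VO2 zone cutoffs, L/min: [0, 1.80) low, [1.80, 2.51) moderate,
#: [2.51, inf) high.  The printed moderate band ends at 2.47 and the high
#: band starts at 2.51; the gap is closed at the inclusive high bound.
ABSOLUTE_CUTOFFS = (1.80, 2.51)

#: Relative cutoffs as fractions of VO2max: <46% low, [46%, 64%) moderate.
RELATIVE_CUTOFFS = (0.46, 0.64)


class DegenerateTargetError(ValueError):
    """Raised when R² is requested for a constant target vector."""


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D arrays of equal length")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean square error, sqrt(mean((y - yhat)^2))."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    """Mean absolute error, mean(|y - yhat|)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def r2(y, yhat) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot.

    Not clamped: a model worse than the mean predictor yields a negative
    value, which is reported as computed.
    """
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateTargetError("R² undefined for a constant target")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class Metrics:
    rmse: float
    mae: float
    r2: float
    n: int

    @classmethod
    def compute(cls, y, yhat) -> "Metrics":
        y, yhat = _check_pair(y, yhat)
        return cls(rmse=rmse(y, yhat), mae=mae(y, yhat), r2=r2(y, yhat), n=y.size)


def hr_max(age: float) -> float:
    """Age-predicted maximal heart rate, 208 − 0.7·age (beats/min)."""
    if age <= 0:
        raise ValueError("age must be positive")
    return 208.0 - 0.7 * age


def assign_zone(vo2: float, mode: str = "absolute", vo2max: float | None = None) -> str:
    """Classify a VO₂ value (L/min) into an ACSM intensity zone.

    mode="absolute" uses fixed L/min cutoffs; mode="relative" uses the
    fraction of the individual's VO₂max and requires `vo2max`.
    """
    if vo2 < 0:
        raise ValueError("vo2 must be non-negative")
    if mode == "absolute":
        lo, hi = ABSOLUTE_CUTOFFS
        x = vo2
    elif mode == "relative":
        if vo2max is None:
            raise ValueError("relative mode requires vo2max")
        lo, hi = RELATIVE_CUTOFFS
        x = vo2 / vo2max
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if x < lo:
        return "low"
    if x < hi:
        return "moderate"
    return "high"


def assign_zones(vo2, mode: str = "absolute", vo2max=None) -> np.ndarray:
    """Vectorised zone assignment; `vo2max` may be scalar or per-sample."""
    vo2 = np.asarray(vo2, dtype=float)
    if mode == "relative":
        if vo2max is None:
            raise ValueError("relative mode requires vo2max")
        frac = vo2 / np.asarray(vo2max, dtype=float)
        lo, hi = RELATIVE_CUTOFFS
    else:
        frac = vo2
        lo, hi = ABSOLUTE_CUTOFFS
    out = np.where(frac < lo, "low", np.where(frac < hi, "moderate", "high"))
    return out.astype(object)


@dataclass(frozen=True)
class ZoneReport:
    """Per-zone metrics plus mean signed error (prediction − truth)."""

    metrics: dict = field(default_factory=dict)      # zone -> Metrics | None
    signed_error: dict = field(default_factory=dict)  # zone -> float | None
    counts: dict = field(default_factory=dict)        # zone -> int
    cutoffs: tuple = ABSOLUTE_CUTOFFS

    def to_dict(self) -> dict:
        out = {"cutoffs": list(self.cutoffs), "zones": {}}
        for z in ZONES:
            m = self.metrics[z]
            out["zones"][z] = {
                "n": self.counts[z],
                "rmse": None if m is None else m.rmse,
                "mae": None if m is None else m.mae,
                "r2": None if m is None else m.r2,
                "mean_signed_error": self.signed_error[z],
            }
        return out


def zone_report(y, yhat, zones, cutoffs=ABSOLUTE_CUTOFFS) -> ZoneReport:
    """Stratify prediction errors by intensity zone.

    An empty zone is reported with n=0 and null metrics rather than raising.
    R² inside a zone with a constant target is likewise reported as null.
    """
    y, yhat = _check_pair(y, yhat)
    zones = np.asarray(zones, dtype=object)
    if zones.shape != y.shape:
        raise ValueError("zones must align with y")
    metrics, signed, counts = {}, {}, {}
    for z in ZONES:
        mask = zones == z
        n = int(mask.sum())
        counts[z] = n
        if n == 0:
            metrics[z] = None
            signed[z] = None
            continue
        yz, yhz = y[mask], yhat[mask]
        try:
            mz = Metrics.compute(yz, yhz)
        except DegenerateTargetError:
            mz = Metrics(rmse=rmse(yz, yhz), mae=mae(yz, yhz), r2=float("nan"), n=n)
        metrics[z] = mz
        signed[z] = float(np.mean(yhz - yz))
    return ZoneReport(metrics=metrics, signed_error=signed, counts=counts,
                      cutoffs=tuple(cutoffs))
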