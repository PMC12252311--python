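"""Preprocessing: Kalman smoothing, alignment, windowing, standardization.

Raw CPET streams arrive at three rates (accelerometer 10 Hz, heart rate
1 Hz, breath-gas VO₂ 0.1 Hz).  The pipeline:

1. smooths each accelerometer axis with a scalar random-walk Kalman filter
   (A=H=1, Q=0.01 g², R=0.10 g², P₀=1 g², x̂₀ = first measurement);
2. downsamples the filtered axes to 1 Hz by per-second averaging and adds
   the vector magnitude VM = √(ax²+ay²+az²);
3. joins with heart rate on integer-second timestamps over the overlap of
   both streams, giving the five dynamic features (HR, ax, ay, az, VM);
4. cuts non-overlapping 10-s windows, one per VO₂ sample, serialising the
   dynamic features in 1-s increments (10×5 block) with the VO₂ value as
   the window label; missing cells are filled with that window's
   per-feature mean;
5. Z-scores dynamic and static features with statistics from a fit set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import STATIC_FEATURE_NAMES, RawSession

DYNAMIC_FEATURE_NAMES = ("hr", "ax", "ay", "az", "vm")
WINDOW_LEN = 10  # seconds, = rows per window at 1 Hz


class DegenerateFeatureError(ValueError):
    """Raised when a feature has zero variance on the scaler fit set."""


@dataclass(frozen=True)
class KalmanParams:
    """Scalar random-walk state-observation model x_k = x_{k-1} + w, z = x + v."""

    A: float = 1.0
    H: float = 1.0
    Q: float = 0.01   # process noise variance, g^2
    R: float = 0.10   # observation noise variance, g^2
    P0: float = 1.0   # initial covariance, g^2

    def __post_init__(self):
        if self.Q <= 0 or self.R <= 0 or self.P0 <= 0:
            raise ValueError("Q, R and P0 must be strictly positive")

    def steady_state_gain(self) -> float:
        """Closed-form limit of the Kalman gain.

        The covariance recursion P⁻ = P + Q, K = P⁻/(P⁻+R), P = (1−K)P⁻
        has fixed point P* solving P*² + Q·P* − QR = 0, so
        P* = (−Q + √(Q² + 4QR))/2 and K∞ = (P*+Q)/(P*+Q+R).
        """
        p_star = (-self.Q + np.sqrt(self.Q ** 2 + 4.0 * self.Q * self.R)) / 2.0
        return float((p_star + self.Q) / (p_star + self.Q + self.R))


def kalman_filter_1d(z, params: KalmanParams = KalmanParams()) -> np.ndarray:
    """Filter one measurement series with the scalar predict/update recursion.

    Initialised at the first measurement; output has the input's length.
    NaNs are rejected — gaps are handled later, at the window stage.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("input must be a non-empty 1-D series")
    if not np.all(np.isfinite(z)):
        raise ValueError("input contains non-finite values")
    out = np.empty_like(z)
    x, p = z[0], params.P0
    out[0] = x
    for k in range(1, z.size):
        p_pred = p + params.Q
        gain = p_pred / (p_pred + params.R)
        x = x + gain * (z[k] - x)
        p = (1.0 - gain) * p_pred
        out[k] = x
    return out


def vector_magnitude(ax, ay, az) -> np.ndarray:
    """Euclidean norm of the three acceleration axes, elementwise (g)."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError("axis series must share a length")
    return np.sqrt(ax ** 2 + ay ** 2 + az ** 2)


def downsample_accel(accel: pd.DataFrame) -> pd.DataFrame:
    """Average 10 Hz accelerometer samples into 1 Hz bins [t, t+1).

    Seconds with no samples (sensor dropouts) yield NaN rows, which the
    window stage later imputes.  Columns other than the timestamp are
    averaged as-is.
    """
    if accel.empty:
        raise ValueError("empty accelerometer stream")
    sec = np.floor(accel["timestamp_s"].to_numpy()).astype(int)
    value_cols = [c for c in accel.columns if c != "timestamp_s"]
    grouped = accel[value_cols].groupby(sec).mean()
    grid = np.arange(sec.min(), sec.max() + 1)
    out = grouped.reindex(grid)
    out.insert(0, "timestamp_s", grid.astype(float))
    return out.reset_index(drop=True)


def align_streams(session: RawSession,
                  params: KalmanParams = KalmanParams()) -> pd.DataFrame:
    """Kalman-filter, downsample and join the dynamic streams at 1 Hz.

    Returns a frame with columns timestamp_s, hr, ax, ay, az, vm covering
    the integer-second overlap of the accelerometer and heart-rate streams.
    Heart-rate gaps appear as NaN for the window stage to impute.
    """
    accel = session.accel.copy()
    for col in ("ax_g", "ay_g", "az_g"):
        accel[col] = kalman_filter_1d(accel[col].to_numpy(), params)
    acc1 = downsample_accel(accel)
    hr = session.hr
    lo = max(int(acc1["timestamp_s"].min()), int(np.floor(hr["timestamp_s"].min())))
    hi = min(int(acc1["timestamp_s"].max()), int(np.floor(hr["timestamp_s"].max())))
    if hi < lo:
        raise ValueError("streams have no temporal overlap")
    grid = np.arange(lo, hi + 1)
    acc1 = acc1.set_index(acc1["timestamp_s"].astype(int)).reindex(grid)
    hr_series = hr.set_index(hr["timestamp_s"].astype(int))["hr_bpm"].reindex(grid)
    out = pd.DataFrame({
        "timestamp_s": grid.astype(float),
        "hr": hr_series.to_numpy(),
        "ax": acc1["ax_g"].to_numpy(),
        "ay": acc1["ay_g"].to_numpy(),
        "az": acc1["az_g"].to_numpy(),
    })
    out["vm"] = vector_magnitude(out["ax"], out["ay"], out["az"])
    return out


@dataclass(frozen=True)
class Scaler:
    """Per-feature Z-score statistics (population σ), fit-set only."""

    dynamic_mean: np.ndarray
    dynamic_std: np.ndarray
    static_mean: np.ndarray
    static_std: np.ndarray
    dynamic_names: tuple = DYNAMIC_FEATURE_NAMES
    static_names: tuple = STATIC_FEATURE_NAMES

    def to_dict(self) -> dict:
        return {"dynamic_mean": self.dynamic_mean.tolist(),
                "dynamic_std": self.dynamic_std.tolist(),
                "static_mean": self.static_mean.tolist(),
                "static_std": self.static_std.tolist(),
                "dynamic_names": list(self.dynamic_names),
                "static_names": list(self.static_names)}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(dynamic_mean=np.array(d["dynamic_mean"]),
                   dynamic_std=np.array(d["dynamic_std"]),
                   static_mean=np.array(d["static_mean"]),
                   static_std=np.array(d["static_std"]),
                   dynamic_names=tuple(d["dynamic_names"]),
                   static_names=tuple(d["static_names"]))


@dataclass(frozen=True)
class WindowSet:
    """Model-ready examples: (10×d dynamic block, 6 static values, VO₂ label)."""

    dynamic: np.ndarray        # (n, 10, n_dynamic)
    static: np.ndarray         # (n, 6)
    labels: np.ndarray         # (n,) VO2 L/min — never standardized
    subject_ids: np.ndarray    # (n,) str
    dynamic_names: tuple = DYNAMIC_FEATURE_NAMES
    dropped_windows: int = 0
    scaler: Scaler | None = None
    vo2max: np.ndarray | None = None  # per-window subject VO2max (latent)

    def __post_init__(self):
        n = self.dynamic.shape[0]
        if not (self.static.shape[0] == self.labels.shape[0]
                == self.subject_ids.shape[0] == n):
            raise ValueError("inconsistent window counts")

    def __len__(self):
        return self.dynamic.shape[0]

    def subset(self, mask) -> "WindowSet":
        mask = np.asarray(mask)
        return replace(self, dynamic=self.dynamic[mask], static=self.static[mask],
                       labels=self.labels[mask], subject_ids=self.subject_ids[mask],
                       vo2max=None if self.vo2max is None else self.vo2max[mask])

    def for_subjects(self, subjects) -> "WindowSet":
        return self.subset(np.isin(self.subject_ids, list(subjects)))

    def select_features(self, names) -> "WindowSet":
        """Restrict the dynamic block to a named feature subset (e.g. HR only)."""
        idx = [self.dynamic_names.index(n) for n in names]
        return replace(self, dynamic=self.dynamic[:, :, idx],
                       dynamic_names=tuple(names), scaler=None)

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.subject_ids.tolist()))


def concat_windows(sets: list[WindowSet]) -> WindowSet:
    if not sets:
        raise ValueError("no window sets")
    names = sets[0].dynamic_names
    if any(s.dynamic_names != names for s in sets):
        raise ValueError("feature mismatch")
    vo2max = (None if any(s.vo2max is None for s in sets)
              else np.concatenate([s.vo2max for s in sets]))
    return WindowSet(
        dynamic=np.concatenate([s.dynamic for s in sets]),
        static=np.concatenate([s.static for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        subject_ids=np.concatenate([s.subject_ids for s in sets]),
        dynamic_names=names,
        dropped_windows=sum(s.dropped_windows for s in sets))


def make_windows(aligned: pd.DataFrame, vo2: pd.DataFrame,
                 profile=None) -> WindowSet:
    """Cut one 10-s window per VO₂ sample whose support lies in the aligned range.

    The VO₂ timestamp marks the END of its window (gas analyzers report
    breath-averaged values over the preceding interval), so the sample at
    time t labels aligned seconds [t−10, t).  Missing cells are replaced by
    the window's per-feature mean; a window where a whole feature is missing
    is dropped and counted.
    """
    cols = list(DYNAMIC_FEATURE_NAMES)
    t0 = int(aligned["timestamp_s"].iloc[0])
    t1 = int(aligned["timestamp_s"].iloc[-1])
    block = aligned[cols].to_numpy()
    dyn, labels, dropped = [], [], 0
    for ts, y in zip(vo2["timestamp_s"].to_numpy(), vo2["vo2_lmin"].to_numpy()):
        start = int(ts) - WINDOW_LEN
        if start < t0 or int(ts) - 1 > t1:
            continue
        w = block[start - t0:start - t0 + WINDOW_LEN].copy()
        if np.isnan(w).any():
            if np.isnan(w).all(axis=0).any():
                dropped += 1
                continue
            col_mean = np.nanmean(w, axis=0)
            nan_r, nan_c = np.where(np.isnan(w))
            w[nan_r, nan_c] = col_mean[nan_c]
        dyn.append(w)
        labels.append(y)
    if not dyn:
        raise ValueError("no complete windows in the aligned range")
    n = len(dyn)
    if profile is not None:
        static = np.tile(profile.static_features, (n, 1))
        sids = np.array([profile.subject_id] * n)
        vo2max = np.full(n, profile.vo2max)
    else:
        static = np.zeros((n, len(STATIC_FEATURE_NAMES)))
        sids = np.array(["?"] * n)
        vo2max = None
    return WindowSet(dynamic=np.array(dyn), static=static,
                     labels=np.array(labels), subject_ids=sids,
                     dropped_windows=dropped, vo2max=vo2max)


def windows_from_session(session: RawSession,
                         params: KalmanParams = KalmanParams()) -> WindowSet:
    """Full per-session pipeline: align, window, label."""
    aligned = align_streams(session, params)
    return make_windows(aligned, session.vo2, profile=session.profile)


def windows_from_cohort(sessions: list[RawSession],
                        params: KalmanParams = KalmanParams()) -> WindowSet:
    return concat_windows([windows_from_session(s, params) for s in sessions])


def zscore_fit(windows: WindowSet) -> Scaler:
    """Fit per-feature Z-score statistics on a (training) window set.

    Dynamic features pool all windows and time steps per feature; each
    static feature is fit separately.  Population σ (divide by N).
    """
    dyn = windows.dynamic.reshape(-1, windows.dynamic.shape[-1])
    d_mu, d_sd = dyn.mean(axis=0), dyn.std(axis=0)
    s_mu, s_sd = windows.static.mean(axis=0), windows.static.std(axis=0)
    for names, mus, sds in ((windows.dynamic_names, d_mu, d_sd),
                            (STATIC_FEATURE_NAMES, s_mu, s_sd)):
        for name, mu, sd in zip(names, mus, sds):
            if sd <= 1e-12 * max(1.0, abs(mu)):
                raise DegenerateFeatureError(
                    f"feature {name!r} has zero variance on the fit set")
    return Scaler(dynamic_mean=d_mu, dynamic_std=d_sd,
                  static_mean=s_mu, static_std=s_sd,
                  dynamic_names=windows.dynamic_names)


def zscore_apply(scaler: Scaler, windows: WindowSet) -> WindowSet:
    """Standardize a window set with a previously fit scaler (labels untouched)."""
    if scaler.dynamic_names != windows.dynamic_names:
        raise ValueError("scaler fit on a different dynamic feature set")
    dyn = (windows.dynamic - scaler.dynamic_mean) / scaler.dynamic_std
    stat = (windows.static - scaler.static_mean) / scaler.static_std
    return replace(windows, dynamic=dyn, static=stat, scaler=scaler)


# ---------------------------------------------------------------------------
# Cohort-level window storage: one .npz plus a JSON sidecar.

def save_windows(windows: WindowSet, path) -> None:
    path = Path(path)
    arrays = {"dynamic": windows.dynamic, "static": windows.static,
              "labels": windows.labels,
              "subject_ids": windows.subject_ids.astype(str)}
    if windows.vo2max is not None:
        arrays["vo2max"] = windows.vo2max
    np.savez(path, **arrays)
    sidecar = {"dynamic_names": list(windows.dynamic_names),
               "dropped_windows": windows.dropped_windows,
               "scaler": None if windows.scaler is None else windows.scaler.to_dict()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                    sort_keys=True) + "\n")


def load_windows(path) -> WindowSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    data = np.load(path, allow_pickle=False)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    scaler = (None if sidecar["scaler"] is None
              else Scaler.from_dict(sidecar["scaler"]))
    return WindowSet(dynamic=data["dynamic"], static=data["static"],
                     labels=data["labels"],
                     subject_ids=data["subject_ids"].astype(object),
                     dynamic_names=tuple(sidecar["dynamic_names"]),
                     dropped_windows=sidecar["dropped_windows"],
                     scaler=scaler,
                     vo2max=data["vo2max"] if "vo2max" in data else None)
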