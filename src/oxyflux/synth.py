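"""Synthetic subjects and ramp-protocol cardiopulmonary exercise tests.

The generator emulates the data a treadmill CPET produces: a linear speed
ramp (1 km/h per minute at 0% incline), wrist-worn triaxial accelerometry at
10 Hz whose rhythmic amplitude and noise grow with intensity, a chest-strap
heart rate at 1 Hz and breath-gas VO₂ at 0.1 Hz, both following first-order
(mono-exponential) kinetics toward ramp-dependent targets that plateau near
the individual's HRmax and VO₂max.  A session terminates when heart rate
reaches 90% of age-predicted HRmax, or at the protocol's maximum duration.

All latent quantities (the noiseless intensity→VO₂ mapping, kinetic time
constants, peak speed) are kept on the session so model-recovery tests can
score predictions against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .evaluate import hr_max

SEXES = ("male", "female")

# Cohort anthropometrics (mean, sd) used as sampling distributions:
# age yr, height m, weight kg, body-fat %.
_ANTHRO = {
    "male": {"age": (24, 3), "height": (1.76, 0.08), "weight": (70.6, 13.3),
             "body_fat_pct": (16.2, 5.8)},
    "female": {"age": (25, 3), "height": (1.63, 0.05), "weight": (52.3, 6.0),
               "body_fat_pct": (23.7, 3.4)},
}
# Relative fitness (VO2max in mL/kg/min): sex-specific mean/sd and bounds.
# Absolute VO2max is mass-scaled, body-fat-adjusted and coupled to resting
# heart rate (fitter subjects have lower resting HR), as in real cohorts, so
# the static features carry information about an individual's VO2 range.
_REL_VO2MAX = {"male": (48.0, 3.0, 36.0, 62.0), "female": (40.0, 3.0, 30.0, 52.0)}
_VO2MAX_BOUNDS = (2.0, 4.5)  # plausible absolute range, L/min


def _tnorm(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


@dataclass(frozen=True)
class SubjectProfile:
    """Static per-subject features plus the latent VO₂max ground truth."""

    subject_id: str
    sex: str
    age: int
    weight: float           # kg
    height: float           # m
    bmi: float              # kg/m^2
    body_fat_pct: float
    resting_vo2: float      # L/min
    resting_hr: float       # beats/min
    vo2max: float           # L/min (latent; never a model input)

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        for name in ("age", "weight", "height", "bmi", "body_fat_pct",
                     "resting_vo2", "resting_hr", "vo2max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if abs(self.bmi - self.weight / self.height ** 2) > 0.01 * self.bmi:
            raise ValueError("bmi inconsistent with weight/height")
        if self.resting_hr >= hr_max(self.age):
            raise ValueError("resting_hr must be below HRmax")
        if self.resting_vo2 >= self.vo2max:
            raise ValueError("resting_vo2 must be below vo2max")

    @property
    def static_features(self) -> np.ndarray:
        """The six static model inputs, in fixed order."""
        return np.array([self.weight, self.height, self.bmi, self.body_fat_pct,
                         self.resting_vo2, self.resting_hr])


STATIC_FEATURE_NAMES = ("weight", "height", "bmi", "body_fat_pct",
                        "resting_vo2", "resting_hr")


@dataclass(frozen=True)
class RampProtocol:
    """Incremental treadmill protocol: linear speed ramp at fixed incline."""

    start_speed: float = 4.0     # km/h
    increment: float = 1.0       # km/h per minute
    incline_pct: float = 0.0
    max_duration: float = 900.0  # s

    def __post_init__(self):
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if self.start_speed <= 0 or self.max_duration <= 0:
            raise ValueError("start_speed and max_duration must be positive")

    def speed(self, t):
        return self.start_speed + self.increment * np.asarray(t, float) / 60.0


@dataclass(frozen=True)
class SessionLatent:
    """Noiseless generative state exposed for parameter-recovery tests."""

    t: np.ndarray          # 1 Hz seconds
    speed: np.ndarray      # km/h
    intensity: np.ndarray  # fraction of peak speed, in [0, 1]
    hr_true: np.ndarray    # beats/min
    vo2_true: np.ndarray   # L/min
    peak_speed: float      # km/h at which targets saturate
    tau_hr: float          # s
    tau_vo2: float         # s


@dataclass(frozen=True)
class RawSession:
    """Unaligned multi-rate streams for one subject's CPET."""

    profile: SubjectProfile
    accel: pd.DataFrame    # timestamp_s, ax_g, ay_g, az_g at 10 Hz
    hr: pd.DataFrame       # timestamp_s, hr_bpm at 1 Hz
    vo2: pd.DataFrame      # timestamp_s, vo2_lmin at 0.1 Hz
    termination_reason: str
    latent: SessionLatent


def sample_profile(rng_seed: int, sex: str, subject_id: str = "S00") -> SubjectProfile:
    """Draw a subject from sex-specific truncated-normal distributions.

    BMI is recomputed from the sampled weight and height rather than drawn;
    resting VO₂ scales with body mass (≈3.5 mL/kg/min with individual
    variation) and resting HR is drawn in the normal adult range.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    rng = np.random.default_rng(rng_seed)
    a = _ANTHRO[sex]
    age = int(round(_tnorm(rng, *a["age"], 20, 30)))
    height = _tnorm(rng, *a["height"], 1.45, 2.05)
    weight = _tnorm(rng, *a["weight"], 40.0, 115.0)
    body_fat = _tnorm(rng, *a["body_fat_pct"], 5.0, 40.0)
    resting_hr = _tnorm(rng, 62.0, 8.0, 45.0, 85.0)
    resting_vo2 = 0.0035 * weight * _tnorm(rng, 1.0, 0.10, 0.7, 1.3)
    mu, sd, lo, hi = _REL_VO2MAX[sex]
    bf_mean = _ANTHRO[sex]["body_fat_pct"][0]
    # truncate the relative-fitness draw so the absolute value stays in the
    # plausible range without piling probability mass at the bounds
    lo = max(lo, _VO2MAX_BOUNDS[0] * 1000.0 / weight)
    hi = min(hi, _VO2MAX_BOUNDS[1] * 1000.0 / weight)
    rel_mu = mu - 0.4 * (body_fat - bf_mean) - 0.5 * (resting_hr - 62.0)
    rel = _tnorm(rng, rel_mu, sd, min(lo, hi - 1e-6), hi)
    vo2max = max(weight * rel / 1000.0, resting_vo2 * 2.5)
    return SubjectProfile(
        subject_id=subject_id, sex=sex, age=age,
        weight=round(weight, 2), height=round(height, 3),
        bmi=round(weight / height ** 2, 3), body_fat_pct=round(body_fat, 2),
        resting_vo2=round(resting_vo2, 4), resting_hr=round(resting_hr, 1),
        vo2max=round(vo2max, 4),
    )


def simulate_session(profile: SubjectProfile,
                     protocol: RampProtocol | None = None,
                     rng_seed: int = 0,
                     noise_scale: float = 1.0,
                     missing_frac: float = 0.0) -> RawSession:
    """Simulate one ramp CPET for a subject.

    HR and VO₂ each follow first-order kinetics x' = (target(t) − x)/τ where
    the target rises linearly with treadmill speed up to the subject's peak
    speed, then saturates at HRmax / VO₂max.  `noise_scale` multiplies every
    observation-noise standard deviation (0 gives noiseless streams whose
    VO₂ is exactly the first-order filter of intensity); `missing_frac`
    removes that fraction of interior 1 Hz heart-rate samples and whole
    accelerometer seconds, to exercise downstream window-mean imputation.
    """
    if protocol is None:
        protocol = RampProtocol()
    if not 0.0 <= missing_frac < 0.5:
        raise ValueError("missing_frac must be in [0, 0.5)")
    rng = np.random.default_rng(rng_seed)
    hrmax = hr_max(profile.age)

    # Subject-level kinetic latents.
    tau_hr = float(rng.uniform(25.0, 45.0))
    tau_vo2 = float(rng.uniform(20.0, 40.0))
    # Peak speed: ramp speed at which the subject would reach VO2max,
    # scaling with relative fitness (mL/kg/min).
    rel = profile.vo2max / profile.weight * 1000.0
    peak_speed = 10.5 + 0.18 * (rel - 40.0) + float(rng.normal(0.0, 0.5))

    # Integrate latent dynamics at 1 Hz until termination.
    n_max = int(protocol.max_duration)
    t = np.arange(n_max + 1, dtype=float)
    speed = protocol.speed(t)
    frac = np.clip(speed / peak_speed, 0.0, 1.0)
    hr_true = np.empty(n_max + 1)
    vo2_true = np.empty(n_max + 1)
    hr_true[0] = profile.resting_hr + frac[0] * 10.0  # warm-up offset
    vo2_true[0] = profile.resting_vo2 + frac[0] * 0.1
    hr_target = profile.resting_hr + (hrmax - profile.resting_hr) * frac
    vo2_target = profile.resting_vo2 + (profile.vo2max - profile.resting_vo2) * frac
    end = n_max
    reason = "max_duration"
    for k in range(1, n_max + 1):
        hr_true[k] = hr_true[k - 1] + (hr_target[k] - hr_true[k - 1]) / tau_hr
        vo2_true[k] = vo2_true[k - 1] + (vo2_target[k] - vo2_true[k - 1]) / tau_vo2
        if hr_true[k] >= 0.9 * hrmax:
            end = k
            reason = "hr_criterion"
            break
    # Round the session length down to a whole 10-s gas-analyzer interval.
    dur = max(60, (end // 10) * 10)
    t = t[:dur]
    speed, frac = speed[:dur], frac[:dur]
    hr_true, vo2_true = hr_true[:dur], vo2_true[:dur]

    # Observed heart rate at 1 Hz.
    hr_obs = hr_true + noise_scale * rng.normal(0.0, 1.5, size=dur)

    # Observed VO2 at 0.1 Hz: breath-averaged over the preceding 10 s.
    edges = np.arange(10, dur + 1, 10)
    vo2_avg = np.array([vo2_true[e - 10:e].mean() for e in edges])
    vo2_obs = vo2_avg + noise_scale * rng.normal(0.0, 0.05, size=edges.size)
    vo2_obs = np.maximum(vo2_obs, 0.0)

    # Accelerometer at 10 Hz: per-axis rhythmic oscillation at a cadence that
    # rises with speed, intensity-scaled Gaussian noise, and a high-variance
    # onset transient while the gait settles.
    t10 = np.arange(0.0, dur, 0.1)
    frac10 = np.interp(t10, t, frac)
    speed10 = np.interp(t10, t, speed)
    cadence = 1.2 + 0.12 * speed10                      # arm-swing Hz
    phase = 2.0 * np.pi * np.cumsum(cadence) * 0.1
    onset = 0.20 * np.exp(-t10 / 30.0)
    noise_sd = noise_scale * (0.03 + 0.12 * frac10) + onset
    amp = 0.15 + 0.55 * frac10
    axes = {}
    for name, scale, off, ph in (("ax_g", 1.0, 0.0, 0.0),
                                 ("ay_g", 0.6, 0.0, 2.1),
                                 ("az_g", 0.8, 1.0, 4.2)):
        axes[name] = (off + scale * amp * np.sin(phase + ph)
                      + rng.normal(0.0, 1.0, size=t10.size) * noise_sd * scale)
    accel = pd.DataFrame({"timestamp_s": np.round(t10, 1), **axes})
    hr = pd.DataFrame({"timestamp_s": t, "hr_bpm": hr_obs})
    vo2 = pd.DataFrame({"timestamp_s": edges.astype(float), "vo2_lmin": vo2_obs})

    if missing_frac > 0.0:
        keep_hr = rng.random(dur) >= missing_frac
        keep_hr[0] = keep_hr[-1] = True
        hr = hr.loc[keep_hr].reset_index(drop=True)
        sec_drop = rng.random(dur) < missing_frac
        sec_drop[0] = sec_drop[-1] = False
        drop_mask = sec_drop[np.floor(accel["timestamp_s"].to_numpy()).astype(int)]
        accel = accel.loc[~drop_mask].reset_index(drop=True)

    latent = SessionLatent(t=t, speed=speed, intensity=frac, hr_true=hr_true,
                           vo2_true=vo2_true, peak_speed=peak_speed,
                           tau_hr=tau_hr, tau_vo2=tau_vo2)
    return RawSession(profile=profile, accel=accel, hr=hr, vo2=vo2,
                      termination_reason=reason, latent=latent)


def generate_cohort(n_subjects: int, rng_seed: int,
                    protocol: RampProtocol | None = None,
                    noise_scale: float = 1.0,
                    missing_frac: float = 0.02) -> list[RawSession]:
    """Generate a deterministic cohort with a ~2:1 male:female ratio.

    Subject i is male when i mod 3 < 2, so 21 subjects yield 14 males and
    7 females.  Per-subject seeds are derived from `rng_seed` via a seed
    sequence, making the cohort reproducible end to end.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(rng_seed)
    state = ss.generate_state(2 * n_subjects)
    sessions = []
    for i in range(n_subjects):
        sex = "male" if i % 3 < 2 else "female"
        sid = f"S{i + 1:02d}"
        pseed = int(state[2 * i] & 0x7FFFFFFF)
        sseed = int(state[2 * i + 1] & 0x7FFFFFFF)
        profile = sample_profile(pseed, sex, subject_id=sid)
        sessions.append(simulate_session(profile, protocol, sseed,
                                         noise_scale=noise_scale,
                                         missing_frac=missing_frac))
    return sessions


# ---------------------------------------------------------------------------
# Serialization: one directory per subject, CSV per stream + JSON profile.

def save_cohort(sessions: list[RawSession], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"n_subjects": len(sessions),
                "subject_ids": [s.profile.subject_id for s in sessions]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    for s in sessions:
        d = out / s.profile.subject_id
        d.mkdir(exist_ok=True)
        meta = asdict(s.profile)
        meta["termination_reason"] = s.termination_reason
        meta["latent"] = {"peak_speed": s.latent.peak_speed,
                          "tau_hr": s.latent.tau_hr, "tau_vo2": s.latent.tau_vo2}
        (d / "profile.json").write_text(json.dumps(meta, indent=2,
                                                   sort_keys=True) + "\n")
        s.accel.to_csv(d / "accel.csv", index=False)
        s.hr.to_csv(d / "hr.csv", index=False)
        s.vo2.to_csv(d / "vo2.csv", index=False)
        pd.DataFrame({"timestamp_s": s.latent.t, "speed_kmh": s.latent.speed,
                      "intensity": s.latent.intensity,
                      "hr_true_bpm": s.latent.hr_true,
                      "vo2_true_lmin": s.latent.vo2_true,
                      }).to_csv(d / "latent.csv", index=False)


def load_cohort(in_dir) -> list[RawSession]:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    sessions = []
    for sid in manifest["subject_ids"]:
        d = src / sid
        meta = json.loads((d / "profile.json").read_text())
        lat_meta = meta.pop("latent")
        reason = meta.pop("termination_reason")
        profile = SubjectProfile(**meta)
        lat_df = pd.read_csv(d / "latent.csv")
        latent = SessionLatent(
            t=lat_df["timestamp_s"].to_numpy(),
            speed=lat_df["speed_kmh"].to_numpy(),
            intensity=lat_df["intensity"].to_numpy(),
            hr_true=lat_df["hr_true_bpm"].to_numpy(),
            vo2_true=lat_df["vo2_true_lmin"].to_numpy(),
            peak_speed=lat_meta["peak_speed"], tau_hr=lat_meta["tau_hr"],
            tau_vo2=lat_meta["tau_vo2"])
        sessions.append(RawSession(
            profile=profile,
            accel=pd.read_csv(d / "accel.csv"),
            hr=pd.read_csv(d / "hr.csv"),
            vo2=pd.read_csv(d / "vo2.csv"),
            termination_reason=reason, latent=latent))
    return sessions
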