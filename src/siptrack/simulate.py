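"""Seeded simulator of scripted drinking trials.

Emulates the study design the analysis pipeline assumes: each trial is a
sequence of 12 drinks from a 750 mL bottle refilled at the start, with
the bottle resting upright and stationary between drinks.  Because the
study's human dataset was never deposited, this generator provides
ground-truthed raw traces with the same statistical structure:

* fill ratios skewed toward high values (the bottle starts full) and
  right-skewed drink volumes (a small/medium/large prompt mixture with a
  heavy large-drink tail);
* sip duration increasing with drink volume (affine law
  ``d0 + d_per_ml * v``) and maximum inclination increasing as the fill
  level drops (affine in ``1 - FR``: an emptier bottle must be tipped
  further to reach the liquid);
* the axial angle alpha rotating during lift and place but held
  stationary during the sip;
* per-subject multiplicative random effects on tilt, sip duration and
  sensor noise, emulating biomechanical differences across individuals.

The accelerometer trace is reconstructed from the angle trajectories
under the gravity-only assumption (ax = cos(theta),
ay = sin(theta) cos(alpha), az = sin(theta) sin(alpha), plus white
noise), matching the assumption the inclination estimator makes.  Angle
trajectories use raised-cosine ramps so that derivatives stay continuous
and the rate features are not dominated by segment boundaries.

Every trial draws from its own named random stream derived from the
master seed, so datasets are reproducible regardless of generation
order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .io_types import DrinkLabel, Recording, write_labels, write_recording

__all__ = [
    "SimConfig",
    "SubjectProfile",
    "SimTrial",
    "simulate_trial",
    "simulate_cohort",
    "simulate_dataset",
    "draw_profile",
    "tilt_law",
]


@dataclass(frozen=True)
class SimConfig:
    """Cohort design, motion laws and noise levels for the simulator.

    Defaults encode the scripted 12-drink / 750 mL protocol and motion
    laws producing the qualitative dependencies the pipeline exploits.
    ``theta_base``/``theta_span`` set the tilt law
    theta_max = theta_base + theta_span * (1 - FR_post); ``d0_s``/
    ``d_per_ml`` set the sip-duration law d = d0 + d_per_ml * v.  Setting
    the three noise fields (``accel_noise_g``, ``tilt_jitter_deg``,
    ``duration_jitter_frac``) to zero yields deterministic trajectories
    that follow the laws exactly (see :meth:`noiseless`).
    """

    n_subjects: int = 40
    trials_per_subject: int = 1
    drinks_per_trial: int = 12
    capacity_ml: float = 750.0
    rate_hz: float = 20.0
    seed: int = 0
    # tilt law, degrees
    theta_base: float = 30.0
    theta_span: float = 60.0
    # sip-duration law; the fill coupling lengthens sips from an emptier
    # bottle (steeper tilt, slower pour), entangling duration with fill
    # level the same way drink kinematics entangle them in practice
    d0_s: float = 1.0
    d_per_ml: float = 0.05
    duration_fill_coupling: float = 1.2
    # drink-volume mixture (small / medium / large prompts), grams of water
    volume_means: tuple[float, ...] = (20.0, 45.0, 90.0)
    volume_sds: tuple[float, ...] = (5.0, 10.0, 25.0)
    volume_weights: tuple[float, ...] = (0.40, 0.35, 0.25)
    volume_min_g: float = 5.0
    # noise
    accel_noise_g: float = 0.02
    tilt_jitter_deg: float = 2.0
    duration_jitter_frac: float = 0.25
    transport_jitter_frac: float = 0.15
    # per-subject random-effect spreads (lognormal sigmas)
    subject_tilt_sd: float = 0.10
    subject_duration_sd: float = 0.20
    subject_noise_sd: float = 0.25
    # transport
    lift_s: float = 0.8
    place_s: float = 0.7
    still_s: float = 3.0
    axial_rotation_deg: float = 170.0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.trials_per_subject, self.drinks_per_trial) < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.still_s * self.rate_hz < 50:
            raise ValueError(
                "initial still segment must cover the 50 samples the bias "
                "estimate averages"
            )
        if abs(sum(self.volume_weights) - 1.0) > 1e-9:
            raise ValueError("volume mixture weights must sum to 1")

    def noiseless(self) -> "SimConfig":
        """A copy with all stochastic perturbations switched off."""
        return replace(
            self,
            accel_noise_g=0.0,
            tilt_jitter_deg=0.0,
            duration_jitter_frac=0.0,
            transport_jitter_frac=0.0,
            subject_tilt_sd=0.0,
            subject_duration_sd=0.0,
            subject_noise_sd=0.0,
        )


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject multiplicative random effects (all positive)."""

    tilt: float = 1.0
    duration: float = 1.0
    noise: float = 1.0

    def __post_init__(self) -> None:
        if min(self.tilt, self.duration, self.noise) <= 0:
            raise ValueError("subject multipliers must be positive")


@dataclass
class SimTrial:
    """One simulated trial: trace, labels and the post-trial fill ratio."""

    recording: Recording
    labels: list[DrinkLabel]
    fill_ratio_final: float
    subject_id: str

    @property
    def trial_id(self) -> str:
        return self.recording.trial_id


def draw_profile(cfg: SimConfig, rng: np.random.Generator) -> SubjectProfile:
    """Draw a subject's random-effect multipliers (lognormal, median 1)."""
    return SubjectProfile(
        tilt=float(np.exp(rng.normal(0.0, cfg.subject_tilt_sd))),
        duration=float(np.exp(rng.normal(0.0, cfg.subject_duration_sd))),
        noise=float(np.exp(rng.normal(0.0, cfg.subject_noise_sd))),
    )


def tilt_law(cfg: SimConfig, fr_post: float, tilt_mult: float = 1.0) -> float:
    """Maximum drinking inclination implied by the post-drink fill level.

    theta_max = (theta_base + theta_span * (1 - fr_post)) * tilt_mult,
    clipped to physically sensible tilts.
    """
    theta_max = (cfg.theta_base + cfg.theta_span * (1.0 - fr_post)) * tilt_mult
    return float(np.clip(theta_max, 5.0, 175.0))


def _raised_cosine(a: float, b: float, n: int) -> np.ndarray:
    """Smooth monotone ramp from a to b over n samples (endpoints excluded at b)."""
    u = np.arange(n) / n
    return a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * u))


def _draw_volumes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(len(cfg.volume_means), size=cfg.drinks_per_trial, p=cfg.volume_weights)
    v = rng.normal(np.take(cfg.volume_means, comp), np.take(cfg.volume_sds, comp))
    v = np.maximum(v, cfg.volume_min_g)
    total = float(v.sum())
    if total > cfg.capacity_ml:
        warnings.warn(
            f"drawn volumes total {total:.0f} mL > capacity "
            f"{cfg.capacity_ml:.0f} mL; rescaled",
            stacklevel=2,
        )
        v *= 0.95 * cfg.capacity_ml / total
    return v


def simulate_trial(
    cfg: SimConfig,
    profile: SubjectProfile,
    rng: np.random.Generator,
    trial_id: str = "T000",
    subject_id: str = "S000",
) -> SimTrial:
    """Simulate one 12-drink trial: raw trace plus ground-truth labels.

    The trial starts with the bottle full (FR = 1) and upright for
    ``still_s`` seconds (covering the bias-estimation window), then per
    drink: a lift with axial rotation, a sip with stationary alpha during
    which the inclination rises to the tilt-law maximum and holds for the
    duration-law time, a place returning the bottle upright, and another
    still rest.
    """
    rate = cfg.rate_hz
    n_still = int(round(cfg.still_s * rate))

    def _transport_samples(base_s: float) -> int:
        s = base_s
        if cfg.transport_jitter_frac > 0:
            s *= float(np.exp(rng.normal(0.0, cfg.transport_jitter_frac)))
        return max(int(round(s * rate)), 4)

    volumes = _draw_volumes(cfg, rng)
    theta_parts: list[np.ndarray] = [np.zeros(n_still)]
    alpha_parts: list[np.ndarray] = [np.zeros(n_still)]
    labels: list[DrinkLabel] = []
    fr = 1.0
    for k, v in enumerate(volumes, start=1):
        fr_pre = fr
        fr_post = fr - v / cfg.capacity_ml
        theta_max = tilt_law(cfg, fr_post, profile.tilt)
        if cfg.tilt_jitter_deg > 0:
            theta_max = float(
                np.clip(theta_max + rng.normal(0.0, cfg.tilt_jitter_deg), 5.0, 175.0)
            )
        sip_s = (
            (cfg.d0_s + cfg.d_per_ml * v)
            * (1.0 + cfg.duration_fill_coupling * (1.0 - fr_pre))
            * profile.duration
        )
        if cfg.duration_jitter_frac > 0:
            sip_s *= float(np.exp(rng.normal(0.0, cfg.duration_jitter_frac)))
        n_sip = max(int(round(sip_s * rate)), 6)
        n_lift = _transport_samples(cfg.lift_s)
        n_place = _transport_samples(cfg.place_s)
        n_rise = min(max(int(round(0.4 * rate)), 2), n_sip // 3)

        rot = cfg.axial_rotation_deg * (1 if k % 2 else -1)
        theta_half = 0.5 * theta_max
        # lift: tilt to half the drinking angle while rotating about the axis
        theta_parts.append(_raised_cosine(0.0, theta_half, n_lift))
        alpha_parts.append(_raised_cosine(0.0, rot, n_lift))
        # sip: alpha frozen; theta completes its rise then holds
        theta_sip = np.concatenate(
            [
                _raised_cosine(theta_half, theta_max, n_rise),
                np.full(n_sip - n_rise, theta_max),
            ]
        )
        theta_parts.append(theta_sip)
        alpha_parts.append(np.full(n_sip, rot))
        # place: return upright, rotating back
        theta_parts.append(_raised_cosine(theta_max, 0.0, n_place))
        alpha_parts.append(_raised_cosine(rot, 0.0, n_place))
        theta_parts.append(np.zeros(n_still))
        alpha_parts.append(np.zeros(n_still))

        labels.append(
            DrinkLabel(
                trial_id=trial_id,
                drink_index=k,
                mass_g=float(v),
                fill_ratio_pre=fr_pre,
            )
        )
        fr = fr_post

    theta = np.radians(np.concatenate(theta_parts))
    alpha = np.radians(np.concatenate(alpha_parts))
    ax = np.cos(theta)
    ay = np.sin(theta) * np.cos(alpha)
    az = np.sin(theta) * np.sin(alpha)
    if cfg.accel_noise_g > 0:
        sd = cfg.accel_noise_g * profile.noise
        ax = ax + rng.normal(0.0, sd, len(ax))
        ay = ay + rng.normal(0.0, sd, len(ay))
        az = az + rng.normal(0.0, sd, len(az))
    t = np.arange(len(ax)) / rate
    rec = Recording(
        trial_id=trial_id,
        subject_id=subject_id,
        t=t,
        ax=ax,
        ay=ay,
        az=az,
        nominal_rate=rate,
    )
    return SimTrial(
        recording=rec, labels=labels, fill_ratio_final=fr, subject_id=subject_id
    )


def _trial_rng(seed: int, subject: int, trial: int) -> np.random.Generator:
    # named per-trial stream: independent of generation order
    return np.random.default_rng(np.random.SeedSequence([seed, subject, trial]))


def simulate_cohort(cfg: SimConfig) -> list[SimTrial]:
    """Simulate the whole cohort in memory, one named stream per trial."""
    trials: list[SimTrial] = []
    for s in range(cfg.n_subjects):
        profile = draw_profile(cfg, _trial_rng(cfg.seed, s, 10**6))
        for j in range(cfg.trials_per_subject):
            rng = _trial_rng(cfg.seed, s, j)
            tid = f"S{s:03d}_T{j:02d}"
            trials.append(
                simulate_trial(cfg, profile, rng, trial_id=tid, subject_id=f"S{s:03d}")
            )
    return trials


def simulate_dataset(cfg: SimConfig, out_dir: str | Path, force: bool = False) -> Path:
    """Simulate a cohort and write it to disk in the pipeline's file formats.

    Writes one trace CSV per trial, a dataset-level ``labels.csv`` and a
    ``manifest.json`` recording the full configuration, the seed and each
    trial's post-trial fill ratio.  Refuses a non-empty output directory
    unless ``force``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True to overwrite)")
    trials = simulate_cohort(cfg)
    all_labels: list[DrinkLabel] = []
    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "trials": {},
    }
    for tr in trials:
        write_recording(tr.recording, out / f"{tr.trial_id}.csv")
        all_labels.extend(tr.labels)
        manifest["trials"][tr.trial_id] = {
            "subject_id": tr.subject_id,
            "fill_ratio_final": tr.fill_ratio_final,
            "n_samples": len(tr.recording),
        }
    write_labels(all_labels, out / "labels.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
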