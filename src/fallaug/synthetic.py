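"""Synthetic wrist-IMU cohort generator.

Emulates the statistical structure of a multi-subject wearable fall
dataset: activities of daily living (ADL) are long quasi-periodic
6-channel streams (gait harmonics over a gravity offset), falls are short
clips containing one sharp impact transient embedded in an elevated
loss-of-balance disturbance, and subjects differ by random amplitude and
cadence multipliers so that group-wise cross-validation is meaningful.
Amplitudes are in normalized gravity units throughout; nothing here aims
at biomechanical realism beyond the two class signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import RawRecording, WINDOW_LEN, SAMPLING_RATE_HZ
from .config import child_seed


@dataclass
class SynthParams:
    """Cohort-level generator settings (defaults define the study conditions)."""

    n_subjects: int = 17
    adl_recordings_per_subject: int = 6
    fall_recordings_per_subject: int = 5
    adl_duration_range_samples: tuple[int, int] = (600, 1400)
    fall_duration_samples: int = 300
    gait_freq_hz_range: tuple[float, float] = (1.4, 2.2)
    impact_peak_g: float = 4.0
    #: peak-relative amplitude of the loss-of-balance disturbance that
    #: spans the fall clip after the quiet lead-in
    disturbance_rel: float = 0.85
    #: range of the fundamental gait-harmonic amplitude per recording
    adl_amp_range: tuple[float, float] = (0.25, 0.5)
    n_harmonics_range: tuple[int, int] = (1, 3)
    #: every third ADL recording is a vigorous activity (jumping-like)
    #: whose burst amplitude is this fraction of the impact peak; these
    #: overlap falls in amplitude and make the detection task realistic
    vigor_amp_rel: float = 0.2
    noise_sd: float = 0.15
    subject_effect_sd: float = 0.15
    sampling_rate_hz: float = SAMPLING_RATE_HZ
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("need at least 4 subjects for group-wise CV")
        if min(self.adl_duration_range_samples) < WINDOW_LEN:
            raise ValueError(f"ADL durations must be >= window length {WINDOW_LEN}")
        if self.fall_duration_samples < 200:
            raise ValueError("fall clips need >= 200 samples for the impact margins")
        if min(self.gait_freq_hz_range) <= 0:
            raise ValueError("gait frequencies must be positive")
        max_adl_env = 1.0 + sum(self.adl_amp_range[1] / 2**k for k in range(3))
        if self.impact_peak_g <= max_adl_env:
            raise ValueError("impact peak must exceed the ADL amplitude envelope")


GRAVITY_OFFSET = np.array([0.0, 0.0, 1.0])  # wrist at rest, accel z carries 1 g


def _harmonic_series(rng, n, fs, freq, base_amp, n_harmonics, channel_gains):
    """Sum of ``n_harmonics`` phase-randomized harmonics per channel."""
    t = np.arange(n) / fs
    sig = np.zeros((n, len(channel_gains)))
    for h in range(1, n_harmonics + 1):
        amp = base_amp / 2 ** (h - 1)
        phases = rng.uniform(0, 2 * np.pi, size=len(channel_gains))
        sig += amp * channel_gains * np.sin(2 * np.pi * h * freq * t[:, None] + phases)
    return sig


def generate_adl_recording(params: SynthParams, subject_id: int, seed: int,
                           amp_mult: float = 1.0, freq_mult: float = 1.0,
                           activity_id: int = 6, trial_id: int = 1,
                           vigorous: bool = False,
                           return_info: bool = False):
    """One quasi-periodic ADL stream: gravity offset + gait harmonics + noise.

    With ``vigorous`` a train of moderate half-sine bursts (jumping-like,
    amplitude ``vigor_amp_rel * impact_peak_g``) rides on the harmonics,
    recurring often enough that every window contains at least one burst.
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.adl_duration_range_samples
    n = int(rng.integers(lo, hi + 1))
    freq = rng.uniform(*params.gait_freq_hz_range) * freq_mult
    base_amp = rng.uniform(*params.adl_amp_range) * amp_mult
    n_harm = int(rng.integers(params.n_harmonics_range[0],
                              params.n_harmonics_range[1] + 1))
    accel_gains = rng.uniform(0.6, 1.0, size=3)
    gyro_gains = rng.uniform(0.5, 0.9, size=3)
    accel = GRAVITY_OFFSET + _harmonic_series(
        rng, n, params.sampling_rate_hz, freq, base_amp, n_harm, accel_gains)
    gyro = _harmonic_series(
        rng, n, params.sampling_rate_hz, freq, 0.8 * base_amp, n_harm, gyro_gains)
    if vigorous:
        burst_amp = params.vigor_amp_rel * params.impact_peak_g * amp_mult
        width = 6
        pos = int(rng.integers(0, 40))
        while pos + width < n:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            shape = np.sin(np.pi * np.arange(width) / (width - 1))
            accel[pos:pos + width] += burst_amp * shape[:, None] * direction
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            gyro[pos:pos + width] += 0.8 * burst_amp * shape[:, None] * axis
            pos += int(rng.integers(40, 70))
    samples = np.hstack([accel, gyro])
    if params.noise_sd > 0:
        samples = samples + rng.normal(0, params.noise_sd, size=samples.shape)
    rec = RawRecording(subject_id=subject_id, activity_id=activity_id,
                       trial_id=trial_id, samples=samples,
                       sampling_rate_hz=params.sampling_rate_hz, is_fall=False)
    if return_info:
        info = {"duration": n, "gait_freq_hz": freq, "base_amp": base_amp,
                "n_harmonics": n_harm, "accel_gains": accel_gains,
                "gyro_gains": gyro_gains, "vigorous": vigorous}
        return rec, info
    return rec


IMPACT_WIDTH = 8  # samples; the transient spans well under 10 samples


def generate_fall_recording(params: SynthParams, subject_id: int, seed: int,
                            amp_mult: float = 1.0,
                            activity_id: int = 1, trial_id: int = 1,
                            return_info: bool = False):
    """One fall clip: loss-of-balance disturbance with a single sharp impact.

    The clip opens with a short quiet lead-in (pre-fall sway), then an
    elevated broadband disturbance (descent, impact, settling) whose
    acceleration norm is capped below the peak; the impact itself is a
    half-sine burst of <= 10 samples on a random direction whose
    acceleration norm equals ``impact_peak_g`` exactly in the noiseless
    limit.  Gyro channels carry a correlated rotational burst.  Windows
    cut entirely from the lead-in keep the FALL label while looking like
    low-activity ADL, as in real fall clips.
    """
    rng = np.random.default_rng(seed)
    n = params.fall_duration_samples
    peak = params.impact_peak_g * amp_mult
    dist_amp = params.disturbance_rel * peak
    # quiet lead-in before the loss of balance: windows cut from it carry
    # the FALL label but look like low-activity ADL, as in real clips
    lead = int(rng.integers(30, 181))
    pos = int(rng.integers(max(50, lead + 20), n - 50 - IMPACT_WIDTH + 1))

    # broadband disturbance: 3 incommensurate oscillations with
    # channel-asymmetric gains and slow amplitude modulation
    t = np.arange(n) / params.sampling_rate_hz
    acc_gain = np.array([1.0, 0.5, 0.35])
    gyr_gain = np.array([0.9, 0.6, 0.45])
    freqs = rng.uniform(2.5, 6.0, size=3)
    modulation = 0.9 + 0.1 * np.abs(np.sin(2 * np.pi * rng.uniform(0.2, 0.5) * t
                                           + rng.uniform(0, 2 * np.pi)))
    accel = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    wsum = 1.0 + 0.5 + 0.25  # normalize the summed oscillation envelope
    for k, f in enumerate(freqs):
        ph_a = rng.uniform(0, 2 * np.pi, size=3)
        ph_g = rng.uniform(0, 2 * np.pi, size=3)
        amp_k = dist_amp / wsum / 2**k
        accel += amp_k * acc_gain * np.sin(2 * np.pi * f * t[:, None] + ph_a)
        gyro += 0.8 * amp_k * gyr_gain * np.sin(2 * np.pi * f * t[:, None] + ph_g)
    envelope = modulation.copy()
    envelope[:lead] *= 0.15 / params.disturbance_rel  # quiet sway before descent
    accel *= envelope[:, None]
    gyro *= envelope[:, None]
    accel += GRAVITY_OFFSET
    # the impact must stay the global acceleration extremum: cap the
    # disturbance norm at 90 % of the peak
    mag = np.linalg.norm(accel, axis=1)
    over = mag > 0.9 * peak
    accel[over] *= (0.9 * peak / mag[over])[:, None]

    # impact: replace the burst samples so the norm peaks at exactly `peak`
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    burst = np.sin(np.pi * np.arange(IMPACT_WIDTH) / (IMPACT_WIDTH - 1))
    burst[IMPACT_WIDTH // 2] = 1.0  # exact unit maximum at the centre sample
    accel[pos:pos + IMPACT_WIDTH] = peak * burst[:, None] * direction
    rot_axis = rng.normal(size=3)
    rot_axis /= np.linalg.norm(rot_axis)
    gyro[pos:pos + IMPACT_WIDTH] = 0.9 * peak * burst[:, None] * rot_axis

    samples = np.hstack([accel, gyro])
    if params.noise_sd > 0:
        samples = samples + rng.normal(0, params.noise_sd, size=samples.shape)
    rec = RawRecording(subject_id=subject_id, activity_id=activity_id,
                       trial_id=trial_id, samples=samples,
                       sampling_rate_hz=params.sampling_rate_hz, is_fall=True)
    if return_info:
        return rec, {"impact_index": pos + IMPACT_WIDTH // 2, "peak": peak}
    return rec


ADL_ACTIVITY_IDS = (6, 7, 8, 9, 10, 11)
FALL_ACTIVITY_IDS = (1, 2, 3, 4, 5)


def subject_effects(params: SynthParams) -> dict[int, tuple[float, float]]:
    """Per-subject (amplitude, frequency) multipliers, drawn once per subject."""
    rng = np.random.default_rng(child_seed(params.seed, "subject-effects"))
    out = {}
    for s in range(1, params.n_subjects + 1):
        amp = float(np.exp(params.subject_effect_sd * rng.standard_normal()))
        freq = float(np.exp(0.5 * params.subject_effect_sd * rng.standard_normal()))
        out[s] = (amp, freq)
    return out


def generate_cohort(params: SynthParams) -> list[RawRecording]:
    """All subjects' recordings with per-subject random effects and labels."""
    effects = subject_effects(params)
    recordings = []
    for s in range(1, params.n_subjects + 1):
        amp, freq = effects[s]
        for i in range(params.adl_recordings_per_subject):
            act = ADL_ACTIVITY_IDS[i % len(ADL_ACTIVITY_IDS)]
            trial = i // len(ADL_ACTIVITY_IDS) + 1
            seed = child_seed(params.seed, f"adl-{s}-{i}")
            recordings.append(generate_adl_recording(
                params, s, seed, amp_mult=amp, freq_mult=freq,
                activity_id=act, trial_id=trial,
                vigorous=(i % 3 == 2)))
        for i in range(params.fall_recordings_per_subject):
            act = FALL_ACTIVITY_IDS[i % len(FALL_ACTIVITY_IDS)]
            trial = i // len(FALL_ACTIVITY_IDS) + 1
            seed = child_seed(params.seed, f"fall-{s}-{i}")
            recordings.append(generate_fall_recording(
                params, s, seed, amp_mult=amp, activity_id=act, trial_id=trial))
    return recordings


def tiny_params(seed: int = 0, n_subjects: int = 8) -> SynthParams:
    """Small cohort for smoke runs: fewer recordings, same signal structure."""
    return SynthParams(n_subjects=n_subjects, adl_recordings_per_subject=3,
                       fall_recordings_per_subject=3, seed=seed)
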