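"""Synthetic floor-sensor signal generator.

Stands in for real nursing-home recordings: 5-channel, 100 Hz, ~10 s
events with ground-truth step boxes.  The generator aims at statistical,
not biomechanical, fidelity — it reproduces the contrasts that drive the
downstream method:

* staff walks: high amplitude, regular cadence, ~20 dB SNR;
* elderly walks: markedly smaller amplitude (hence lower SNR at the same
  floor-noise level) and irregular cadence;
* multi-walker events superpose two independent walkers of one status;
* non-gait events: wheelchair (low-frequency rolling load), pushed
  wheelchair (rolling plus the pusher's steps), cart walk (steps plus
  periodic wheel bumps), and other transients.

Each step is an asymmetric double bump (heel strike then toe-off) with a
touch of damped ringing, its energy spread across channels by a smooth
spatial profile that drifts as the walker moves along the sensor band.
White measurement noise and a per-channel affine drift are added last;
the noise power is calibrated on a reference staff walk so that staff
recordings sit at the configured SNR and elderly recordings come out
quieter by their amplitude ratio.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from floorgait.dataset import (
    Dataset,
    EventAnnotation,
    EventClass,
    PersonStatus,
    Recording,
    StepBox,
)

__all__ = [
    "PersonProfile",
    "SyntheticConfig",
    "STAFF_PROFILE",
    "ELDERLY_PROFILE",
    "synth_step",
    "synth_walk",
    "synth_event",
    "add_noise_and_trend",
    "generate_dataset",
]

BOX_LEVEL = 0.05  # a step box covers samples where |pulse| > 5% of its peak


@dataclass(frozen=True)
class PersonProfile:
    """Gait parameters of one walker category."""

    status: PersonStatus
    step_amplitude_mean: float
    step_amplitude_cv: float
    cadence_sec: float
    cadence_jitter_cv: float
    step_duration_sec: float = 0.30
    step_duration_jitter_cv: float = 0.10
    rise_fraction: float = 0.30  # position of the heel-strike bump
    ringing: float = 0.12  # damped-oscillation coefficient

    def __post_init__(self) -> None:
        if self.step_amplitude_mean <= 0:
            raise ValueError("step amplitude must be positive")
        if not 0.0 < self.step_duration_sec <= 0.7:
            raise ValueError("step duration must lie in (0, 0.7] s")


STAFF_PROFILE = PersonProfile(
    status=PersonStatus.STAFF,
    step_amplitude_mean=1.0,
    step_amplitude_cv=0.1,
    cadence_sec=0.55,
    cadence_jitter_cv=0.05,
    step_duration_sec=0.30,
    step_duration_jitter_cv=0.08,
)

ELDERLY_PROFILE = PersonProfile(
    status=PersonStatus.ELDERLY,
    step_amplitude_mean=0.4,
    step_amplitude_cv=0.3,
    cadence_sec=0.8,
    cadence_jitter_cv=0.2,
    step_duration_sec=0.32,
    step_duration_jitter_cv=0.12,
)


def _default_composition() -> dict[tuple[EventClass, PersonStatus], int]:
    """Event counts mirroring the reference 93-signal corpus: 42/16 single
    walks (staff/elderly), 11 multi walks (8 staff / 3 elderly), 9
    wheelchairs, 5 pushed wheelchairs, 5 cart walks, 5 other events.
    A signal is labelled staff only if everyone involved is staff, so
    wheelchair events carry the elderly label."""
    return {
        (EventClass.WALK_SINGLE, PersonStatus.STAFF): 42,
        (EventClass.WALK_SINGLE, PersonStatus.ELDERLY): 16,
        (EventClass.WALK_MULTI, PersonStatus.STAFF): 8,
        (EventClass.WALK_MULTI, PersonStatus.ELDERLY): 3,
        (EventClass.WHEELCHAIR, PersonStatus.ELDERLY): 9,
        (EventClass.WHEELCHAIR_PUSHED, PersonStatus.ELDERLY): 5,
        (EventClass.CART_WALK, PersonStatus.STAFF): 5,
        (EventClass.OTHER, PersonStatus.STAFF): 2,
        (EventClass.OTHER, PersonStatus.ELDERLY): 3,
    }


@dataclass
class SyntheticConfig:
    n_channels: int = 5
    rate_hz: float = 100.0
    duration_sec: float = 10.0
    snr_db: float = 20.0  # calibrated on staff walks
    trend_amp: float = 0.2
    seed: int = 0
    composition: dict[tuple[EventClass, PersonStatus], int] = field(
        default_factory=_default_composition
    )
    staff_profile: PersonProfile = STAFF_PROFILE
    elderly_profile: PersonProfile = ELDERLY_PROFILE

    def profile_for(self, status: PersonStatus) -> PersonProfile:
        return self.staff_profile if status is PersonStatus.STAFF else self.elderly_profile


# ---------------------------------------------------------------------------
# Step and event synthesis


def _gauss(t: np.ndarray, mu: float, w: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / w) ** 2)


def synth_step(
    profile: PersonProfile, t0: int, rng: np.random.Generator, rate_hz: float = 100.0
) -> tuple[np.ndarray, StepBox]:
    """One footstep pulse starting at raw sample ``t0``.

    The pulse is a heel-strike bump followed by a broader toe-off bump and
    faint damped ringing; its box covers the samples where the magnitude
    exceeds 5% of the peak.  Under the default profiles the box width
    falls in the 20-40 sample range of typical step durations.
    """
    dur_sec = profile.step_duration_sec * (
        1.0 + profile.step_duration_jitter_cv * rng.standard_normal()
    )
    dur_sec = float(np.clip(dur_sec, 0.24, 0.42))
    n = max(int(round(dur_sec * rate_hz)), 8)
    t = np.arange(n) / (n - 1)
    heel = _gauss(t, profile.rise_fraction, 0.13)
    toe = 0.8 * _gauss(t, 1.0 - profile.rise_fraction * 0.9, 0.17)
    ring = profile.ringing * np.exp(-4.0 * t) * np.sin(2 * math.pi * 7.0 * t * dur_sec)
    pulse = heel + toe + ring
    pulse *= np.sin(math.pi * t) ** 0.5  # taper to zero at both ends
    peak = np.max(np.abs(pulse))
    amp = profile.step_amplitude_mean * (
        1.0 + profile.step_amplitude_cv * rng.standard_normal()
    )
    amp = max(abs(amp), 0.05 * profile.step_amplitude_mean)
    pulse = pulse / peak * amp
    above = np.flatnonzero(np.abs(pulse) > BOX_LEVEL * amp)
    box = StepBox(int(t0 + above[0]), int(t0 + above[-1] + 1))
    return pulse, box


def _channel_weights(pos: float, n_channels: int, spread: float = 0.8) -> np.ndarray:
    w = _gauss(np.arange(n_channels, dtype=float), pos, spread)
    return w / w.sum()


def synth_walk(
    profile: PersonProfile,
    duration_sec: float,
    rng: np.random.Generator,
    n_channels: int = 5,
    rate_hz: float = 100.0,
) -> tuple[np.ndarray, list[StepBox]]:
    """A walk across the sensor band: steps at (jittered) cadence intervals,
    each step's energy spread over channels by a drifting spatial profile.
    Returned boxes are sorted and pairwise disjoint."""
    t_total = int(round(duration_sec * rate_hz))
    channels = np.zeros((n_channels, t_total))
    boxes: list[StepBox] = []
    pos0 = rng.uniform(0, n_channels - 1)
    pos1 = rng.uniform(0, n_channels - 1)
    t_sec = 0.3
    min_gap_sec = 0.46  # keeps consecutive boxes disjoint
    while True:
        t0 = int(round(t_sec * rate_hz))
        pulse, box = synth_step(profile, t0, rng, rate_hz)
        if t0 + pulse.size > t_total:
            break
        frac = t_sec / duration_sec
        weights = _channel_weights(pos0 + (pos1 - pos0) * frac, n_channels)
        channels[:, t0 : t0 + pulse.size] += weights[:, None] * pulse[None, :]
        boxes.append(box)
        interval = profile.cadence_sec * (
            1.0 + profile.cadence_jitter_cv * rng.standard_normal()
        )
        t_sec += max(interval, min_gap_sec)
    if len(boxes) < 2:
        raise ValueError("duration too short to place at least two steps")
    return channels, boxes


def _merge_boxes(boxes: list[StepBox]) -> list[StepBox]:
    """Sort boxes and merge any overlapping ones into their union."""
    merged: list[StepBox] = []
    for b in sorted(boxes):
        if merged and b.start < merged[-1].end:
            merged[-1] = StepBox(merged[-1].start, max(merged[-1].end, b.end))
        else:
            merged.append(b)
    return merged


def _rolling_load(
    rng: np.random.Generator, n_channels: int, t_total: int, amp: float = 0.5
) -> np.ndarray:
    """Continuous low-frequency load of wheels rolling along the band."""
    t = np.arange(t_total)
    base = np.zeros(t_total)
    for _ in range(3):
        f = rng.uniform(0.3, 2.0)
        base += rng.uniform(0.3, 1.0) * np.sin(2 * math.pi * f * t / 100.0 + rng.uniform(0, 2 * math.pi))
    base *= amp / max(np.max(np.abs(base)), 1e-9)
    env = 0.5 * (1 - np.cos(2 * math.pi * np.minimum(t / t_total, 1.0)))  # fade in/out
    base *= env
    pos = np.linspace(rng.uniform(0, n_channels - 1), rng.uniform(0, n_channels - 1), t_total)
    channels = np.zeros((n_channels, t_total))
    for k in range(n_channels):
        channels[k] = base * _gauss(pos, float(k), 0.8)
    return channels


def synth_event(
    event_class: EventClass,
    rng: np.random.Generator,
    cfg: SyntheticConfig | None = None,
    status: PersonStatus = PersonStatus.STAFF,
) -> tuple[np.ndarray, list[StepBox], int]:
    """Clean (noise-free) signal for one event class.

    Returns ``(channels, step_boxes, n_persons)``; only walk-bearing
    classes carry boxes, and only for the walker.
    """
    cfg = cfg or SyntheticConfig()
    event_class = EventClass(event_class)
    k, dur, rate = cfg.n_channels, cfg.duration_sec, cfg.rate_hz
    t_total = int(round(dur * rate))
    profile = cfg.profile_for(status)

    if event_class is EventClass.WALK_SINGLE:
        channels, boxes = synth_walk(profile, dur, rng, k, rate)
        return channels, boxes, 1
    if event_class is EventClass.WALK_MULTI:
        c1, b1 = synth_walk(profile, dur, rng, k, rate)
        c2, b2 = synth_walk(profile, dur, rng, k, rate)
        return c1 + c2, _merge_boxes(b1 + b2), 2
    if event_class is EventClass.WHEELCHAIR:
        return _rolling_load(rng, k, t_total), [], 1
    if event_class is EventClass.WHEELCHAIR_PUSHED:
        # rolling load plus the pusher's (staff-gait) steps
        roll = _rolling_load(rng, k, t_total)
        walk, boxes = synth_walk(cfg.staff_profile, dur, rng, k, rate)
        return roll + walk, boxes, 2
    if event_class is EventClass.CART_WALK:
        walk, boxes = synth_walk(cfg.staff_profile, dur, rng, k, rate)
        t = np.arange(t_total)
        f = rng.uniform(1.5, 2.5)
        bumps = 0.15 * np.sin(2 * math.pi * f * t / rate) ** 8
        pos = np.linspace(rng.uniform(0, k - 1), rng.uniform(0, k - 1), t_total)
        cart = np.zeros((k, t_total))
        for ch in range(k):
            cart[ch] = bumps * _gauss(pos, float(ch), 0.8)
        return walk + cart, boxes, 1
    if event_class is EventClass.OTHER:
        channels = np.zeros((k, t_total))
        for _ in range(rng.integers(2, 6)):
            center = rng.integers(50, t_total - 50)
            width = rng.integers(20, 80)
            t0 = max(center - width // 2, 0)
            seg = np.hanning(width) * rng.uniform(0.2, 0.8) * rng.choice([-1, 1])
            w = _channel_weights(rng.uniform(0, k - 1), k)
            channels[:, t0 : t0 + width] += w[:, None] * seg[None, :]
        return channels, [], 1
    raise ValueError(f"unknown event class {event_class!r}")


# ---------------------------------------------------------------------------
# Noise, trend, dataset assembly


def add_noise_and_trend(
    clean: np.ndarray,
    snr_db: float,
    trend_amp: float,
    rng: np.random.Generator,
    return_parts: bool = False,
):
    """Add white Gaussian noise at the requested SNR plus per-channel
    affine drift of amplitude at most ``trend_amp``.

    SNR is defined over the whole record: ``10 log10(P_signal / P_noise)``
    with powers as mean squares over all channels and samples.
    """
    clean = np.atleast_2d(np.asarray(clean, dtype=float))
    p_signal = float(np.mean(clean**2))
    if np.isfinite(snr_db):
        if p_signal == 0.0:
            raise ValueError("cannot set a finite SNR on an identically zero signal")
        sigma = math.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
        noise = rng.normal(0.0, sigma, size=clean.shape)
    else:
        noise = np.zeros_like(clean)
    t = np.linspace(0.0, 1.0, clean.shape[1])
    v0 = rng.uniform(-trend_amp, trend_amp, size=clean.shape[0])
    v1 = rng.uniform(-trend_amp, trend_amp, size=clean.shape[0])
    trend = v0[:, None] + (v1 - v0)[:, None] * t[None, :]
    noisy = clean + noise + trend
    if return_parts:
        return noisy, noise, trend
    return noisy


def _reference_walk_power(cfg: SyntheticConfig, n_probe: int = 8) -> float:
    """Mean clean power of staff single walks, used to fix the floor-noise
    level so that staff recordings sit at ``cfg.snr_db``."""
    rng = np.random.default_rng([cfg.seed, 0x5EED])
    powers = []
    for _ in range(n_probe):
        channels, _, _ = synth_event(EventClass.WALK_SINGLE, rng, cfg, PersonStatus.STAFF)
        powers.append(np.mean(channels**2))
    return float(np.mean(powers))


def synthesize_recording(
    event_class: EventClass,
    status: PersonStatus,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    rec_id: str = "",
    noise_power: float | None = None,
    return_parts: bool = False,
):
    """One noisy annotated recording (optionally with its clean/noise parts).

    ``noise_power`` fixes the floor-noise level; when omitted it is derived
    from the staff-walk reference power and ``cfg.snr_db``, so quieter
    events (e.g. elderly walks) come out with proportionally lower SNR.
    """
    if noise_power is None:
        noise_power = _reference_walk_power(cfg) / 10.0 ** (cfg.snr_db / 10.0)
    clean, boxes, n_persons = synth_event(event_class, rng, cfg, status)
    p_clean = float(np.mean(clean**2))
    snr_eff = 10.0 * math.log10(p_clean / noise_power) if p_clean > 0 else math.inf
    out = add_noise_and_trend(clean, snr_eff, cfg.trend_amp, rng, return_parts=True)
    noisy, noise, trend = out
    rec = Recording(
        channels=noisy,
        rate_hz=cfg.rate_hz,
        id=rec_id or f"{event_class.value}_{status.value}",
        annotation=EventAnnotation(
            event_class=event_class,
            person_status=status,
            n_persons=n_persons,
            step_boxes=boxes,
        ),
    )
    if return_parts:
        return rec, clean, noise, trend
    return rec


def generate_dataset(cfg: SyntheticConfig | None = None) -> Dataset:
    """Generate the full synthetic corpus described by ``cfg.composition``
    (default: the 93-signal reference composition), reproducibly from
    ``cfg.seed``."""
    cfg = cfg or SyntheticConfig()
    noise_power = _reference_walk_power(cfg) / 10.0 ** (cfg.snr_db / 10.0)
    recordings = []
    for (event_class, status), count in sorted(
        cfg.composition.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        for i in range(count):
            rng = np.random.default_rng(
                [cfg.seed, zlib.crc32(f"{event_class.value}/{status.value}".encode()), i]
            )
            rec = synthesize_recording(
                event_class, status, cfg, rng,
                rec_id=f"{event_class.value}_{status.value}_{i:03d}",
                noise_power=noise_power,
            )
            recordings.append(rec)
    return Dataset(recordings)
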