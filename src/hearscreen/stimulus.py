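"""Calibrated pure-tone stimulus generation.

The level chain runs dB HL -> dB SPL -> digital amplitude. A calibration
profile supplies, per frequency, the RETSPL (the SPL corresponding to
0 dB HL for the transducer/coupler pairing) and the SPL the device produces
at digital full scale with the volume at maximum; then

    SPL = HL + RETSPL(f)
    amplitude = 10 ** ((SPL - max_output_SPL(f)) / 20)

Tones are amplitude-modulated sinusoids (default 100% depth — the envelope
reaches zero each modulation cycle, giving the warbling quality used to
hold children's attention) with cosine on/off ramps, scheduled with silent
intervals drawn uniformly from a configurable range (default 2-3 s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.io import wavfile

from .errors import CalibrationError, ClippingError, ConfigError, DomainError


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-frequency RETSPL and maximum-output SPL for a device+earphone pair.

    ``max_output_spl_db[f]`` is the SPL measured at the eardrum (coupler)
    when a full-scale digital sinusoid at frequency f is played with the
    user volume at 100%; the full-scale assumption is recorded in
    ``volume_policy``.
    """

    device: str
    retspl_db: Mapping[int, float]
    max_output_spl_db: Mapping[int, float]
    volume_policy: str = "full-scale"

    def __post_init__(self):
        missing = set(self.retspl_db) - set(self.max_output_spl_db)
        if missing:
            raise ConfigError(f"max_output_spl_db missing frequencies {sorted(missing)}")
        for f in self.retspl_db:
            if self.max_output_spl_db[f] <= self.retspl_db[f]:
                raise ConfigError(
                    f"max output SPL must exceed RETSPL at {f} Hz "
                    f"({self.max_output_spl_db[f]} <= {self.retspl_db[f]})"
                )

    def frequencies(self) -> Tuple[int, ...]:
        return tuple(sorted(self.retspl_db))

    def to_dict(self) -> dict:
        return {
            "device": self.device,
            "retspl_db": {str(f): v for f, v in self.retspl_db.items()},
            "max_output_spl_db": {str(f): v for f, v in self.max_output_spl_db.items()},
            "volume_policy": self.volume_policy,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationProfile":
        return cls(
            device=d["device"],
            retspl_db={int(k): float(v) for k, v in d["retspl_db"].items()},
            max_output_spl_db={
                int(k): float(v) for k, v in d["max_output_spl_db"].items()
            },
            volume_policy=d.get("volume_policy", "full-scale"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def synthetic_reference_profile() -> CalibrationProfile:
    """A synthetic placeholder calibration profile.

    The RETSPL and maximum-output values here are plausible for a consumer
    earbud but are NOT measurements of any real device; real use requires a
    user-measured profile (see :class:`CalibrationProfile`). The values are
    round numbers chosen only so the level chain is exercisable end to end.
    """
    return CalibrationProfile(
        device="synthetic-placeholder",
        retspl_db={500: 6.0, 1000: 5.5, 2000: 8.5, 4000: 9.5},
        max_output_spl_db={500: 100.0, 1000: 100.0, 2000: 100.0, 4000: 100.0},
    )


def hl_to_spl(level_db_hl: float, frequency_hz: int, profile: CalibrationProfile) -> float:
    """Convert dB HL to dB SPL via the profile's RETSPL at that frequency."""
    f = int(frequency_hz)
    if f not in profile.retspl_db:
        raise CalibrationError(
            f"profile {profile.device!r} has no RETSPL at {f} Hz "
            f"(have {list(profile.frequencies())})"
        )
    return float(level_db_hl) + float(profile.retspl_db[f])


def spl_to_amplitude(
    target_spl_db: float, frequency_hz: int, profile: CalibrationProfile
) -> float:
    """Linear amplitude (fraction of digital full scale) producing a target SPL.

    Raises :class:`CalibrationError` naming the missing headroom if the
    target exceeds the device's maximum output at that frequency.
    """
    f = int(frequency_hz)
    if f not in profile.max_output_spl_db:
        raise CalibrationError(
            f"profile {profile.device!r} has no max-output SPL at {f} Hz"
        )
    max_spl = float(profile.max_output_spl_db[f])
    if target_spl_db > max_spl:
        raise CalibrationError(
            f"target {target_spl_db:.1f} dB SPL exceeds device maximum "
            f"{max_spl:.1f} dB SPL at {f} Hz ({target_spl_db - max_spl:.1f} dB "
            "of headroom missing)"
        )
    return float(10.0 ** ((target_spl_db - max_spl) / 20.0))


def amplitude_for_hl(
    level_db_hl: float, frequency_hz: int, profile: CalibrationProfile
) -> float:
    """Full level chain: dB HL -> dB SPL -> digital amplitude fraction."""
    return spl_to_amplitude(
        hl_to_spl(level_db_hl, frequency_hz, profile), frequency_hz, profile
    )


@dataclass(frozen=True)
class ToneSpec:
    """One test tone: carrier, level, duration, modulation and ramps."""

    frequency_hz: float
    level_db_hl: Optional[float] = None
    duration_s: float = 1.5
    am_depth: float = 1.0
    am_rate_hz: float = 20.0  # modulation rate; an assumption, see docs
    ramp_s: float = 0.02
    sample_rate_hz: int = 44100

    def __post_init__(self):
        if not 0.0 <= self.am_depth <= 1.0:
            raise ConfigError(f"am_depth {self.am_depth} outside [0, 1]")
        if self.duration_s <= 2 * self.ramp_s:
            raise ConfigError(
                f"duration {self.duration_s}s must exceed twice the ramp {self.ramp_s}s"
            )
        if self.sample_rate_hz < 2 * (self.frequency_hz + self.am_rate_hz):
            raise ConfigError(
                f"sample rate {self.sample_rate_hz} below Nyquist for "
                f"{self.frequency_hz} Hz carrier with {self.am_rate_hz} Hz AM"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))


def synthesize_tone(spec: ToneSpec, amplitude: float) -> np.ndarray:
    """Sampled waveform of an AM tone at the given peak amplitude.

    The envelope is ``(1 - m) + m * (1 + cos(2 pi f_am t)) / 2`` — unity at
    the start of each modulation cycle, ``1 - m`` at its trough, so depth 1
    pinches the tone to silence once per cycle. Cosine on/off ramps of
    ``spec.ramp_s`` avoid spectral splatter. Peak never exceeds *amplitude*.
    """
    if not 0.0 <= amplitude <= 1.0:
        raise DomainError(f"amplitude {amplitude!r} outside [0, 1]")
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate_hz
    carrier = np.sin(2 * np.pi * spec.frequency_hz * t)
    m = spec.am_depth
    am_env = (1.0 - m) + m * 0.5 * (1.0 + np.cos(2 * np.pi * spec.am_rate_hz * t))
    env = am_env.copy()
    n_ramp = int(round(spec.ramp_s * spec.sample_rate_hz))
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] *= ramp
        env[-n_ramp:] *= ramp[::-1]
    return amplitude * carrier * env


def build_session_playlist(
    presentations: Sequence[ToneSpec],
    isi_bounds_s: Tuple[float, float] = (2.0, 3.0),
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[ToneSpec, float]]:
    """Schedule tones with randomized silent intervals.

    Returns ``(tone, onset_s)`` pairs in presentation order; each silent
    interval is drawn uniformly from *isi_bounds_s*, reproducibly under a
    seeded *rng*. Onsets are strictly increasing.
    """
    lo, hi = isi_bounds_s
    if lo < 0 or hi < lo:
        raise ConfigError(f"invalid ISI bounds {isi_bounds_s!r}")
    rng = np.random.default_rng() if rng is None else rng
    schedule: List[Tuple[ToneSpec, float]] = []
    t = 0.0
    for tone in presentations:
        schedule.append((tone, t))
        t += tone.duration_s + float(rng.uniform(lo, hi))
    return schedule


def write_wav(waveform: np.ndarray, sample_rate_hz: int, path) -> None:
    """Write a mono 16-bit PCM WAV; refuses out-of-range samples.

    Samples must lie in [-1, 1]; anything outside raises
    :class:`ClippingError` rather than truncating silently. Round-trips
    through :func:`read_wav` within one quantization step.
    """
    x = np.asarray(waveform, dtype=np.float64)
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    if peak > 1.0:
        raise ClippingError(
            f"waveform peak {peak:.4f} exceeds full scale; rescale before writing"
        )
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(sample_rate_hz), pcm)


def read_wav(path) -> Tuple[np.ndarray, int]:
    """Read a 16-bit PCM WAV back to float samples in [-1, 1]."""
    rate, pcm = wavfile.read(str(path))
    return pcm.astype(np.float64) / 32767.0, int(rate)
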