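"""Run configuration: every tunable of the detection pipeline in one place.

Defaults are the values the method was designed around at 250 Hz: a
1-20 Hz BCG passband, 10 s segments with 2 s pads, the 4.5-7 Hz J-wave
band for the STFT energy curve, a 0.3 s physiological floor on beat
spacing, 3 % ensemble noise for EEMD, a +/-40 ms regional search window
and a 9-beat offset history for the fusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # pre-processing
    bcg_band: tuple = (1.0, 20.0)       # Hz, FIR bandpass for the BCG channel
    ecg_band: tuple = (1.0, 40.0)       # Hz, FIR bandpass for the ECG channel
    notch_hz: float = 50.0              # power-line notch centre frequency
    segment_s: float = 10.0             # core segment length
    pad_s: float = 2.0                  # pad added before/after each segment
    # STFT beat locator
    jband: tuple = (4.5, 7.0)           # Hz, J-wave band summed into S(t)
    wt_start: float = 0.3               # s, initial STFT window length
    wt_step: float = 0.1                # s, window-length increment
    wt_max: float = 1.0                 # s, largest window tried
    prominence_ratio: float = 3.0       # peak must exceed ratio x local competitors
    prominence_quantifier: str = "all"  # "all": every candidate must win; "any": one suffices
    min_beat_gap: float = 0.3           # s, minimum inter-beat interval
    # EEMD
    nstd: float = 0.03                  # ensemble noise sigma / signal sigma
    ne: int = 100                       # ensemble size
    max_sift: int = 50                  # sifting iterations cap per mode
    sd_stop: float = 0.2                # Cauchy SD sifting stop criterion
    # fusion / refinement
    region_ms: float = 40.0             # regional search half-window around S(t) peaks
    history: int = 9                    # offsets remembered for the trend rule
    trend_rule: str = "median"          # "median" of offsets or "count" of left/right
    refine_ms: float = 12.0             # half-window for raw-signal peak refinement
    # misc
    imf_band: tuple = (1.0, 12.0)       # Hz, admissible cardiac-mode band
    include_interpolated_in_hrv: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bcg_band", "ecg_band", "jband", "imf_band"):
            band = tuple(float(x) for x in getattr(self, name))
            if len(band) != 2 or not band[0] < band[1]:
                raise ValueError(f"{name} must be (low, high) with low < high, got {band}")
            setattr(self, name, band)
        if not self.wt_start <= self.wt_max:
            raise ValueError("wt_start must not exceed wt_max")
        if not 0 <= self.nstd < 1:
            raise ValueError("nstd must lie in [0, 1)")
        if self.ne < 1:
            raise ValueError("ne must be >= 1")
        if self.prominence_quantifier not in ("all", "any"):
            raise ValueError("prominence_quantifier must be 'all' or 'any'")
        if self.trend_rule not in ("median", "count"):
            raise ValueError("trend_rule must be 'median' or 'count'")

    def validate_against_fs(self, fs: float) -> None:
        """Check band edges against the Nyquist frequency of a record."""
        for name in ("bcg_band", "ecg_band", "jband"):
            lo, hi = getattr(self, name)
            if hi >= fs / 2:
                raise ValueError(f"{name} upper edge {hi} Hz >= Nyquist {fs / 2} Hz")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
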