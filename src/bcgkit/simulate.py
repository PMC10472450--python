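"""Synthetic BCG/ECG generator with exact ground truth.

Real bed-sensor BCG recordings of the kind this pipeline targets are not
publicly deposited, so the test and acceptance machinery runs on simulated
records that reproduce the statistical structure the detector must cope
with: a W-shaped HIJKL complex per heartbeat (with optional H/L dominance
over J), respiratory-sinus-arrhythmia-structured inter-beat intervals,
residual respiration near 0.3 Hz, broadband noise and motion-artifact
bursts.  Each heartbeat wave is a Gaussian lobe, so the true extremum of
every I/J/K lobe is known exactly before noise is added and is exported as
ground truth alongside a stylized ECG R-spike train.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .records import BeatAnnotations, SignalRecord

__all__ = ["SimConfig", "GroundTruth", "generate_ibi", "simulate_record", "hard_mode"]

# (latency relative to the J fiducial [s], amplitude [J units], width [s]).
# Negative amplitudes are the I and K troughs; latencies span ~440 ms so the
# I-K width is ~160 ms, typical of adult supine BCG.
DEFAULT_WAVES = {
    "H": (-0.150, 0.45, 0.022),
    "I": (-0.080, -0.60, 0.020),
    "J": (0.000, 1.00, 0.020),
    "K": (0.080, -0.65, 0.020),
    "L": (0.150, 0.35, 0.024),
    "M": (0.220, 0.18, 0.030),
    "N": (0.290, 0.12, 0.032),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cardiomechanical signal.

    Units: frequencies in Hz, times and widths in seconds, amplitudes
    relative to a unit J wave.
    """

    fs: float = 250.0
    duration_s: float = 60.0
    mean_hr_bpm: float = 60.0
    sdnn_s: float = 0.04           # target SD of the inter-beat intervals
    rsa_freq_hz: float = 0.3       # respiratory sinus arrhythmia frequency
    rsa_depth_s: float = 0.02      # amplitude of the sinusoidal IBI component
    wave_params: dict = field(default_factory=lambda: dict(DEFAULT_WAVES))
    r_to_j_s: float = 0.25         # fixed ECG-R to BCG-J latency
    resp_freq_hz: float = 0.3      # residual respiration left by the front end
    resp_amplitude: float = 0.3
    noise_sigma: float = 0.05      # white-noise SD, J units
    band_noise_sigma: float = 0.0  # extra 1-12 Hz in-band noise SD
    artifact_rate_per_min: float = 0.5
    artifact_duration_s: float = 1.0
    artifact_gain: float = 6.0     # burst SD in J units
    seed: int = 0

    def __post_init__(self) -> None:
        if 60.0 / self.mean_hr_bpm < 0.3:
            raise ValueError(
                f"mean_hr_bpm={self.mean_hr_bpm} implies intervals below the 0.3 s floor"
            )
        lat = [self.wave_params[w][0] for w in "HIJKLMN" if w in self.wave_params]
        if lat != sorted(lat):
            raise ValueError("wave latencies must be ordered H<I<J<K<L<M<N")
        if any(p[2] <= 0 for p in self.wave_params.values()):
            raise ValueError("wave widths must be positive")


def hard_mode(config: SimConfig | None = None) -> SimConfig:
    """Preset where the L wave outgrows the J wave.

    Subjects whose H or L lobe rivals J make the band-energy peak shift
    consistently off the J wave; this preset exercises the trend-following
    branch of the fusion rule.
    """
    cfg = config if config is not None else SimConfig()
    waves = dict(cfg.wave_params)
    lat, amp, width = waves["L"]
    jamp = waves["J"][1]
    waves["L"] = (lat, 1.1 * jamp, width)
    return replace(cfg, wave_params=waves)


@dataclass
class GroundTruth:
    """Exact beat annotations and reference trains for a simulated record."""

    annotations: BeatAnnotations
    r_indices: np.ndarray
    ibi_s: np.ndarray
    artifact_mask: np.ndarray


def generate_ibi(config: SimConfig, n_beats: int) -> np.ndarray:
    """Draw ``n_beats - 1`` inter-beat intervals (seconds).

    The intervals are a fixed mean (60/HR) plus a sinusoidal RSA component
    and white jitter whose variance is chosen so the total sample SD is
    close to ``sdnn_s``; every interval is clipped at the 0.3 s
    physiological floor.
    """
    if n_beats < 2:
        raise ValueError("need at least 2 beats for an interval sequence")
    base = 60.0 / config.mean_hr_bpm
    if base < 0.3:
        raise ValueError("mean interval below the 0.3 s floor")
    rng = np.random.default_rng(config.seed)
    n = n_beats - 1
    t_nominal = np.arange(n) * base
    rsa = config.rsa_depth_s * np.sin(2 * np.pi * config.rsa_freq_hz * t_nominal)
    rsa_var = config.rsa_depth_s**2 / 2.0
    jitter_sd = float(np.sqrt(max(config.sdnn_s**2 - rsa_var, 0.0)))
    intervals = base + rsa + rng.normal(0.0, jitter_sd, size=n)
    return np.maximum(intervals, 0.3)


def _band_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """White noise band-limited to 1-12 Hz, scaled to the requested SD."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [1.0, 12.0], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    s = shaped.std()
    return shaped * (sd / s) if s > 0 else shaped


def simulate_record(config: SimConfig) -> tuple[SignalRecord, GroundTruth]:
    """Simulate one annotated BCG(+ECG) record.

    Returns the record (channels ``bcg`` and ``ecg``) and the ground truth
    holding exact I/J/K sample indices (extrema of the clean beat train
    before respiration/noise are added), ECG R-peak samples, true
    inter-beat intervals and the motion-artifact mask.
    """
    fs = config.fs
    n = int(round(config.duration_s * fs))
    tail = max(p[0] + 3 * p[2] for p in config.wave_params.values())
    head = -min(p[0] - 3 * p[2] for p in config.wave_params.values())
    t0 = max(head, config.r_to_j_s + 0.02) + 0.1
    if config.duration_s < t0 + tail + 2 * (60.0 / config.mean_hr_bpm):
        raise ValueError("duration too short for at least 2 beats")
    rng = np.random.default_rng(config.seed)

    n_max = int(np.ceil(config.duration_s * config.mean_hr_bpm / 60.0)) + 8
    ibi_all = generate_ibi(config, n_max + 1)
    j_times = t0 + np.concatenate([[0.0], np.cumsum(ibi_all)])
    j_times = j_times[j_times < config.duration_s - tail - 0.05]
    if j_times.size < 2:
        raise ValueError("duration too short for at least 2 beats")
    ibi_s = np.diff(j_times)

    t = np.arange(n) / fs
    clean = np.zeros(n)
    for tj in j_times:
        for lat, amp, width in config.wave_params.values():
            centre = tj + lat
            lo = max(int((centre - 5 * width) * fs), 0)
            hi = min(int((centre + 5 * width) * fs) + 1, n)
            tw = t[lo:hi]
            clean[lo:hi] += amp * np.exp(-0.5 * ((tw - centre) / width) ** 2)

    # Exact ground truth from the clean beat train: J is the argmax near its
    # nominal time, I and K the nearest local minima flanking it.
    beats = []
    half = int(round(0.03 * fs))
    for tj in j_times:
        jc = int(round(tj * fs))
        lo, hi = max(jc - half, 0), min(jc + half + 1, n)
        j_idx = lo + int(np.argmax(clean[lo:hi]))
        i_idx = _nearest_local_min(clean, j_idx, direction=-1, limit=int(0.2 * fs))
        k_idx = _nearest_local_min(clean, j_idx, direction=+1, limit=int(0.2 * fs))
        beats.append((i_idx, j_idx, k_idx))
    annotations = BeatAnnotations(beats=beats, valid=[True] * len(beats), fs=fs)

    bcg = clean.copy()
    if config.resp_amplitude:
        phase = rng.uniform(0, 2 * np.pi)
        bcg += config.resp_amplitude * np.sin(2 * np.pi * config.resp_freq_hz * t + phase)
    if config.noise_sigma:
        bcg += rng.normal(0.0, config.noise_sigma, size=n)
    if config.band_noise_sigma:
        bcg += _band_noise(rng, n, fs, config.band_noise_sigma)

    artifact_mask = np.zeros(n, dtype=bool)
    expected = config.artifact_rate_per_min * config.duration_s / 60.0
    n_bursts = rng.poisson(expected) if expected > 0 else 0
    for _ in range(n_bursts):
        start = rng.uniform(0.0, max(config.duration_s - config.artifact_duration_s, 0.0))
        lo = int(start * fs)
        hi = min(lo + int(config.artifact_duration_s * fs), n)
        burst = _band_noise(rng, hi - lo, fs, config.artifact_gain)
        window = np.hanning(hi - lo)  # taper so bursts start/stop smoothly
        bcg[lo:hi] += burst * window
        artifact_mask[lo:hi] = True

    r_times = j_times - config.r_to_j_s
    r_indices = np.round(r_times * fs).astype(np.int64)
    ecg = np.zeros(n)
    spike_w = 0.006
    for tr in r_times:
        lo = max(int((tr - 5 * spike_w) * fs), 0)
        hi = min(int((tr + 5 * spike_w) * fs) + 1, n)
        ecg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - tr) / spike_w) ** 2)

    record = SignalRecord(
        fs=fs,
        channels={"bcg": bcg, "ecg": ecg},
        meta={"simulated": True, "seed": config.seed, "n_beats": len(beats)},
    )
    truth = GroundTruth(
        annotations=annotations,
        r_indices=r_indices,
        ibi_s=ibi_s,
        artifact_mask=artifact_mask,
    )
    return record, truth


def _nearest_local_min(x: np.ndarray, start: int, direction: int, limit: int) -> int | None:
    """Index of the nearest strict local minimum of ``x`` scanning from ``start``."""
    n = x.size
    idx = start + direction
    steps = 0
    while 0 < idx < n - 1 and steps < limit:
        if x[idx] <= x[idx - 1] and x[idx] <= x[idx + 1]:
            return int(idx)
        idx += direction
        steps += 1
    return None
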