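"""Seeded synthetic biosignal generators (RESP-, EMG- and ECG-like).

These emulate the morphological structure the model has to learn — slow
quasi-periodic breathing, burst-modulated muscle noise, and the cyclic
P-QRS-T composite of the heart beat — so the whole pipeline can be
trained and evaluated without any recorded data.  They are not
physiologically validated simulators: amplitudes are in arbitrary units,
and inter-signal couplings (respiratory sinus arrhythmia, movement
artifacts, electrode noise spectra) are absent.

Three "subjects" per signal kind are shipped, differing in rate/amplitude
parameters, to exercise source discrimination.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["SUBJECTS", "gen_resp", "gen_emg", "gen_ecg", "generate"]

DEFAULT_RATE = 250.0  # samples per second

# Per-subject morphology parameters.  ECG wave positions/widths are
# fractions of the beat cycle; amplitudes arbitrary units.
SUBJECTS = {
    "resp": [
        {"base_period": 4.0, "amplitude": 1.0},
        {"base_period": 3.4, "amplitude": 0.8},
        {"base_period": 4.8, "amplitude": 1.2},
    ],
    "emg": [
        {"burst_period": 1.0, "duty": 0.40},
        {"burst_period": 0.8, "duty": 0.50},
        {"burst_period": 1.3, "duty": 0.35},
    ],
    "ecg": [
        {"heart_rate": 60.0,
         "amps": {"P": 0.15, "Q": -0.10, "R": 1.00, "S": -0.20, "T": 0.35}},
        {"heart_rate": 70.0,
         "amps": {"P": 0.12, "Q": -0.08, "R": 0.90, "S": -0.25, "T": 0.50}},
        {"heart_rate": 80.0,
         "amps": {"P": 0.20, "Q": -0.12, "R": 1.10, "S": -0.15, "T": 0.25}},
    ],
}

# PQRST centres and Gaussian widths as fractions of one cycle.
ECG_PHASES = {"P": 0.10, "Q": 0.225, "R": 0.25, "S": 0.275, "T": 0.55}
ECG_WIDTHS = {"P": 0.040, "Q": 0.010, "R": 0.012, "S": 0.010, "T": 0.060}


def _n_samples(duration: float, rate: float) -> int:
    n = int(round(duration * rate))
    if n < 1 or rate <= 0:
        raise ValueError("duration * rate must be >= 1 sample")
    return n


def gen_resp(
    duration: float,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    base_period: float = 4.0,
    amplitude: float = 1.0,
    period_jitter: float = 0.05,
    amp_drift: float = 0.10,
    noise: float = 0.01,
) -> np.ndarray:
    """Respiration-like quasi-sinusoid.

    Each breathing cycle's period is the base period perturbed by a
    multiplicative Gaussian jitter (sigma ``period_jitter``); amplitude
    drifts slowly (sinusoidal, depth ``amp_drift``, random phase) and
    white noise of sigma ``noise`` is added.  With jitter, drift and
    noise all zero the output is a pure sinusoid.
    """
    n = _n_samples(duration, rate)
    rng = np.random.default_rng(seed)
    # build the instantaneous phase cycle by cycle
    phase = np.empty(n)
    t_idx = 0
    phase_offset = 0.0
    while t_idx < n:
        period = base_period * (1.0 + period_jitter * rng.standard_normal())
        period = max(period, base_period * 0.2)
        n_cyc = max(1, int(round(period * rate)))
        seg = np.arange(min(n_cyc, n - t_idx))
        phase[t_idx:t_idx + seg.size] = phase_offset + 2 * np.pi * seg / n_cyc
        t_idx += seg.size
        phase_offset += 2 * np.pi
    t = np.arange(n) / rate
    if amp_drift > 0:
        drift_phase = rng.uniform(0, 2 * np.pi)
        amp = amplitude * (1.0 + amp_drift * np.sin(2 * np.pi * t / 30.0 + drift_phase))
    else:
        amp = amplitude
    sig = amp * np.sin(phase)
    if noise > 0:
        sig = sig + noise * rng.standard_normal(n)
    return sig


def gen_emg(
    duration: float,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    burst_period: float = 1.0,
    duty: float = 0.4,
    band: tuple[float, float] = (20.0, 110.0),
    baseline_level: float = 0.05,
) -> np.ndarray:
    """EMG-like burst-modulated band-limited noise.

    A white-noise carrier band-passed to ``band`` Hz is multiplied by a
    periodic burst envelope (period ``burst_period`` s, raised-cosine
    onsets/offsets, fraction ``duty`` of the cycle active); between bursts
    the envelope sits at ``baseline_level``, emulating resting muscle
    tone.  ``duty=1`` gives a stationary (unmodulated) carrier.
    """
    if not 0 < duty <= 1:
        raise ValueError("duty must be in (0, 1]")
    n = _n_samples(duration, rate)
    rng = np.random.default_rng(seed)
    carrier = rng.standard_normal(n)
    nyq = rate / 2
    hi = min(band[1], 0.95 * nyq)
    b, a = butter(4, [band[0] / nyq, hi / nyq], btype="band")
    carrier = filtfilt(b, a, carrier)
    carrier /= max(carrier.std(), 1e-12)
    if duty >= 1.0:
        return carrier
    t = np.arange(n) / rate
    cycle_pos = (t % burst_period) / burst_period  # in [0, 1)
    ramp = min(0.1, duty / 4)  # raised-cosine edge width (cycle fraction)
    env = np.full(n, baseline_level)
    inside = cycle_pos < duty
    x = cycle_pos[inside] / duty  # position within the burst, [0, 1)
    shape = np.ones(x.size)
    rise = x < ramp / duty
    fall = x > 1 - ramp / duty
    shape[rise] = 0.5 * (1 - np.cos(np.pi * x[rise] / (ramp / duty)))
    shape[fall] = 0.5 * (1 - np.cos(np.pi * (1 - x[fall]) / (ramp / duty)))
    env[inside] = baseline_level + (1 - baseline_level) * shape
    return carrier * env


def gen_ecg(
    duration: float,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    heart_rate: float = 60.0,
    amps: dict[str, float] | None = None,
    widths: dict[str, float] | None = None,
    phases: dict[str, float] | None = None,
    beat_jitter: float = 0.03,
    noise: float = 0.005,
) -> np.ndarray:
    """ECG-like cyclic sum of five Gaussian waves (P, Q, R, S, T).

    Each beat places the five waves at fixed phase fractions of its cycle;
    beat lengths are ``60/heart_rate`` seconds with multiplicative
    Gaussian jitter (sigma ``beat_jitter``).  The baseline is a constant
    zero plus white measurement noise.  Per-subject amplitude tables give
    the "individual traits" that distinguish sources.
    """
    amps = amps if amps is not None else SUBJECTS["ecg"][0]["amps"]
    widths = widths if widths is not None else ECG_WIDTHS
    phases = phases if phases is not None else ECG_PHASES
    n = _n_samples(duration, rate)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    sig = np.zeros(n)
    base_period = 60.0 / heart_rate
    onset = 0.0
    while onset < duration + base_period:
        period = base_period * (1.0 + beat_jitter * rng.standard_normal())
        period = max(period, base_period * 0.5)
        for wave, frac in phases.items():
            centre = onset + frac * period
            width = widths[wave] * period
            lo = np.searchsorted(t, centre - 5 * width)
            hi = np.searchsorted(t, centre + 5 * width)
            if lo < hi:
                seg = t[lo:hi]
                sig[lo:hi] += amps[wave] * np.exp(-0.5 * ((seg - centre) / width) ** 2)
        onset += period
    if noise > 0:
        sig = sig + noise * rng.standard_normal(n)
    return sig


def generate(kind: str, subject: int = 1, duration: float = 60.0,
             rate: float = DEFAULT_RATE, seed: int = 0, **overrides) -> np.ndarray:
    """Generate a signal for one of the shipped subjects.

    ``subject`` is 1-based.  Keyword overrides replace the subject's
    stored morphology parameters.
    """
    if kind not in SUBJECTS:
        raise ValueError(f"unknown signal kind '{kind}'")
    table = SUBJECTS[kind]
    if not 1 <= subject <= len(table):
        raise ValueError(f"subject must be 1..{len(table)}")
    params = {**table[subject - 1], **overrides}
    fn = {"resp": gen_resp, "emg": gen_emg, "ecg": gen_ecg}[kind]
    return fn(duration=duration, rate=rate, seed=seed, **params)
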