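"""Synthetic cortical-excitability phantom.

A phantom is a simulated subject with a known ground truth: a spatial
excitability field (Gaussian fall-off around a hotspot coordinate), a
sigmoidal input--output recruitment curve mapping effective stimulation
intensity to motor-evoked-potential (MEP) peak-to-peak amplitude, and a
noise model (multiplicative lognormal amplitude noise, Gaussian latency
jitter, baseline EMG noise, Bernoulli muscle pre-activation).  Every other
module in the package can be driven end-to-end against a phantom, so the
whole search pipeline is testable without hardware or human subjects.

The expected (noise-free) amplitude at scalp position ``p`` and stimulator
intensity ``I`` (% of maximum stimulator output, MSO) is

    A(p, I) = a_max * sigmoid(slope * (I * w(p) - i50))
    w(p)    = exp(-||p - c||^2 / (2 * sigma^2))

with ``c`` the true hotspot centre.  ``w`` attenuates the *effective*
intensity with distance, so the recruitment curve shifts rightward away
from the hotspot — the behaviour a grid search exploits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import expit

# Mean FDI (first dorsal interosseous) motor hotspot in MNI space, used as
# the seed coordinate of the coarse search grid.
FDI_MNI_MM = np.array([-34.19, -14.33, 66.83])

#: MEP search window after the pulse, ms.  Latencies are confined to it.
MEP_WINDOW_MS = (10.0, 40.0)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class RecruitmentCurve:
    """Sigmoidal input-output curve of MEP amplitude vs. intensity.

    Parameters
    ----------
    a_max : float
        Plateau peak-to-peak amplitude, uV.
    i50 : float
        Intensity at half-maximum amplitude, % MSO.
    slope : float
        Sigmoid steepness, 1/(% MSO).
    """

    a_max: float = 2000.0
    i50: float = 50.0
    slope: float = 0.3

    def __post_init__(self):
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (0 < self.i50 <= 100):
            raise ValueError("i50 must be in (0, 100]")

    def amplitude(self, effective_intensity: float) -> float:
        """Noise-free p2p amplitude (uV) at an effective intensity (% MSO)."""
        return float(self.a_max * expit(self.slope * (effective_intensity - self.i50)))

    def inverse(self, amplitude_uv: float) -> float:
        """Effective intensity (% MSO) producing ``amplitude_uv``; analytic."""
        if not (0 < amplitude_uv < self.a_max):
            raise ValueError("amplitude must lie strictly inside (0, a_max)")
        q = amplitude_uv / self.a_max
        return float(self.i50 + np.log(q / (1 - q)) / self.slope)


@dataclass
class ExcitabilityField:
    """Spatial weight w(p) in (0, 1], maximal at the hotspot centre."""

    hotspot_center: np.ndarray = field(default_factory=lambda: FDI_MNI_MM.copy())
    sigma: float = 7.0  # mm, isotropic spread
    anisotropy: np.ndarray | None = None  # optional 2x2 shape matrix, grid plane

    def __post_init__(self):
        self.hotspot_center = np.asarray(self.hotspot_center, dtype=float)
        if self.hotspot_center.shape != (3,):
            raise ValueError("hotspot_center must be a 3-vector (mm)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.anisotropy is not None:
            self.anisotropy = np.asarray(self.anisotropy, dtype=float)
            if self.anisotropy.shape != (2, 2):
                raise ValueError("anisotropy must be a 2x2 matrix")

    def weight(self, position) -> float:
        d = np.asarray(position, dtype=float) - self.hotspot_center
        if self.anisotropy is None:
            q = float(d @ d)
        else:
            # shape matrix acts on the in-plane (x, y) components only
            q = float(d[:2] @ self.anisotropy @ d[:2] + d[2] ** 2)
        return float(np.exp(-q / (2.0 * self.sigma**2)))


@dataclass
class NoiseModel:
    amp_cv: float = 0.3           # lognormal CV of the p2p amplitude
    baseline_rms: float = 5.0     # uV, background EMG noise
    preactivation_prob: float = 0.0
    preactivation_amp: float = 0.0  # uV, peak deviation of the injected burst

    def __post_init__(self):
        if min(self.amp_cv, self.baseline_rms, self.preactivation_amp) < 0:
            raise ValueError("noise parameters must be non-negative")
        if not (0.0 <= self.preactivation_prob <= 1.0):
            raise ValueError("preactivation_prob must be in [0, 1]")


@dataclass
class SubjectPhantom:
    """Ground-truth simulated subject.

    Default latency statistics follow the typical resting FDI MEP onset
    (~24 ms with ~2 ms between-trial spread); amplitude/recruitment/noise
    defaults are plain simulation configuration, not measured physiology.
    """

    field: ExcitabilityField = dataclasses.field(default_factory=ExcitabilityField)
    curve: RecruitmentCurve = dataclasses.field(default_factory=RecruitmentCurve)
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    latency_mean: float = 24.05  # ms
    latency_sd: float = 1.88     # ms

    def __post_init__(self):
        lo, hi = MEP_WINDOW_MS
        if not (lo < self.latency_mean < hi):
            raise ValueError(f"latency_mean must lie in the MEP window {MEP_WINDOW_MS}")
        if self.latency_sd < 0:
            raise ValueError("latency_sd must be non-negative")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "field": {
                "hotspot_center": [float(v) for v in self.field.hotspot_center],
                "sigma": self.field.sigma,
                "anisotropy": None
                if self.field.anisotropy is None
                else self.field.anisotropy.tolist(),
            },
            "curve": dataclasses.asdict(self.curve),
            "noise": dataclasses.asdict(self.noise),
            "latency_mean": self.latency_mean,
            "latency_sd": self.latency_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectPhantom":
        return cls(
            field=ExcitabilityField(**d.get("field", {})),
            curve=RecruitmentCurve(**d.get("curve", {})),
            noise=NoiseModel(**d.get("noise", {})),
            latency_mean=d.get("latency_mean", 24.05),
            latency_sd=d.get("latency_sd", 1.88),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SubjectPhantom":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class EMGTrace:
    """One sampled EMG epoch around a single stimulus.

    ``samples`` are in uV; the pulse occurs at sample ``stim_index``.  At
    least 300 ms of pre-stimulus signal is required so the far
    pre-activation rule (300-100 ms before the pulse) can be evaluated.
    """

    samples: np.ndarray
    rate: float          # Hz
    stim_index: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate < 5000 * (1 - 1e-9):
            raise ValueError("sampling rate must be >= 5000 Hz")
        if not (0 <= self.stim_index < len(self.samples)):
            raise ValueError("stim_index outside the trace")

    @property
    def pre_window_ms(self) -> float:
        return self.stim_index / self.rate * 1000.0

    @property
    def post_window_ms(self) -> float:
        return (len(self.samples) - self.stim_index) / self.rate * 1000.0

    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to the stimulus (0 = pulse)."""
        return (np.arange(len(self.samples)) - self.stim_index) / self.rate * 1000.0

    def replace_samples(self, samples: np.ndarray) -> "EMGTrace":
        return EMGTrace(samples=samples, rate=self.rate, stim_index=self.stim_index)


# ---------------------------------------------------------------------------
# Simulation operations
# ---------------------------------------------------------------------------

def expected_amplitude(phantom: SubjectPhantom, position, intensity: float) -> float:
    """Noise-free MEP p2p amplitude (uV) at a position and intensity.

    Deterministic simulation oracle: strictly increasing in intensity and
    strictly decreasing in distance from the hotspot at fixed positive
    intensity.
    """
    if not (0.0 <= intensity <= 100.0):
        raise ValueError("intensity must be in [0, 100] % MSO")
    w = phantom.field.weight(position)
    return phantom.curve.amplitude(intensity * w)


def sample_response(
    phantom: SubjectPhantom, position, intensity: float, rng_seed
) -> tuple[float, float, bool]:
    """Draw one noisy trial: (p2p amplitude uV, onset latency ms, preactivated).

    Amplitude noise is lognormal parameterized so its *mean* equals
    ``expected_amplitude`` (CV = ``amp_cv``).  Latency is Gaussian truncated
    to the MEP window so every synthetic MEP stays detectable.
    """
    rng = _rng(rng_seed)
    mean_amp = expected_amplitude(phantom, position, intensity)
    cv = phantom.noise.amp_cv
    if cv > 0:
        s2 = np.log1p(cv * cv)
        amp = mean_amp * np.exp(rng.normal(-0.5 * s2, np.sqrt(s2)))
    else:
        amp = mean_amp
    lo, hi = MEP_WINDOW_MS
    if phantom.latency_sd > 0:
        latency = float(rng.normal(phantom.latency_mean, phantom.latency_sd))
        for _ in range(100):
            if lo < latency < hi:
                break
            latency = float(rng.normal(phantom.latency_mean, phantom.latency_sd))
        latency = float(np.clip(latency, lo + 1e-6, hi - 1e-6))
    else:
        latency = phantom.latency_mean
    preactivated = bool(rng.random() < phantom.noise.preactivation_prob)
    return float(amp), latency, preactivated


def _mep_wavelet(rate: float, width_ms: float = 8.0) -> np.ndarray:
    """One cycle of a Hann-windowed sine — the biphasic MEP template."""
    n = max(int(round(width_ms / 1000.0 * rate)), 4)
    u = np.arange(n) / n
    return np.sin(2 * np.pi * u) * 0.5 * (1 - np.cos(2 * np.pi * u))


def synthesize_trace(
    amplitude: float,
    latency_ms: float,
    noise: NoiseModel,
    rate: float = 5000.0,
    pre_ms: float = 400.0,
    post_ms: float = 100.0,
    rng_seed=None,
    preactivated: bool = False,
) -> EMGTrace:
    """Render a full synthetic EMG epoch for one trial.

    The biphasic wavelet is scaled so its sampled peak-to-peak equals
    ``amplitude`` exactly, its onset placed ``latency_ms`` after the pulse,
    on top of Gaussian baseline noise of RMS ``noise.baseline_rms``.  When
    ``preactivated``, a 100 Hz burst of peak deviation
    ``noise.preactivation_amp`` spans -80..-10 ms so the near
    pre-activation QC rule can fire.
    """
    rng = _rng(rng_seed)
    n_pre = int(round(pre_ms / 1000.0 * rate))
    n_post = int(round(post_ms / 1000.0 * rate))
    n = n_pre + n_post
    if not (0 <= latency_ms < post_ms):
        raise ValueError("latency must fall inside the post-stimulus span")
    samples = (
        rng.normal(0.0, noise.baseline_rms, n) if noise.baseline_rms > 0 else np.zeros(n)
    )
    if amplitude > 0:
        wav = _mep_wavelet(rate)
        wav = wav * (amplitude / np.ptp(wav))
        onset = n_pre + int(round(latency_ms / 1000.0 * rate))
        end = min(onset + len(wav), n)
        if end <= onset:
            raise ValueError("latency leaves no room for the MEP waveform")
        samples[onset:end] += wav[: end - onset]
    if preactivated and noise.preactivation_amp > 0:
        t = np.arange(n_pre) / rate * 1000.0 - pre_ms  # ms, negative
        burst = (-80.0 <= t) & (t <= -10.0)
        samples[:n_pre][burst] += noise.preactivation_amp * np.sin(
            2 * np.pi * 100.0 * (t[burst] / 1000.0)
        )
    return EMGTrace(samples=samples, rate=rate, stim_index=n_pre)


def simulate_trial(
    phantom: SubjectPhantom,
    position,
    intensity: float,
    rng_seed,
    rate: float = 5000.0,
    pre_ms: float = 400.0,
    post_ms: float = 100.0,
) -> tuple[EMGTrace, float, float, bool]:
    """Full-trace trial: returns (trace, true p2p, true latency, preactivated)."""
    rng = _rng(rng_seed)
    amp, latency, pre = sample_response(phantom, position, intensity, rng)
    trace = synthesize_trace(
        amp, latency, phantom.noise, rate=rate, pre_ms=pre_ms, post_ms=post_ms,
        rng_seed=rng, preactivated=pre,
    )
    return trace, amp, latency, pre


def pulse_train(n: int, isi: float = 4.0, jitter_frac: float = 0.10, rng_seed=None) -> np.ndarray:
    """Onset times (s) of ``n`` pulses with uniformly jittered spacing.

    Successive gaps are drawn uniformly from ``isi * (1 +/- jitter_frac)``
    (4 s with 10% jitter by default), so times are strictly increasing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isi <= 0:
        raise ValueError("isi must be positive")
    if not (0.0 <= jitter_frac < 1.0):
        raise ValueError("jitter_frac must be in [0, 1)")
    rng = _rng(rng_seed)
    gaps = rng.uniform(isi * (1 - jitter_frac), isi * (1 + jitter_frac), n - 1)
    return np.concatenate([[0.0], np.cumsum(gaps)])


# ---------------------------------------------------------------------------
# Trace CSV I/O (columns: time_s, amplitude_uV; stimulus at time 0)
# ---------------------------------------------------------------------------

def trace_to_csv(trace: EMGTrace, path) -> None:
    import pandas as pd

    t = trace.times_ms() / 1000.0
    pd.DataFrame({"time_s": t, "amplitude_uV": trace.samples}).to_csv(path, index=False)


def trace_from_csv(path) -> EMGTrace:
    import pandas as pd

    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    stim_index = int(np.argmin(np.abs(t)))
    return EMGTrace(samples=df["amplitude_uV"].to_numpy(), rate=rate, stim_index=stim_index)
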