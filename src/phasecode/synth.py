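"""Synthetic behavioral and neural datasets with known phase structure.

Behavioral generator: binomial choice data whose per-SOA choice probability
is sinusoidally modulated at a set frequency, emulating the entrainment
psychophysics design (12 SOAs spanning two 6.25 Hz cycles, ~18
participants, tens of trials per SOA).

Neural generator: multi-participant sets of single-trial oscillatory time
series ("streams" standing in for source-localized ROI activity, e.g.
STG-like and MTG-like).  Each stream is a sum of narrowband oscillations
with stochastic envelopes plus 1/f noise.  Binary responses under a given
labeling (consonant-frequency or word-frequency percept) are drawn with
probability sigma(beta * cos(phi - phi0)) where phi is the trial's true
oscillatory phase at one specific (frequency, time) point of one specific
stream; labelings without an effect draw fair coins.  The preferred phase
phi0 is constant within a participant and uniformly random across
participants, so group statistics must be phase-agnostic (as the magnitude
+ cluster pipeline is).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

DEFAULT_SOAS = tuple(np.linspace(0.1, 0.42, 12))

STREAMS = ("STG", "MTG")
LABELINGS = ("consonant", "word")


# ---------------------------------------------------------------------------
# behavioral


@dataclass(frozen=True)
class BehavioralSimSpec:
    """Design of a synthetic entrainment psychophysics dataset.

    ``modulation_amplitude`` is in probability units; the per-trial choice
    probability is ``base_prob + amplitude * sin(2 pi f SOA + phase)``.
    ``phase_jitter`` adds a uniform per-participant offset in
    [-jitter, +jitter] radians to the common modulation phase.
    ``amplitude_second_half`` lets the modulation differ between experiment
    halves (None = same amplitude).
    """

    n_participants: int = 18
    n_trials_per_soa: int = 40
    soas: tuple = DEFAULT_SOAS
    base_prob: float = 0.5
    modulation_amplitude: float = 0.15
    modulation_frequency: float = 6.25
    modulation_phase: float = 0.0
    phase_jitter: float = 0.0
    amplitude_second_half: float | None = None
    morph: str = "xɑt-dɑt"
    seed: int = 0

    def __post_init__(self):
        amps = [self.modulation_amplitude]
        if self.amplitude_second_half is not None:
            amps.append(self.amplitude_second_half)
        for a in amps:
            lo, hi = self.base_prob - a, self.base_prob + a
            if lo < 0.0 or hi > 1.0:
                raise ValueError("choice probabilities leave [0, 1]")

    def with_(self, **kw):
        return replace(self, **kw)


def generate_behavioral_dataset(spec: BehavioralSimSpec) -> pd.DataFrame:
    """Simulate a response table (participant, soa_s, morph, response, half)."""
    rng = np.random.default_rng(spec.seed)
    soas = np.asarray(spec.soas, float)
    n_p, n_s, n_t = spec.n_participants, len(soas), spec.n_trials_per_soa
    n_half1 = n_t // 2
    phases = np.full(n_p, spec.modulation_phase)
    if spec.phase_jitter > 0:
        phases = phases + rng.uniform(-spec.phase_jitter, spec.phase_jitter,
                                      n_p)
    amp2 = (spec.modulation_amplitude if spec.amplitude_second_half is None
            else spec.amplitude_second_half)
    amps = np.r_[np.full(n_half1, spec.modulation_amplitude),
                 np.full(n_t - n_half1, amp2)]           # per trial slot
    half = np.r_[np.ones(n_half1, int), np.full(n_t - n_half1, 2, int)]
    arg = 2 * np.pi * spec.modulation_frequency * soas
    # probability per (participant, soa, trial slot)
    prob = (spec.base_prob
            + amps[None, None, :] * np.sin(arg[None, :, None]
                                           + phases[:, None, None]))
    resp = rng.random((n_p, n_s, n_t)) < prob
    pid = np.array([f"p{i:02d}" for i in range(n_p)])
    return pd.DataFrame({
        "participant": np.repeat(pid, n_s * n_t),
        "soa_s": np.tile(np.repeat(soas, n_t), n_p),
        "morph": spec.morph,
        "response": resp.reshape(-1).astype(int),
        "half": np.tile(half, n_p * n_s),
    })


# ---------------------------------------------------------------------------
# neural


@dataclass(frozen=True)
class PhaseEffectSpec:
    """A phase-behavior coupling: which labeling reads which stream where."""

    labeling: str
    stream: str
    frequency: float    # Hz
    time: float         # s, within the analysis window
    beta: float = 1.0


@dataclass(frozen=True)
class NeuralSimSpec:
    """Design of a synthetic multi-participant trial-stream dataset.

    Every stream contains narrowband oscillations at all effect frequencies
    (and a background alpha band) regardless of coupling, so that a null
    stream differs from an effect stream only in the phase-response
    coupling, not in its spectrum.  Trial count reflects the scale of the
    source experiment (a few hundred ambiguous-word trials per
    participant).
    """

    n_participants: int = 20
    n_trials: int = 150
    sampling_rate: float = 200.0
    epoch: tuple = (-1.2, 0.7)           # s, relative to stimulus onset
    oscillation_amplitude: float = 1.0
    envelope_bandwidth: float = 1.0      # Hz FWHM of the narrowband envelope
    background_bands: tuple = ((10.0, 1.0),)
    noise_level: float = 1.0             # 1/f noise std
    noise_exponent: float = 1.0          # power ~ 1/f^exponent
    effects: tuple = (
        PhaseEffectSpec("consonant", "STG", 7.6, -0.2, 1.0),
        PhaseEffectSpec("word", "MTG", 6.4, -0.1, 1.0),
    )
    streams: tuple = STREAMS
    labelings: tuple = LABELINGS
    seed: int = 0

    def __post_init__(self):
        for eff in self.effects:
            if not self.epoch[0] <= eff.time <= self.epoch[1]:
                raise ValueError("effect time outside the epoch")
            if eff.frequency >= self.sampling_rate / 2:
                raise ValueError("effect frequency above Nyquist")
            if eff.stream not in self.streams:
                raise ValueError(f"unknown stream {eff.stream!r}")
            if eff.labeling not in self.labelings:
                raise ValueError(f"unknown labeling {eff.labeling!r}")

    def with_(self, **kw):
        return replace(self, **kw)

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.epoch[1] - self.epoch[0]) * self.sampling_rate)) + 1
        return self.epoch[0] + np.arange(n) / self.sampling_rate


def _narrowband(rng, n_trials, times, freq, bandwidth_hz, sfreq):
    """Narrowband oscillation via a smoothed complex envelope.

    Returns (signal, analytic) where ``analytic`` carries the true
    instantaneous phase.  The envelope autocorrelation time is set by the
    bandwidth: sigma_t = 1 / (pi * bandwidth).
    """
    n = len(times)
    env = rng.standard_normal((n_trials, n)) + 1j * rng.standard_normal(
        (n_trials, n))
    sigma_t = 1.0 / (np.pi * bandwidth_hz)
    env = gaussian_filter1d(env, sigma=sigma_t * sfreq, axis=1,
                            mode="reflect")
    carrier = np.exp(2j * np.pi * freq * times)[None, :]
    analytic = env * carrier
    signal = analytic.real
    rms = signal.std(axis=1, keepdims=True) + 1e-12
    return signal / rms, analytic


def _one_over_f_noise(rng, n_trials, n_samples, sfreq, exponent, level):
    white = rng.standard_normal((n_trials, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    shaped = np.fft.irfft(spec * shaping[None, :], n=n_samples, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True) + 1e-12
    return level * shaped


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_neural_dataset(spec: NeuralSimSpec) -> dict:
    """Simulate trial streams and phase-coupled responses.

    Returns a dict with keys ``streams`` (stream -> (P, trials, samples)),
    ``responses`` (labeling -> (P, trials)), ``true_phase``
    (labeling -> (P, trials) true phase at the effect point, nan when the
    labeling has no effect), ``times``, ``sfreq``, ``spec``.
    """
    rng = np.random.default_rng(spec.seed)
    times = spec.times
    sfreq = spec.sampling_rate
    n, p = spec.n_trials, spec.n_participants
    effect_by_label = {e.labeling: e for e in spec.effects}
    effect_freqs = sorted({e.frequency for e in spec.effects})

    streams = {s: np.empty((p, n, len(times))) for s in spec.streams}
    responses = {lb: np.empty((p, n), dtype=np.int8) for lb in spec.labelings}
    true_phase = {lb: np.full((p, n), np.nan) for lb in spec.labelings}

    for ip in range(p):
        preferred = {lb: rng.uniform(-np.pi, np.pi) for lb in spec.labelings}
        analytic = {}
        for s in spec.streams:
            x = _one_over_f_noise(rng, n, len(times), sfreq,
                                  spec.noise_exponent, spec.noise_level)
            for freq, amp in spec.background_bands:
                sig, _ = _narrowband(rng, n, times, freq,
                                     spec.envelope_bandwidth, sfreq)
                x += amp * sig
            for freq in effect_freqs:
                sig, ana = _narrowband(rng, n, times, freq,
                                       spec.envelope_bandwidth, sfreq)
                x += spec.oscillation_amplitude * sig
                analytic[(s, freq)] = ana
            streams[s][ip] = x
        for lb in spec.labelings:
            eff = effect_by_label.get(lb)
            if eff is None or eff.beta == 0.0:
                responses[lb][ip] = rng.random(n) < 0.5
                continue
            idx = int(round((eff.time - spec.epoch[0]) * sfreq))
            phi = np.angle(analytic[(eff.stream, eff.frequency)][:, idx])
            prob = _sigmoid(eff.beta * np.cos(phi - preferred[lb]))
            responses[lb][ip] = rng.random(n) < prob
            true_phase[lb][ip] = phi
    return {"streams": streams, "responses": responses,
            "true_phase": true_phase, "times": times, "sfreq": sfreq,
            "spec": spec}
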