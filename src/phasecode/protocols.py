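"""Simulated experiments on the categorization model.

Three protocols mirror the behavioral and neural experiments:

1. a *psychometric sweep*: every morph level of a word-pair continuum is
   presented at oscillatory phases evenly spanning one cycle and the mean
   categorization value defines a psychometric curve, whose fitted midpoint
   is the most ambiguous morph;
2. an *entrainment experiment*: a rhythmic train of empty-word stimuli fixes
   the oscillator phase, after which the ambiguous morph is presented at a
   grid of stimulus onset asynchronies (SOAs) spanning two oscillation
   cycles;
3. a *random-phase experiment*: the ambiguous morph is presented at uniform
   random phases on single trials, yielding per-trial (phase, choice)
   records from which circular phase differences between response categories
   are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import circmean

from . import lexicon as lx
from .lexicon import Connectivity, TraitLexicon, build_connectivity
from .model import GUESS, ModelConfig, apply_sensitivity, simulate_batch

#: The four morph continua of the study (endpoint_a -> coded 0,
#: endpoint_b -> coded 1): two consonant morphs and two vowel morphs.
STUDY_SPECTRA = (
    (lx.W_XAT_LONG, lx.W_DAT_LONG),    # /xat/-/dat/   consonant, long vowel
    (lx.W_XAT_SHORT, lx.W_DAT_SHORT),  # /xɑt/-/dɑt/   consonant, short vowel
    (lx.W_DAT_SHORT, lx.W_DAT_LONG),   # /dɑt/-/dat/   vowel, /d/ onset
    (lx.W_XAT_SHORT, lx.W_XAT_LONG),   # /xɑt/-/xat/   vowel, /x/ onset
)

DEFAULT_SOAS = np.linspace(0.1, 0.42, 12)  # s; exactly two 6.25 Hz cycles

_LEAD_MS = 200.0  # settle time before the first stimulus
_TAIL_MS = 150.0  # post-stimulus time kept in the simulation


@dataclass(frozen=True)
class MorphSpectrum:
    """A morph continuum between two words differing in exactly one trait."""

    endpoint_a: str
    endpoint_b: str
    proportions: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 10))

    def __post_init__(self):
        props = np.asarray(self.proportions, dtype=float)
        if np.any(np.diff(props) <= 0):
            raise ValueError("proportions must be strictly increasing")
        object.__setattr__(self, "proportions", props)

    def candidates(self, lexicon: TraitLexicon, level: str):
        """Candidate node pair at a level, ordered (endpoint_a, endpoint_b)."""
        if level == "word":
            return (self.endpoint_a, self.endpoint_b)
        trait = lexicon.differing_trait(self.endpoint_a, self.endpoint_b)
        pos = 0 if trait == "consonant" else 1
        return (self.endpoint_a[pos], self.endpoint_b[pos])


@dataclass
class PsychometricCurve:
    proportions: np.ndarray
    value_combined: np.ndarray
    value_phoneme: np.ndarray
    value_word: np.ndarray


@dataclass
class PsychometricFit:
    slope: float
    midpoint: float
    residual: float
    ok: bool


@dataclass
class PhaseTrialRecord:
    trial: int
    phase: float          # oscillator phase at probe onset, [-pi, pi)
    phoneme_choice: str   # word id (via its distinguishing phoneme) or GUESS id
    word_choice: str


def make_morph_input(spectrum: MorphSpectrum, p: float,
                     lexicon: TraitLexicon) -> np.ndarray:
    """Input-word amplitudes for morph proportion ``p`` of endpoint_b."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("morph proportion must lie in [0, 1]")
    amps = np.zeros(len(lexicon.words))
    amps[lexicon.word_index(spectrum.endpoint_a)] = 1.0 - p
    amps[lexicon.word_index(spectrum.endpoint_b)] = p
    return amps


def phase_to_onset_ms(phase: float, config: ModelConfig,
                      lead_ms: float = _LEAD_MS) -> float:
    """Earliest onset >= lead_ms at which the oscillator is at ``phase``."""
    period = config.period_ms
    t = ((phase - config.osc_phase_offset) % (2 * np.pi)) / (2 * np.pi) * period
    while t < lead_ms:
        t += period
    return round(t / config.dt_ms) * config.dt_ms


def onset_phase(t_ms, config: ModelConfig):
    """Oscillator phase at time ``t_ms``, wrapped to [-pi, pi)."""
    ph = (2 * np.pi * config.osc_frequency * np.asarray(t_ms, float) / 1000.0
          + config.osc_phase_offset)
    return (ph + np.pi) % (2 * np.pi) - np.pi


def _first_crossings(crossed, activation, thresholds, cand_idx, onset_idx):
    """Per batch element: decision among two candidates, vectorized.

    Simultaneous crossings are resolved by the larger suprathreshold
    activation (see :func:`phasecode.model.decide`).  Returns ``values`` in
    {0., 1., nan} (nan = guess / no decision) for the candidate coding
    (cand_idx[0] -> 0, cand_idx[1] -> 1).
    """
    n_b, _, n_t = crossed.shape
    t_grid = np.arange(n_t)
    after = t_grid[None, :] >= onset_idx[:, None]
    res = []
    for c in cand_idx:
        mask = crossed[:, c, :] & after
        has = mask.any(axis=1)
        first = np.argmax(mask, axis=1)
        act = activation[np.arange(n_b), c, first] - thresholds[c]
        res.append((has, first, act))
    (has0, t0, a0), (has1, t1, a1) = res
    values = np.full(n_b, np.nan)
    only0 = has0 & ~has1
    only1 = has1 & ~has0
    both = has0 & has1
    values[only0] = 0.0
    values[only1] = 1.0
    earlier0 = both & (t0 < t1)
    earlier1 = both & (t1 < t0)
    values[earlier0] = 0.0
    values[earlier1] = 1.0
    tie = both & (t0 == t1)
    values[tie & (a0 > a1)] = 0.0
    values[tie & (a1 > a0)] = 1.0
    # exact activation tie stays nan -> guess
    return values


def _resolve_guesses(values, mode, rng=None):
    out = values.copy()
    nan = np.isnan(out)
    if mode == "deterministic":
        out[nan] = 0.5
    else:
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        out[nan] = rng.integers(0, 2, size=int(nan.sum())).astype(float)
    return out


def _run_probe_batch(config, connectivity, thresholds, lexicon, amps_batch,
                     onsets_ms, t_max_ms):
    """Simulate a batch of single-probe presentations."""
    n_b = len(onsets_ms)
    n_t = int(np.ceil(t_max_ms / config.dt_ms))
    times = np.arange(n_t) * config.dt_ms
    drive = np.zeros((n_b, n_t, len(lexicon.words)))
    dur = config.stimulus_duration_ms
    for i, (amps, on) in enumerate(zip(amps_batch, onsets_ms)):
        sel = (times >= on) & (times < on + dur)
        if config.input_mode == "linear_ramp":
            frac = (times[sel] - on) / dur
            drive[i, sel, :] = frac[:, None] * amps[None, :]
        else:
            drive[i, sel, :] = amps[None, :]
    return simulate_batch(drive, config, connectivity, thresholds)


def run_psychometric_sweep(config: ModelConfig, spectrum: MorphSpectrum,
                           lexicon: TraitLexicon,
                           connectivity: Connectivity | None = None,
                           phase_grid_size: int = 16) -> PsychometricCurve:
    """Present every morph level at phases evenly spanning one cycle.

    The categorization value of each presentation is the average of the
    phoneme-level and word-level decisions (guesses coded 0.5); the curve
    averages these across phases per morph proportion.
    """
    if phase_grid_size < 8:
        raise ValueError("phase_grid_size must be >= 8")
    if connectivity is None:
        connectivity = build_connectivity(lexicon, config.topology)
    thresholds = apply_sensitivity(lexicon, config)
    phases = np.linspace(-np.pi, np.pi, phase_grid_size, endpoint=False)
    onsets = np.array([phase_to_onset_ms(ph, config) for ph in phases])
    props = spectrum.proportions
    amps_batch = []
    onset_rep = []
    for p in props:
        amps = make_morph_input(spectrum, p, lexicon)
        for on in onsets:
            amps_batch.append(amps)
            onset_rep.append(on)
    onset_rep = np.asarray(onset_rep)
    t_max = onset_rep.max() + config.stimulus_duration_ms + _TAIL_MS
    times, activation, crossed = _run_probe_batch(
        config, connectivity, thresholds, lexicon, amps_batch, onset_rep,
        t_max)
    onset_idx = np.round(onset_rep / config.dt_ms).astype(int)

    level_means = {}
    for level in ("phoneme", "word"):
        cand = spectrum.candidates(lexicon, level)
        ids = lexicon.phonemes if level == "phoneme" else lexicon.words
        cand_idx = [ids.index(c) for c in cand]
        vals = _first_crossings(crossed[level], activation[level],
                                thresholds[level], cand_idx, onset_idx)
        vals = _resolve_guesses(vals, "deterministic")
        level_means[level] = vals.reshape(len(props), len(phases)).mean(axis=1)
    combined = 0.5 * (level_means["phoneme"] + level_means["word"])
    return PsychometricCurve(props, combined, level_means["phoneme"],
                             level_means["word"])


def _logistic(params, x):
    k, m = params
    return 1.0 / (1.0 + np.exp(-k * (x - m)))


def fit_psychometric(curve: PsychometricCurve) -> PsychometricFit:
    """Least-squares logistic fit; the midpoint is the most ambiguous morph."""
    x = np.asarray(curve.proportions, float)
    y = np.asarray(curve.value_combined, float)
    if len(x) < 5:
        raise ValueError("need at least 5 morph levels to fit")
    m0 = float(x[np.argmin(np.abs(y - 0.5))])
    sign = 1.0 if y[-1] >= y[0] else -1.0
    sol = least_squares(lambda q: _logistic(q, x) - y, x0=[8.0 * sign, m0],
                        method="lm", max_nfev=2000)
    k, m = sol.x
    resid = float(np.sqrt(np.mean(sol.fun ** 2)))
    ok = bool(np.ptp(y) >= 0.1 and abs(k) > 1e-2 and resid < 0.15
              and 0.0 <= m <= 1.0)
    return PsychometricFit(slope=float(k),
                           midpoint=float(np.clip(m, 0.0, 1.0)),
                           residual=resid, ok=ok)


def most_ambiguous_morph(config: ModelConfig, spectrum: MorphSpectrum,
                         lexicon: TraitLexicon, **kwargs) -> float:
    """Fitted 50% point of the psychometric curve for this spectrum."""
    curve = run_psychometric_sweep(config, spectrum, lexicon, **kwargs)
    return fit_psychometric(curve).midpoint


def run_entrainment_experiment(config: ModelConfig, spectrum: MorphSpectrum,
                               ambiguous_p: float, lexicon: TraitLexicon,
                               soas=None, n_train: int = 5,
                               connectivity: Connectivity | None = None):
    """Entrainment train of empty words followed by the morph at each SOA.

    Returns ``(soas, values)`` where ``values`` is the deterministic choice
    value (0 / 0.5 / 1 averaged over the phoneme and word levels) per SOA.
    """
    soas = DEFAULT_SOAS if soas is None else np.asarray(soas, float)
    if soas.size == 0:
        raise ValueError("need at least one SOA")
    if np.any(soas * 1000.0 < config.dt_ms):
        raise ValueError("SOA shorter than one time step")
    if connectivity is None:
        connectivity = build_connectivity(lexicon, config.topology)
    thresholds = apply_sensitivity(lexicon, config)
    period = config.period_ms
    t0 = np.ceil(_LEAD_MS / period) * period
    train_onsets = [round(t0 + k * period) for k in range(n_train)]
    last = train_onsets[-1]
    probe_onsets = np.array(
        [round((last + soa * 1000.0) / config.dt_ms) * config.dt_ms
         for soa in soas])
    dur = config.stimulus_duration_ms
    empty_amps = np.zeros(len(lexicon.words))
    empty_amps[lexicon.word_index(lx.EMPTY)] = 1.0
    morph_amps = make_morph_input(spectrum, ambiguous_p, lexicon)

    n_t = int(np.ceil((probe_onsets.max() + dur + _TAIL_MS) / config.dt_ms))
    times = np.arange(n_t) * config.dt_ms
    drive = np.zeros((len(soas), n_t, len(lexicon.words)))
    for on in train_onsets:
        sel = (times >= on) & (times < on + dur)
        drive[:, sel, :] += empty_amps[None, None, :]
    for i, on in enumerate(probe_onsets):
        sel = (times >= on) & (times < on + dur)
        drive[i, sel, :] += morph_amps[None, :]
    if config.input_mode == "linear_ramp":
        # ramp each pulse: rebuild with per-event ramps (rare path, loop)
        drive[:] = 0.0
        for i, pon in enumerate(probe_onsets):
            for on, amps in [(o, empty_amps) for o in train_onsets] + [
                    (pon, morph_amps)]:
                sel = (times >= on) & (times < on + dur)
                frac = (times[sel] - on) / dur
                drive[i, sel, :] += frac[:, None] * amps[None, :]

    times, activation, crossed = simulate_batch(drive, config, connectivity,
                                                thresholds)
    onset_idx = np.round(probe_onsets / config.dt_ms).astype(int)
    values = np.zeros(len(soas))
    for level in ("phoneme", "word"):
        cand = spectrum.candidates(lexicon, level)
        ids = lexicon.phonemes if level == "phoneme" else lexicon.words
        cand_idx = [ids.index(c) for c in cand]
        vals = _first_crossings(crossed[level], activation[level],
                                thresholds[level], cand_idx, onset_idx)
        values += 0.5 * _resolve_guesses(vals, "deterministic")
    return soas, values


def run_random_phase_experiment(config: ModelConfig, spectrum: MorphSpectrum,
                                ambiguous_p: float, lexicon: TraitLexicon,
                                n_trials: int = 1000, seed: int = 0,
                                connectivity: Connectivity | None = None):
    """Present the ambiguous morph at uniform random phases, single trials.

    Guesses are resolved stochastically (a random choice of either
    endpoint).  Returns a list of :class:`PhaseTrialRecord`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if connectivity is None:
        connectivity = build_connectivity(lexicon, config.topology)
    thresholds = apply_sensitivity(lexicon, config)
    rng = np.random.default_rng(seed)
    phases = rng.uniform(-np.pi, np.pi, size=n_trials)
    onsets = np.array([phase_to_onset_ms(ph, config) for ph in phases])
    amps = make_morph_input(spectrum, ambiguous_p, lexicon)
    t_max = onsets.max() + config.stimulus_duration_ms + _TAIL_MS
    times, activation, crossed = _run_probe_batch(
        config, connectivity, thresholds, lexicon,
        [amps] * n_trials, onsets, t_max)
    onset_idx = np.round(onsets / config.dt_ms).astype(int)
    realized = onset_phase(onsets, config)

    choices = {}
    endpoints = (spectrum.endpoint_a, spectrum.endpoint_b)
    for level in ("phoneme", "word"):
        cand = spectrum.candidates(lexicon, level)
        ids = lexicon.phonemes if level == "phoneme" else lexicon.words
        cand_idx = [ids.index(c) for c in cand]
        vals = _first_crossings(crossed[level], activation[level],
                                thresholds[level], cand_idx, onset_idx)
        vals = _resolve_guesses(vals, "stochastic", rng)
        choices[level] = np.array([endpoints[int(v)] for v in vals])
    return [
        PhaseTrialRecord(trial=i, phase=float(realized[i]),
                         phoneme_choice=choices["phoneme"][i],
                         word_choice=choices["word"][i])
        for i in range(n_trials)
    ]


def compute_model_phase_differences(records, reference_word: str,
                                    level: str) -> dict:
    """Circular mean presentation phase per choice, relative to a reference.

    ``records`` may pool trials from several morph continua.  Returns a dict
    mapping each non-reference choice category to its circular mean phase
    minus that of the reference-word choices, wrapped to [-pi, pi); empty
    categories map to ``nan``.
    """
    attr = "phoneme_choice" if level == "phoneme" else "word_choice"
    by_choice = {}
    for r in records:
        by_choice.setdefault(getattr(r, attr), []).append(r.phase)
    if reference_word not in by_choice or not by_choice[reference_word]:
        raise ValueError(f"no trials with reference choice {reference_word!r}")
    ref_mean = circmean(by_choice[reference_word], high=np.pi, low=-np.pi)
    out = {}
    for word, phs in by_choice.items():
        if word == reference_word:
            out[word] = 0.0
        elif not phs:
            out[word] = np.nan
        else:
            mu = circmean(phs, high=np.pi, low=-np.pi)
            out[word] = float((mu - ref_mean + np.pi) % (2 * np.pi) - np.pi)
    return out
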