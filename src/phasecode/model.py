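"""Two-level oscillation-modulated threshold node model.

Each content node (phonemes and words, plus one empty node per level for the
rhythmic entrainment stimulus) receives at every millisecond

    A[l, T] = C[l-1 -> l] @ A[l-1, T] + postThresAct(Ta) + osc(T)

i.e. connectivity-weighted input from the level below, a post-threshold
activation function of the time ``Ta`` since the node last became active,
and a global sinusoidal excitability oscillation.  A node becomes active
when its activation reaches its threshold; ``Ta`` then resets to zero and
the node runs through a brief excitatory burst followed by a strong
self-inhibition before returning to rest inhibition:

    postThresAct(Ta) = -3 * B   for 0 <= Ta < 20 ms   (burst, B < 0)
                       +3 * B   for 20 <= Ta <= 100 ms (self-inhibition)
                       B        for Ta > 100 ms and never-active nodes

Sensitivity to the statistics of the language enters through per-node
thresholds: units with high corpus frequency get their threshold lowered by
a configurable reduction, which makes them reach threshold at earlier, less
excitable phases of the oscillation — the phase code the model embodies.

Default oscillation amplitude and base inhibition were calibrated once so
that at rest (no stimulus) no node becomes active for any admissible
threshold reduction while an ambiguous stimulus is categorized at some but
not all oscillatory phases; they are fixed in :class:`ModelConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .lexicon import Connectivity, TraitLexicon

GUESS = "guess"

#: Calibrated default oscillation amplitude (activation units).
DEFAULT_OSC_AMPLITUDE = 0.63
#: Calibrated default base inhibition level (activation units, negative).
DEFAULT_BASE_INHIBITION = -0.2


@dataclass(frozen=True)
class ModelConfig:
    """Model parameters.

    Parameters
    ----------
    osc_frequency : float
        Frequency of the excitability oscillation in Hz.
    osc_amplitude : float
        Peak oscillation excursion in activation units.
    osc_phase_offset : float
        Phase of the oscillation at T=0 (radians, cosine convention).
    base_threshold : float
        Activation threshold of low-frequency and empty nodes.
    threshold_reduction : float
        Amount subtracted from the threshold of high-frequency units,
        in [0, 0.5].
    base_inhibition : float
        Rest inhibition level B (negative).
    excitation_window_ms, inhibition_window_ms : tuple
        Post-threshold burst and self-inhibition windows (ms).
    dt_ms : int
        Integration step in ms.
    input_mode : {"stable", "linear_ramp"}
        Rectangular stimulus pulses, or amplitude ramping linearly from 0
        to peak over the event duration.
    topology : {"parallel", "hierarchical"}
        Whether the word level is driven by the input directly or by the
        phoneme level.
    sensitivity_enabled : bool
        If False all thresholds equal ``base_threshold`` (control model).
    stimulus_duration_ms : float
        Default stimulus event duration (one half oscillation cycle at
        6.25 Hz).
    hierarchical_gain : float
        Scaling of the phoneme-to-word drive in the hierarchical topology
        (0.5 averages a word's two phonemes).
    """

    osc_frequency: float = 6.25
    osc_amplitude: float = DEFAULT_OSC_AMPLITUDE
    osc_phase_offset: float = 0.0
    base_threshold: float = 1.0
    threshold_reduction: float = 0.3
    base_inhibition: float = DEFAULT_BASE_INHIBITION
    excitation_window_ms: tuple = (0.0, 20.0)
    inhibition_window_ms: tuple = (20.0, 100.0)
    dt_ms: int = 1
    input_mode: str = "stable"
    topology: str = "parallel"
    sensitivity_enabled: bool = True
    stimulus_duration_ms: float = 80.0
    hierarchical_gain: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.threshold_reduction <= 0.5:
            raise ValueError("threshold_reduction must lie in [0, 0.5]")
        if self.dt_ms < 1:
            raise ValueError("dt_ms must be >= 1")
        if self.osc_frequency <= 0:
            raise ValueError("osc_frequency must be positive")
        if self.base_inhibition >= 0:
            raise ValueError("base_inhibition must be negative")
        if self.input_mode not in ("stable", "linear_ramp"):
            raise ValueError(f"unknown input_mode: {self.input_mode!r}")
        if self.topology not in ("parallel", "hierarchical"):
            raise ValueError(f"unknown topology: {self.topology!r}")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.osc_frequency

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus: onset, duration, and amplitude per input-word node."""

    onset_ms: float
    duration_ms: float
    amplitudes: np.ndarray

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        if np.any(amps < 0):
            raise ValueError("stimulus amplitudes must be nonnegative")
        object.__setattr__(self, "amplitudes", amps)


@dataclass
class NodeState:
    """State of one node at one time point (for inspection/debugging)."""

    activation: float
    time_since_activation: float  # ms; inf = never activated
    threshold: float


@dataclass
class Decision:
    level: str
    choice: str          # node id, or GUESS
    choice_value: float  # 0, 0.5 or 1
    decision_time_ms: float | None


@dataclass
class SimulationTrace:
    """Activation time courses and threshold-crossing events of one run."""

    times: np.ndarray                  # ms grid
    activation: dict                   # level -> (nodes, T) array
    crossings: list                    # (level, node_index, t_ms, activation)
    node_ids: dict                     # level -> tuple of node identifiers
    thresholds: dict                   # level -> (nodes,) array


def oscillation_value(t_ms, config: ModelConfig):
    """Global excitability oscillation at time ``t_ms`` (cosine convention)."""
    t_ms = np.asarray(t_ms, dtype=float)
    return config.osc_amplitude * np.cos(
        2.0 * np.pi * config.osc_frequency * t_ms / 1000.0
        + config.osc_phase_offset
    )


def post_threshold_activation(ta_ms, base_inhibition,
                              excitation_window=(0.0, 20.0),
                              inhibition_window=(20.0, 100.0)):
    """Post-threshold activation as a function of time since activation.

    ``ta_ms`` may be a scalar or array; ``np.inf`` marks never-active nodes,
    which sit at the rest inhibition level ``base_inhibition``.
    """
    if base_inhibition >= 0:
        raise ValueError("base_inhibition must be negative")
    ta = np.asarray(ta_ms, dtype=float)
    b = base_inhibition
    out = np.full(ta.shape, b)
    burst = (ta >= excitation_window[0]) & (ta < excitation_window[1])
    inhib = (ta >= inhibition_window[0]) & (ta <= inhibition_window[1])
    out[burst] = -3.0 * b
    out[inhib] = 3.0 * b
    return out if out.shape else float(out)


def apply_sensitivity(lexicon: TraitLexicon, config: ModelConfig) -> dict:
    """Per-node activation thresholds for both levels.

    High-frequency units get ``base_threshold - threshold_reduction``; all
    other units (including the empty nodes) keep the base threshold.  With
    ``sensitivity_enabled=False`` every threshold equals the base threshold.
    """
    thresholds = {}
    for level, units in (("phoneme", lexicon.phonemes), ("word", lexicon.words)):
        thr = np.full(len(units), config.base_threshold, dtype=float)
        if config.sensitivity_enabled and config.threshold_reduction > 0:
            high = set(lexicon.high_units(level))
            for i, u in enumerate(units):
                if u in high:
                    thr[i] -= config.threshold_reduction
        thresholds[level] = thr
    return thresholds


def events_to_input(sequence, config: ModelConfig, n_input, t_max_ms=None):
    """Rasterize a stimulus sequence onto the (T, n_input) drive array."""
    if not sequence:
        raise ValueError("stimulus sequence must not be empty")
    sequence = sorted(sequence, key=lambda e: e.onset_ms)
    for a, b in zip(sequence, sequence[1:]):
        if b.onset_ms < a.onset_ms + a.duration_ms:
            raise ValueError("overlapping stimulus events")
    if t_max_ms is None:
        last = sequence[-1]
        t_max_ms = last.onset_ms + last.duration_ms + 200.0
    n_t = int(np.ceil(t_max_ms / config.dt_ms))
    drive = np.zeros((n_t, n_input))
    times = np.arange(n_t) * config.dt_ms
    for ev in sequence:
        on = (times >= ev.onset_ms) & (times < ev.onset_ms + ev.duration_ms)
        if config.input_mode == "linear_ramp":
            frac = (times[on] - ev.onset_ms) / ev.duration_ms
            drive[on] += frac[:, None] * ev.amplitudes[None, :]
        else:
            drive[on] += ev.amplitudes[None, :]
    return times, drive


def simulate_batch(drive, config: ModelConfig, connectivity: Connectivity,
                   thresholds: dict):
    """Run the model on a batch of input drives.

    Parameters
    ----------
    drive : (B, T, n_input) array
        Input-word activation at every time step, per batch element.
    thresholds : dict
        Output of :func:`apply_sensitivity`.

    Returns
    -------
    times : (T,) ms grid
    activation : dict level -> (B, nodes, T)
    crossed : dict level -> (B, nodes, T) bool, True where the node became
        active at that step.
    """
    drive = np.asarray(drive, dtype=float)
    if drive.ndim != 3:
        raise ValueError("drive must be (batch, time, input_nodes)")
    n_b, n_t, _ = drive.shape
    c_ip = connectivity.input_to_phoneme
    c_iw = connectivity.input_to_word
    hierarchical = config.topology == "hierarchical"
    if hierarchical and connectivity.phoneme_to_word is None:
        raise ValueError("hierarchical topology requires phoneme_to_word")
    n_ph = c_ip.shape[1]
    n_wd = c_iw.shape[1]
    times = np.arange(n_t) * float(config.dt_ms)
    osc = oscillation_value(times, config)

    thr_ph = thresholds["phoneme"]
    thr_wd = thresholds["word"]
    exc_w = config.excitation_window_ms
    inh_w = config.inhibition_window_ms
    b = config.base_inhibition
    dt = float(config.dt_ms)

    ta_ph = np.full((n_b, n_ph), np.inf)
    ta_wd = np.full((n_b, n_wd), np.inf)
    act_ph = np.empty((n_b, n_ph, n_t))
    act_wd = np.empty((n_b, n_wd, n_t))
    x_ph = np.zeros((n_b, n_ph, n_t), dtype=bool)
    x_wd = np.zeros((n_b, n_wd, n_t), dtype=bool)

    inp_ph_all = drive @ c_ip  # (B, T, n_ph)
    inp_wd_all = drive @ c_iw

    for it in range(n_t):
        o = osc[it]
        a_ph = inp_ph_all[:, it, :] + _pta(ta_ph, b, exc_w, inh_w) + o
        if hierarchical:
            wd_drive = config.hierarchical_gain * (
                a_ph @ connectivity.phoneme_to_word
            )
        else:
            wd_drive = inp_wd_all[:, it, :]
        a_wd = wd_drive + _pta(ta_wd, b, exc_w, inh_w) + o

        for ta, a, thr, xing in ((ta_ph, a_ph, thr_ph, x_ph),
                                 (ta_wd, a_wd, thr_wd, x_wd)):
            eligible = ta > inh_w[1]  # includes np.inf (never active)
            crossed = (a >= thr[None, :]) & eligible
            ta += dt
            ta[crossed] = 0.0
            xing[:, :, it] = crossed
        act_ph[:, :, it] = a_ph
        act_wd[:, :, it] = a_wd

    activation = {"phoneme": act_ph, "word": act_wd}
    crossed = {"phoneme": x_ph, "word": x_wd}
    return times, activation, crossed


def _pta(ta, b, exc_w, inh_w):
    out = np.full(ta.shape, b)
    out[(ta >= exc_w[0]) & (ta < exc_w[1])] = -3.0 * b
    out[(ta >= inh_w[0]) & (ta <= inh_w[1])] = 3.0 * b
    return out


def simulate(sequence, config: ModelConfig, connectivity: Connectivity,
             thresholds: dict, lexicon: TraitLexicon,
             t_max_ms=None) -> SimulationTrace:
    """Simulate one stimulus sequence and return its trace.

    The trace records full activation time courses for both levels and
    every threshold-crossing event (time and activation at crossing).
    Deterministic given its inputs.
    """
    times, drive = events_to_input(sequence, config, len(lexicon.words),
                                   t_max_ms)
    times, activation, crossed = simulate_batch(
        drive[None, :, :], config, connectivity, thresholds)
    crossings = []
    for level in ("phoneme", "word"):
        nodes, t_idx = np.nonzero(crossed[level][0])
        for n, ti in zip(nodes, t_idx):
            crossings.append(
                (level, int(n), float(times[ti]),
                 float(activation[level][0, n, ti]))
            )
    crossings.sort(key=lambda c: c[2])
    return SimulationTrace(
        times=times,
        activation={lv: activation[lv][0] for lv in activation},
        crossings=crossings,
        node_ids={"phoneme": lexicon.phonemes, "word": lexicon.words},
        thresholds=thresholds,
    )


def node_state(trace: SimulationTrace, level: str, node: str,
               t_ms: float) -> NodeState:
    """Reconstruct a node's state at a time point from its trace.

    ``time_since_activation`` is measured from the node's most recent
    threshold crossing at or before ``t_ms`` (inf if it never crossed).
    """
    if level not in trace.activation:
        raise ValueError(f"level {level!r} not in trace")
    idx = trace.node_ids[level].index(node)
    it = int(np.argmin(np.abs(trace.times - t_ms)))
    ta = np.inf
    for lv, n, t, _ in trace.crossings:
        if lv == level and n == idx and t <= trace.times[it]:
            ta = float(trace.times[it] - t)
    return NodeState(activation=float(trace.activation[level][idx, it]),
                     time_since_activation=ta,
                     threshold=float(trace.thresholds[level][idx]))


def decide(trace: SimulationTrace, level: str, onset_ms: float,
           candidates: tuple, mode: str = "deterministic",
           rng: np.random.Generator | None = None) -> Decision:
    """Categorization decision: the candidate node active first after onset.

    Simultaneous crossings (an artifact of the discrete time step) go to
    the node with the stronger suprathreshold activation at the crossing —
    the node that would have reached its own threshold first in continuous
    time; an exact tie, or no crossing at all, is a guess.  In
    deterministic mode a guess is coded 0.5; in stochastic mode it is a
    seeded random choice of 0 or 1.
    """
    if level not in trace.activation:
        raise ValueError(f"level {level!r} not in trace")
    ids = trace.node_ids[level]
    cand_idx = [ids.index(c) for c in candidates]
    if len(cand_idx) != 2:
        raise ValueError("exactly two candidates required")
    thr = trace.thresholds[level]
    first = {}
    for lv, n, t, a in trace.crossings:
        if lv == level and n in cand_idx and t >= onset_ms and n not in first:
            first[n] = (t, a - thr[n])
    choice_idx = None
    t_dec = None
    if len(first) == 1:
        (choice_idx, (t_dec, _)), = first.items()
    elif len(first) == 2:
        (i0, (t0, a0)), (i1, (t1, a1)) = first.items()
        if t0 != t1:
            choice_idx, t_dec = (i0, t0) if t0 < t1 else (i1, t1)
        elif a0 != a1:
            choice_idx, t_dec = (i0, t0) if a0 > a1 else (i1, t1)
        # equal time and equal activation -> guess
    if choice_idx is None:
        if mode == "deterministic":
            return Decision(level, GUESS, 0.5, None)
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        return Decision(level, GUESS, float(rng.integers(2)), None)
    value = float(cand_idx.index(choice_idx))
    return Decision(level, ids[choice_idx], value, t_dec)
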