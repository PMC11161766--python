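"""End-to-end workflows tying model, protocols, and statistics together."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import lexicon as lx
from .clusters import (ClusterTestResult, effect_magnitude_maps,
                       extract_tf_phase, group_cluster_test)
from .config import StudyConfig
from .io import RunManifest
from .lexicon import build_lexicon
from .protocols import (MorphSpectrum, STUDY_SPECTRA,
                        compute_model_phase_differences, fit_psychometric,
                        run_entrainment_experiment,
                        run_psychometric_sweep, run_random_phase_experiment)
from .stats import (circular_mean_difference, logistic_phase_regression,
                    permutation_sinusoid_test, v_test)
from .synth import generate_behavioral_dataset

logger = logging.getLogger("phasecode")


class _stage:
    """Log the wall time of one workflow stage."""

    def __init__(self, name):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        logger.info("stage %s: %.2f s", self.name,
                    time.perf_counter() - self.t0)


# ---------------------------------------------------------------------------
# model study (psychometric sweep -> entrainment -> random phase -> readout)


def run_full_model_study(config: StudyConfig | None = None,
                         out_dir=None) -> dict:
    """Run the complete simulated study and return its result bundle.

    Stages: psychometric sweep and fit for each of the four morph continua;
    entrainment SOA sweep at each continuum's most ambiguous morph; the
    same sweep across a grid of threshold reductions; the random-phase
    single-trial experiment on the two consonant continua; and the
    circular phase-difference readout relative to /dɑt/.
    """
    config = config or StudyConfig()
    lexicon = build_lexicon()
    mcfg = config.model
    pcfg = config.protocols
    soas = np.asarray(pcfg.soas)

    logger.info("model study: seed %d", config.seed)
    psychometric = []
    entrainment = []
    midpoints = {}
    with _stage("psychometric+entrainment"):
        for pair in STUDY_SPECTRA:
            spectrum = MorphSpectrum(*pair)
            curve = run_psychometric_sweep(
                mcfg, spectrum, lexicon,
                phase_grid_size=pcfg.phase_grid_size)
            fit = fit_psychometric(curve)
            midpoints[pair] = fit.midpoint
            for p, v_c, v_p, v_w in zip(curve.proportions,
                                        curve.value_combined,
                                        curve.value_phoneme,
                                        curve.value_word):
                psychometric.append((f"{pair[0]}-{pair[1]}", p, v_c, v_p,
                                     v_w, fit.midpoint, fit.slope, fit.ok))
            _, values = run_entrainment_experiment(
                mcfg, spectrum, fit.midpoint, lexicon, soas=soas,
                n_train=pcfg.n_train_events)
            for soa, v in zip(soas, values):
                entrainment.append((f"{pair[0]}-{pair[1]}", soa, v))
    psychometric = pd.DataFrame(
        psychometric, columns=["spectrum", "proportion", "value",
                               "value_phoneme", "value_word", "midpoint",
                               "slope", "fit_ok"])
    entrainment = pd.DataFrame(entrainment,
                               columns=["spectrum", "soa_s", "value"])

    sweep = []
    with _stage("reduction-sweep"):
        for reduction in pcfg.reduction_grid:
            rcfg = mcfg.with_(threshold_reduction=float(reduction))
            for pair in STUDY_SPECTRA:
                spectrum = MorphSpectrum(*pair)
                fit = fit_psychometric(run_psychometric_sweep(
                    rcfg, spectrum, lexicon,
                    phase_grid_size=pcfg.phase_grid_size))
                _, values = run_entrainment_experiment(
                    rcfg, spectrum, fit.midpoint, lexicon, soas=soas,
                    n_train=pcfg.n_train_events)
                sweep.append((float(reduction), f"{pair[0]}-{pair[1]}",
                              float(np.ptp(values))))
    sweep = pd.DataFrame(sweep, columns=["reduction", "spectrum",
                                         "value_range"])

    rcfg = mcfg.with_(threshold_reduction=pcfg.phase_diff_reduction)
    records = []
    with _stage("random-phase"):
        for pair in (STUDY_SPECTRA[1], STUDY_SPECTRA[0]):
            spectrum = MorphSpectrum(*pair)
            fit = fit_psychometric(run_psychometric_sweep(
                rcfg, spectrum, lexicon,
                phase_grid_size=pcfg.phase_grid_size))
            records += run_random_phase_experiment(
                rcfg, spectrum, fit.midpoint, lexicon,
                n_trials=pcfg.n_random_phase_trials, seed=config.seed)
    phase_diffs = []
    for level in ("phoneme", "word"):
        diffs = compute_model_phase_differences(records, lx.W_DAT_SHORT,
                                                level)
        for word, diff in diffs.items():
            phase_diffs.append((level, word, diff))
    phase_diffs = pd.DataFrame(phase_diffs,
                               columns=["level", "choice", "phase_diff_rad"])

    results = {"psychometric": psychometric, "entrainment": entrainment,
               "reduction_sweep": sweep, "phase_differences": phase_diffs,
               "midpoints": midpoints}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs = []
        for name in ("psychometric", "entrainment", "reduction_sweep",
                     "phase_differences"):
            path = out_dir / f"model_{name}.tsv"
            results[name].to_csv(path, sep="\t", index=False)
            outputs.append(str(path))
        RunManifest(command="model-study", config=config.to_dict(),
                    seeds={"study": config.seed}, outputs=outputs,
                    ).write(out_dir / "model_study_manifest.json")
    return results


# ---------------------------------------------------------------------------
# neural pipeline (phase maps -> cluster tests -> phase readout)


def participant_phase_grids(data: dict, stream: str, frequencies, times,
                            n_cycles: float = 5.0) -> list:
    """Morlet phase grids for every participant of one stream."""
    grids = []
    epoch_tmin = float(data["times"][0])
    for ip in range(data["streams"][stream].shape[0]):
        grids.append(extract_tf_phase(
            data["streams"][stream][ip], sfreq=data["sfreq"],
            epoch_tmin=epoch_tmin, frequencies=frequencies, times=times,
            n_cycles=n_cycles, participant=f"p{ip:02d}"))
    return grids


def analyze_stream_labeling(grids: list, responses, n_perm_maps: int = 100,
                            n_perm_cluster: int = 1000,
                            cluster_alpha: float = 0.05,
                            seed: int = 0) -> ClusterTestResult:
    """Cluster test of one stream's phases against one labeling's responses."""
    obs, nulls = [], []
    for ip, grid in enumerate(grids):
        grid.response = np.asarray(responses[ip])
        o, nmaps = effect_magnitude_maps(grid, n_perm=n_perm_maps,
                                         seed=seed * 100003 + ip)
        obs.append(o)
        nulls.append(nmaps)
    return group_cluster_test(np.stack(obs), np.stack(nulls),
                              cluster_alpha=cluster_alpha,
                              n_perm=n_perm_cluster, seed=seed)


def analyze_neural_dataset(data: dict, config: StudyConfig | None = None,
                           seed: int = 0) -> dict:
    """Run every stream x labeling cluster analysis (the 2x2 design)."""
    config = config or StudyConfig()
    scfg = config.stats
    freqs = np.asarray(scfg.frequencies)
    times = np.asarray(scfg.times)
    out = {}
    for stream in data["streams"]:
        grids = participant_phase_grids(data, stream, freqs, times,
                                        scfg.morlet_cycles)
        for labeling, resp in data["responses"].items():
            out[(stream, labeling)] = analyze_stream_labeling(
                grids, resp, n_perm_maps=scfg.n_perm_maps,
                n_perm_cluster=scfg.n_perm_cluster,
                cluster_alpha=scfg.cluster_alpha, seed=seed)
    return out


def phase_difference_readout(grids: list, responses,
                             result: ClusterTestResult,
                             alpha: float = 0.05):
    """Per-participant phase difference between response categories.

    For each participant, phases are read at that participant's peak
    time-frequency point within the significant cluster (their largest
    phase-effect magnitude); the readout is the circular mean phase of
    1-responses minus that of 0-responses.  Returns the per-participant
    differences and a v-test against the hypothesized direction pi
    (opposite phases for opposite percepts).
    """
    sig = result.significant(alpha)
    if not sig:
        raise ValueError("no significant cluster to read phases from")
    mask = np.zeros_like(sig[0].mask)
    for c in sig:
        mask |= c.mask
    diffs = []
    for ip, grid in enumerate(grids):
        resp = np.asarray(responses[ip])
        fit_mag = np.full(mask.shape, -np.inf)
        valid = grid.valid_mask & mask
        fi, ti = np.nonzero(valid)
        for f_idx, t_idx in zip(fi, ti):
            fit = logistic_phase_regression(grid.phase[:, f_idx, t_idx],
                                            resp)
            fit_mag[f_idx, t_idx] = fit.effect_magnitude
        f_idx, t_idx = np.unravel_index(np.argmax(fit_mag), fit_mag.shape)
        phases = grid.phase[:, f_idx, t_idx]
        diffs.append(circular_mean_difference(phases[resp == 1],
                                              phases[resp == 0]))
    diffs = np.asarray(diffs)
    return diffs, v_test(diffs, np.pi)


# ---------------------------------------------------------------------------
# synthetic validation suites


def run_synthetic_validation(config: StudyConfig | None = None,
                             n_datasets: int = 200, n_perm: int = 500,
                             seed: int = 0, out_path=None) -> dict:
    """Small-scale calibration report for the statistics chain.

    Sections: type-I rate of the behavioral sinusoid permutation test under
    the null, its power under injected modulation, recovery error of the
    phase logistic regression, and a reduced FWER check of the cluster
    test on Gaussian maps.  The full-size calibrations live in the test
    suite; this report is the quick machine-readable variant.
    """
    from .clusters import group_cluster_test as _gct

    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    freq = config.stats.sinusoid_frequency

    def rejection_rate(amplitude, n_sets):
        rej = 0
        for i in range(n_sets):
            spec = config.behavioral.with_(
                modulation_amplitude=amplitude,
                seed=int(rng.integers(2 ** 31)))
            table = generate_behavioral_dataset(spec)
            res = permutation_sinusoid_test(table, freq, n_perm=n_perm,
                                            seed=int(rng.integers(2 ** 31)))
            rej += res.p <= 0.05
        return rej / n_sets

    report = {"seed": seed, "n_datasets": n_datasets, "n_perm": n_perm}
    report["behavioral"] = {
        "type_one_rate": rejection_rate(0.0, n_datasets),
        "power": {str(a): rejection_rate(a, max(50, n_datasets // 4))
                  for a in (0.05, 0.10, 0.15)},
    }

    errors = []
    for _ in range(20):
        phi0 = rng.uniform(-np.pi, np.pi)
        phases = rng.uniform(-np.pi, np.pi, 500)
        prob = 1 / (1 + np.exp(-np.cos(phases - phi0)))
        resp = rng.random(500) < prob
        fit = logistic_phase_regression(phases, resp.astype(float))
        err = np.abs((fit.preferred_phase - phi0 + np.pi) % (2 * np.pi)
                     - np.pi)
        errors.append(err)
    report["logistic_recovery"] = {
        "median_abs_phase_error_rad": float(np.median(errors))}

    n_sub, shape = 20, (15, 26)
    false_pos = 0
    n_fwer = max(50, n_datasets // 4)
    for i in range(n_fwer):
        obs = rng.standard_normal((n_sub,) + shape)
        nulls = rng.standard_normal((n_sub, 100) + shape)
        res = _gct(obs, nulls, n_perm=200, seed=int(rng.integers(2 ** 31)))
        false_pos += bool(res.significant(0.05))
    report["cluster_fwer"] = {"nominal": 0.05,
                              "rate": false_pos / n_fwer,
                              "n_simulations": n_fwer}

    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2) + "\n")
    return report
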