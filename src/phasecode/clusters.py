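"""Time-frequency phase maps and cluster-based permutation statistics.

The neural analysis chain: extract single-trial phase on a time-frequency
grid from prestimulus epochs (Morlet wavelets), fit a phase logistic
regression at every grid point per participant, summarize each participant
by the magnitude of the phase effect null-centered against label
permutations, and test the group-level t-map with a cluster-based
permutation test (sum-of-t cluster statistic against a max-cluster null).

Magnitudes of logistic phase coefficients are positively biased under the
null, so each participant's observed map is centered by the mean of that
participant's own label-permutation maps; the same permutation maps provide
the exchangeable draws for the group-level null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import t as t_dist

from .stats import batched_logistic_irls

DEFAULT_FREQUENCIES = np.arange(1.0, 15.5, 1.0)          # Hz, 15 rows
DEFAULT_TIMES = np.round(np.arange(-0.5, 0.0001, 0.02), 3)  # s, 26 columns
DEFAULT_N_CYCLES = 5.0


@dataclass
class TFPhaseGrid:
    """Per-trial phase on a time-frequency grid for one participant."""

    participant: str
    frequencies: np.ndarray    # Hz
    times: np.ndarray          # s (prestimulus times are negative)
    phase: np.ndarray          # (n_trials, n_freqs, n_times), rad; nan = missing
    response: np.ndarray | None = None  # (n_trials,) binary labels

    @property
    def valid_mask(self) -> np.ndarray:
        """Grid points with phase available on every trial."""
        return np.isfinite(self.phase).all(axis=0)


def extract_tf_phase(data, sfreq, epoch_tmin, frequencies=None, times=None,
                     n_cycles=DEFAULT_N_CYCLES, participant="p00",
                     response=None) -> TFPhaseGrid:
    """Single-trial phase via Morlet wavelet convolution.

    Parameters
    ----------
    data : (n_trials, n_samples) array
        Epoch time series; sample 0 is at ``epoch_tmin`` seconds.
    sfreq : float
        Sampling rate (Hz); must be at least twice the highest frequency.
    frequencies, times : arrays
        Time-frequency grid on which phase is returned.  Grid points whose
        wavelet (half-width ``n_cycles / (2 f)``) extends beyond the epoch
        are flagged missing (nan): their phase estimate would be
        edge-contaminated.
    """
    from mne.time_frequency import tfr_array_morlet

    frequencies = (DEFAULT_FREQUENCIES if frequencies is None
                   else np.asarray(frequencies, float))
    times = DEFAULT_TIMES if times is None else np.asarray(times, float)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (n_trials, n_samples)")
    if sfreq < 2.0 * frequencies.max():
        raise ValueError("sampling rate below Nyquist for requested grid")
    n_samples = data.shape[1]
    epoch_tmax = epoch_tmin + (n_samples - 1) / sfreq
    if times.min() < epoch_tmin or times.max() > epoch_tmax:
        raise ValueError("requested times outside the epoch")

    # frequencies whose wavelet support (10 sigma_t) exceeds the epoch
    # cannot be estimated at all; everything else is computed and then
    # edge-flagged per time point below.
    sigma_t = n_cycles / (2.0 * np.pi * frequencies)
    computable = np.ceil(10.0 * sigma_t * sfreq) < n_samples
    sample_idx = np.round((times - epoch_tmin) * sfreq).astype(int)
    phase = np.full((data.shape[0], len(frequencies), len(times)), np.nan)
    if computable.any():
        tfr = tfr_array_morlet(data[:, None, :], sfreq=sfreq,
                               freqs=frequencies[computable],
                               n_cycles=n_cycles, output="complex",
                               zero_mean=True, verbose=False)
        phase[:, computable, :] = np.angle(tfr[:, 0, :, :][:, :, sample_idx])

    half_width = n_cycles / (2.0 * frequencies)
    ok = ((times[None, :] - half_width[:, None] >= epoch_tmin - 1e-9)
          & (times[None, :] + half_width[:, None] <= epoch_tmax + 1e-9))
    phase = np.where(ok[None, :, :], phase, np.nan)
    return TFPhaseGrid(participant=participant, frequencies=frequencies,
                       times=times, phase=phase,
                       response=None if response is None
                       else np.asarray(response))


def effect_magnitude_maps(grid: TFPhaseGrid, n_perm: int = 100,
                          seed: int = 0):
    """Observed and label-permutation phase-effect magnitude maps.

    At every valid grid point the responses are regressed on the sin/cos of
    phase; the map value is the norm of the two phase coefficients.  The
    ``n_perm`` permutation maps reuse one shuffled response vector per
    permutation across all grid points, preserving the spatial correlation
    of the maps under the null.
    """
    if grid.response is None:
        raise ValueError("grid carries no responses")
    rng = np.random.default_rng(seed)
    valid = grid.valid_mask
    n_trials = grid.phase.shape[0]
    phases = grid.phase[:, valid].T            # (B, n_trials)
    n_f, n_t = valid.shape
    b = phases.shape[0]

    perms = np.empty((n_perm, n_trials), dtype=np.int64)
    for k in range(n_perm):
        perms[k] = rng.permutation(n_trials)
    labels = np.concatenate([grid.response[None, :],
                             grid.response[perms]], axis=0)  # (K+1, n)

    beta = _phase_logistic_shared_design(phases, labels)
    mag = np.hypot(beta[:, :, 1], beta[:, :, 2])

    obs_map = np.full((n_f, n_t), np.nan)
    null_maps = np.full((n_perm, n_f, n_t), np.nan)
    obs_map[valid] = mag[0]
    null_maps[:, valid] = mag[1:]
    return obs_map, null_maps


def _phase_logistic_shared_design(phases, labels, n_iter=6, ridge=1e-6):
    """Newton logistic fits for many grid points x label sets.

    ``phases``: (B, n) per grid point; ``labels``: (K, n) response vectors
    shared across grid points.  Exploits that the design [1, sin, cos] is
    common to all label sets of a grid point: sufficient statistics are
    accumulated with batched matmuls against a per-point moment basis.
    Returns betas of shape (K, B, 3).  Agrees with the reference IRLS
    (:func:`phasecode.stats.batched_logistic_irls`) to optimizer tolerance.
    """
    phases = np.asarray(phases, dtype=np.float32)
    y = np.asarray(labels, dtype=np.float32)
    b, n = phases.shape
    k = y.shape[0]
    s, c = np.sin(phases), np.cos(phases)
    one = np.ones_like(s)
    # basis[b, n, j]: integrands of the gradient (1, s, c) and of the
    # Hessian upper triangle (1, s, c, s^2, s*c, c^2)
    basis = np.stack([one, s, c, s * s, s * c, c * c], axis=-1)  # (B, n, 6)
    beta = np.zeros((b, k, 3), dtype=np.float32)
    ybar = np.clip(y.mean(axis=1), 1e-3, 1 - 1e-3)
    beta[:, :, 0] = np.log(ybar / (1 - ybar))[None, :]
    y_t = np.broadcast_to(y, (b, k, n))
    hess = np.empty((b, k, 3, 3), dtype=np.float32)
    for _ in range(n_iter):
        eta = (beta[:, :, 0:1] + beta[:, :, 1:2] * s[:, None, :]
               + beta[:, :, 2:3] * c[:, None, :])
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + np.float32(1e-8)
        g_mom = (y_t - mu) @ basis[:, :, :3]        # (B, K, 3)
        h_mom = w @ basis[:, :, 3:]                 # (B, K, 3): s2, sc, c2
        wsum = w @ basis[:, :, :3]                  # (B, K, 3): w, ws, wc
        hess[:, :, 0, 0] = wsum[:, :, 0] + ridge
        hess[:, :, 0, 1] = hess[:, :, 1, 0] = wsum[:, :, 1]
        hess[:, :, 0, 2] = hess[:, :, 2, 0] = wsum[:, :, 2]
        hess[:, :, 1, 1] = h_mom[:, :, 0] + ridge
        hess[:, :, 1, 2] = hess[:, :, 2, 1] = h_mom[:, :, 1]
        hess[:, :, 2, 2] = h_mom[:, :, 2] + ridge
        step = np.linalg.solve(hess, (g_mom - ridge * beta)[..., None]
                               )[..., 0]
        np.clip(step, -5.0, 5.0, out=step)
        beta += step
        if np.abs(step).max() < 1e-5:
            break
    return beta.swapaxes(0, 1).astype(np.float64)


@dataclass
class Cluster:
    mask: np.ndarray      # (n_freqs, n_times) bool
    statistic: float      # sum of member t-values
    p: float


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    clusters: list
    cluster_threshold: float
    n_permutations: int
    seed: int

    def significant(self, alpha: float = 0.05):
        return [c for c in self.clusters if c.p <= alpha]

    def covers(self, freq_idx: int, time_idx: int, alpha: float = 0.05):
        """Does any significant cluster contain this grid point?"""
        return any(c.mask[freq_idx, time_idx] for c in self.significant(alpha))


def _t_map(maps):
    """One-sample t across participants (axis 0); nan where any missing."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return mean / (sd / np.sqrt(n))


_ADJACENCY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-neighborhood


def _max_cluster_stat(t_map, threshold):
    supra = np.nan_to_num(t_map, nan=-np.inf) > threshold
    labeled, n_lab = ndimage.label(supra, structure=_ADJACENCY)
    if n_lab == 0:
        return 0.0
    sums = ndimage.sum_labels(t_map, labeled, index=np.arange(1, n_lab + 1))
    return float(sums.max())


def group_cluster_test(observed_maps, null_maps, cluster_alpha: float = 0.05,
                       n_perm: int = 1000, seed: int = 0) -> ClusterTestResult:
    """Cluster-based permutation test over participants.

    Parameters
    ----------
    observed_maps : (n_subjects, n_freqs, n_times)
        Per-participant effect magnitude maps.
    null_maps : (n_subjects, n_perm_subject, n_freqs, n_times)
        Per-participant label-permutation maps; their per-participant mean
        centers both the observed and the permuted maps, and the group null
        is built by drawing one permutation map per participant.
    cluster_alpha : float
        Pointwise one-sided cluster-forming threshold (t distribution,
        df = n_subjects - 1).

    The cluster statistic is the sum of t-values over a 4-connected
    suprathreshold cluster; cluster p-values are computed against the
    distribution of the maximum cluster statistic across permutations
    (add-one rule).
    """
    observed_maps = np.asarray(observed_maps, float)
    null_maps = np.asarray(null_maps, float)
    n_sub, k_per = null_maps.shape[:2]
    if n_sub < 5:
        raise ValueError("need at least 5 participants")
    if k_per < 100 or n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    center = null_maps.mean(axis=1)
    obs_c = observed_maps - center
    null_c = null_maps - center[:, None]

    # grid points missing for any participant are excluded entirely
    valid = (np.isfinite(obs_c).all(axis=0)
             & np.isfinite(null_c).all(axis=(0, 1)))
    obs_c = np.where(valid, obs_c, np.nan)

    threshold = float(t_dist.ppf(1.0 - cluster_alpha, df=n_sub - 1))
    t_obs = _t_map(obs_c)
    supra = np.nan_to_num(t_obs, nan=-np.inf) > threshold
    labeled, n_lab = ndimage.label(supra, structure=_ADJACENCY)

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, k_per, size=(n_perm, n_sub))
    max_null = np.empty(n_perm)
    sub_idx = np.arange(n_sub)
    for i in range(n_perm):
        sel = null_c[sub_idx, draws[i]]
        sel = np.where(valid, sel, np.nan)
        max_null[i] = _max_cluster_stat(_t_map(sel), threshold)

    clusters = []
    for lab in range(1, n_lab + 1):
        mask = labeled == lab
        stat = float(t_obs[mask].sum())
        p = (1.0 + np.sum(max_null >= stat)) / (1.0 + n_perm)
        clusters.append(Cluster(mask=mask, statistic=stat, p=float(p)))
    clusters.sort(key=lambda c: c.statistic, reverse=True)
    return ClusterTestResult(t_map=t_obs, clusters=clusters,
                             cluster_threshold=threshold,
                             n_permutations=n_perm, seed=seed)
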