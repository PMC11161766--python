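"""Statistical procedures for detecting phase-dependent behavior.

Behavioral side: per-participant demeaning of response proportions across
SOA, a fixed-frequency sinusoid fit to the group curve, and a permutation
null built by shuffling SOA labels within participant.  Neural side (see
:mod:`phasecode.clusters` for the map-level machinery): logistic regression
of single-trial responses on the sine and cosine of prestimulus phase.
Circular statistics: circular mean differences, the v-test for
nonuniformity toward a hypothesized direction, and the product rule for
combining independent one-sided probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import circmean, norm

REQUIRED_COLUMNS = ("participant", "morph", "response")


# ---------------------------------------------------------------------------
# response tables


def _condition_column(table: pd.DataFrame) -> str:
    has_soa = "soa_s" in table.columns
    has_phase = "phase_rad" in table.columns
    if has_soa == has_phase:
        raise ValueError(
            "response table needs exactly one of 'soa_s' or 'phase_rad'")
    return "soa_s" if has_soa else "phase_rad"


def validate_response_table(table: pd.DataFrame) -> str:
    """Validate a behavioral response table; return its condition column."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"response table misses column {col!r}")
    cond = _condition_column(table)
    resp = table["response"].to_numpy()
    if not np.isin(resp, (0, 1)).all():
        raise ValueError("responses must be binary 0/1")
    if cond == "soa_s" and table[cond].max() > 5.0:
        raise ValueError(
            "SOA values above 5 look like milliseconds; SOAs must be in s")
    return cond


def proportion_matrix(table: pd.DataFrame):
    """Per-participant proportion of 1-responses per condition.

    Returns (participants, conditions, matrix) with matrix shape
    (n_participants, n_conditions).  A participant missing any condition is
    an error: the demeaning step needs a complete design.
    """
    cond = validate_response_table(table)
    pivot = table.pivot_table(index="participant", columns=cond,
                              values="response", aggfunc="mean")
    if pivot.isna().any().any():
        missing = pivot.isna().sum(axis=1)
        bad = missing[missing > 0].index.tolist()
        raise ValueError(f"participants with missing conditions: {bad}")
    return (pivot.index.to_numpy(), pivot.columns.to_numpy(float),
            pivot.to_numpy(float))


def demean_responses(table: pd.DataFrame):
    """Subtract each participant's mean across conditions; group average.

    Returns (conditions, per_participant_demeaned, group_curve).
    """
    _, conds, mat = proportion_matrix(table)
    dem = mat - mat.mean(axis=1, keepdims=True)
    return conds, dem, dem.mean(axis=0)


# ---------------------------------------------------------------------------
# fixed-frequency sinusoid fit and permutation null


@dataclass
class SinusoidFit:
    frequency: float
    sin_coef: float
    cos_coef: float
    amplitude: float
    phase: float
    r_squared: float
    degenerate: bool = False


@dataclass
class PermutationTestResult:
    observed: float
    null: np.ndarray
    p: float
    n_permutations: int
    seed: int


def _sinusoid_design(soas, frequency):
    soas = np.asarray(soas, dtype=float)
    arg = 2.0 * np.pi * frequency * soas
    return np.column_stack([np.sin(arg), np.cos(arg)])


def fit_fixed_frequency_sinusoid(y, soas, frequency) -> SinusoidFit:
    """Least-squares fit of a sinusoid of known frequency to a demeaned curve.

    The regressors are sin(2*pi*f*SOA) and cos(2*pi*f*SOA); the returned
    amplitude is sqrt(a^2 + b^2) and the phase atan2(a, b).  r^2 is the
    proportion of variance of ``y`` captured by the fit.  A zero-variance
    input yields ``r_squared = nan`` with the degenerate flag set.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 conditions")
    x = _sinusoid_design(soas, frequency)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return SinusoidFit(frequency, float(coef[0]), float(coef[1]),
                           float(np.hypot(*coef)),
                           float(np.arctan2(coef[0], coef[1])),
                           np.nan, degenerate=True)
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot
    return SinusoidFit(frequency, float(coef[0]), float(coef[1]),
                       float(np.hypot(*coef)),
                       float(np.arctan2(coef[0], coef[1])), r2)


def _r2_batch(curves, x):
    """r^2 of the (already centered) curves against the sinusoid design."""
    q, _ = np.linalg.qr(x - x.mean(axis=0))  # orthonormal, centered design
    proj = curves @ q
    ss_fit = np.sum(proj ** 2, axis=-1)
    centered = curves - curves.mean(axis=-1, keepdims=True)
    ss_tot = np.sum(centered ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ss_tot > 0, ss_fit / ss_tot, np.nan)


def permutation_sinusoid_test(table: pd.DataFrame, frequency: float,
                              n_perm: int = 10000, seed: int = 0
                              ) -> PermutationTestResult:
    """Permutation test of the fixed-frequency sinusoid fit.

    The observed statistic is the r^2 of the group-level fit.  The null
    shuffles each participant's SOA labels independently and refits; the
    p-value uses the add-one rule so it can never be zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    conds, dem, group = demean_responses(table)
    x = _sinusoid_design(conds, frequency)
    obs = float(_r2_batch(group[None, :], x)[0])
    rng = np.random.default_rng(seed)
    n_sub, n_cond = dem.shape
    order = np.argsort(rng.random((n_perm, n_sub, n_cond)), axis=-1)
    perm_curves = np.take_along_axis(
        np.broadcast_to(dem, (n_perm, n_sub, n_cond)), order, axis=-1
    ).mean(axis=1)
    null = _r2_batch(perm_curves, x)
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return PermutationTestResult(obs, null, float(p), n_perm, seed)


def split_half_comparison(table: pd.DataFrame, frequency: float,
                          n_perm: int = 10000, seed: int = 0):
    """Difference of sinusoid fit quality between experiment halves.

    The statistic is r^2(first half) - r^2(second half); the null
    reassigns trials to halves at random within each participant-by-SOA
    cell (a hypergeometric redraw of the per-half success counts), keeping
    per-cell trial counts fixed.  One-sided p (first-half fit stronger).
    """
    if "half" not in table.columns:
        raise ValueError("split-half comparison needs a 'half' column")
    cond = validate_response_table(table)
    grp = table.groupby(["participant", cond, "half"])["response"]
    agg = grp.agg(["sum", "count"]).unstack("half")
    if agg.isna().any().any():
        raise ValueError("each participant x condition needs both halves")
    k1 = agg[("sum", 1)].unstack(cond).to_numpy(float)
    k2 = agg[("sum", 2)].unstack(cond).to_numpy(float)
    n1 = agg[("count", 1)].unstack(cond).to_numpy(float)
    n2 = agg[("count", 2)].unstack(cond).to_numpy(float)
    conds = agg[("sum", 1)].unstack(cond).columns.to_numpy(float)
    x = _sinusoid_design(conds, frequency)

    def stat(a1, a2):
        curves = []
        for k, n in ((a1, n1), (a2, n2)):
            prop = k / n
            dem = prop - prop.mean(axis=1, keepdims=True)
            curves.append(dem.mean(axis=0))
        r2 = _r2_batch(np.stack(curves), x)
        return float(r2[0] - r2[1])

    observed = stat(k1, k2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    ktot = (k1 + k2).astype(int)
    ntot = (n1 + n2).astype(int)
    n1i = n1.astype(int)
    for i in range(n_perm):
        new_k1 = rng.hypergeometric(ktot, ntot - ktot, n1i)
        null[i] = stat(new_k1, ktot - new_k1)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationTestResult(observed, null, float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# phase logistic regression


@dataclass
class LogisticPhaseFit:
    beta0: float
    beta_sin: float
    beta_cos: float
    effect_magnitude: float
    preferred_phase: float
    separation: bool = False


_BETA_CAP = 10.0


def logistic_phase_regression(phases, responses) -> LogisticPhaseFit:
    """Logistic regression of binary responses on sin/cos of phase.

    The effect magnitude is the norm of the two phase coefficients, the
    preferred phase their atan2 angle (the phase at which the probability
    of a 1-response is maximal).  Perfect separation is flagged and the
    coefficients are refit with a small ridge penalty and capped.
    """
    phases = np.asarray(phases, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(phases) < 20:
        raise ValueError("need at least 20 trials")
    if y.min() == y.max():
        raise ValueError("both response classes must be present")
    x = np.column_stack([np.ones_like(phases), np.sin(phases),
                         np.cos(phases)])
    separation = False
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, x).fit(disp=0, maxiter=100)
        beta = res.params
        if not np.all(np.isfinite(beta)) or np.abs(beta).max() > _BETA_CAP:
            raise ValueError("diverged")
    except Exception:
        separation = True
        beta = batched_logistic_irls(phases[None, :], y[None, :],
                                     ridge=1e-2)[0]
        beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
    return LogisticPhaseFit(
        beta0=float(beta[0]), beta_sin=float(beta[1]), beta_cos=float(beta[2]),
        effect_magnitude=float(np.hypot(beta[1], beta[2])),
        preferred_phase=float(np.arctan2(beta[1], beta[2])),
        separation=separation)


def batched_logistic_irls(phases, responses, ridge=1e-6, n_iter=8):
    """Newton/IRLS logistic fits for many (phase, response) units at once.

    ``phases`` has shape (B, n); ``responses`` broadcasts against it.
    Returns coefficients (B, 3) for the design [1, sin(phase), cos(phase)].
    A small ridge keeps near-separated units finite; this is the fast path
    used for time-frequency maps and is cross-checked against statsmodels
    in the test suite.
    """
    phases = np.asarray(phases, dtype=np.float64)
    y = np.broadcast_to(np.asarray(responses, dtype=np.float64),
                        phases.shape)
    n_b, n = phases.shape
    x = np.empty((n_b, n, 3))
    x[:, :, 0] = 1.0
    x[:, :, 1] = np.sin(phases)
    x[:, :, 2] = np.cos(phases)
    beta = np.zeros((n_b, 3))
    ybar = np.clip(y.mean(axis=1), 1e-3, 1 - 1e-3)
    beta[:, 0] = np.log(ybar / (1 - ybar))
    eye = ridge * np.eye(3)
    for _ in range(n_iter):
        eta = np.einsum("bnp,bp->bn", x, beta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-12
        grad = np.einsum("bnp,bn->bp", x, y - mu) - ridge * beta
        hess = np.einsum("bnp,bn,bnq->bpq", x, w, x) + eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        np.clip(step, -5.0, 5.0, out=step)
        beta += step
        if np.abs(step).max() < 1e-8:
            break
    return beta


# ---------------------------------------------------------------------------
# circular statistics


def wrap_angle(a):
    """Wrap angles to [-pi, pi)."""
    return (np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi


def circular_mean_difference(phases_a, phases_b) -> float:
    """Difference of circular means, wrapped to [-pi, pi).

    The boundary case (means exactly pi apart) wraps to -pi.
    """
    phases_a = np.asarray(phases_a, dtype=float)
    phases_b = np.asarray(phases_b, dtype=float)
    if phases_a.size == 0 or phases_b.size == 0:
        raise ValueError("empty phase set")
    mu_a = circmean(phases_a, high=np.pi, low=-np.pi)
    mu_b = circmean(phases_b, high=np.pi, low=-np.pi)
    return float(wrap_angle(mu_a - mu_b))


@dataclass
class VTestResult:
    n: int
    mean_direction: float
    resultant_length: float
    mu: float
    v: float
    u: float
    p: float


def v_test(phases, mu: float) -> VTestResult:
    """v-test for circular nonuniformity toward a hypothesized direction.

    V = n * Rbar * cos(theta_bar - mu); under uniformity
    u = V * sqrt(2 / n) is approximately standard normal, and the one-sided
    p-value is 1 - Phi(u).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 5:
        raise ValueError("v-test needs at least 5 phases")
    c = np.cos(phases).sum()
    s = np.sin(phases).sum()
    rbar = np.hypot(c, s) / n
    theta = np.arctan2(s, c)
    v = n * rbar * np.cos(theta - mu)
    u = v * np.sqrt(2.0 / n)
    return VTestResult(n=int(n), mean_direction=float(theta),
                       resultant_length=float(rbar), mu=float(mu),
                       v=float(v), u=float(u), p=float(1.0 - norm.cdf(u)))


def combine_pvalues_product(ps) -> float:
    """Combine one-sided p-values by their product.

    This is the probability of the conjunction of the events under
    independence; it is deliberately the plain product (no correction for
    the number of tests), matching how the region-level phase tests are
    combined.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.prod(ps))
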