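"""Publication-bias procedures for a correlation meta-analysis.

The battery bundles the procedures a sensitivity analysis triangulates
over: Duval–Tweedie trim-and-fill (L estimator), a-priori step-function
selection models with the Vevea–Woods one-tailed moderate and severe
weights, PET-PEESE precision regressions, the p-uniform estimator, the
test of excess significance (TES), cumulative meta-analysis by precision,
and contour-enhanced funnel plot data.

Scale conventions: trim-and-fill, selection models and p-uniform operate
on Fisher z (back-transforming estimates to r); PET-PEESE operates on raw
correlations. All adjusted means are reported in the r metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core_meta import (
    MetaDataset,
    PooledResult,
    from_fisher_z,
    pool,
    to_fisher_z,
)

__all__ = [
    "VEVEA_WOODS_CUTPOINTS",
    "VEVEA_WOODS_MODERATE_ONE_TAILED",
    "VEVEA_WOODS_SEVERE_ONE_TAILED",
    "MIN_K_FOR_BIAS",
    "TrimFillResult",
    "SelectionModelResult",
    "PetPeeseResult",
    "PUniformResult",
    "TesResult",
    "CumulativeStep",
    "FunnelContour",
    "BatteryRow",
    "trim_and_fill",
    "selection_model",
    "pet_peese",
    "p_uniform",
    "tes",
    "cumulative_by_precision",
    "funnel_contours",
    "run_battery",
]

# ---------------------------------------------------------------------------
# Constants: Vevea–Woods a-priori one-tailed step weights
# ---------------------------------------------------------------------------
# One-tailed p-value cut-points delimiting 14 intervals (last bound 1.0) and
# the fixed retention weights for the "moderate" and "severe" publication-
# bias scenarios. Version 1 of these constants; override via the
# ``cutpoints``/``weights`` arguments of :func:`selection_model`.

VEVEA_WOODS_CUTPOINTS: tuple[float, ...] = (
    0.005, 0.010, 0.050, 0.100, 0.250, 0.350, 0.500,
    0.650, 0.750, 0.900, 0.950, 0.990, 0.995, 1.000,
)
VEVEA_WOODS_MODERATE_ONE_TAILED: tuple[float, ...] = (
    1.00, 0.99, 0.95, 0.80, 0.75, 0.65, 0.60,
    0.55, 0.50, 0.50, 0.50, 0.50, 0.50, 0.50,
)
VEVEA_WOODS_SEVERE_ONE_TAILED: tuple[float, ...] = (
    1.00, 0.99, 0.90, 0.75, 0.60, 0.50, 0.40,
    0.35, 0.30, 0.25, 0.10, 0.10, 0.10, 0.10,
)

#: distributions smaller than this are not subjected to bias analyses
MIN_K_FOR_BIAS = 10

#: tau^2 (z scale) above which a selection-model variance component is
#: treated as nonsensical for correlation data (tau > 0.5 on the z scale)
_TAU2_SANITY_BOUND = 0.25


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimFillResult:
    side: str                      # "left" | "right"
    k0: int                        # number of imputed studies
    adjusted_mean: float           # r metric, RE pooling of observed+imputed
    adjusted_ci95: tuple[float, float]
    imputed_effects: tuple[tuple[float, float], ...]  # (z, variance)
    converged: bool = True


@dataclass(frozen=True)
class SelectionModelResult:
    severity: str                  # "moderate" | "severe"
    adjusted_mean: float
    variance_component: float      # tau^2 on the z scale
    converged: bool
    loglik: float
    applicable: bool = True        # False when the variance is nonsensical


@dataclass(frozen=True)
class PetPeeseResult:
    pet_estimate: float
    pet_p_one_tailed: float
    peese_estimate: float
    selected: float
    slope_pet: float
    slope_peese: float


@dataclass(frozen=True)
class PUniformResult:
    estimate: float
    ci95: tuple[float, float]
    k_sig: int


@dataclass(frozen=True)
class TesResult:
    observed_sig: int
    expected_sig: float
    statistic: float
    p_tes: float


@dataclass(frozen=True)
class CumulativeStep:
    n_cum: int
    k_cum: int
    mean: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class FunnelContour:
    """Significance-contour geometry for a funnel plot.

    ``boundary(level, se)`` gives the two-sided significance boundary
    (effect_low, effect_high) at a given standard error.
    """

    axis_y: str                    # "inverse_se" | "precision" | "se"
    levels: tuple[float, ...] = (0.05, 0.10)

    def boundary(self, level: float, se: float) -> tuple[float, float]:
        zc = stats.norm.ppf(1 - level / 2)
        return (-zc * se, zc * se)

    def classify(self, effect: float, se: float) -> str:
        p = 2 * stats.norm.sf(abs(effect) / se)
        if p < 0.05:
            return "significant"
        if p < 0.10:
            return "marginal"
        return "clear"


# ---------------------------------------------------------------------------
# Trim and fill
# ---------------------------------------------------------------------------

def _l0_estimate(y_sorted, center: float) -> int:
    """Rank-based L0 estimator of the number of suppressed studies.

    ``y_sorted`` must be ascending with suppression assumed on the left.
    L0 = (4*T - k(k+1)) / (2k - 1) where T is the Wilcoxon sum of the
    ranks (midranks for ties, so exact mirror symmetry gives L0 = 0) of
    the absolute centered deviations that are positive.
    """
    dev = y_sorted - center
    k = len(y_sorted)
    ranks = stats.rankdata(np.abs(dev), method="average")
    t_n = float(np.sum(ranks[dev > 0]))
    l0 = (4.0 * t_n - k * (k + 1)) / (2.0 * k - 1.0)
    return max(0, int(round(l0)))


def _egger_side(y: np.ndarray, v: np.ndarray) -> str:
    """Auto side: sign of the SE slope in a weighted meta-regression.

    A positive small-study slope (larger effects from noisier studies)
    indicates suppression of small effects, so imputation goes left.
    """
    se = np.sqrt(v)
    X = np.column_stack([np.ones_like(se), se])
    w = 1.0 / v
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ y)
    return "right" if beta[1] < 0 else "left"


def trim_and_fill(
    dataset: MetaDataset,
    side: str = "auto",
    scale: str = "fisher_z",
    max_iter: int = 100,
) -> TrimFillResult:
    """Duval-Tweedie trim-and-fill with the L estimator.

    Iteratively trims the most extreme effects on the unsuppressed side,
    re-centering with fixed-effect pooling, until the L0 count stabilises;
    then mirror-imputes the k0 trimmed studies about the final center and
    reports the random-effects mean of observed plus imputed studies.
    ``side`` is where the imputed (suppressed) studies go; "auto" picks it
    from the sign of the small-study (Egger-type) slope.
    """
    if dataset.k < 3:
        raise ValueError(f"trim-and-fill needs k >= 3, got {dataset.k}")
    y, v = dataset.effects(scale)

    if side == "auto":
        side = _egger_side(y, v)
    if side not in ("left", "right"):
        raise ValueError(f"unknown side {side!r}")

    # Flip so suppression sits on the left; sort ascending.
    flip = -1.0 if side == "right" else 1.0
    order = np.argsort(flip * y, kind="stable")
    ys = flip * y[order]
    vs = v[order]
    k = dataset.k

    k0, k0_prev, center = 0, -1, 0.0
    iters = 0
    while k0 != k0_prev:
        k0_prev = k0
        iters += 1
        if iters > max_iter:
            break
        keep = slice(0, k - k0)
        center = float(np.sum(ys[keep] / vs[keep]) / np.sum(1.0 / vs[keep]))
        k0 = min(_l0_estimate(ys, center), k - 2)
    converged = iters <= max_iter

    if k0 == 0:
        base = pool(dataset, model="random", scale=scale)
        return TrimFillResult(
            side=side, k0=0, adjusted_mean=base.mean,
            adjusted_ci95=base.ci95, imputed_effects=(), converged=converged,
        )

    # Mirror the k0 largest (flipped) effects about the final center,
    # undoing the flip.
    imputed = tuple(
        (float(flip * (2.0 * center - ys[i])), float(vs[i]))
        for i in range(k - k0, k)
    )
    y_all = np.concatenate([y, [z for z, _ in imputed]])
    v_all = np.concatenate([v, [vv for _, vv in imputed]])
    adj_mean_s, adj_ci_s = _re_pool_arrays(y_all, v_all)
    back = from_fisher_z if scale == "fisher_z" else (lambda x: x)
    return TrimFillResult(
        side=side, k0=k0,
        adjusted_mean=back(adj_mean_s),
        adjusted_ci95=(back(adj_ci_s[0]), back(adj_ci_s[1])),
        imputed_effects=imputed, converged=converged,
    )


def _re_pool_arrays(y: np.ndarray, v: np.ndarray) -> tuple[float, tuple[float, float]]:
    """DL random-effects mean and 95% CI for raw effect/variance arrays."""
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    df = len(y) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(math.sqrt(1.0 / np.sum(w_re)))
    zc = stats.norm.ppf(0.975)
    return mu, (mu - zc * se, mu + zc * se)


# ---------------------------------------------------------------------------
# A-priori selection models
# ---------------------------------------------------------------------------

def _one_tailed_p(y: np.ndarray, v: np.ndarray) -> np.ndarray:
    """One-tailed p against H1: effect > 0, on the analysis scale."""
    return stats.norm.sf(y / np.sqrt(v))


def selection_model(
    dataset: MetaDataset,
    severity: str = "moderate",
    cutpoints: tuple[float, ...] | None = None,
    weights: tuple[float, ...] | None = None,
) -> SelectionModelResult:
    """Weighted-likelihood estimate of the mean under fixed step weights.

    Each study's retention weight is a step function of its one-tailed
    p-value (Vevea–Woods moderate or severe scenario). The likelihood in
    (mu, tau^2) on the Fisher-z scale multiplies each study's normal
    density by its interval weight and divides by the per-study
    normalising constant sum_j w_j * P(p in interval j | mu, tau^2).
    """
    if cutpoints is None:
        cutpoints = VEVEA_WOODS_CUTPOINTS
    if weights is None:
        if severity == "moderate":
            weights = VEVEA_WOODS_MODERATE_ONE_TAILED
        elif severity == "severe":
            weights = VEVEA_WOODS_SEVERE_ONE_TAILED
        else:
            raise ValueError(f"unknown severity {severity!r}")
    if len(cutpoints) != len(weights):
        raise ValueError("cutpoints and weights must have the same length")
    if dataset.k < 3:
        raise ValueError(f"selection model needs k >= 3, got {dataset.k}")

    y, v = dataset.effects("fisher_z")
    sd = np.sqrt(v)
    p_one = _one_tailed_p(y, v)
    intervals = np.searchsorted(np.asarray(cutpoints), p_one, side="left")
    intervals = np.clip(intervals, 0, len(weights) - 1)
    if len(np.unique(intervals)) < 2 and not np.allclose(weights, weights[0]):
        raise ValueError(
            "all studies fall into a single p-value interval; "
            "step weights are not identified"
        )

    w_vec = np.asarray(weights, dtype=float)
    log_w_obs = np.log(w_vec[intervals])

    # y-space thresholds per study: p < c  <=>  y > sd * z_{1-c}
    # interval j spans (lower_j, upper_j] in y, upper_0 = +inf
    zq = stats.norm.isf(np.asarray(cutpoints))          # z_{1-c_j}
    uppers = np.concatenate([[np.inf], zq[:-1]])        # per interval j
    lowers = zq
    # matrices (k, m): bounds in y for each study x interval
    U = sd[:, None] * uppers[None, :]
    L = sd[:, None] * lowers[None, :]

    def neg_loglik(params: np.ndarray) -> float:
        mu, log_tau2 = params
        tau2 = math.exp(log_tau2)
        s2 = v + tau2
        s = np.sqrt(s2)
        dens = stats.norm.logpdf(y, loc=mu, scale=s)
        probs = stats.norm.cdf((U - mu) / s[:, None]) - stats.norm.cdf(
            (L - mu) / s[:, None]
        )
        norm_const = probs @ w_vec
        if np.any(norm_const <= 0):
            return 1e10
        ll = np.sum(log_w_obs + dens - np.log(norm_const))
        return -ll

    # start from the naive RE fit
    base = pool(dataset, model="random", scale="fisher_z")
    tau2_0 = max(base.tau2 or 1e-4, 1e-4)
    res = optimize.minimize(
        neg_loglik,
        x0=np.array([base.mean_on_scale, math.log(tau2_0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    mu_hat = float(res.x[0])
    tau2_hat = float(math.exp(res.x[1]))
    converged = bool(res.success) and math.isfinite(res.fun)
    applicable = converged and tau2_hat <= _TAU2_SANITY_BOUND
    return SelectionModelResult(
        severity=severity,
        adjusted_mean=from_fisher_z(mu_hat),
        variance_component=tau2_hat,
        converged=converged,
        loglik=float(-res.fun),
        applicable=applicable,
    )


# ---------------------------------------------------------------------------
# PET-PEESE
# ---------------------------------------------------------------------------

def pet_peese(dataset: MetaDataset, alpha: float = 0.05) -> PetPeeseResult:
    """Precision-effect test / precision-effect estimate with SE.

    On raw correlations: PET regresses r on SE, PEESE regresses r on SE^2,
    both weighted by 1/SE^2; each intercept estimates the effect of an
    infinitely precise study. PEESE is selected when PET's intercept is
    significantly positive at the one-tailed ``alpha``, else PET.
    """
    if dataset.k < 3:
        raise ValueError(f"PET-PEESE needs k >= 3, got {dataset.k}")
    y = dataset.r_values()
    # Common-rho plug-in variance: (1 - rbar^2)^2 / (n_i - 1) with rbar the
    # fixed-effect pooled raw mean. Using each study's own r in its SE would
    # mechanically correlate effect and SE and bias the small-study slope
    # away from zero even without suppression. se_override takes precedence.
    n = dataset.n_values()
    rbar = float(np.sum(y * (n - 1)) / np.sum(n - 1))
    v = np.array(
        [
            s.se_override**2 if s.se_override is not None
            else (1.0 - rbar**2) ** 2 / (s.n - 1)
            for s in dataset.studies
        ]
    )
    se = np.sqrt(v)
    if np.allclose(se, se[0]):
        raise ValueError("all standard errors identical; PET regressor is collinear")

    import statsmodels.api as sm

    w = 1.0 / v
    pet_fit = sm.WLS(y, sm.add_constant(se), weights=w).fit()
    peese_fit = sm.WLS(y, sm.add_constant(v), weights=w).fit()

    pet_est = float(pet_fit.params[0])
    t_stat = float(pet_fit.params[0] / pet_fit.bse[0])
    p_one = float(stats.t.sf(t_stat, df=dataset.k - 2))
    peese_est = float(peese_fit.params[0])
    return PetPeeseResult(
        pet_estimate=pet_est,
        pet_p_one_tailed=p_one,
        peese_estimate=peese_est,
        selected=peese_est if p_one < alpha else pet_est,
        slope_pet=float(pet_fit.params[1]),
        slope_peese=float(peese_fit.params[1]),
    )


# ---------------------------------------------------------------------------
# p-uniform
# ---------------------------------------------------------------------------

def _neg_log_q_sum(mu: float, z: np.ndarray, sd: np.ndarray, zcrit: np.ndarray) -> float:
    """sum_i -ln q_i(mu), q_i the conditional exceedance probability."""
    log_q = stats.norm.logsf((z - mu) / sd) - stats.norm.logsf((zcrit - mu) / sd)
    return float(-np.sum(log_q))


def p_uniform(
    dataset: MetaDataset, alpha_one_tailed: float = 0.05
) -> PUniformResult:
    """Effect estimate from significant studies only (Irwin–Hall moment form).

    Among studies one-tailed significant on the Fisher-z scale, each
    conditional probability q_i(mu) = P(Z > z_i | Z > z_crit,i; mu) is
    uniform at the true mu, so sum_i -ln q_i(mu) ~ Gamma(k_sig, 1). The
    estimate solves sum -ln q_i = k_sig; CI bounds solve the 97.5% and
    2.5% gamma quantile equations. Estimates back-transform to r.
    """
    y, v = dataset.effects("fisher_z")
    sd = np.sqrt(v)
    zcrit = stats.norm.isf(alpha_one_tailed) * sd
    sig = y > zcrit
    k_sig = int(np.sum(sig))
    if k_sig == 0:
        raise ValueError("no study is significant at the one-tailed threshold")
    z_s, sd_s, zc_s = y[sig], sd[sig], zcrit[sig]

    def solve(target: float) -> float:
        f = lambda mu: _neg_log_q_sum(mu, z_s, sd_s, zc_s) - target
        lo = float(np.min(z_s) - 10 * np.max(sd_s))
        hi = float(np.max(z_s) + 10 * np.max(sd_s))
        for _ in range(60):
            if f(lo) > 0 and f(hi) < 0:
                break
            if f(lo) <= 0:
                lo -= 5 * float(np.max(sd_s))
            if f(hi) >= 0:
                hi += 5 * float(np.max(sd_s))
        else:
            raise RuntimeError(
                f"p-uniform root not bracketed: target={target}, "
                f"f(lo)={f(lo):.3g}, f(hi)={f(hi):.3g}"
            )
        return float(optimize.brentq(f, lo, hi, xtol=1e-10))

    est = solve(float(k_sig))
    lo_ci = solve(float(stats.gamma.ppf(0.975, k_sig)))
    hi_ci = solve(float(stats.gamma.ppf(0.025, k_sig)))
    return PUniformResult(
        estimate=from_fisher_z(est),
        ci95=(from_fisher_z(lo_ci), from_fisher_z(hi_ci)),
        k_sig=k_sig,
    )


# ---------------------------------------------------------------------------
# Test of excess significance
# ---------------------------------------------------------------------------

def tes(
    dataset: MetaDataset,
    rho_hat: float | None = None,
    alpha: float = 0.05,
) -> TesResult:
    """Test of excess significance: observed vs power-expected counts.

    Per-study power is the probability of two-sided significance at
    ``alpha`` given a true effect equal to ``rho_hat`` (the RE pooled mean
    when not supplied) on the Fisher-z scale. The chi-square statistic
    A = (O-E)^2/E + (O-E)^2/(k-E) has 1 df; a small upper-tail probability
    (conventionally < .1) suggests the set of studies lacks credibility.
    """
    if rho_hat is None:
        rho_hat = pool(dataset, model="random", scale="fisher_z").mean
    theta = to_fisher_z(rho_hat)
    y, v = dataset.effects("fisher_z")
    sd = np.sqrt(v)
    zc = stats.norm.isf(alpha / 2)
    crit = zc * sd

    power = stats.norm.sf((crit - theta) / sd) + stats.norm.cdf((-crit - theta) / sd)
    E = float(np.sum(power))
    O = int(np.sum(np.abs(y) > crit))
    k = dataset.k

    if E <= 0 or E >= k:
        p = 1.0 if O == round(E) else 0.0
        return TesResult(observed_sig=O, expected_sig=E, statistic=float("inf"), p_tes=p)
    A = (O - E) ** 2 / E + (O - E) ** 2 / (k - E)
    p = float(stats.chi2.sf(A, 1))
    return TesResult(observed_sig=O, expected_sig=E, statistic=float(A), p_tes=p)


# ---------------------------------------------------------------------------
# Cumulative meta-analysis by precision
# ---------------------------------------------------------------------------

def cumulative_by_precision(
    dataset: MetaDataset, scale: str = "fisher_z"
) -> list[CumulativeStep]:
    """RE pooling of the j largest studies, j = 1..k, sorted by n descending.

    A drift from smaller to larger means as small studies enter is
    consistent with suppression of small nonsignificant effects.
    """
    if dataset.k < 2:
        raise ValueError(f"cumulative meta-analysis needs k >= 2, got {dataset.k}")
    order = sorted(dataset.studies, key=lambda s: (-s.n, s.id))
    steps: list[CumulativeStep] = []
    n_cum = 0
    for j in range(1, len(order) + 1):
        sub = MetaDataset(tuple(order[:j]), label=dataset.label)
        p = pool(sub, model="random", scale=scale)
        n_cum += order[j - 1].n
        steps.append(CumulativeStep(n_cum=n_cum, k_cum=j, mean=p.mean, ci95=p.ci95))
    return steps


# ---------------------------------------------------------------------------
# Funnel contours
# ---------------------------------------------------------------------------

def funnel_contours(
    dataset: MetaDataset,
    axis_y: str = "inverse_se",
    scale: str = "raw_r",
):
    """Contour-enhanced funnel data: study coordinates plus significance regions.

    Returns (FunnelContour, DataFrame) where the frame holds one row per
    study with its effect, SE, y-axis coordinate and significance region
    (clear: p > .10; marginal: .05 < p <= .10; significant: p < .05).
    """
    import pandas as pd

    if axis_y not in ("inverse_se", "precision", "se"):
        raise ValueError(f"unknown axis_y {axis_y!r}")
    y, v = dataset.effects(scale)
    se = np.sqrt(v)
    contour = FunnelContour(axis_y=axis_y)
    if axis_y == "se":
        ycoord = se
    elif axis_y == "precision":
        ycoord = 1.0 / v
    else:
        ycoord = 1.0 / se
    frame = pd.DataFrame(
        {
            "study_id": [s.id for s in dataset.studies],
            "effect": y,
            "se": se,
            "y": ycoord,
            "region": [contour.classify(e, s) for e, s in zip(y, se)],
        }
    )
    return contour, frame


# ---------------------------------------------------------------------------
# Battery driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatteryRow:
    """All battery outputs for one (sub-)distribution; None where skipped.

    ``skipped_reason`` explains a below-gate distribution (pooled
    statistics are still present, mirroring blank bias cells in a report).
    """

    label: str
    k: int
    pooled: PooledResult
    pooled_fe: PooledResult
    osr: "OsrSummary | None" = None
    trim_fill: TrimFillResult | None = None
    sm_moderate: SelectionModelResult | None = None
    sm_severe: SelectionModelResult | None = None
    tes_result: TesResult | None = None
    petpeese: PetPeeseResult | None = None
    puniform: PUniformResult | None = None
    cumulative: tuple[CumulativeStep, ...] | None = None
    skipped_reason: str | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)


def run_battery(
    dataset: MetaDataset,
    min_k: int = MIN_K_FOR_BIAS,
    alpha_pet: float = 0.05,
) -> BatteryRow:
    """Run pooling plus, when k >= min_k, the full bias battery.

    Distributions below the gate report pooled statistics only (the
    conventional guard against second-order sampling error); individual
    method failures are recorded in ``notes`` rather than aborting.
    """
    from .influence import one_sample_removed

    pooled = pool(dataset, model="random", scale="fisher_z")
    pooled_fe = pool(dataset, model="fixed", scale="fisher_z")
    osr = one_sample_removed(dataset) if dataset.k >= 3 else None

    if dataset.k < min_k:
        return BatteryRow(
            label=dataset.label, k=dataset.k, pooled=pooled, pooled_fe=pooled_fe,
            osr=osr, skipped_reason=f"k={dataset.k} < {min_k}",
        )

    notes: list[str] = []

    def attempt(fn, *args, **kw):
        try:
            return fn(dataset, *args, **kw)
        except (ValueError, RuntimeError) as exc:
            notes.append(f"{fn.__name__}: {exc}")
            return None

    tf = attempt(trim_and_fill)
    sm_m = attempt(selection_model, severity="moderate")
    sm_s = attempt(selection_model, severity="severe")
    tes_res = attempt(tes)
    pp = attempt(pet_peese, alpha=alpha_pet)
    pu = attempt(p_uniform)
    cum = attempt(cumulative_by_precision)

    return BatteryRow(
        label=dataset.label, k=dataset.k, pooled=pooled, pooled_fe=pooled_fe,
        osr=osr, trim_fill=tf, sm_moderate=sm_m, sm_severe=sm_s,
        tes_result=tes_res, petpeese=pp, puniform=pu,
        cumulative=tuple(cum) if cum else None,
        notes=tuple(notes),
    )
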