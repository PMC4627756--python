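"""Effect-size transforms and fixed-/random-effects pooling of correlations.

Correlations are pooled in the Hedges–Olkin tradition: each Pearson r is
mapped to Fisher's z = arctanh(r) with sampling variance 1/(n - 3),
inverse-variance weighted, and the pooled mean and its intervals are
back-transformed to the r metric. The random-effects model adds a
DerSimonian–Laird estimate of the between-study variance tau^2 to every
sampling variance. Some downstream procedures (PET-PEESE, outlier
diagnostics) instead operate on raw correlations with the large-sample
variance (1 - r^2)^2 / (n - 1); both conventions live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Study",
    "MetaDataset",
    "PooledResult",
    "to_fisher_z",
    "from_fisher_z",
    "variance_of_effect",
    "pool",
    "prediction_interval",
    "subgroup_q_test",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Study:
    """A single correlation effect size.

    Parameters
    ----------
    id : str
        Unique label within a dataset.
    r : float
        Observed Pearson correlation, strictly inside (-1, 1).
    n : int
        Sample size; at least 4 so the Fisher-z variance 1/(n-3) exists.
    moderators : mapping
        Categorical moderator labels, e.g. ``{"source": "journal"}``.
    se_override : float, optional
        If given, ``se_override**2`` replaces the formula-based variance on
        both scales.
    """

    id: str
    r: float
    n: int
    moderators: Mapping[str, str] = field(default_factory=dict)
    se_override: float | None = None

    def __post_init__(self) -> None:
        if not (-1.0 < self.r < 1.0):
            raise ValueError(f"study {self.id!r}: r={self.r} outside (-1, 1)")
        if self.n < 4:
            raise ValueError(f"study {self.id!r}: n={self.n} < 4")
        if self.se_override is not None and self.se_override <= 0:
            raise ValueError(f"study {self.id!r}: se_override must be positive")


@dataclass(frozen=True)
class MetaDataset:
    """An ordered collection of studies forming one (sub-)distribution."""

    studies: tuple[Study, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        if len(self.studies) < 1:
            raise ValueError("dataset must contain at least one study")
        ids = [s.id for s in self.studies]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate study ids: {dupes}")

    @property
    def k(self) -> int:
        return len(self.studies)

    @property
    def total_n(self) -> int:
        return int(sum(s.n for s in self.studies))

    def r_values(self) -> np.ndarray:
        return np.array([s.r for s in self.studies], dtype=float)

    def n_values(self) -> np.ndarray:
        return np.array([s.n for s in self.studies], dtype=float)

    def effects(self, scale: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (effects, variances) on the requested scale."""
        y = np.array(
            [to_fisher_z(s.r) if scale == "fisher_z" else s.r for s in self.studies]
        )
        v = np.array([variance_of_effect(s, scale) for s in self.studies])
        return y, v

    def subset(self, keep: Iterable[int], label: str | None = None) -> "MetaDataset":
        keep = list(keep)
        return MetaDataset(
            studies=tuple(self.studies[i] for i in keep),
            label=label if label is not None else self.label,
        )

    def without(self, study_id: str) -> "MetaDataset":
        return MetaDataset(
            studies=tuple(s for s in self.studies if s.id != study_id),
            label=self.label,
        )

    def split_by(self, moderator: str) -> dict[str, "MetaDataset"]:
        """Partition into sub-distributions by a moderator's categories."""
        groups: dict[str, list[Study]] = {}
        for s in self.studies:
            key = s.moderators.get(moderator, "")
            groups.setdefault(key, []).append(s)
        return {
            lvl: MetaDataset(tuple(members), label=f"{moderator}={lvl}")
            for lvl, members in groups.items()
        }


@dataclass(frozen=True)
class PooledResult:
    """A fixed- or random-effects pooled mean with heterogeneity statistics.

    ``mean``/``ci95``/``pi90`` are reported in the r metric even when the
    computation ran on Fisher z; ``tau2``/``tau`` stay on the analysis scale.
    """

    model: str              # "fixed" | "random"
    scale: str              # "raw_r" | "fisher_z"
    mean: float
    se: float
    ci95: tuple[float, float]
    pi90: tuple[float, float] | None
    Q: float | None
    df: int | None
    I2: float | None
    tau2: float | None
    tau: float | None
    k: int

    @property
    def mean_on_scale(self) -> float:
        """Pooled mean on the analysis scale (z when scale='fisher_z')."""
        return to_fisher_z(self.mean) if self.scale == "fisher_z" else self.mean


# ---------------------------------------------------------------------------
# Transforms and variances
# ---------------------------------------------------------------------------

def to_fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform z = arctanh(r)."""
    if not (-1.0 < r < 1.0):
        raise ValueError(f"r={r} outside the open interval (-1, 1)")
    return math.atanh(r)


def from_fisher_z(z: float) -> float:
    """Inverse transform r = tanh(z)."""
    if not math.isfinite(z):
        raise ValueError(f"z={z} is not finite")
    return math.tanh(z)


def variance_of_effect(study: Study, scale: str) -> float:
    """Sampling variance of a study's effect on the requested scale.

    Fisher z: 1/(n-3). Raw r: the large-sample form (1-r^2)^2/(n-1).
    An ``se_override`` takes precedence on either scale.
    """
    if study.se_override is not None:
        return study.se_override**2
    if scale == "fisher_z":
        if study.n <= 3:
            raise ValueError(f"study {study.id!r}: n={study.n} <= 3 on fisher_z scale")
        return 1.0 / (study.n - 3)
    if scale == "raw_r":
        return (1.0 - study.r**2) ** 2 / (study.n - 1)
    raise ValueError(f"unknown scale {scale!r}")


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def _dl_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float, int]:
    """DerSimonian–Laird tau^2 with the fixed-effect Q it derives from.

    Returns (tau2, Q, df). tau2 is truncated at zero.
    """
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    df = len(y) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    return tau2, Q, df


def _back(x: float, scale: str) -> float:
    return from_fisher_z(x) if scale == "fisher_z" else x


def pool(
    dataset: MetaDataset,
    model: str = "random",
    scale: str = "fisher_z",
    tau2_method: str = "DL",
) -> PooledResult:
    """Inverse-variance pooled mean of a dataset.

    Parameters
    ----------
    model : {"random", "fixed"}
        Random-effects adds the estimated tau^2 to every sampling variance.
    scale : {"fisher_z", "raw_r"}
        Analysis scale; means and intervals are always reported as r.
    tau2_method : {"DL", "REML"}
        Between-study variance estimator; DerSimonian–Laird by default,
        restricted maximum likelihood as an extension.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    y, v = dataset.effects(scale)
    k = dataset.k

    if k == 1:
        se = float(np.sqrt(v[0]))
        zc = stats.norm.ppf(0.975)
        return PooledResult(
            model=model, scale=scale, mean=_back(float(y[0]), scale), se=se,
            ci95=(_back(float(y[0] - zc * se), scale), _back(float(y[0] + zc * se), scale)),
            pi90=None, Q=None, df=None, I2=None, tau2=None, tau=None, k=1,
        )

    tau2, Q, df = _dl_tau2(y, v)
    if tau2_method == "REML":
        tau2 = _reml_tau2(y, v, start=tau2)
    elif tau2_method != "DL":
        raise ValueError(f"unknown tau2_method {tau2_method!r}")
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0

    w = 1.0 / (v + tau2) if model == "random" else 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    zc = stats.norm.ppf(0.975)

    result = PooledResult(
        model=model, scale=scale,
        mean=_back(mu, scale), se=se,
        ci95=(_back(mu - zc * se, scale), _back(mu + zc * se, scale)),
        pi90=None, Q=Q, df=df, I2=I2,
        tau2=tau2 if model == "random" else tau2,  # reported for both models
        tau=math.sqrt(tau2), k=k,
    )
    if model == "random" and k >= 3:
        result = _with_pi(result, k)
    return result


def _reml_tau2(y: np.ndarray, v: np.ndarray, start: float) -> float:
    from scipy.optimize import minimize_scalar

    def neg_restricted_ll(tau2: float) -> float:
        s2 = v + tau2
        w = 1.0 / s2
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(s2)) + math.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    hi = max(4 * start, 10 * float(np.var(y)), 0.1)
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, hi), method="bounded")
    return float(res.x)


def _with_pi(pooled: PooledResult, k: int, level: float = 0.90) -> PooledResult:
    pi = prediction_interval(pooled, k, level)
    return PooledResult(**{**pooled.__dict__, "pi90": pi})


def prediction_interval(
    pooled: PooledResult, k: int, level: float = 0.90
) -> tuple[float, float]:
    """Interval expected to contain the true effect of a new study.

    On the analysis scale: mean +/- t_{(1+level)/2, k-2} * sqrt(tau2 + se^2),
    back-transformed to r when pooling ran on Fisher z (Higgins convention,
    t with k-2 degrees of freedom).
    """
    if k < 3:
        raise ValueError(f"prediction interval undefined for k={k} < 3")
    if pooled.tau2 is None:
        raise ValueError("pooled result lacks tau2; pool with k >= 2 first")
    mu = pooled.mean_on_scale
    tcrit = stats.t.ppf((1 + level) / 2, k - 2)
    half = tcrit * math.sqrt(pooled.tau2 + pooled.se**2)
    return (_back(mu - half, pooled.scale), _back(mu + half, pooled.scale))


def subgroup_q_test(
    groups: Sequence[MetaDataset],
    model: str = "random",
    scale: str = "fisher_z",
) -> tuple[float, int, float]:
    """Between-group Q test for moderator effects.

    Pools each subgroup separately (random-effects by default), then
    Q_between = sum_j W_j (mu_j - mu_bar)^2 with W_j = 1/se_j^2 and mu_bar
    their W-weighted mean; p from chi-square with (groups - 1) df.
    """
    if len(groups) < 2:
        raise ValueError("need at least two subgroups")
    mus, Ws = [], []
    for g in groups:
        p = pool(g, model=model, scale=scale)
        mus.append(p.mean_on_scale)
        Ws.append(1.0 / p.se**2)
    mus_arr, Ws_arr = np.array(mus), np.array(Ws)
    mu_bar = float(np.sum(Ws_arr * mus_arr) / np.sum(Ws_arr))
    Qb = float(np.sum(Ws_arr * (mus_arr - mu_bar) ** 2))
    df = len(groups) - 1
    p_val = float(stats.chi2.sf(Qb, df))
    return Qb, df, p_val
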