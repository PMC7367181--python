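"""Regulation-strength estimation, construct-rate prediction, and the noise-vs-1/mean fit.

Strengths are estimated by inverting the fold-change expressions of the
two-state model at guide saturation.  A lone repressor at saturation gives

    fold = [k_on_wt*(1-k_r) / (k_on_wt*(1-k_r) + k_off_wt)]
           / [k_on_wt / (k_on_wt + k_off_wt)]

and a lone activator the analogous expression with ``k_off_wt*(1-k_a)``.
Both are monotone and invert in closed form.

The noise-mean relationship is scored by ordinary least squares of eta^2 on
1/(normalized mean): a constitutive promoter falls exactly on a line, and
the average vertical deviation (d_ave) of paired-construct points from the
single-guide reference line quantifies noise-mean decoupling per expression
region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateFitError,
    IncompleteEstimationError,
    InsufficientDataError,
    NotAnActivatorError,
    NotARepressorError,
    SaturationWarning,
)
from .library import CrisprarConstruct, classify_construct, strand_relation
from .telegraph import (
    CrisprParams,
    PromoterKinetics,
    apply_crisprar,
    mean_expression,
    noise_expression,
)

import warnings

__all__ = [
    "NoisePoint",
    "LinearNoiseFit",
    "estimate_repression_strength",
    "estimate_activation_strength",
    "predict_construct_rates",
    "predicted_summaries",
    "fit_noise_line",
    "average_deviation",
    "matched_mean_comparison",
    "MatchedComparison",
]


@dataclass(frozen=True)
class NoisePoint:
    """One construct in the noise-vs-1/mean plane."""

    construct_id: str
    inv_norm_mean: float
    noise: float
    region: str | None = None  # "high_expression" | "low_expression"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.inv_norm_mean) and self.inv_norm_mean > 0):
            raise InsufficientDataError("inv_norm_mean must be finite and positive")
        if not (math.isfinite(self.noise) and self.noise > 0):
            raise InsufficientDataError("noise must be finite and positive")


@dataclass(frozen=True)
class LinearNoiseFit:
    """OLS fit of noise on 1/(normalized mean), both on linear scale."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    d_ave_by_region: dict[str, float] = field(default_factory=dict)

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def _check_fold(fold_change: float) -> None:
    if not (math.isfinite(fold_change) and fold_change > 0):
        raise InsufficientDataError(f"fold change must be finite and > 0, got {fold_change}")


def estimate_repression_strength(
    fold_change: float, wt: PromoterKinetics | None = None
) -> float:
    """Invert the repressed/control mean ratio to the strength k_r.

    With wild-type rates 1 this reduces to ``k_r = (2 - 2f)/(2 - f)``.
    Assumes the repressing guide is at saturation.
    """
    _check_fold(fold_change)
    if fold_change > 1.0:
        raise NotARepressorError(
            f"fold change {fold_change} > 1: expression rose, not a repressor"
        )
    a = wt.k_on_wt if wt is not None else 1.0
    b = wt.k_off_wt if wt is not None else 1.0
    m0 = a / (a + b)
    # fold*m0 = x/(x+b) with x = a*(1-k_r)
    x = b * fold_change * m0 / (1.0 - fold_change * m0)
    k_r = 1.0 - x / a
    return min(max(k_r, 0.0), 1.0)


def estimate_activation_strength(
    fold_change: float, wt: PromoterKinetics | None = None
) -> float:
    """Invert the activated/control mean ratio to the strength k_a.

    With wild-type rates 1: ``k_a = 2 - 2/f``.  A fold change beyond the
    model's ceiling (f > (a+b)/a, i.e. 2 under unit wild-type rates) cannot
    be expressed; the estimate is clamped to 1 with a warning.
    """
    _check_fold(fold_change)
    if fold_change < 1.0:
        raise NotAnActivatorError(
            f"fold change {fold_change} < 1: expression fell, not an activator"
        )
    a = wt.k_on_wt if wt is not None else 1.0
    b = wt.k_off_wt if wt is not None else 1.0
    m0 = a / (a + b)
    ceiling = 1.0 / m0
    if fold_change > ceiling:
        warnings.warn(
            f"fold change {fold_change} exceeds the model ceiling {ceiling:g}; "
            "k_a clamped to 1",
            SaturationWarning,
            stacklevel=2,
        )
        return 1.0
    # f*m0 = a/(a + b*(1-k_a))
    k_a = 1.0 - (a / (fold_change * m0) - a) / b
    return min(max(k_a, 0.0), 1.0)


def predict_construct_rates(
    c: CrisprarConstruct,
    params: CrisprParams,
    wt: PromoterKinetics,
) -> tuple[PromoterKinetics, float, float]:
    """Modulated kinetics and analytic (mean, noise) for one paired construct.

    The strand relation comes from the two modules' target strands; the
    modules' estimated strengths replace ``params.k_r``/``params.k_a``.
    Transcription order carries no model term, so order-swapped constructs
    predict identically.
    """
    k_a = c.act_module.regulation_strength
    k_r = c.rep_module.regulation_strength
    if k_a is None or k_r is None:
        raise IncompleteEstimationError(
            f"{c.construct_id}: both modules need an estimated regulation strength"
        )
    p = CrisprParams(
        k_r=k_r,
        k_a=k_a,
        K_ro=params.K_ro,
        K_ao=params.K_ao,
        K_i=params.K_i,
        K_int1=params.K_int1,
        K_int2=params.K_int2,
    )
    kin = apply_crisprar(wt, p, c.conc_A, c.conc_R, strand_relation(c))
    mean = mean_expression(kin)
    noise = noise_expression(kin, mean)
    return kin, mean, noise


def predicted_summaries(
    library: list[CrisprarConstruct],
    params: CrisprParams,
    wt: PromoterKinetics,
) -> pd.DataFrame:
    """Model-predicted summary table for a construct library.

    Means are normalized to the wild-type (no-sgRNA control) mean, and the
    empirical-rule labels are attached, so the output feeds directly into
    :func:`crisprar.library.decision_tree_select`.
    """
    control_mean = mean_expression(wt.with_rates(wt.k_on_wt, wt.k_off_wt))
    rows = []
    for c in library:
        kin, mean, noise = predict_construct_rates(c, params, wt)
        labels = classify_construct(c)
        rows.append(
            {
                "construct_id": c.construct_id,
                "k_on": kin.k_on,
                "k_off": kin.k_off,
                "mean": mean,
                "noise": noise,
                "norm_mean": mean / control_mean,
                "inv_norm_mean": control_mean / mean,
                "rule1": labels.rule1,
                "rule2": labels.rule2,
                "rule3": labels.rule3,
            }
        )
    return pd.DataFrame(rows)


def fit_noise_line(points: list[NoisePoint]) -> LinearNoiseFit:
    """Ordinary least squares of noise on 1/(normalized mean)."""
    if len(points) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(points)}")
    x = np.array([p.inv_norm_mean for p in points])
    y = np.array([p.noise for p in points])
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0.0:
        raise DegenerateFitError("zero variance in 1/norm-mean: cannot fit a line")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return LinearNoiseFit(slope=slope, intercept=intercept, r_squared=r2, n_points=len(points))


def average_deviation(points: list[NoisePoint], fit: LinearNoiseFit) -> dict[str, float]:
    """Mean vertical |residual| from the reference line, per expression region.

    Points without a region label are pooled under ``"all"``.  Regions with
    no points are simply absent from the result.
    """
    resid: dict[str, list[float]] = {}
    for p in points:
        region = p.region if p.region is not None else "all"
        resid.setdefault(region, []).append(
            abs(p.noise - (fit.slope * p.inv_norm_mean + fit.intercept))
        )
    return {region: float(np.mean(v)) for region, v in resid.items()}


@dataclass(frozen=True)
class MatchedComparison:
    """Matched-mean noise comparison between two construct groups."""

    pairs: pd.DataFrame  # id_a, id_b, x_a, x_b, noise_a, noise_b, noise_diff
    mean_noise_diff: float
    n_matched: int
    f_statistic: float
    p_value: float


def matched_mean_comparison(
    group_a: list[NoisePoint],
    group_b: list[NoisePoint],
    match_tolerance: float = 0.03,
) -> MatchedComparison:
    """Pair points across groups at matched 1/(normalized mean) and compare noise.

    Pairing is greedy closest-first on |x_a - x_b| <= ``match_tolerance``,
    each point used at most once.  ``noise_diff = noise_a - noise_b`` per
    pair.  The matched subset is tested with a two-way ANOVA (factors:
    group, pair); the reported F and p refer to the group factor.  With no
    matched pairs a result with ``n_matched = 0`` and NaN statistics is
    returned (a no-overlap signal, not an error).
    """
    if not group_a or not group_b:
        raise InsufficientDataError("both groups must be nonempty")
    candidates = sorted(
        (
            (abs(pa.inv_norm_mean - pb.inv_norm_mean), i, j)
            for i, pa in enumerate(group_a)
            for j, pb in enumerate(group_b)
            if abs(pa.inv_norm_mean - pb.inv_norm_mean) <= match_tolerance
        ),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pa, pb = group_a[i], group_b[j]
        rows.append(
            {
                "id_a": pa.construct_id,
                "id_b": pb.construct_id,
                "x_a": pa.inv_norm_mean,
                "x_b": pb.inv_norm_mean,
                "noise_a": pa.noise,
                "noise_b": pb.noise,
                "noise_diff": pa.noise - pb.noise,
            }
        )
    pairs = pd.DataFrame(
        rows, columns=["id_a", "id_b", "x_a", "x_b", "noise_a", "noise_b", "noise_diff"]
    )
    if pairs.empty:
        return MatchedComparison(
            pairs=pairs,
            mean_noise_diff=float("nan"),
            n_matched=0,
            f_statistic=float("nan"),
            p_value=float("nan"),
        )
    f_stat, p_val = _two_way_anova(pairs)
    return MatchedComparison(
        pairs=pairs,
        mean_noise_diff=float(pairs["noise_diff"].mean()),
        n_matched=len(pairs),
        f_statistic=f_stat,
        p_value=p_val,
    )


def _two_way_anova(pairs: pd.DataFrame) -> tuple[float, float]:
    """Two-factor (group x pair) ANOVA on the matched noise values."""
    if len(pairs) < 2:
        return float("nan"), float("nan")
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    long = pd.DataFrame(
        {
            "noise": np.concatenate([pairs["noise_a"], pairs["noise_b"]]),
            "group": ["a"] * len(pairs) + ["b"] * len(pairs),
            "pair": list(range(len(pairs))) * 2,
        }
    )
    model = ols("noise ~ C(group) + C(pair)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return float(table.loc["C(group)", "F"]), float(table.loc["C(group)", "PR(>F)"])
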