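"""Inverse-variance random-effects meta-analysis of MCID-unit outcomes.

The random-effects model assumes observed study effects y_i ~ N(theta_i, v_i)
with true effects theta_i ~ N(mu, tau^2).  The between-study variance tau^2 is
estimated by restricted maximum likelihood (REML), which profiles out the
pooled mean so that estimating mu costs no bias in tau^2.  Pooling then uses
weights w_i* = 1/(v_i + tau^2); heterogeneity is summarised by Cochran's Q
(computed with fixed-effect weights) and Higgins' I^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from os import PathLike
from typing import Sequence

import numpy as np

from .errors import ConvergenceError, DegenerateEffectError, ValidationError
from .prioritize import UnifiedOutcome

__all__ = [
    "EffectSize",
    "MetaResult",
    "ForestRow",
    "Z_975",
    "md_effect",
    "effects_from_unified",
    "restricted_loglik",
    "dersimonian_laird_tau2",
    "reml_tau2",
    "pool_random_effects",
    "heterogeneity_stats",
    "i2_band",
    "random_effects_meta",
    "forest_data",
    "render_forest",
]

#: Two-sided 97.5% standard-normal quantile used for all Wald 95% CIs.
Z_975 = 1.959964


@dataclass(frozen=True)
class EffectSize:
    """Per-study mean difference in MCID units with its sampling variance."""

    study_id: str
    md: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise DegenerateEffectError(
                f"study {self.study_id}: sampling variance must be positive, got {self.variance}"
            )

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity statistics and normalized weights."""

    mu: float
    se_mu: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    df: int
    i2: float
    band: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mu <= self.ci_high:
            raise ValidationError("CI must bracket the pooled estimate")
        if self.tau2 < 0 or not 0 <= self.i2 <= 100:
            raise ValidationError("tau2 must be >= 0 and i2 in [0, 100]")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValidationError("normalized weights must sum to 1")


def md_effect(arm1: UnifiedOutcome, arm2: UnifiedOutcome) -> EffectSize:
    """Mean difference (arm1 - arm2) with the two-sample summary variance.

    variance = sd1^2/n1 + sd2^2/n2, the standard formula for the difference of
    two independent arm means.
    """
    if arm1.study_id != arm2.study_id:
        raise ValidationError(
            f"arms belong to different studies: {arm1.study_id} vs {arm2.study_id}"
        )
    if arm1.n < 2 or arm2.n < 2:
        raise ValidationError(f"study {arm1.study_id}: each arm needs n >= 2")
    variance = arm1.sd_mcid**2 / arm1.n + arm2.sd_mcid**2 / arm2.n
    if variance <= 0:
        raise DegenerateEffectError(
            f"study {arm1.study_id}: both arms report zero SD; effect cannot be weighted"
        )
    return EffectSize(study_id=arm1.study_id, md=arm1.mean_mcid - arm2.mean_mcid, variance=variance)


def effects_from_unified(
    unified: Sequence[UnifiedOutcome], reference_arm: str
) -> list[EffectSize]:
    """Build one effect per study as (other arm) - (reference arm).

    ``reference_arm`` is the subtrahend: positive effects favour the
    non-reference arm on a higher-is-better MCID scale.  Each study must have
    exactly two arms, one of them labelled ``reference_arm``.
    """
    order: list[str] = []
    grouped: dict[str, list[UnifiedOutcome]] = {}
    for u in unified:
        if u.study_id not in grouped:
            order.append(u.study_id)
            grouped[u.study_id] = []
        grouped[u.study_id].append(u)
    effects = []
    for study_id in order:
        arms = grouped[study_id]
        if len(arms) != 2:
            raise ValidationError(f"study {study_id}: expected 2 arms, got {len(arms)}")
        labels = {a.arm_id for a in arms}
        if str(reference_arm) not in labels:
            raise ValidationError(
                f"study {study_id}: reference arm {reference_arm!r} not found in {sorted(labels)}"
            )
        ref = next(a for a in arms if a.arm_id == str(reference_arm))
        other = next(a for a in arms if a is not ref)
        effects.append(md_effect(other, ref))
    return effects


def _arrays(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.md for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    return y, v


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of tau^2 (constant terms dropped).

    l(tau^2) = -1/2 [ sum log(v_i + tau^2) + log sum 1/(v_i + tau^2)
                      + sum (y_i - mu_hat)^2 / (v_i + tau^2) ]
    with mu_hat the inverse-variance weighted mean at this tau^2.
    """
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return -0.5 * (
        np.sum(np.log(v + tau2)) + math.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
    )


def dersimonian_laird_tau2(effects: Sequence[EffectSize]) -> float:
    """Moment (DerSimonian-Laird) estimate of tau^2; the REML starting value."""
    if len(effects) < 2:
        raise ValidationError("tau2 estimation needs at least 2 studies")
    y, v = _arrays(effects)
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (len(effects) - 1)) / denom)


def reml_tau2(
    effects: Sequence[EffectSize],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> float:
    """REML estimate of the between-study variance tau^2.

    Fisher scoring on the restricted likelihood, started at the
    DerSimonian-Laird moment estimate, with tau^2 clamped to >= 0 after every
    step; convergence when successive iterates differ by less than ``tol``.
    The sign of the score brackets the maximizer as the iteration proceeds;
    when a scoring step oscillates or leaves the bracket (undamped Fisher
    steps overshoot near flat optima) the iterate falls back to bisection of
    the bracket, which guarantees convergence.
    """
    if len(effects) < 2:
        raise ValidationError("REML needs at least 2 studies")
    y, v = _arrays(effects)

    tau2 = dersimonian_laird_tau2(effects)
    lo, hi = 0.0, None  # score-sign bracket around the maximizer
    prev_score = None
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw = np.sum(w)
        mu = np.sum(w * y) / sw
        resid = y - mu
        # score and expected information of the restricted likelihood,
        # specialised to an intercept-only model
        tr_p = sw - np.sum(w**2) / sw
        score = 0.5 * (np.sum((w * resid) ** 2) - tr_p)
        tr_p2 = float(np.sum(w**2) - 2.0 * np.sum(w**3) / sw + (np.sum(w**2) / sw) ** 2)
        info = 0.5 * tr_p2
        if info <= 0:
            break
        if score > 0:
            lo = max(lo, tau2)
        else:
            hi = tau2 if hi is None else min(hi, tau2)
        new = max(0.0, tau2 + score / info)
        oscillating = prev_score is not None and score * prev_score < 0
        if hi is not None and (oscillating or not lo <= new <= hi):
            new = 0.5 * (lo + hi)
        prev_score = score
        if abs(new - tau2) < tol:
            return float(new)
        tau2 = new
    # boundary solutions oscillate harmlessly at 0; accept them
    if tau2 <= tol:
        return 0.0
    raise ConvergenceError(
        f"REML did not converge within {max_iter} iterations (last tau2={tau2:.3e})",
        last_value=float(tau2),
    )


def i2_band(i2: float) -> str:
    """Qualitative heterogeneity band: low (< 25), moderate (25-75 inclusive), high (> 75)."""
    if not 0.0 <= i2 <= 100.0:
        raise ValidationError(f"I^2 must lie in [0, 100], got {i2}")
    if i2 < 25.0:
        return "low"
    if i2 <= 75.0:
        return "moderate"
    return "high"


def heterogeneity_stats(effects: Sequence[EffectSize]) -> tuple[float, int, float, str]:
    """Cochran's Q, its df, Higgins' I^2 (percent) and the qualitative band.

    Q uses fixed-effect weights 1/v_i around the fixed-effect mean;
    I^2 = max(0, (Q - df)/Q) * 100.
    """
    if len(effects) < 2:
        raise ValidationError("heterogeneity statistics need at least 2 studies")
    y, v = _arrays(effects)
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    df = len(effects) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, i2, i2_band(i2)


def pool_random_effects(
    effects: Sequence[EffectSize], tau2: float, ci_method: str = "wald"
) -> MetaResult:
    """Inverse-variance pooling with weights 1/(v_i + tau^2).

    ``ci_method="wald"`` (default) gives the plain normal 95% interval
    mu +/- 1.959964 se.  ``ci_method="knapp-hartung"`` rescales the variance
    of the pooled mean by the weighted residual mean square and uses a
    t(k-1) quantile, which widens small-k intervals and improves coverage.
    """
    if not effects:
        raise ValidationError("no effects to pool")
    if tau2 < 0:
        raise ValidationError(f"tau2 must be >= 0, got {tau2}")
    if ci_method not in ("wald", "knapp-hartung"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    y, v = _arrays(effects)
    w = 1.0 / (v + tau2)
    sw = float(np.sum(w))
    mu = float(np.sum(w * y) / sw)
    se_mu = sw**-0.5
    if len(effects) >= 2:
        q, df, i2, band = heterogeneity_stats(effects)
    else:
        q, df, i2, band = 0.0, 0, 0.0, "low"
    if ci_method == "knapp-hartung":
        if len(effects) < 2:
            raise ValidationError("Knapp-Hartung needs at least 2 studies")
        from scipy.stats import t as t_dist

        se_mu = math.sqrt(float(np.sum(w * (y - mu) ** 2)) / (len(effects) - 1) / sw)
        crit = float(t_dist.ppf(0.975, len(effects) - 1))
        return MetaResult(
            mu=mu,
            se_mu=se_mu,
            ci_low=mu - crit * se_mu,
            ci_high=mu + crit * se_mu,
            tau2=float(tau2),
            q=q,
            df=df,
            i2=i2,
            band=band,
            weights=tuple(float(x) for x in w / sw),
        )
    return MetaResult(
        mu=mu,
        se_mu=se_mu,
        ci_low=mu - Z_975 * se_mu,
        ci_high=mu + Z_975 * se_mu,
        tau2=float(tau2),
        q=q,
        df=df,
        i2=i2,
        band=band,
        weights=tuple(float(x) for x in w / sw),
    )


def random_effects_meta(effects: Sequence[EffectSize]) -> MetaResult:
    """REML tau^2 followed by inverse-variance pooling (the default analysis)."""
    tau2 = reml_tau2(effects) if len(effects) >= 2 else 0.0
    return pool_random_effects(effects, tau2)


@dataclass(frozen=True)
class ForestRow:
    label: str
    md: float
    ci_low: float
    ci_high: float
    weight_percent: float
    is_summary: bool = False


def forest_data(effects: Sequence[EffectSize], result: MetaResult) -> list[ForestRow]:
    """Rows for a forest plot: one per study (Wald CI from its own SE) plus a summary."""
    if len(effects) != len(result.weights):
        raise ValidationError("result weights do not match the effects")
    rows = [
        ForestRow(
            label=e.study_id,
            md=e.md,
            ci_low=e.md - Z_975 * e.se,
            ci_high=e.md + Z_975 * e.se,
            weight_percent=100.0 * w,
        )
        for e, w in zip(effects, result.weights)
    ]
    rows.append(
        ForestRow(
            label="Pooled (random effects)",
            md=result.mu,
            ci_low=result.ci_low,
            ci_high=result.ci_high,
            weight_percent=100.0,
            is_summary=True,
        )
    )
    return rows


def render_forest(
    rows: Sequence[ForestRow],
    path: str | PathLike,
    title: str | None = None,
    result: MetaResult | None = None,
) -> None:
    """Draw a forest plot (marker + CI per study, diamond for the pooled row).

    The file format follows the extension (.svg or .png).  When ``result`` is
    given, tau^2 and I^2 are annotated under the plot.
    """
    if not rows:
        raise ValidationError("no rows to plot")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(rows)
    fig, ax = plt.subplots(figsize=(7.5, 1.0 + 0.45 * n))
    ypos = list(range(n, 0, -1))
    for y, r in zip(ypos, rows):
        if r.is_summary:
            half = 0.28
            ax.fill(
                [r.ci_low, r.md, r.ci_high, r.md],
                [y, y + half, y, y - half],
                color="#2b6ca3",
                alpha=0.9,
            )
        else:
            ax.plot([r.ci_low, r.ci_high], [y, y], color="black", lw=1.2)
            ax.plot(
                r.md, y, marker="s", color="#2b6ca3",
                markersize=4 + 8 * r.weight_percent / 100.0,
            )
        ax.annotate(
            f"{r.md:.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}]  {r.weight_percent:.1f}%",
            xy=(1.02, y), xycoords=("axes fraction", "data"),
            va="center", fontsize=8,
        )
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels([r.label for r in rows], fontsize=9)
    ax.set_xlabel("Mean difference (MCID units)")
    if result is not None:
        ax.annotate(
            f"$\\tau^2$ = {result.tau2:.3f}   $I^2$ = {result.i2:.1f}% ({result.band})   "
            f"Q = {result.q:.2f} (df = {result.df})",
            xy=(0.0, -0.12), xycoords="axes fraction", fontsize=8, va="top",
        )
    if title:
        ax.set_title(title)
    ax.spines[["top", "right", "left"]].set_visible(False)
    fig.subplots_adjust(right=0.68)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
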