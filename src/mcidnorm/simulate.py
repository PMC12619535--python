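"""Synthetic multi-study two-arm PROM datasets with known ground truth.

The generator emulates the kind of data the pipeline is built for: a handful
of two-arm hip-arthroscopy studies, each reporting one to three instruments
drawn with literature-frequency probabilities, arm summaries on the raw
instrument scale, and a true treatment effect expressed in MCID units with
between-study heterogeneity.  Arm summaries are drawn analytically from their
sampling distributions (mean from a normal, SD from a scaled chi) rather than
by simulating patient-level scores, since the pipeline consumes summaries
only.

Defaults mirror the demonstration dataset shipped with the package: seven
studies, per-arm sizes 20-180, raw-scale SDs 9-19 points, and the six
MCID-bearing instruments with their observed reporting frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .audit import AuditLog
from .errors import ConfigurationError
from .meta import EffectSize
from .normalize import MeasurementRecord, Timepoint
from .registry import Orientation, PromRegistry

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "simulate_effects"]

#: Reporting probabilities for the six MCID-bearing instruments, proportional
#: to their mention counts in the packaged frequency table (71/35/33/27/27/7).
DEFAULT_PROM_POOL: dict[str, float] = {
    "mHHS": 0.355,
    "iHOT-12": 0.175,
    "HOS-SSS": 0.165,
    "NAHS": 0.135,
    "HOS-ADL": 0.135,
    "iHOT-33": 0.035,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the generator; defaults emulate the demo dataset."""

    k: int = 7
    delta: float = 0.4  # true pooled effect, MCID units (arm 1 minus arm 2)
    tau: float = 0.2  # between-study SD of true effects, MCID units
    n_range: tuple[int, int] = (20, 180)
    prom_pool: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROM_POOL))
    proms_per_study_range: tuple[int, int] = (1, 3)
    sd_points_range: tuple[float, float] = (9.0, 19.0)
    missing_sd_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.tau < 0:
            raise ConfigurationError("tau must be >= 0")
        if not self.n_range[0] <= self.n_range[1] or self.n_range[0] < 2:
            raise ConfigurationError("n_range must be ordered with lower bound >= 2")
        lo, hi = self.proms_per_study_range
        if not 1 <= lo <= hi <= len(self.prom_pool):
            raise ConfigurationError("proms_per_study_range must fit within the PROM pool")
        if not 0 < self.sd_points_range[0] <= self.sd_points_range[1]:
            raise ConfigurationError("sd_points_range must be ordered and positive")
        if not 0.0 <= self.missing_sd_prob <= 1.0:
            raise ConfigurationError("missing_sd_prob must be a probability")
        total = sum(self.prom_pool.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"prom_pool probabilities must sum to 1, got {total}")


@dataclass(frozen=True)
class GroundTruth:
    """Answer key for a simulated dataset."""

    delta: float
    tau: float
    theta: tuple[float, ...]  # true per-study effects, MCID units
    retained_prom: tuple[str, ...]  # expected prioritization choice per study
    truncated_arms: int = 0


def _study_rngs(seed: int, k: int) -> list[np.random.Generator]:
    # one named stream per study: output for study i is stable when k changes
    children = np.random.SeedSequence(seed).spawn(k)
    return [np.random.default_rng(c) for c in children]


def simulate_dataset(
    config: SimulationConfig,
    registry: PromRegistry,
    audit: AuditLog | None = None,
) -> tuple[list[MeasurementRecord], GroundTruth]:
    """Generate postoperative two-arm summaries with a known effect in MCID units.

    Per study i a true effect theta_i = delta + tau * z_i is drawn; every
    instrument the study reports carries that same effect on its own raw scale
    (difference of arm means = theta_i * MCID).  Observed arm means get
    sampling noise sd^2/n; observed SDs are drawn from the chi sampling
    distribution of a normal-sample SD.  Means falling outside the instrument
    scale are truncated to the bounds and flagged; a run truncating more than
    1% of arm summaries raises, since silent truncation would bias recovery
    studies.
    """
    proms = list(config.prom_pool)
    probs = np.array([config.prom_pool[p] for p in proms], dtype=float)
    for p in proms:
        if not registry.lookup(p).normalizable:
            raise ConfigurationError(f"PROM pool entry {p} has no MCID in the registry")

    # rank within the pool follows pool order (caller supplies frequency order)
    pool_rank = {p: i for i, p in enumerate(proms)}

    records: list[MeasurementRecord] = []
    theta: list[float] = []
    retained: list[str] = []
    truncated = 0
    total_arm_summaries = 0

    for i, rng in enumerate(_study_rngs(config.seed, config.k)):
        study_id = f"sim-{i + 1:03d}"
        th = config.delta + config.tau * rng.standard_normal()
        theta.append(th)
        n1, n2 = rng.integers(config.n_range[0], config.n_range[1] + 1, size=2)
        m = int(rng.integers(config.proms_per_study_range[0], config.proms_per_study_range[1] + 1))
        chosen = list(rng.choice(proms, size=m, replace=False, p=probs))
        retained.append(min(chosen, key=pool_rank.__getitem__))

        for prom_name in chosen:
            prom = registry.lookup(prom_name)
            mcid = prom.mcid
            sigma = float(rng.uniform(*config.sd_points_range))
            effect_points = th * mcid
            if prom.orientation is Orientation.higher_worse:
                effect_points = -effect_points
            # place the worse arm so that both true means sit inside the scale
            span = prom.scale_max - prom.scale_min
            margin = 3.0 * sigma / math.sqrt(min(n1, n2))
            lo = prom.scale_min + margin + max(0.0, -effect_points)
            hi = prom.scale_max - margin - max(0.0, effect_points)
            if lo >= hi:
                raise ConfigurationError(
                    f"{prom_name}: effect {effect_points:.1f} points cannot fit the "
                    f"scale [{prom.scale_min}, {prom.scale_max}]"
                )
            # realistic postoperative region: upper part of the feasible band
            mu2 = float(rng.uniform(max(lo, lo + 0.5 * (hi - lo)), hi))
            mu1 = mu2 + effect_points
            for arm_id, mu, n in (("1", mu1, int(n1)), ("2", mu2, int(n2))):
                total_arm_summaries += 1
                mean_obs = float(mu + sigma / math.sqrt(n) * rng.standard_normal())
                if not prom.scale_min <= mean_obs <= prom.scale_max:
                    mean_obs = min(max(mean_obs, prom.scale_min), prom.scale_max)
                    truncated += 1
                    if audit is not None:
                        audit.record(
                            "simulate",
                            "truncated",
                            "observed mean truncated to scale bounds",
                            study_id=study_id,
                            arm_id=arm_id,
                            prom=prom_name,
                        )
                sd_obs = float(sigma * math.sqrt(rng.chisquare(n - 1) / (n - 1)))
                if rng.uniform() < config.missing_sd_prob:
                    rec = MeasurementRecord(
                        study_id=study_id, arm_id=arm_id, prom=prom_name,
                        timepoint=Timepoint.post, n=n, mean=round(mean_obs, 1),
                        sd=None,
                        range_min=round(mean_obs - 2 * sd_obs, 1),
                        range_max=round(mean_obs + 2 * sd_obs, 1),
                    )
                else:
                    rec = MeasurementRecord(
                        study_id=study_id, arm_id=arm_id, prom=prom_name,
                        timepoint=Timepoint.post, n=n, mean=round(mean_obs, 1),
                        sd=round(sd_obs, 1),
                    )
                records.append(rec)

    if total_arm_summaries and truncated / total_arm_summaries > 0.01:
        raise ConfigurationError(
            f"{truncated}/{total_arm_summaries} arm summaries truncated (> 1%); "
            "widen the scale margins or shrink the effect"
        )
    truth = GroundTruth(
        delta=config.delta,
        tau=config.tau,
        theta=tuple(theta),
        retained_prom=tuple(retained),
        truncated_arms=truncated,
    )
    return records, truth


def simulate_effects(
    k: int,
    delta: float,
    tau: float,
    rng: np.random.Generator,
    n_range: tuple[int, int] = (40, 200),
    sd_mcid_range: tuple[float, float] = (0.9, 1.7),
) -> tuple[list[EffectSize], np.ndarray]:
    """Lightweight effect-level simulation for meta-analysis calibration studies.

    Draws true effects theta_i ~ N(delta, tau^2), per-arm sizes and MCID-unit
    SDs in the given ranges, and observed effects y_i ~ N(theta_i, v_i) with
    v_i the known two-arm sampling variance — the random-effects model's own
    data-generating process, as is standard for estimator calibration studies.
    (The full generator, :func:`simulate_dataset`, additionally draws observed
    SDs from their chi sampling law.)  Returns the effects and the vector of
    true theta_i.
    """
    theta = delta + tau * rng.standard_normal(k)
    effects = []
    for i in range(k):
        n1, n2 = rng.integers(n_range[0], n_range[1] + 1, size=2)
        s1, s2 = rng.uniform(*sd_mcid_range, size=2)
        v = s1**2 / n1 + s2**2 / n2
        y = float(theta[i] + math.sqrt(v) * rng.standard_normal())
        effects.append(EffectSize(study_id=f"sim-{i + 1:03d}", md=y, variance=v))
    return effects, theta
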