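"""Synthetic paired-cohort generator with known persistence and drift.

Each subject carries a *persistent* community component shared by both
collections and a timepoint-specific *transient* component.  Both timepoint
compositions are mixtures

    composition_t = w * persistent + (1 - w) * transient_t,     t = 1, 2

so the shared relative abundance measured by the pipeline equals the mixture
weight ``w`` at either timepoint (up to multinomial detection noise), and the
statistic the pipeline averages, ``(abund_1 + abund_2)/2``, is an unbiased
probe of ``w``.

``w`` declines linearly with the collection interval: it is drawn from a Beta
distribution whose *mean* is exactly ``(intercept + slope * months)/100`` and
whose SD is the configured noise level, capped just below the feasibility
bound ``sqrt(mu*(1-mu))`` near the boundaries.  Using a Beta variate rather
than a clamped Gaussian keeps the regression function exactly linear in
months while respecting the [0, 1] support, so the configured slope is the
estimand of the pipeline's own decay-model estimator — the property the
parameter-recovery suite exercises.

Counts are multinomial draws at per-sample depths; richness, depth, interval
and covariate distributions default to a 63-subject urine cohort (see
:class:`SyntheticConfig`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import (
    CATHETER,
    MSU,
    OtuCountTable,
    PairedCohort,
    SampleRecord,
    SubjectRecord,
    build_paired_cohort,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a paired urine cohort.

    Defaults emulate a 63-subject cohort: per-subject taxon pools of
    ~152 +/- 128 OTUs (log-normal, truncated >= 5), long-tailed Dirichlet
    baseline compositions, ~27% of taxa persistent between collections,
    sequencing depth ~11,524 +/- 8,669 reads (log-normal, truncated >= 1000
    so rarefaction at depth 1000 is always feasible), collection intervals
    uniform on 3-40 months, and a shared-abundance decline of -0.66% per
    month from an intercept of 99.78% with 15% between-subject noise.
    """

    n_subjects: int = 63
    global_pool_size: int = 2000
    subject_pool_mean: float = 152.0
    subject_pool_sd: float = 128.0
    subject_pool_min: int = 5
    abundance_shape: float = 0.3
    persistence_prob: float = 0.27
    shared_abund_intercept_pct: float = 99.78
    shared_abund_slope_pct_per_month: float = -0.66
    shared_abund_noise_sd_pct: float = 15.0
    interval_min_months: float = 3.0
    interval_max_months: float = 40.0
    depth_mean: float = 11524.0
    depth_sd: float = 8669.0
    depth_min: int = 1000
    age_mean: float = 61.1
    age_sd: float = 14.8
    age_min: float = 18.0
    p_male: float = 43 / 63
    p_cancer: float = 28 / 63
    p_stones: float = 22 / 63
    p_catheter_first: float = 26 / 63
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("persistence_prob", "p_male", "p_cancer", "p_stones", "p_catheter_first"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.subject_pool_min < 1:
            raise ConfigError("subject_pool_min must be >= 1")
        if self.global_pool_size < 2 * self.subject_pool_min:
            raise ConfigError(
                "global pool too small for even the minimum subject pool: "
                f"{self.global_pool_size} < 2*{self.subject_pool_min}"
            )
        if self.interval_min_months <= 0 or self.interval_max_months < self.interval_min_months:
            raise ConfigError("invalid interval range")
        if self.depth_min < 1:
            raise ConfigError("depth_min must be >= 1")


@dataclass(frozen=True)
class SubjectTruth:
    subject_id: str
    interval_months: float
    w: float
    pool_size: int
    n_persistent: int
    persistent_otus: tuple[str, ...]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated cohort, for parameter-recovery checks."""

    subjects: tuple[SubjectTruth, ...]
    intercept_pct: float
    slope_pct_per_month: float
    config: SyntheticConfig

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    subject_id=t.subject_id,
                    interval_months=t.interval_months,
                    true_w=t.w,
                    pool_size=t.pool_size,
                    n_persistent=t.n_persistent,
                )
                for t in self.subjects
            ]
        )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _truncated_lognormal(
    rng: np.random.Generator, mean: float, sd: float, minimum: float
) -> float:
    mu, sigma = _lognormal_params(mean, sd)
    for _ in range(1000):
        value = rng.lognormal(mu, sigma)
        if value >= minimum:
            return float(value)
    return float(minimum)  # pathological config; fall back to the bound


def _beta_weight(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw with the given mean and (feasibility-capped) SD."""
    eps = 1e-6
    mu = float(np.clip(mean, eps, 1.0 - eps))
    if sd <= 0:
        return mu
    cap = 0.95 * np.sqrt(mu * (1.0 - mu))
    s = min(sd, cap)
    nu = mu * (1.0 - mu) / (s * s) - 1.0
    return float(rng.beta(mu * nu, (1.0 - mu) * nu))


def generate_cohort(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[PairedCohort, SyntheticTruth]:
    """Generate one paired cohort; deterministic given the seed.

    ``seed`` overrides ``config.seed`` when given.  Returns the assembled
    :class:`PairedCohort` (count table + metadata) and the generative truth.
    """
    config = config or SyntheticConfig()
    used_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    width = len(str(config.global_pool_size))
    pool = np.array([f"OTU{i:0{width}d}" for i in range(config.global_pool_size)])

    samples: list[SampleRecord] = []
    subjects: list[SubjectRecord] = []
    truths: list[SubjectTruth] = []
    count_rows: dict[str, dict[str, int]] = {}

    n_digits = len(str(config.n_subjects))
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:0{n_digits}d}"
        pool_size = int(round(_truncated_lognormal(
            rng, config.subject_pool_mean, config.subject_pool_sd, config.subject_pool_min
        )))
        pool_size = max(pool_size, config.subject_pool_min)
        if 2 * pool_size > config.global_pool_size:
            logger.warning(
                "subject %s: pool draw %d infeasible, truncating to %d",
                subject_id, pool_size, config.global_pool_size // 2,
            )
            pool_size = config.global_pool_size // 2

        if config.persistence_prob >= 1.0:
            n_pers = pool_size
        elif config.persistence_prob <= 0.0:
            n_pers = 0
        else:
            n_pers = max(1, int(rng.binomial(pool_size, config.persistence_prob)))
        n_trans = pool_size - n_pers
        needed = n_pers + 2 * n_trans
        if needed > config.global_pool_size:
            raise ConfigError(
                f"global pool of {config.global_pool_size} cannot supply "
                f"{needed} distinct taxa for subject {subject_id}"
            )
        chosen = rng.choice(config.global_pool_size, size=needed, replace=False)
        pers_ids = pool[chosen[:n_pers]]
        trans_ids = (
            pool[chosen[n_pers:n_pers + n_trans]],
            pool[chosen[n_pers + n_trans:]],
        )

        interval = float(rng.uniform(config.interval_min_months, config.interval_max_months))
        mean_w = (
            config.shared_abund_intercept_pct
            + config.shared_abund_slope_pct_per_month * interval
        ) / 100.0
        w = _beta_weight(rng, mean_w, config.shared_abund_noise_sd_pct / 100.0)

        pers_profile = (
            rng.dirichlet(np.full(n_pers, config.abundance_shape)) if n_pers else None
        )
        for timepoint in (1, 2):
            if n_trans:
                trans_profile = rng.dirichlet(np.full(n_trans, config.abundance_shape))
            else:
                trans_profile = None
            if pers_profile is None:
                ids = trans_ids[timepoint - 1]
                probs = trans_profile
            elif trans_profile is None:
                ids, probs = pers_ids, pers_profile
            else:
                ids = np.concatenate([pers_ids, trans_ids[timepoint - 1]])
                probs = np.concatenate([w * pers_profile, (1.0 - w) * trans_profile])
            depth = int(round(_truncated_lognormal(
                rng, config.depth_mean, config.depth_sd, config.depth_min
            )))
            counts = rng.multinomial(depth, probs / probs.sum())
            sample_id = f"{subject_id}T{timepoint}"
            count_rows[sample_id] = {
                otu: int(c) for otu, c in zip(ids, counts) if c > 0
            }
            method = MSU
            if timepoint == 1 and rng.random() < config.p_catheter_first:
                method = CATHETER
            samples.append(
                SampleRecord(
                    sample_id=sample_id,
                    subject_id=subject_id,
                    timepoint=timepoint,
                    collection_method=method,
                )
            )

        age = float(rng.normal(config.age_mean, config.age_sd))
        while age < config.age_min:
            age = float(rng.normal(config.age_mean, config.age_sd))
        subjects.append(
            SubjectRecord(
                subject_id=subject_id,
                sex="M" if rng.random() < config.p_male else "F",
                age=round(age, 1),
                cancer=bool(rng.random() < config.p_cancer),
                stones=bool(rng.random() < config.p_stones),
                interval_months=round(interval, 1),
            )
        )
        truths.append(
            SubjectTruth(
                subject_id=subject_id,
                interval_months=round(interval, 1),
                w=w,
                pool_size=pool_size,
                n_persistent=n_pers,
                persistent_otus=tuple(sorted(pers_ids)),
            )
        )

    data = (
        pd.DataFrame.from_dict(count_rows, orient="index")
        .fillna(0)
        .astype(np.int64)
    )
    table = OtuCountTable(data)
    cohort = build_paired_cohort(table, samples, subjects)
    truth = SyntheticTruth(
        subjects=tuple(truths),
        intercept_pct=config.shared_abund_intercept_pct,
        slope_pct_per_month=config.shared_abund_slope_pct_per_month,
        config=replace(config, seed=used_seed),
    )
    return cohort, truth


def inject_singletons(
    table: OtuCountTable, rate: float, seed: int | None = None
) -> tuple[OtuCountTable, int]:
    """Add artefactual global-singleton OTUs (total count 1 each).

    The number injected is Poisson with mean ``rate * n_samples``; each
    singleton lands in a uniformly chosen sample under a fresh OTU id.
    Returns the augmented table and the number injected.
    """
    if rate < 0:
        raise ConfigError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    k = int(rng.poisson(rate * table.n_samples)) if rate > 0 else 0
    if k == 0 or table.n_samples == 0:
        return table, 0
    data = table.data.copy()
    positions = rng.integers(0, table.n_samples, size=k)
    new_cols = {}
    for j in range(k):
        col = np.zeros(table.n_samples, dtype=np.int64)
        col[positions[j]] = 1
        new_cols[f"SINGLETON{j:06d}"] = col
    augmented = pd.concat(
        [data, pd.DataFrame(new_cols, index=data.index)], axis=1
    )
    return OtuCountTable(augmented, taxonomy=table.taxonomy), k


def truth_report(
    truth: SyntheticTruth,
    overlap_summary: pd.DataFrame | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Flat per-subject truth table, optionally joined to pipeline output.

    When an overlap summary is given its measured fields are merged on
    ``subject_id`` so recovered-vs-true scatter plots are one call away.
    """
    frame = truth.frame()
    if overlap_summary is not None:
        frame = frame.merge(
            overlap_summary.drop(columns=["interval_months"], errors="ignore"),
            on="subject_id",
            how="left",
        )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
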