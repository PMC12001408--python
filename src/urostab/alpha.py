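"""Alpha diversity: Chao1, Shannon, and iterated rarefaction.

Rarefaction draws reads without replacement (multivariate hypergeometric) to a
common depth, repeats the draw many times, and averages the index per sample —
the standard way to compare richness/evenness across unequal sequencing
depths.  Subjects with any sample below the depth are excluded as a pair, so
paired comparisons stay balanced.

Each sample gets its own RNG stream derived from ``(seed, sha256(sample_id))``,
so results are bit-reproducible and independent of cohort ordering.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import PairedCohort
from .errors import EmptyCohortError, InsufficientDepthError, UndefinedStatisticError


@dataclass(frozen=True)
class RarefactionConfig:
    """Depth/iteration settings for iterated rarefaction.

    Defaults (depth 1000, 1000 iterations) match common practice for urine
    16S data, where sequencing depth is highly variable.
    """

    depth: int = 1000
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class AlphaResult:
    """Per-sample iteration means/SDs of Chao1 and Shannon.

    ``per_sample`` columns: sample_id, subject_id, chao1_mean, chao1_sd,
    shannon_mean, shannon_sd, observed_richness_mean, n_iterations.
    ``excluded_subjects``: subjects dropped because a sample fell below depth.
    """

    per_sample: pd.DataFrame
    excluded_subjects: tuple[str, ...]
    config: RarefactionConfig


def chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from one count vector.

    Bias-corrected form (default): ``S_obs + F1*(F1-1) / (2*(F2+1))`` where
    F1/F2 count OTUs seen exactly once/twice; finite even when F2 = 0.  The
    classic form ``S_obs + F1^2/(2*F2)`` is available for sensitivity runs.
    """
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    if s_obs == 0:
        warnings.warn("Chao1 of an empty sample is 0", stacklevel=2)
        return 0.0
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0  # classic form's F2=0 convention
    return s_obs + f1 * f1 / (2.0 * f2)


def shannon(values: np.ndarray, base: float | None = None) -> float:
    """Shannon diversity index, in nats by default.

    Accepts counts or proportions; values are renormalized internally.
    """
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total <= 0:
        raise UndefinedStatisticError("Shannon index is undefined for an all-zero vector")
    p = values[values > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def rarefy_once(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """One without-replacement subsample of ``depth`` reads."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if total < depth:
        raise InsufficientDepthError(f"sample total {total} < rarefaction depth {depth}")
    if total == depth:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    digest = hashlib.sha256(sample_id.encode("utf-8")).digest()
    stream = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=[seed, stream]))


def _chao1_rows(matrix: np.ndarray) -> np.ndarray:
    s_obs = (matrix > 0).sum(axis=1)
    f1 = (matrix == 1).sum(axis=1)
    f2 = (matrix == 2).sum(axis=1)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _shannon_rows(matrix: np.ndarray) -> np.ndarray:
    totals = matrix.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = matrix / totals
        terms = np.where(matrix > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=1)


def iterated_alpha(cohort: PairedCohort, config: RarefactionConfig) -> AlphaResult:
    """Iterated-rarefaction alpha diversity for every retained sample.

    Applies the pair-level exclusion rule (drop a subject when any of its
    samples has fewer reads than ``config.depth``), then for each retained
    sample draws ``config.iterations`` rarefied vectors and summarizes Chao1
    and Shannon across iterations.  Deterministic given ``config.seed``.
    """
    totals = cohort.table.total_reads
    excluded = sorted(
        {
            s.subject_id
            for s in cohort.samples
            if int(totals.loc[s.sample_id]) < config.depth
        }
    )
    retained = [s for s in cohort.samples if s.subject_id not in excluded]
    if not retained:
        raise EmptyCohortError(
            f"no subject has all samples at >= {config.depth} reads"
        )
    rows = []
    for sample in retained:
        counts = cohort.table.sample_counts(sample.sample_id)
        rng = _sample_rng(config.seed, sample.sample_id)
        if int(counts.sum()) == config.depth:
            draws = np.tile(counts, (config.iterations, 1))
        else:
            draws = rng.multivariate_hypergeometric(
                counts, config.depth, size=config.iterations
            )
        c = _chao1_rows(draws)
        h = _shannon_rows(draws)
        rows.append(
            dict(
                sample_id=sample.sample_id,
                subject_id=sample.subject_id,
                chao1_mean=float(c.mean()),
                chao1_sd=float(c.std(ddof=1)) if config.iterations > 1 else 0.0,
                shannon_mean=float(h.mean()),
                shannon_sd=float(h.std(ddof=1)) if config.iterations > 1 else 0.0,
                observed_richness_mean=float((draws > 0).sum(axis=1).mean()),
                n_iterations=config.iterations,
            )
        )
    per_sample = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
    return AlphaResult(per_sample=per_sample, excluded_subjects=tuple(excluded), config=config)
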