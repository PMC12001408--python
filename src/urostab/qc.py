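"""Sample-level quality gate and normalization.

The fixed pipeline order is: Good's-coverage pair exclusion (computed on raw,
unfiltered counts) -> global-singleton OTU removal -> per-sample
relative-abundance normalization.  Good's coverage uses *sample-level*
singletons (OTUs with count exactly 1 within one sample); the OTU filter uses
*global* singletons (OTUs with summed count exactly 1 across the whole
dataset).  The two notions are deliberately named apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import OtuCountTable, PairedCohort
from .errors import EmptyCohortError, NormalizationError, UndefinedStatisticError

logger = logging.getLogger(__name__)

#: coverage gate used by the analysis (percent scale, strict "<")
DEFAULT_COVERAGE_THRESHOLD = 85.0


@dataclass(frozen=True)
class CoverageReport:
    """Per-sample Good's coverage plus the list of excluded subjects.

    ``per_sample`` columns: sample_id, subject_id, total_reads,
    sample_singletons, goods_coverage_pct.  ``excluded_subjects`` is a list of
    (subject_id, reason) tuples.
    """

    per_sample: pd.DataFrame
    excluded_subjects: tuple[tuple[str, str], ...]
    threshold: float


def goods_coverage(counts: np.ndarray) -> float:
    """Good's coverage of one sample, on the percent scale.

    ``100 * (1 - F1/N)`` where ``F1`` is the number of OTUs observed exactly
    once in the sample and ``N`` the sample's total reads.  A sample with no
    singletons has coverage 100.
    """
    counts = np.asarray(counts)
    n = int(counts.sum())
    if n <= 0:
        raise UndefinedStatisticError("Good's coverage is undefined for an all-zero sample")
    f1 = int((counts == 1).sum())
    return 100.0 * (1.0 - f1 / n)


def coverage_report(cohort: PairedCohort, threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> CoverageReport:
    """Compute per-sample coverage and flag subjects failing the gate."""
    rows = []
    failing: dict[str, list[str]] = {}
    for sample in cohort.samples:
        counts = cohort.table.sample_counts(sample.sample_id)
        cov = goods_coverage(counts)
        rows.append(
            dict(
                sample_id=sample.sample_id,
                subject_id=sample.subject_id,
                total_reads=int(counts.sum()),
                sample_singletons=int((counts == 1).sum()),
                goods_coverage_pct=cov,
            )
        )
        if cov < threshold:
            failing.setdefault(sample.subject_id, []).append(
                f"{sample.sample_id}: coverage {cov:.2f} < {threshold:g}"
            )
    excluded = tuple(
        (subj, "; ".join(reasons)) for subj, reasons in sorted(failing.items())
    )
    return CoverageReport(
        per_sample=pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True),
        excluded_subjects=excluded,
        threshold=threshold,
    )


def exclude_low_coverage_pairs(
    cohort: PairedCohort, threshold: float = DEFAULT_COVERAGE_THRESHOLD
) -> tuple[PairedCohort, CoverageReport]:
    """Drop both samples of every subject with any sample below the gate.

    Coverage is computed on the raw table, before any OTU filtering.  Raises
    :class:`EmptyCohortError` when nothing survives.
    """
    if cohort.n_subjects == 0:
        raise EmptyCohortError("cannot apply coverage gate to an empty cohort")
    report = coverage_report(cohort, threshold)
    excluded_ids = {subj for subj, _ in report.excluded_subjects}
    keep = [s for s in cohort.subject_ids if s not in excluded_ids]
    if not keep:
        raise EmptyCohortError(
            f"all {cohort.n_subjects} subjects fall below coverage {threshold:g}"
        )
    if excluded_ids:
        logger.info(
            "coverage gate at %g%%: excluded %d of %d subjects (%s)",
            threshold, len(excluded_ids), cohort.n_subjects, ", ".join(sorted(excluded_ids)),
        )
    return cohort.subset_subjects(keep), report


def remove_global_singletons(table: OtuCountTable) -> OtuCountTable:
    """Drop every OTU whose summed count across all samples is exactly 1."""
    totals = table.data.sum(axis=0)
    keep = totals.index[totals != 1]
    dropped = table.n_otus - len(keep)
    if dropped:
        logger.info("removed %d global-singleton OTUs (of %d)", dropped, table.n_otus)
    return table.subset_otus(keep)


@dataclass(frozen=True)
class RelAbundanceTable:
    """Per-sample relative abundances; each row sums to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1)
        if self.data.shape[0] and not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums.index[~np.isclose(sums, 1.0, atol=1e-9)][0]
            raise NormalizationError(f"sample {bad!r} proportions do not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample_proportions(self, sample_id: str) -> pd.Series:
        return self.data.loc[sample_id]


def to_relative_abundance(table: OtuCountTable) -> RelAbundanceTable:
    """Divide each sample's counts by its total; rejects zero-read samples."""
    totals = table.total_reads
    zero = totals.index[totals == 0]
    if len(zero):
        raise NormalizationError(
            f"cannot normalize zero-read sample(s): {sorted(zero)}"
        )
    return RelAbundanceTable(table.data.div(totals, axis=0))


def run_qc(
    cohort: PairedCohort, threshold: float = DEFAULT_COVERAGE_THRESHOLD
) -> tuple[PairedCohort, CoverageReport, RelAbundanceTable]:
    """Full QC chain: coverage gate -> global-singleton removal -> normalize.

    Returns the filtered cohort (whose table has singletons removed), the
    coverage report, and the relative-abundance table of the filtered cohort.
    """
    gated, report = exclude_low_coverage_pairs(cohort, threshold)
    filtered = gated.with_table(remove_global_singletons(gated.table))
    rel = to_relative_abundance(filtered.table)
    return filtered, report, rel
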