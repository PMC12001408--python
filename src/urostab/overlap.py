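"""Per-subject overlap of OTUs between two urine collections.

For each subject the two samples are compared on a common OTU index:

* ``n_shared`` — OTUs detected (> 0) at both timepoints;
* ``frac_shared`` — ``n_shared`` divided by the mean of the two per-sample
  richness values (denominator configurable: ``mean``, ``union`` or ``min``);
* ``shared_abund_t1`` / ``shared_abund_t2`` — summed relative abundance of the
  shared OTUs within each sample;
* ``shared_abund_mean`` — their average, the statistic whose decline with
  collection interval quantifies community drift.

Also provided: a sex-stratified prevalence table of taxa detected at both
timepoints, and a diagnostic for dominant-but-discordant OTUs (high abundance
in one sample, absent in the other), which explain the lowest-overlap pairs.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import PairedCohort
from .errors import AlignmentError, EmptyCohortError, MetadataError
from .qc import RelAbundanceTable, to_relative_abundance

OVERLAP_FIELDS = (
    "n_otus_t1", "n_otus_t2", "n_shared", "frac_shared",
    "shared_abund_t1", "shared_abund_t2", "shared_abund_mean",
)


def subject_overlap(
    t1: pd.Series, t2: pd.Series, denominator: str = "mean"
) -> dict[str, float]:
    """Overlap statistics for one subject's pair of relative-abundance vectors.

    Both vectors must be indexed by the same OTU ids and sum to 1.  Presence
    is strictly ``> 0``.
    """
    if not t1.index.equals(t2.index):
        if set(t1.index) == set(t2.index):
            t2 = t2.reindex(t1.index)
        else:
            raise AlignmentError("paired vectors do not share a common OTU index")
    p1 = t1.to_numpy(dtype=float)
    p2 = t2.to_numpy(dtype=float)
    present1 = p1 > 0
    present2 = p2 > 0
    shared = present1 & present2
    n1, n2, ns = int(present1.sum()), int(present2.sum()), int(shared.sum())
    if denominator == "mean":
        denom = (n1 + n2) / 2.0
    elif denominator == "union":
        denom = float((present1 | present2).sum())
    elif denominator == "min":
        denom = float(min(n1, n2))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    a1 = float(p1[shared].sum())
    a2 = float(p2[shared].sum())
    return dict(
        n_otus_t1=n1,
        n_otus_t2=n2,
        n_shared=ns,
        frac_shared=ns / denom if denom > 0 else 0.0,
        shared_abund_t1=a1,
        shared_abund_t2=a2,
        shared_abund_mean=(a1 + a2) / 2.0,
    )


def _aggregate(df: pd.DataFrame) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for field in OVERLAP_FIELDS:
        col = df[field]
        out[field] = dict(
            mean=float(col.mean()),
            sd=float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            median=float(col.median()),
            iqr=float(col.quantile(0.75) - col.quantile(0.25)),
        )
    return out


def cohort_overlap(
    cohort: PairedCohort,
    rel: RelAbundanceTable | None = None,
    denominator: str = "mean",
) -> tuple[pd.DataFrame, dict]:
    """Per-subject overlap table plus cohort aggregates.

    Call after QC (coverage gate + global-singleton removal).  When ``rel``
    is not given the cohort's table is normalized internally.  Aggregates
    (mean, sd, median, IQR of every overlap field) are reported overall and
    stratified by sex, cancer status and collection-method combination.
    """
    if cohort.n_subjects == 0:
        raise EmptyCohortError("cannot compute overlap on an empty cohort")
    if rel is None:
        rel = to_relative_abundance(cohort.table)
    rows = []
    for subj in cohort.subjects:
        s1, s2 = cohort.sample_pair(subj.subject_id)
        stats = subject_overlap(
            rel.sample_proportions(s1.sample_id),
            rel.sample_proportions(s2.sample_id),
            denominator=denominator,
        )
        rows.append(
            dict(
                subject_id=subj.subject_id,
                sex=subj.sex,
                age=subj.age,
                cancer=subj.cancer,
                stones=subj.stones,
                interval_months=subj.interval_months,
                method_combo=cohort.method_combo(subj.subject_id),
                **stats,
            )
        )
    summary = pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
    aggregates: dict = {"overall": _aggregate(summary), "n_subjects": len(summary)}
    for factor in ("sex", "cancer", "method_combo"):
        aggregates[f"by_{factor}"] = {
            str(level): _aggregate(group)
            for level, group in summary.groupby(factor, sort=True)
        }
    return summary, aggregates


def prevalence_table(
    cohort: PairedCohort,
    rel: RelAbundanceTable | None = None,
    min_prevalence: float = 0.5,
) -> pd.DataFrame:
    """Sex-stratified prevalence of taxa detected at both timepoints.

    An OTU counts as present for a subject only when detected in *both* of
    the subject's samples.  Rows are kept when prevalence reaches
    ``min_prevalence`` (fraction) in at least one sex, and sorted by male
    then female prevalence, descending.  Columns: otu_id, label,
    n_present_males, pct_males, n_present_females, pct_females.
    """
    if cohort.n_subjects == 0:
        raise EmptyCohortError("cannot compute prevalence on an empty cohort")
    if rel is None:
        rel = to_relative_abundance(cohort.table)
    sexes = {s.subject_id: s.sex for s in cohort.subjects}
    if set(sexes.values()) - {"F", "M"}:
        raise MetadataError("prevalence table requires F/M sex metadata")
    n_by_sex = {"M": 0, "F": 0}
    present_by_sex = {
        "M": np.zeros(len(rel.otu_ids), dtype=int),
        "F": np.zeros(len(rel.otu_ids), dtype=int),
    }
    for subj in cohort.subjects:
        s1, s2 = cohort.sample_pair(subj.subject_id)
        both = (
            (rel.sample_proportions(s1.sample_id).to_numpy() > 0)
            & (rel.sample_proportions(s2.sample_id).to_numpy() > 0)
        )
        sex = sexes[subj.subject_id]
        n_by_sex[sex] += 1
        present_by_sex[sex] += both.astype(int)
    taxonomy: Mapping[str, str] = cohort.table.taxonomy or {}
    rows = []
    for i, otu in enumerate(rel.otu_ids):
        nm = int(present_by_sex["M"][i])
        nf = int(present_by_sex["F"][i])
        pm = 100.0 * nm / n_by_sex["M"] if n_by_sex["M"] else 0.0
        pf = 100.0 * nf / n_by_sex["F"] if n_by_sex["F"] else 0.0
        if pm >= 100.0 * min_prevalence or pf >= 100.0 * min_prevalence:
            rows.append(
                dict(
                    otu_id=otu,
                    label=taxonomy.get(otu, otu),
                    n_present_males=nm,
                    pct_males=pm,
                    n_present_females=nf,
                    pct_females=pf,
                )
            )
    columns = [
        "otu_id", "label", "n_present_males", "pct_males",
        "n_present_females", "pct_females",
    ]
    out = pd.DataFrame(rows, columns=columns)
    return out.sort_values(
        ["pct_males", "pct_females", "otu_id"], ascending=[False, False, True]
    ).reset_index(drop=True)


def dominant_discordant(
    t1: pd.Series, t2: pd.Series, dominance_threshold: float = 0.5
) -> list[str]:
    """OTUs dominant (> threshold relative abundance) in one sample, absent in the other."""
    if not t1.index.equals(t2.index):
        if set(t1.index) == set(t2.index):
            t2 = t2.reindex(t1.index)
        else:
            raise AlignmentError("paired vectors do not share a common OTU index")
    p1 = t1.to_numpy(dtype=float)
    p2 = t2.to_numpy(dtype=float)
    hits = ((p1 > dominance_threshold) & (p2 == 0)) | ((p2 > dominance_threshold) & (p1 == 0))
    return sorted(t1.index[hits])
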