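"""Reading, validation and assembly of paired-cohort OTU data.

The central objects are:

* :class:`OtuCountTable` — an integer abundance matrix (samples x OTUs) with
  optional taxonomy labels.  Internally rows and columns are kept in
  lexicographic order so every downstream statistic is permutation-invariant
  by construction.
* :class:`SampleRecord` / :class:`SubjectRecord` — per-sample and per-subject
  metadata for a two-timepoint design (mid-stream vs catheterized urine,
  interval between collections in months, clinical covariates).
* :class:`PairedCohort` — the cross-validated bundle of table + metadata with
  a perfect 1:2 subject-to-sample matching.

Two plain-text table dialects are supported: a dense TSV whose first column is
the OTU id and whose header row carries sample ids, and a sparse triplet TSV
with columns (otu_id, sample_id, count).  Zero-count OTUs and samples are
retained at I/O time; dropping only happens in explicit filter operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    MetadataError,
    PairingError,
    ReconciliationError,
    TableFormatError,
    TableValidationError,
)

MSU = "MSU"
CATHETER = "CATHETER"

_METHOD_ALIASES = {
    "msu": MSU,
    "midstream": MSU,
    "mid-stream": MSU,
    "voided": MSU,
    "catheter": CATHETER,
    "catheterized": CATHETER,
    "catheterised": CATHETER,
    "cath": CATHETER,
    "tuc": CATHETER,
}

_SEX_ALIASES = {"f": "F", "female": "F", "m": "M", "male": "M"}

_BOOL_ALIASES = {
    "1": True, "true": True, "yes": True, "y": True, "t": True,
    "0": False, "false": False, "no": False, "n": False, "f": False,
}

#: canonical metadata column names; a user-supplied column map may rename them
METADATA_COLUMNS = (
    "subject_id", "sample_id", "timepoint", "method",
    "sex", "age", "cancer", "stones", "interval_months",
)


def _parse_bool(value: object, column: str) -> bool:
    key = str(value).strip().lower()
    if key not in _BOOL_ALIASES:
        raise MetadataError(f"cannot interpret {value!r} as boolean in column {column!r}")
    return _BOOL_ALIASES[key]


@dataclass(frozen=True)
class OtuCountTable:
    """Integer OTU count matrix, samples as rows, OTUs as columns.

    ``data`` is a pandas DataFrame with a lexicographically sorted sample-id
    index and OTU-id columns, dtype int64, all entries >= 0.  ``taxonomy``
    optionally maps an OTU id to a lineage/label string.
    """

    data: pd.DataFrame
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise TableValidationError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise TableValidationError(f"duplicate OTU ids: {dupes}")
        if df.size and not np.issubdtype(df.to_numpy().dtype, np.integer):
            raise TableValidationError("counts must be integers")
        if df.size and (df.to_numpy() < 0).any():
            raise TableValidationError("counts must be non-negative")
        canonical = df.sort_index(axis=0).sort_index(axis=1).astype(np.int64)
        canonical.index.name = None
        canonical.columns.name = None
        object.__setattr__(self, "data", canonical)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(canonical.columns)
            if unknown:
                raise TableValidationError(
                    f"taxonomy refers to unknown OTU ids: {sorted(unknown)}"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_otus(self) -> int:
        return self.data.shape[1]

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def total_reads(self) -> pd.Series:
        """Reads per sample (row sums)."""
        return self.data.sum(axis=1)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        """Count vector for one sample over the full OTU index."""
        return self.data.loc[sample_id].to_numpy()

    # -- derivation --------------------------------------------------------
    def subset_samples(self, keep: Iterable[str]) -> "OtuCountTable":
        keep = list(keep)
        missing = set(keep) - set(self.data.index)
        if missing:
            raise TableValidationError(f"unknown sample ids: {sorted(missing)}")
        return OtuCountTable(self.data.loc[sorted(keep)], taxonomy=self.taxonomy)

    def subset_otus(self, keep: Iterable[str]) -> "OtuCountTable":
        keep = sorted(keep)
        missing = set(keep) - set(self.data.columns)
        if missing:
            raise TableValidationError(f"unknown OTU ids: {sorted(missing)}")
        tax = None
        if self.taxonomy is not None:
            tax = {o: t for o, t in self.taxonomy.items() if o in set(keep)}
        return OtuCountTable(self.data[keep], taxonomy=tax)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    subject_id: str
    timepoint: int
    collection_method: str
    total_reads: int | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in (1, 2):
            raise MetadataError(
                f"sample {self.sample_id!r}: timepoint must be 1 or 2, got {self.timepoint!r}"
            )
        if self.collection_method not in (MSU, CATHETER):
            raise MetadataError(
                f"sample {self.sample_id!r}: unknown collection method "
                f"{self.collection_method!r}"
            )
        if self.timepoint == 2 and self.collection_method != MSU:
            # The study design collects every second sample as mid-stream
            # urine; external data may deviate, so this is only advisory.
            warnings.warn(
                f"sample {self.sample_id!r}: second-timepoint sample is not MSU",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    sex: str
    age: float
    cancer: bool
    stones: bool
    interval_months: float

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise MetadataError(
                f"subject {self.subject_id!r}: sex must be F or M, got {self.sex!r}"
            )
        if not self.interval_months > 0:
            raise MetadataError(
                f"subject {self.subject_id!r}: interval_months must be > 0, "
                f"got {self.interval_months!r}"
            )
        if self.age < 18:
            warnings.warn(
                f"subject {self.subject_id!r}: age {self.age} below the adult "
                "inclusion threshold",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PairedCohort:
    """Validated bundle of subjects, samples and the count table."""

    subjects: tuple[SubjectRecord, ...]
    samples: tuple[SampleRecord, ...]
    table: OtuCountTable

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def sample_pair(self, subject_id: str) -> tuple[SampleRecord, SampleRecord]:
        """The (timepoint-1, timepoint-2) samples of one subject."""
        pair = sorted(
            (s for s in self.samples if s.subject_id == subject_id),
            key=lambda s: s.timepoint,
        )
        if len(pair) != 2:
            raise PairingError(f"subject {subject_id!r} does not have 2 samples")
        return pair[0], pair[1]

    def method_combo(self, subject_id: str) -> str:
        """Collection-method combination, e.g. ``"MSU/MSU"`` or ``"CATHETER/MSU"``."""
        t1, t2 = self.sample_pair(subject_id)
        return f"{t1.collection_method}/{t2.collection_method}"

    def with_table(self, table: OtuCountTable) -> "PairedCohort":
        """Same cohort over a new table (e.g. after OTU filtering).

        The new table must keep exactly the cohort's samples; OTUs may differ.
        """
        return build_paired_cohort(table, list(self.samples), list(self.subjects))

    def subset_subjects(self, keep: Iterable[str]) -> "PairedCohort":
        keep = set(keep)
        subjects = [s for s in self.subjects if s.subject_id in keep]
        samples = [s for s in self.samples if s.subject_id in keep]
        table = self.table.subset_samples([s.sample_id for s in samples])
        return build_paired_cohort(table, samples, subjects)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _int_or_raise(token: str, row: str, col: str) -> int:
    try:
        value = int(token)
    except ValueError:
        raise TableFormatError(
            f"non-integer count {token!r} at OTU {row!r}, sample {col!r}"
        ) from None
    if value < 0:
        raise TableFormatError(
            f"negative count {token!r} at OTU {row!r}, sample {col!r}"
        )
    return value


def read_otu_table(
    path: str | Path,
    dialect: str = "tsv_dense",
    taxonomy_path: str | Path | None = None,
    column_map: Mapping[str, str] | None = None,
) -> OtuCountTable:
    """Read an OTU count table from a plain-text file.

    Parameters
    ----------
    path
        Input TSV.  ``tsv_dense``: first column OTU id, header row sample ids.
        ``triplet_sparse``: header ``otu_id  sample_id  count``, one nonzero
        (or explicitly zero) entry per row.
    taxonomy_path
        Optional two-column TSV ``otu_id  lineage``.
    column_map
        For externally deposited tables with different column names: maps the
        canonical triplet names (``otu_id``, ``sample_id``, ``count``) to the
        file's column names.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    if dialect == "tsv_dense":
        raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
        raw.index = raw.index.astype(str)
        cells = {}
        for col in raw.columns:
            cells[col] = [
                _int_or_raise(str(v).strip(), str(idx), str(col))
                for idx, v in raw[col].items()
            ]
        counts = pd.DataFrame(cells, index=raw.index.astype(str))
        data = counts.T  # file is OTUs x samples; internal layout is samples x OTUs
    elif dialect == "triplet_sparse":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        names = {"otu_id": "otu_id", "sample_id": "sample_id", "count": "count"}
        if column_map:
            names.update({k: v for k, v in column_map.items() if k in names})
        missing = [v for v in names.values() if v not in raw.columns]
        if missing:
            raise TableFormatError(f"triplet file lacks columns: {missing}")
        otus = raw[names["otu_id"]].astype(str)
        samples = raw[names["sample_id"]].astype(str)
        values = [
            _int_or_raise(str(v).strip(), o, s)
            for v, o, s in zip(raw[names["count"]], otus, samples)
        ]
        dupes = pd.DataFrame({"o": otus, "s": samples}).duplicated()
        if dupes.any():
            first = raw[dupes.to_numpy()].iloc[0]
            raise TableValidationError(
                f"duplicate triplet entry for OTU {first[names['otu_id']]!r}, "
                f"sample {first[names['sample_id']]!r}"
            )
        data = (
            pd.DataFrame({"otu": otus, "sample": samples, "count": values})
            .pivot(index="sample", columns="otu", values="count")
            .fillna(0)
            .astype(np.int64)
        )
        data.index.name = None
        data.columns.name = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)
        taxonomy = {k: v for k, v in taxonomy.items() if k in set(data.columns)}
    return OtuCountTable(data, taxonomy=taxonomy)


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column ``otu_id<TAB>lineage`` TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["otu_id", "lineage"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["otu_id", "lineage"])
    return dict(zip(df["otu_id"].astype(str), df["lineage"].astype(str)))


def write_otu_table(table: OtuCountTable, path: str | Path, dialect: str = "tsv_dense") -> None:
    """Write a table in either dialect.

    The triplet writer emits all nonzero entries plus one explicit zero entry
    for any all-zero OTU or sample, so round-tripping preserves the id sets
    (and therefore the counts) bit-exactly.
    """
    path = Path(path)
    if dialect == "tsv_dense":
        out = table.data.T.copy()  # OTUs x samples on disk
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")
    elif dialect == "triplet_sparse":
        rows: list[tuple[str, str, int]] = []
        data = table.data
        nz = data.to_numpy().nonzero()
        for i, j in zip(*nz):
            rows.append((data.columns[j], data.index[i], int(data.iat[i, j])))
        if data.shape[0] and data.shape[1]:
            first_sample, first_otu = data.index[0], data.columns[0]
            for otu in data.columns[data.sum(axis=0) == 0]:
                rows.append((otu, first_sample, 0))
            for sample in data.index[data.sum(axis=1) == 0]:
                rows.append((first_otu, sample, 0))
        pd.DataFrame(rows, columns=["otu_id", "sample_id", "count"]).sort_values(
            ["otu_id", "sample_id"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------

def read_metadata(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SampleRecord], list[SubjectRecord]]:
    """Read the combined sample/subject metadata TSV.

    Expected canonical columns: subject_id, sample_id, timepoint, method, sex,
    age, cancer, stones, interval_months (one row per sample; subject-level
    fields repeated on both rows and required to be consistent).  A
    ``column_map`` maps canonical names to the file's column names for
    externally deposited metadata.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    names = {c: c for c in METADATA_COLUMNS}
    if column_map:
        names.update({k: v for k, v in column_map.items() if k in names})
    missing = [v for k, v in names.items() if v not in df.columns]
    if missing:
        raise MetadataError(f"metadata lacks columns: {missing}")
    return parse_metadata_frame(df.rename(columns={v: k for k, v in names.items()}))


def parse_metadata_frame(
    df: pd.DataFrame,
) -> tuple[list[SampleRecord], list[SubjectRecord]]:
    """Validate a canonical-column metadata frame into records."""
    samples: list[SampleRecord] = []
    subject_rows: dict[str, dict] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        subj = str(row["subject_id"]).strip()
        method_key = str(row["method"]).strip().lower()
        if method_key not in _METHOD_ALIASES:
            raise MetadataError(f"sample {sid!r}: unknown method {row['method']!r}")
        try:
            timepoint = int(str(row["timepoint"]).strip())
        except ValueError:
            raise MetadataError(
                f"sample {sid!r}: bad timepoint {row['timepoint']!r}"
            ) from None
        samples.append(
            SampleRecord(
                sample_id=sid,
                subject_id=subj,
                timepoint=timepoint,
                collection_method=_METHOD_ALIASES[method_key],
            )
        )
        sex_key = str(row["sex"]).strip().lower()
        if sex_key not in _SEX_ALIASES:
            raise MetadataError(f"subject {subj!r}: unknown sex {row['sex']!r}")
        info = dict(
            subject_id=subj,
            sex=_SEX_ALIASES[sex_key],
            age=float(row["age"]),
            cancer=_parse_bool(row["cancer"], "cancer"),
            stones=_parse_bool(row["stones"], "stones"),
            interval_months=float(row["interval_months"]),
        )
        prior = subject_rows.setdefault(subj, info)
        if prior != info:
            raise MetadataError(f"subject {subj!r}: inconsistent subject-level fields")

    _check_pairing(samples)
    dupes = pd.Series([s.sample_id for s in samples]).duplicated()
    if dupes.any():
        raise MetadataError("duplicate sample ids in metadata")
    subjects = [SubjectRecord(**info) for info in subject_rows.values()]
    subjects.sort(key=lambda s: s.subject_id)
    samples.sort(key=lambda s: s.sample_id)
    return samples, subjects


def _check_pairing(samples: Sequence[SampleRecord]) -> None:
    by_subject: dict[str, list[int]] = {}
    for s in samples:
        by_subject.setdefault(s.subject_id, []).append(s.timepoint)
    offenders = {
        subj: sorted(tps)
        for subj, tps in by_subject.items()
        if sorted(tps) != [1, 2]
    }
    if offenders:
        raise PairingError(
            "subjects without exactly one sample per timepoint: "
            + ", ".join(f"{s} (timepoints {t})" for s, t in sorted(offenders.items()))
        )


def write_metadata(
    samples: Sequence[SampleRecord],
    subjects: Sequence[SubjectRecord],
    path: str | Path,
) -> None:
    by_subject = {s.subject_id: s for s in subjects}
    rows = []
    for s in sorted(samples, key=lambda r: r.sample_id):
        subj = by_subject[s.subject_id]
        rows.append(
            dict(
                subject_id=s.subject_id,
                sample_id=s.sample_id,
                timepoint=s.timepoint,
                method=s.collection_method,
                sex=subj.sex,
                age=subj.age,
                cancer=int(subj.cancer),
                stones=int(subj.stones),
                interval_months=subj.interval_months,
            )
        )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def build_paired_cohort(
    table: OtuCountTable,
    samples: Sequence[SampleRecord],
    subjects: Sequence[SubjectRecord],
) -> PairedCohort:
    """Cross-check ids, attach per-sample read totals and return the cohort.

    Raises :class:`ReconciliationError` naming the symmetric difference when
    the metadata and table sample-id sets disagree, and :class:`PairingError`
    when the subject-to-sample matching is not a perfect 1:2.
    """
    meta_ids = {s.sample_id for s in samples}
    table_ids = set(table.sample_ids)
    if meta_ids != table_ids:
        only_meta = sorted(meta_ids - table_ids)
        only_table = sorted(table_ids - meta_ids)
        raise ReconciliationError(
            f"sample ids disagree; only in metadata: {only_meta}, "
            f"only in table: {only_table}"
        )
    _check_pairing(samples)
    subj_meta = {s.subject_id for s in subjects}
    subj_samples = {s.subject_id for s in samples}
    if subj_meta != subj_samples:
        raise ReconciliationError(
            f"subject ids disagree; only in subjects: {sorted(subj_meta - subj_samples)}, "
            f"only in samples: {sorted(subj_samples - subj_meta)}"
        )
    totals = table.total_reads
    samples_out = tuple(
        replace(s, total_reads=int(totals.loc[s.sample_id]))
        for s in sorted(samples, key=lambda r: r.sample_id)
    )
    subjects_out = tuple(sorted(subjects, key=lambda r: r.subject_id))
    return PairedCohort(subjects=subjects_out, samples=samples_out, table=table)
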