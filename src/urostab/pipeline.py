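"""One-call end-to-end pipeline: QC -> alpha -> overlap -> beta -> models.

A :class:`PipelineConfig` either points at input files (count table +
metadata) or carries a ``simulate`` block; :func:`run_pipeline` executes the
stages, writes per-stage TSVs plus a JSON summary of the headline aggregates,
and logs per-stage row/OTU counts so filter effects are auditable.  Stage
outputs are pure functions of (inputs, resolved config, seed): running twice
with the same seed yields byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import RarefactionConfig, iterated_alpha
from .beta import distance_matrix, single_term_permanova
from .cohort_io import build_paired_cohort, read_metadata, read_otu_table
from .errors import ConfigError, UrostabError
from .models import decay_model, interval_subgroup_analysis, pearson_r2
from .overlap import cohort_overlap, prevalence_table
from .qc import DEFAULT_COVERAGE_THRESHOLD, run_qc
from .synthetic import SyntheticConfig, generate_cohort, truth_report

logger = logging.getLogger(__name__)

PERMANOVA_TERMS = ("subject_id", "interval", "sex", "cancer", "method")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (fully serializable)."""

    otu_table: str | None = None
    metadata: str | None = None
    table_dialect: str = "tsv_dense"
    taxonomy: str | None = None
    simulate: SyntheticConfig | None = None
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD
    rarefaction_depth: int = 1000
    rarefaction_iterations: int = 1000
    n_permutations: int = 999
    model_terms: tuple[str, ...] = ("months", "age", "sex", "cancer")
    split_months: float = 15.0
    seed: int = 0
    output_dir: str = "urostab_out"

    def __post_init__(self) -> None:
        has_files = self.otu_table is not None and self.metadata is not None
        if has_files == (self.simulate is not None):
            raise ConfigError(
                "exactly one input source required: either otu_table+metadata "
                "or a simulate block"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(
            simulate=SyntheticConfig(**sim) if sim is not None else None,
            **{k: tuple(v) if k == "model_terms" else v for k, v in raw.items()},
        )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["model_terms"] = list(self.model_terms)
        if self.simulate is not None:
            raw["simulate"] = dataclasses.asdict(self.simulate)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``output_dir``.

    Returns the JSON-ready summary dict.  Raises a stage-named
    :class:`UrostabError` on failure; partial outputs already written are
    retained for debugging.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    log_lines = [f"urostab {__version__}", f"seed {config.seed}"]

    # -- input ------------------------------------------------------------
    if config.simulate is not None:
        cohort, truth = generate_cohort(config.simulate, seed=config.seed)
        log_lines.append(
            f"simulated cohort: {cohort.n_subjects} subjects, "
            f"{cohort.table.n_otus} OTUs"
        )
    else:
        table = read_otu_table(
            config.otu_table, dialect=config.table_dialect,
            taxonomy_path=config.taxonomy,
        )
        samples, subjects = read_metadata(config.metadata)
        cohort = build_paired_cohort(table, samples, subjects)
        truth = None
        log_lines.append(
            f"loaded cohort: {cohort.n_subjects} subjects, {cohort.table.n_otus} OTUs"
        )

    summary: dict = {"seed": config.seed, "n_subjects_input": cohort.n_subjects}

    # -- qc ----------------------------------------------------------------
    try:
        filtered, report, rel = run_qc(cohort, config.coverage_threshold)
    except UrostabError as exc:
        raise UrostabError(f"stage qc failed: {exc}") from exc
    report.per_sample.to_csv(out / "coverage_report.tsv", sep="\t", index=False)
    summary["qc"] = {
        "coverage_threshold": config.coverage_threshold,
        "n_subjects_excluded": len(report.excluded_subjects),
        "n_subjects_retained": filtered.n_subjects,
        "n_otus_after_singleton_removal": filtered.table.n_otus,
    }
    log_lines.append(
        f"qc: excluded {len(report.excluded_subjects)} subjects, "
        f"retained {filtered.n_subjects}; "
        f"{filtered.table.n_otus} OTUs after global-singleton removal"
    )

    # -- alpha -------------------------------------------------------------
    try:
        alpha = iterated_alpha(
            filtered,
            RarefactionConfig(
                depth=config.rarefaction_depth,
                iterations=config.rarefaction_iterations,
                seed=config.seed,
            ),
        )
    except UrostabError as exc:
        raise UrostabError(f"stage alpha failed: {exc}") from exc
    alpha.per_sample.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
    summary["alpha"] = {
        "depth": config.rarefaction_depth,
        "iterations": config.rarefaction_iterations,
        "n_subjects_excluded_below_depth": len(alpha.excluded_subjects),
        "chao1_mean_over_samples": float(alpha.per_sample["chao1_mean"].mean()),
        "shannon_mean_over_samples": float(alpha.per_sample["shannon_mean"].mean()),
    }

    # -- overlap -----------------------------------------------------------
    try:
        overlap_df, aggregates = cohort_overlap(filtered, rel)
        prevalence = prevalence_table(filtered, rel)
    except UrostabError as exc:
        raise UrostabError(f"stage overlap failed: {exc}") from exc
    overlap_df.to_csv(out / "overlap_subjects.tsv", sep="\t", index=False)
    prevalence.to_csv(out / "prevalence_table.tsv", sep="\t", index=False)
    with open(out / "overlap_aggregates.json", "w") as fh:
        json.dump(_round_floats(aggregates), fh, indent=2, sort_keys=True)
    r2_corr, p_corr = pearson_r2(
        overlap_df["n_shared"].to_numpy(), overlap_df["shared_abund_mean"].to_numpy()
    )
    summary["overlap"] = {
        "mean_richness": float(
            pd.concat([overlap_df["n_otus_t1"], overlap_df["n_otus_t2"]]).mean()
        ),
        "mean_n_shared": float(overlap_df["n_shared"].mean()),
        "mean_shared_abund_pct": float(100.0 * overlap_df["shared_abund_mean"].mean()),
        "pearson_r2_nshared_vs_abund": r2_corr,
    }

    # -- beta --------------------------------------------------------------
    try:
        dist = distance_matrix(rel)
        design = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in filtered.samples],
                "subject_id": [s.subject_id for s in filtered.samples],
                "interval": [
                    filtered.subject(s.subject_id).interval_months
                    for s in filtered.samples
                ],
                "sex": [filtered.subject(s.subject_id).sex for s in filtered.samples],
                "cancer": [
                    filtered.subject(s.subject_id).cancer for s in filtered.samples
                ],
                "method": [s.collection_method for s in filtered.samples],
            }
        )
        usable_terms = [
            t for t in PERMANOVA_TERMS if design[t].nunique() > 1
        ]
        perm = single_term_permanova(
            dist, design, usable_terms,
            n_permutations=config.n_permutations, seed=config.seed,
        )
    except UrostabError as exc:
        raise UrostabError(f"stage beta failed: {exc}") from exc
    perm.to_csv(out / "permanova.tsv", sep="\t", index=False)
    summary["beta"] = {
        "n_permutations": config.n_permutations,
        "r2_by_term": {
            row["term"]: float(row["R2"]) for _, row in perm.iterrows()
        },
    }

    # -- models ------------------------------------------------------------
    try:
        fit = decay_model(overlap_df, terms=config.model_terms)
        subgroups = interval_subgroup_analysis(overlap_df, config.split_months)
    except UrostabError as exc:
        raise UrostabError(f"stage model failed: {exc}") from exc
    fit.coefficients.to_csv(out / "decay_model.tsv", sep="\t", index=False)
    months = fit.coefficient("months")
    summary["decay_model"] = {
        "intercept_pct": float(fit.coefficient("intercept")["estimate"]),
        "slope_pct_per_month": float(months["estimate"]),
        "slope_ci": [float(months["ci_low"]), float(months["ci_high"])],
        "slope_p_value": float(months["p_value"]),
        "marginal_r2": fit.r2_marginal,
        "subgroups": subgroups,
    }

    if truth is not None:
        truth_report(truth, overlap_df, out / "truth_report.tsv")
        summary["truth"] = {
            "slope_pct_per_month": truth.slope_pct_per_month,
            "intercept_pct": truth.intercept_pct,
        }

    summary = _round_floats(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log_lines.append("pipeline complete")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return summary


def recover_decay_slope(
    n_cohorts: int = 200,
    base_seed: int = 1,
    config: SyntheticConfig | None = None,
    terms: tuple[str, ...] = ("months", "age", "sex", "cancer"),
) -> pd.DataFrame:
    """Parameter-recovery experiment for the decay slope.

    Generates ``n_cohorts`` cohorts with per-cohort seeds derived from
    ``SeedSequence([base_seed, i])`` (i = 1..n_cohorts), runs the QC ->
    overlap -> decay-model pipeline on each, and returns one row per cohort:
    fitted months slope, its 95% CI, and whether the CI covers the configured
    truth.
    """
    from .qc import exclude_low_coverage_pairs, remove_global_singletons

    config = config or SyntheticConfig()
    truth_slope = config.shared_abund_slope_pct_per_month
    rows = []
    for i in range(1, n_cohorts + 1):
        seed_i = int(np.random.SeedSequence(entropy=[base_seed, i]).generate_state(1)[0])
        cohort, _ = generate_cohort(config, seed=seed_i)
        gated, _ = exclude_low_coverage_pairs(cohort)
        filtered = gated.with_table(remove_global_singletons(gated.table))
        summary, _ = cohort_overlap(filtered)
        fit = decay_model(summary, terms=terms)
        slope = fit.coefficient("months")
        rows.append(
            dict(
                cohort=i,
                seed=seed_i,
                slope=float(slope["estimate"]),
                ci_low=float(slope["ci_low"]),
                ci_high=float(slope["ci_high"]),
                covered=bool(slope["ci_low"] <= truth_slope <= slope["ci_high"]),
            )
        )
    return pd.DataFrame(rows)
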