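"""End-to-end orchestration: call -> associate -> mine -> epistasis.

A pipeline run reads one genotype TSV, writes per-subject haplogroup calls,
single-feature association results, combination-mining results and pairwise
epistasis results, plus a run log recording configuration, seed and the
subjects excluded by complete-case filtering at every step. Identical
configuration and input produce byte-identical result tables (timestamps
are confined to the log).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .association import Carrier, Feature, associate, carrier_status
from .cohort import CohortTable, read_cohort, write_results
from .epistasis import analyze_pair
from .errors import ConfigError, DataError, MitosynError
from .haplogroups import call_cohort, haplogroup_frequencies
from .mining import enumerate_combinations


@dataclass
class PipelineConfig:
    input_path: str
    features: list[Feature]
    output_dir: str
    max_order: int = 2
    alpha: float = 0.05
    small_cell_threshold: int = 5
    adjust: str = "none"
    sex_strata: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_order < 1:
            raise ConfigError("max_order must be >= 1")
        if self.adjust not in ("none", "bh"):
            raise ConfigError(f"adjust must be 'none' or 'bh', got {self.adjust!r}")
        if not Path(self.input_path).exists():
            raise ConfigError(f"input path {self.input_path!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            features = [Feature.parse(f) for f in raw.pop("features")]
            input_path = raw.pop("input")
            output_dir = raw.pop("output_dir")
        except KeyError as exc:
            raise ConfigError(f"config missing key {exc}") from None
        return cls(
            input_path=input_path, features=features, output_dir=output_dir, **raw
        )


@dataclass
class RunSummary:
    n_subjects: int
    n_case: int
    n_control: int
    outputs: dict[str, str] = field(default_factory=dict)
    exclusions: dict[str, int] = field(default_factory=dict)


def _feature_exclusions(cohort: CohortTable, features, calls) -> dict[str, int]:
    excl = {}
    for f in features:
        n = sum(
            1
            for s in cohort
            if carrier_status(s, f, calls) is Carrier.MISSING
        )
        excl[f.name] = n
    return excl


def run_pipeline(cfg: PipelineConfig) -> RunSummary:
    """Execute all stages; raises module errors annotated with their stage."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        cohort = read_cohort(cfg.input_path)
        if len(cohort) == 0:
            raise DataError("empty cohort")
    except MitosynError as exc:
        raise type(exc)(f"[stage read] {exc}") from exc

    calls = call_cohort(cohort)
    summary = RunSummary(len(cohort), cohort.n_case, cohort.n_control)
    summary.exclusions = _feature_exclusions(cohort, cfg.features, calls)

    # Stage: haplogroup calls + frequency summary
    calls_path = outdir / "haplogroup_calls.tsv"
    write_results(
        [
            {"subject_id": sid, "haplogroup": call.label}
            for sid, call in calls.items()
        ],
        str(calls_path),
        columns=["subject_id", "haplogroup"],
    )
    freq_path = outdir / "haplogroup_frequencies.tsv"
    haplogroup_frequencies(cohort).reset_index().to_csv(
        freq_path, sep="\t", index=False, float_format="%.4g"
    )
    summary.outputs["calls"] = str(calls_path)
    summary.outputs["frequencies"] = str(freq_path)

    # Stage: single-feature association
    try:
        assoc_rows = [
            associate(cohort, f, calls).to_row() for f in cfg.features
        ]
    except MitosynError as exc:
        raise type(exc)(f"[stage assoc] {exc}") from exc
    assoc_path = outdir / "association.tsv"
    write_results(assoc_rows, str(assoc_path))
    summary.outputs["association"] = str(assoc_path)

    # Stage: combination mining
    try:
        report = enumerate_combinations(
            cohort,
            cfg.features,
            max_order=cfg.max_order,
            alpha=cfg.alpha,
            adjust=cfg.adjust,
        )
    except MitosynError as exc:
        raise type(exc)(f"[stage mine] {exc}") from exc
    mine_path = outdir / "mining.tsv"
    write_results(report.to_rows(), str(mine_path))
    summary.outputs["mining"] = str(mine_path)

    # Stage: pairwise epistasis over distinct-locus feature pairs
    epi_rows = []
    try:
        for fa, fb in itertools.combinations(cfg.features, 2):
            if fa.locus == fb.locus:
                continue
            res = analyze_pair(
                cohort,
                fa,
                fb,
                alpha=cfg.alpha,
                small_cell_threshold=cfg.small_cell_threshold,
                calls=calls,
            )
            epi_rows.append(res.to_row())
    except MitosynError as exc:
        raise type(exc)(f"[stage epistasis] {exc}") from exc
    epi_path = outdir / "epistasis.tsv"
    write_results(
        epi_rows,
        str(epi_path),
        columns=[
            "pair",
            "case_cells",
            "control_cells",
            "sf",
            "sf_ci_low",
            "sf_ci_high",
            "correction_applied",
            "p_flint",
            "p_synergy",
            "classification",
        ],
    )
    summary.outputs["epistasis"] = str(epi_path)

    # Run log (the only timestamped output)
    log_path = outdir / "run_log.yaml"
    with open(log_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "timestamp": datetime.now(timezone.utc).isoformat(),
                "version": __version__,
                "seed": cfg.seed,
                "input": cfg.input_path,
                "features": [f.name for f in cfg.features],
                "max_order": cfg.max_order,
                "alpha": cfg.alpha,
                "small_cell_threshold": cfg.small_cell_threshold,
                "adjust": cfg.adjust,
                "n_subjects": summary.n_subjects,
                "n_case": summary.n_case,
                "n_control": summary.n_control,
                "excluded_missing_per_feature": summary.exclusions,
            },
            fh,
            sort_keys=False,
        )
    summary.outputs["log"] = str(log_path)
    return summary
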