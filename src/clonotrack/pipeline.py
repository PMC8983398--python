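"""End-to-end pipeline: simulate/ingest -> QC -> composition -> tracking ->
diversity -> report.

A :class:`PipelineConfig` (JSON or YAML) names the inputs (or an inline
simulation config), the keying scheme, QC thresholds and tracking parameters.
``run_pipeline`` executes the stages in order and writes versioned TSV/JSON
outputs plus a machine-readable run manifest (config hash, seed, package
version, sha256 per output file) so identical configs provably reproduce
identical results.

Study phases and the subtraction chain
--------------------------------------
Each sample belongs to a phase: ``baseline``, ``influenza`` or
``sars_cov_2``.  For a vaccination phase, samples at days <= the dose day are
pre-vaccination; the pre set is the union of clonotypes from all baseline
samples and the phase's own pre-dose samples.  The SARS-CoV-2 phase
additionally subtracts every clonotype observed during the influenza phase
(with an explicit warning when no influenza samples exist).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import __version__
from .errors import ClonotrackError, ConfigurationError
from .io import (TimeSeriesCohort, build_cohorts, contigs_to_frame,
                 read_annotations, read_contigs, read_expression)
from .keys import parse_scheme
from .qc import compare_proportion_tables, compute_proportions, filter_cells
from .simulate import SimConfig, simulate_cohort, write_cohort
from .tracking import (classify_persistence, classify_post_vaccination,
                       celltype_breakdown, detect_dynamic_clonotypes,
                       min_timepoint_filter, subtract_baseline, top_clonotypes)
from .diversity import (chain_overlap_ratio, cohort_contigs,
                        isotype_composition, shannon_by_sample, v_gene_usage)

logger = logging.getLogger(__name__)

PHASES = ("baseline", "influenza", "sars_cov_2")


class SampleEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sample_id: str
    contigs: str
    individual: str
    time_point: int
    phase: Literal["baseline", "influenza", "sars_cov_2"] = "baseline"


class QCThresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_features: int = Field(default=200, ge=0)
    max_features: int = Field(default=4000, gt=0)
    max_percent_mt: float = Field(default=8.0, gt=0.0)


class PipelineConfig(BaseModel):
    """Pipeline configuration (see module docstring)."""

    model_config = ConfigDict(extra="forbid")

    outdir: str = "clonotrack_out"
    seed: int = Field(default=0, ge=0)
    scheme: str = "paired_nt"
    qc: QCThresholds = Field(default_factory=QCThresholds)
    fold: float = Field(default=2.0, gt=1.0)
    min_cells: int = Field(default=3, ge=1)
    t_min: int = Field(default=3, ge=1)
    diversity_chains: list[str] = Field(
        default_factory=lambda: ["IGH", "IGK", "IGL", "TRB"])
    dose_day: dict[str, int] = Field(
        default_factory=lambda: {"influenza": 0, "sars_cov_2": 0})
    # data source: either an inline simulation config ...
    simulate: SimConfig | None = None
    simulated_phase: Literal["baseline", "influenza", "sars_cov_2"] = "influenza"
    # ... or explicit input tables
    annotations: str | None = None
    expression: str | None = None
    samples: list[SampleEntry] = Field(default_factory=list)

    @field_validator("scheme")
    @classmethod
    def _scheme_known(cls, v: str) -> str:
        try:
            parse_scheme(v)
        except ConfigurationError as exc:
            raise ValueError(str(exc)) from exc
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        errors = validate_config(path)
        if errors:
            raise ConfigurationError(
                "invalid pipeline config:\n  " + "\n  ".join(errors))
        return cls.model_validate(_load_document(path))


def _load_document(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def validate_config(path: str | Path) -> list[str]:
    """Schema-check a pipeline config document; all errors listed at once."""
    try:
        doc = _load_document(path)
    except OSError as exc:
        raise ClonotrackError(f"cannot read config {path}: {exc}") from exc
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        return [f"unparsable document: {exc}"]
    errors: list[str] = []
    try:
        cfg = PipelineConfig.model_validate(doc)
    except ValidationError as exc:
        return [
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
    base = Path(path).parent
    if cfg.simulate is None:
        if cfg.annotations is None:
            errors.append("annotations: required when no simulation config is given")
        elif not (base / cfg.annotations).exists():
            errors.append(f"annotations: file not found: {cfg.annotations}")
        if not cfg.samples:
            errors.append("samples: required when no simulation config is given")
        for i, entry in enumerate(cfg.samples):
            if not (base / entry.contigs).exists():
                errors.append(f"samples.{i}.contigs: file not found: {entry.contigs}")
    return errors


# ---------------------------------------------------------------------------
# Stage machinery
# ---------------------------------------------------------------------------

class PipelineStageError(ClonotrackError):
    pass


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _labels_frame(labels: dict) -> pd.DataFrame:
    rows = [(k, lab.category, lab.k, lab.post_vaccination_class or "")
            for k, lab in sorted(labels.items())]
    return pd.DataFrame(rows, columns=[
        "clonotype_key", "category", "k", "post_vaccination_class"])


def _phase_pre_union(cohort: TimeSeriesCohort, phases: pd.Series,
                     phase: str, dose_day: int,
                     extra_phases: list[str]) -> tuple[set[str], TimeSeriesCohort | None]:
    """Pre-vaccination union and post-dose sub-cohort for one phase."""
    pre: set[str] = set()
    post_samples = []
    for s in cohort.samples:
        s_phase = phases.get(s.sample_id, "baseline")
        if s_phase == "baseline" or s_phase in extra_phases:
            pre |= s.keys()
        elif s_phase == phase:
            if s.time_point <= dose_day:
                pre |= s.keys()
            else:
                post_samples.append(s)
    if not post_samples:
        return pre, None
    return pre, TimeSeriesCohort(individual=cohort.individual,
                                 samples=post_samples)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, config_dir: Path | None = None,
                 outdir: str | Path | None = None) -> Path:
    """Execute every stage; returns the output directory.

    Stage failures abort with :class:`PipelineStageError` naming the stage.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    base = config_dir or Path(".")
    stage = "ingest"
    try:
        annotations, contigs, expression, phases = _ingest(config, base, out)

        stage = "qc"
        retained, qc_report = filter_cells(
            annotations,
            min_features=config.qc.min_features,
            max_features=config.qc.max_features,
            max_percent_mt=config.qc.max_percent_mt)
        _write_json(qc_report.to_dict(), out / "qc" / "qc_report.json")

        stage = "join"
        cohorts = build_cohorts(retained, contigs, scheme=config.scheme)

        stage = "composition"
        _composition_stage(retained, out)

        stage = "track"
        _tracking_stage(config, cohorts, phases, out)

        stage = "diversity"
        _diversity_stage(config, cohorts, contigs, out)

        stage = "report"
        _manifest_stage(config, out)
    except ClonotrackError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc
    return out


def _ingest(config: PipelineConfig, base: Path, out: Path):
    if config.simulate is not None:
        annotations, contigs, expression, _truth = simulate_cohort(config.simulate)
        write_cohort(out / "simulated", annotations, contigs, expression,
                     config.simulate)
        phases = pd.Series({
            sid: config.simulated_phase
            for sid in annotations["sample_id"].unique()})
        return annotations, contigs, expression, phases
    annotations = read_annotations(base / config.annotations)
    records = []
    phases = {}
    for entry in config.samples:
        records.extend(read_contigs(base / entry.contigs, entry.sample_id))
        phases[entry.sample_id] = entry.phase
    contigs = contigs_to_frame(records).rename(columns={"cdr3_aa": "cdr3"})
    expression = (read_expression(base / config.expression)
                  if config.expression else None)
    return annotations, contigs, expression, pd.Series(phases)


def _composition_stage(cells: pd.DataFrame, out: Path) -> None:
    for level in ("major", "detailed"):
        props, counts = compute_proportions(cells, level=level)
        _write_tsv(props, out / "composition" / f"proportions_{level}.tsv",
                   index=True)
        _write_tsv(counts, out / "composition" / f"counts_{level}.tsv",
                   index=True)
    # cross-individual comparisons on per-sample major proportions
    props, _ = compute_proportions(cells, level="major")
    sample_ind = cells.drop_duplicates("sample_id").set_index("sample_id")["individual"]
    individuals = sorted(sample_ind.unique())
    rows = []
    for i, a in enumerate(individuals):
        for b in individuals[i + 1:]:
            pa = props.loc[[s for s in props.index if sample_ind[s] == a]]
            pb = props.loc[[s for s in props.index if sample_ind[s] == b]]
            if len(pa) < 2 or len(pb) < 2:
                continue
            res = compare_proportion_tables(pa, pb)
            res.insert(0, "individual_a", a)
            res.insert(1, "individual_b", b)
            rows.append(res)
    if rows:
        _write_tsv(pd.concat(rows, ignore_index=True),
                   out / "composition" / "cross_individual_tests.tsv")


def _tracking_stage(config: PipelineConfig,
                    cohorts: dict[str, TimeSeriesCohort],
                    phases: pd.Series, out: Path) -> None:
    all_samples = [s for c in cohorts.values() for s in c.samples]
    top_table, overlap = top_clonotypes(all_samples, n=10)
    _write_tsv(top_table, out / "tracking" / "top_clonotypes.tsv")
    _write_tsv(overlap, out / "tracking" / "top_clonotype_overlap.tsv")

    for ind, cohort in cohorts.items():
        d = out / "tracking" / ind
        if len(cohort.samples) >= 2:
            res = classify_persistence(cohort)
            _write_tsv(_labels_frame(res.labels), d / "persistence_labels.tsv")
            _write_tsv(res.cell_fractions, d / "unique_overlap_fractions.tsv")
            _write_tsv(celltype_breakdown(cohort, res.labels),
                       d / "celltype_breakdown.tsv")
            calls = detect_dynamic_clonotypes(
                cohort, fold=config.fold, min_cells=config.min_cells)
            _write_json({
                "parameters": {"fold": calls.fold, "min_cells": calls.min_cells},
                "increased": sorted(calls.increased),
                "decreased": sorted(calls.decreased),
            }, d / "dynamic_calls.json")

        for phase in ("influenza", "sars_cov_2"):
            phase_sids = {sid for sid, p in phases.items() if p == phase}
            if not phase_sids & {s.sample_id for s in cohort.samples}:
                continue
            extra = ["influenza"] if phase == "sars_cov_2" else []
            if phase == "sars_cov_2" and not (
                    set(phases[phases == "influenza"].index)
                    & {s.sample_id for s in cohort.samples}):
                logger.warning(
                    "%s: SARS-CoV-2 phase without influenza samples; "
                    "subtraction chain uses the pre-dose set only", ind)
            pre, post = _phase_pre_union(
                cohort, phases, phase, config.dose_day.get(phase, 0), extra)
            if post is None:
                logger.warning("%s/%s: no post-dose samples", ind, phase)
                continue
            labels, stacked = classify_post_vaccination(post, pre)
            _write_tsv(_labels_frame(labels),
                       d / phase / "post_vaccination_labels.tsv")
            _write_tsv(stacked, d / phase / "post_vaccination_fractions.tsv")
            subtracted, removal = subtract_baseline(post, pre)
            _write_tsv(removal, d / phase / "subtraction_report.tsv")
            not_pre = {k for k, lab in labels.items()
                       if lab.post_vaccination_class != "ovl_pre"}
            responsive = min_timepoint_filter(
                {k: labels[k] for k in not_pre}, t_min=config.t_min)
            (d / phase).mkdir(parents=True, exist_ok=True)
            (d / phase / "responsive_clonotypes.txt").write_text(
                f"# scheme={config.scheme} t_min={config.t_min}\n"
                + "".join(f"{k}\n" for k in sorted(responsive)))
            if len(subtracted.samples) >= 2:
                calls = detect_dynamic_clonotypes(
                    subtracted, fold=config.fold, min_cells=config.min_cells)
                _write_json({
                    "parameters": {"fold": calls.fold,
                                   "min_cells": calls.min_cells},
                    "increased": sorted(calls.increased),
                    "decreased": sorted(calls.decreased),
                }, d / phase / "dynamic_calls_post_subtraction.json")


def _diversity_stage(config: PipelineConfig,
                     cohorts: dict[str, TimeSeriesCohort],
                     contigs: pd.DataFrame, out: Path) -> None:
    d = out / "diversity"
    for chain in config.diversity_chains:
        sh = shannon_by_sample(contigs, chain=chain)
        if not sh.empty:
            _write_tsv(sh, d / f"shannon_{chain}.tsv")
        usage = v_gene_usage(contigs, chain)
        if not usage.empty:
            _write_tsv(usage, d / f"v_usage_{chain}.tsv", index=True)
    for ind, cohort in cohorts.items():
        if len(cohort.samples) < 2:
            continue
        with_tp = cohort_contigs(cohort, contigs)
        overlaps = pd.concat(
            [chain_overlap_ratio(with_tp, ch) for ch in config.diversity_chains],
            ignore_index=True)
        _write_tsv(overlaps, d / ind / "chain_overlap.tsv")
        iso = isotype_composition(with_tp)
        if not iso.empty:
            _write_tsv(iso, d / ind / "isotype_composition.tsv", index=True)


def _manifest_stage(config: PipelineConfig, out: Path) -> None:
    config_json = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    outputs = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    _write_json({
        "clonotrack_version": __version__,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "parameters": {"scheme": config.scheme, "fold": config.fold,
                       "min_cells": config.min_cells, "t_min": config.t_min},
        "outputs": outputs,
    }, out / "manifest.json")
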