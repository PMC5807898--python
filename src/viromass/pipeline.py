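"""End-to-end orchestration: measured inputs to an integrated report bundle.

Stages — mass apportioning, library QC, taxonomic profiling, ordination — run
in order from a single structured config; each stage writes its own TSV/JSON
artifacts, and a manifest records every emitted file with a content digest so
reruns can be verified byte-for-byte.  A failing stage halts the run with a
stage-labelled error; artifacts of completed stages are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import __version__
from .apportion import (
    ApportionReport,
    DEFAULT_DS_SIZE_KB,
    DEFAULT_SS_RANGE,
    build_report,
    read_samples_tsv,
)
from .constants import DEFAULT_CONSTANTS, Constants
from .ordination import pca_fit, to_proportions
from .profiler import (
    DEFAULT_MAX_EVALUE,
    DEFAULT_MIN_BITSCORE,
    DEFAULT_TOP_PERCENT,
    assign_reads,
    build_profile,
    collapse_minor,
    parse_blast_tab,
    read_subject_map,
)
from .qc import DEFAULT_RRNA_THRESHOLD_PERCENT, qc_evaluate, summarize_library
from .taxonomy import GenomeSizeRange, default_taxonomy, read_taxonomy_tsv

logger = logging.getLogger("viromass")

ALL_STAGES = ("apportion", "qc", "profile", "ordinate")


class PipelineError(RuntimeError):
    pass


class StageError(PipelineError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class LibraryConfig:
    library_id: str
    hits: Optional[str] = None
    subject_map: Optional[str] = None
    reads: Optional[str] = None
    rrna_reads: int = 0


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    samples: Optional[str] = None
    taxonomy: Optional[str] = None  # None -> packaged default registry
    libraries: tuple[LibraryConfig, ...] = ()
    stages: tuple[str, ...] = ALL_STAGES
    ss_range: GenomeSizeRange = field(default_factory=lambda: DEFAULT_SS_RANGE)
    ds_size_kb: float = DEFAULT_DS_SIZE_KB
    constants: Constants = DEFAULT_CONSTANTS
    max_evalue: float = DEFAULT_MAX_EVALUE
    min_bitscore: float = DEFAULT_MIN_BITSCORE
    top_percent: float = DEFAULT_TOP_PERCENT
    scheme: str = "family"
    collapse_percent: float = 2.0
    qc_threshold: float = DEFAULT_RRNA_THRESHOLD_PERCENT
    n_components: int = 2
    hellinger: bool = False

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise PipelineError(f"unknown stage {stage!r}; expected {ALL_STAGES}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        libs = tuple(
            LibraryConfig(
                library_id=str(entry["library_id"]),
                hits=entry.get("hits"),
                subject_map=entry.get("subject_map"),
                reads=entry.get("reads"),
                rrna_reads=int(entry.get("rrna_reads", 0)),
            )
            for entry in raw.get("libraries", [])
        )
        ss = raw.get("ss_range", [DEFAULT_SS_RANGE.min_kb, DEFAULT_SS_RANGE.max_kb])
        return cls(
            out_dir=str(raw["out_dir"]),
            samples=raw.get("samples"),
            taxonomy=raw.get("taxonomy"),
            libraries=libs,
            stages=tuple(raw.get("stages", ALL_STAGES)),
            ss_range=GenomeSizeRange(float(ss[0]), float(ss[1])),
            ds_size_kb=float(raw.get("ds_size_kb", DEFAULT_DS_SIZE_KB)),
            max_evalue=float(raw.get("max_evalue", DEFAULT_MAX_EVALUE)),
            min_bitscore=float(raw.get("min_bitscore", DEFAULT_MIN_BITSCORE)),
            top_percent=float(raw.get("top_percent", DEFAULT_TOP_PERCENT)),
            scheme=str(raw.get("scheme", "family")),
            collapse_percent=float(raw.get("collapse_percent", 2.0)),
            qc_threshold=float(raw.get("qc_threshold", DEFAULT_RRNA_THRESHOLD_PERCENT)),
            n_components=int(raw.get("n_components", 2)),
            hellinger=bool(raw.get("hellinger", False)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_apportion_report(config: RunConfig) -> ApportionReport:
    """Apportion stage: samples TSV in, Table-1-style report TSV + JSON out."""
    if config.samples is None:
        raise PipelineError("apportion stage needs a samples file")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = read_samples_tsv(config.samples)
    logger.info(
        "apportion: %d samples, ss range %.1f-%.1f kb, ds %.1f kb, "
        "mw_ss_per_nt=%.1f g/mol, viromass %s",
        len(samples), config.ss_range.min_kb, config.ss_range.max_kb,
        config.ds_size_kb, config.constants.mw_ss_per_nt, __version__,
    )
    report = build_report(
        samples,
        ss_range=config.ss_range,
        ds_size_kb=config.ds_size_kb,
        constants=config.constants,
    )
    report.to_tsv(out / "apportion_report.tsv")
    report.to_json(out / "apportion_report.json")
    return report


def run_full(config: RunConfig) -> dict:
    """Run all enabled stages; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "stages_run": [],
        "stages_skipped": [s for s in ALL_STAGES if s not in config.stages],
        "warnings": [],
        "files": {},
    }
    tree = (
        read_taxonomy_tsv(config.taxonomy)
        if config.taxonomy is not None
        else default_taxonomy()
    )

    if "apportion" in config.stages:
        try:
            run_apportion_report(config)
        except Exception as exc:  # noqa: BLE001 - stage-labelled re-raise
            raise StageError("apportion", exc) from exc
        manifest["stages_run"].append("apportion")

    qc_ids: list[str] = []
    if "qc" in config.stages:
        try:
            rows = []
            for lib in config.libraries:
                if lib.reads is None:
                    continue
                summary = summarize_library(lib.reads, library_id=lib.library_id)
                result = qc_evaluate(summary, lib.rrna_reads, config.qc_threshold)
                qc_ids.append(lib.library_id)
                rows.append(
                    {
                        "library_id": lib.library_id,
                        "n_reads": summary.n_reads,
                        "mean_length_bp": round(summary.mean_length, 1),
                        "total_length_mb": round(summary.total_length_mb, 3),
                        "gc_percent": round(summary.gc_percent, 1),
                        "n_rrna_reads": result.n_rrna_reads,
                        "rrna_ratio_percent": result.ratio_display,
                        "passed": result.passed,
                    }
                )
            if rows:
                import pandas as pd

                pd.DataFrame(rows).to_csv(out / "qc_summary.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("qc", exc) from exc
        manifest["stages_run"].append("qc")

    profiles = []
    if "profile" in config.stages:
        try:
            for lib in config.libraries:
                if lib.hits is None:
                    continue
                parsed = parse_blast_tab(lib.hits)
                subject_map = (
                    read_subject_map(lib.subject_map) if lib.subject_map else None
                )
                assignments = assign_reads(
                    parsed.hits,
                    tree,
                    max_evalue=config.max_evalue,
                    min_bitscore=config.min_bitscore,
                    top_percent=config.top_percent,
                    subject_map=subject_map,
                )
                profile = build_profile(
                    assignments, tree, scheme=config.scheme, library_id=lib.library_id
                )
                profile = collapse_minor(profile, config.collapse_percent, tree)
                profile.to_tsv(out / f"profile_{lib.library_id}.tsv")
                profiles.append(profile)
        except Exception as exc:  # noqa: BLE001
            raise StageError("profile", exc) from exc
        manifest["stages_run"].append("profile")
        orphans = sorted(
            set(qc_ids).symmetric_difference(p.library_id for p in profiles)
        )
        if qc_ids and orphans:
            msg = f"library ids present in only one of qc/profiles: {orphans}"
            manifest["warnings"].append(msg)
            logger.warning(msg)

    if "ordinate" in config.stages:
        try:
            if len(profiles) < 2:
                raise PipelineError(
                    "ordination needs >= 2 profiled libraries; "
                    "enable the profile stage with at least two hit tables"
                )
            matrix = to_proportions(profiles)
            model = pca_fit(
                matrix, n_components=config.n_components, hellinger=config.hellinger
            )
            model.sample_scores.to_csv(
                out / "pca_scores.tsv", sep="\t", index_label="sample_id"
            )
            model.loadings.to_csv(
                out / "pca_loadings.tsv", sep="\t", index_label="component"
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("ordinate", exc) from exc
        manifest["stages_run"].append("ordinate")

    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
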