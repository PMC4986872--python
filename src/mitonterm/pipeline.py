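"""End-to-end orchestration: ingest -> filter -> call -> motifs -> properties.

Each stage is a thin composition of the library modules; every intermediate
artifact is written to the output directory so any stage can be re-run in
isolation. Failures are re-raised with the stage name attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calling import (
    StabilityTable,
    SubstrateCall,
    call_icp55_all,
    call_oct1_all,
    write_calls,
)
from .filtering import FilterReport, run_filters, write_assignments
from .io import (
    NTerminalAssignment,
    ProteinRecord,
    QuantifiedPeptide,
    map_peptides,
    read_fasta,
    read_localization_table,
    read_peptide_table,
)
from .motifs import (
    MotifProfile,
    build_pfm,
    consensus_string,
    extract_window,
    icelogo_diff,
    reference_frequencies,
    write_profile,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run."""

    proteome: str | Path
    localization: str | Path
    peptide_tables: dict[str, str | Path]  # comparison_id -> path
    icp55_comparisons: tuple[str, ...] = ("icp55",)
    oct1_comparisons: tuple[str, ...] = ("oct1_1", "oct1_2")
    primary_fold: float = 3.0
    secondary_fold: float = 1.5
    max_start: int = 120
    min_lines: int = 1
    extra_unstable: str = ""  # residues added to the N-end-rule unstable set
    alpha: float = 0.05
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.primary_fold <= 1 or self.secondary_fold <= 1:
            raise ValueError("fold thresholds must exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class ReportBundle:
    """Everything a full run produces."""

    assignments: dict[str, list[NTerminalAssignment]]
    filter_reports: dict[str, FilterReport]
    icp55_calls: list[SubstrateCall]
    oct1_calls: list[SubstrateCall]
    icp55_profile: MotifProfile | None
    oct1_profile: MotifProfile | None
    icp55_consensus: str | None
    oct1_consensus: str | None
    raw_differential: list[QuantifiedPeptide]

    def summary(self) -> dict:
        primary = {c.accession for c in self.icp55_calls if c.tier == "primary"}
        secondary = {c.accession for c in self.icp55_calls
                     if c.tier == "secondary"} - primary
        return {
            "icp55_primary_proteins": len(primary),
            "icp55_secondary_proteins": len(secondary),
            "icp55_total_proteins": len(primary | secondary),
            "oct1_proteins": len({c.accession for c in self.oct1_calls}),
            "icp55_consensus": self.icp55_consensus,
            "oct1_consensus": self.oct1_consensus,
        }


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("ingest")
def _ingest(config: PipelineConfig):
    proteins = {p.accession: p for p in read_fasta(config.proteome)}
    localization = read_localization_table(config.localization)
    peptides: dict[str, list[QuantifiedPeptide]] = {}
    for comp, path in config.peptide_tables.items():
        peps, rejected = read_peptide_table(path)
        if not peps:
            raise ValueError(f"{path}: peptide table is empty")
        for raw, reason in rejected:
            logger.warning("%s: rejected %s (%s)", comp, raw, reason)
        peptides[comp] = peps
    return proteins, localization, peptides


@_stage("mapping")
def _map(peptides, proteins):
    mapped = {}
    for comp, peps in peptides.items():
        ok, excluded = map_peptides(peps, proteins)
        for pep, reason in excluded:
            logger.warning("%s: excluded %s (%s)", comp, pep.peptide, reason)
        mapped[comp] = ok
    return mapped


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the whole analysis described by ``config``."""
    proteins, localization, raw_peptides = _ingest(config)
    mapped = _map(raw_peptides, proteins)

    # -- filtering, per comparison sample -------------------------------
    assignments: dict[str, list[NTerminalAssignment]] = {}
    reports: dict[str, FilterReport] = {}
    retained: dict[str, list[QuantifiedPeptide]] = {}
    try:
        for comp, peps in mapped.items():
            a, r, rep = run_filters(
                peps, localization, proteins,
                max_start=config.max_start,
                differential_threshold=config.primary_fold,
            )
            assignments[comp], retained[comp], reports[comp] = a, r, rep
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filtering", str(exc)) from exc

    # -- substrate calling ----------------------------------------------
    stability = StabilityTable().with_unstable(config.extra_unstable)
    try:
        icp55_peps = [
            p for comp in config.icp55_comparisons for p in retained.get(comp, [])
        ]
        icp55_calls = call_icp55_all(
            icp55_peps, proteins, stability=stability,
            primary_fold=config.primary_fold,
            secondary_fold=config.secondary_fold,
        )
        oct1_peps = [
            p for comp in config.oct1_comparisons for p in retained.get(comp, [])
        ]
        oct1_calls = call_oct1_all(
            oct1_peps, proteins, fold=config.primary_fold,
            min_lines=config.min_lines,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("calling", str(exc)) from exc

    raw_differential = [
        p for p in icp55_peps
        if p.fold_change >= config.primary_fold
    ]

    # -- cleavage motifs ------------------------------------------------
    try:
        ref = reference_frequencies(proteins.values())
        icp55_profile = icp55_consensus = None
        if icp55_calls:
            windows = [
                extract_window(proteins[c.accession].sequence, c.mature_start)
                for c in icp55_calls if c.mature_start is not None
            ]
            icp55_profile = icelogo_diff(build_pfm(windows), ref, config.alpha)
            icp55_consensus = consensus_string(icp55_profile,
                                               alpha=config.alpha)
        oct1_profile = oct1_consensus = None
        if oct1_calls:
            windows = []
            for c in oct1_calls:
                site = c.mature_start if c.mature_start is not None \
                    else c.intermediate_start
                windows.append(
                    extract_window(proteins[c.accession].sequence, site))
            oct1_profile = icelogo_diff(build_pfm(windows), ref, config.alpha)
            oct1_consensus = consensus_string(oct1_profile, alpha=config.alpha)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("motifs", str(exc)) from exc

    bundle = ReportBundle(
        assignments=assignments,
        filter_reports=reports,
        icp55_calls=icp55_calls,
        oct1_calls=oct1_calls,
        icp55_profile=icp55_profile,
        oct1_profile=oct1_profile,
        icp55_consensus=icp55_consensus,
        oct1_consensus=oct1_consensus,
        raw_differential=raw_differential,
    )
    if config.outdir is not None:
        _write_bundle(bundle, config)
    return bundle


@_stage("report")
def _write_bundle(bundle: ReportBundle, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for comp, report in bundle.filter_reports.items():
        report.write(outdir / f"filter_report_{comp}.tsv")
    for comp, assigns in bundle.assignments.items():
        write_assignments(assigns, outdir / f"assignments_{comp}.tsv")
    write_calls(bundle.icp55_calls, outdir / "calls_icp55.tsv")
    write_calls(bundle.oct1_calls, outdir / "calls_oct1.tsv")
    if bundle.icp55_profile is not None:
        write_profile(bundle.icp55_profile, outdir / "motif_icp55")
    if bundle.oct1_profile is not None:
        write_profile(bundle.oct1_profile, outdir / "motif_oct1")
    summary = bundle.summary()
    manifest = {
        "mitonterm_version": __version__,
        "pandas_version": pd.__version__,
        "parameters": {
            "primary_fold": config.primary_fold,
            "secondary_fold": config.secondary_fold,
            "max_start": config.max_start,
            "min_lines": config.min_lines,
            "extra_unstable": config.extra_unstable,
            "alpha": config.alpha,
        },
        "summary": summary,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, allow_unicode=True, sort_keys=False)
    with open(outdir / "summary.txt", "w") as fh:
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
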