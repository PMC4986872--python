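"""Curation of credible N-terminal peptides and per-protein N-terminus assignment.

Three criteria, applied in order, turn the raw identified peptide list into a
set of believable protein N-termini:

1. keep only peptides from proteins with a consensus localization of
   ``mitochondrial`` (the samples are isolated mitochondria; anything else is
   co-purifying contamination),
2. discard peptides starting after residue 120 of the full-length protein
   (deep-internal peptides are almost certainly degradation products, since
   known targeting presequences top out around 117 residues),
3. per protein, take the most N-terminal remaining peptide as the mature
   N-terminus; peptides starting further downstream are kept as evidence only
   when their knockout/wild-type abundance ratio is differential (they are
   then processing intermediates, not degradation).

A protein whose mature N-terminus is at position 1 or 2 carries no cleavable
presequence (translation start, with or without initiator-Met excision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import NTerminalAssignment, ProteinRecord, QuantifiedPeptide

#: Mature start at or before this position means "no presequence".
NO_PRESEQUENCE_MAX_START = 2

#: Peptides starting after this residue are treated as degradation products.
DEFAULT_MAX_START = 120

#: Fold-change gate reused for the "keep differential non-minimal peptides"
#: exception of the representative-selection rule.
DEFAULT_DIFFERENTIAL_THRESHOLD = 3.0


@dataclass
class FilterReport:
    """Counts and per-peptide reasons for each curation stage."""

    n_input: int = 0
    n_after_localization: int = 0
    n_after_position: int = 0
    n_final: int = 0
    discarded: list[tuple[QuantifiedPeptide, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_input != self.n_final + len(self.discarded):
            raise AssertionError(
                f"peptide conservation violated: {self.n_input} in, "
                f"{self.n_final} kept + {len(self.discarded)} discarded"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"accession": p.accession, "peptide": p.peptide,
             "comparison_id": p.comparison_id, "reason": reason}
            for p, reason in self.discarded
        ]
        return pd.DataFrame(rows, columns=["accession", "peptide",
                                           "comparison_id", "reason"])

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# n_input\t{self.n_input}\n")
            fh.write(f"# n_after_localization\t{self.n_after_localization}\n")
            fh.write(f"# n_after_position\t{self.n_after_position}\n")
            fh.write(f"# n_final\t{self.n_final}\n")
        self.to_frame().to_csv(path, sep="\t", index=False, mode="a")


def filter_localization(
    peptides: Iterable[QuantifiedPeptide],
    localization_map: Mapping[str, str],
    required_label: str = "mitochondrial",
) -> tuple[list[QuantifiedPeptide], list[tuple[QuantifiedPeptide, str]]]:
    """Keep peptides whose protein carries the required consensus label.

    Accessions absent from the map are discarded with reason
    ``no_localization`` rather than silently kept.
    """
    kept, discarded = [], []
    for pep in peptides:
        label = localization_map.get(pep.accession)
        if label is None:
            discarded.append((pep, "no_localization"))
        elif label != required_label:
            discarded.append((pep, f"localization:{label}"))
        else:
            kept.append(pep)
    return kept, discarded


def filter_start_position(
    peptides: Iterable[QuantifiedPeptide],
    max_start: int = DEFAULT_MAX_START,
) -> tuple[list[QuantifiedPeptide], list[tuple[QuantifiedPeptide, str]]]:
    """Discard peptides identified after residue ``max_start``.

    The boundary is inclusive-keep: a peptide starting exactly at
    ``max_start`` survives; only peptides *after* it are discarded.
    """
    kept, discarded = [], []
    for pep in peptides:
        if pep.start is None:
            raise ValueError(
                f"{pep.accession} {pep.peptide}: peptide not mapped; "
                "run mapping before position filtering"
            )
        if pep.start <= max_start:
            kept.append(pep)
        else:
            discarded.append((pep, f"start>{max_start}"))
    return kept, discarded


def _is_differential(pep: QuantifiedPeptide, threshold: float) -> bool:
    r = pep.ratio_mut_over_wt
    return r >= threshold or r <= 1.0 / threshold


def select_representative_ntermini(
    peptides: Iterable[QuantifiedPeptide],
    differential_threshold: float = DEFAULT_DIFFERENTIAL_THRESHOLD,
) -> tuple[list[NTerminalAssignment], list[QuantifiedPeptide],
           list[tuple[QuantifiedPeptide, str]]]:
    """Assign each protein its most N-terminal peptide as the true N-terminus.

    Non-minimal peptides are retained as processing-intermediate evidence iff
    differential (>= ``differential_threshold``-fold in either direction) in
    any comparison; otherwise they are dropped as internal. Ties at the
    minimal start (e.g. the same terminus seen in several comparisons or with
    different C-termini) all stay as evidence.

    Returns ``(assignments, retained_peptides, dropped)`` where
    ``retained_peptides`` contains every peptide kept (minimal-start and
    differential non-minimal ones).
    """
    by_acc: dict[str, list[QuantifiedPeptide]] = {}
    for pep in peptides:
        if pep.start is None:
            raise ValueError(f"{pep.accession} {pep.peptide}: peptide not mapped")
        by_acc.setdefault(pep.accession, []).append(pep)

    assignments: list[NTerminalAssignment] = []
    retained: list[QuantifiedPeptide] = []
    dropped: list[tuple[QuantifiedPeptide, str]] = []
    for acc in sorted(by_acc):
        group = by_acc[acc]
        if not group:
            raise ValueError(f"{acc}: empty peptide group")
        min_start = min(p.start for p in group)
        evidence: list[QuantifiedPeptide] = []
        for pep in sorted(group, key=lambda p: (p.start, p.peptide)):
            if pep.start == min_start or _is_differential(pep, differential_threshold):
                evidence.append(pep)
            else:
                dropped.append((pep, "internal_non_differential"))
        retained.extend(evidence)
        assignments.append(_build_assignment(acc, min_start, evidence))
    return assignments, retained, dropped


def _build_assignment(
    accession: str, mature_start: int, evidence: Sequence[QuantifiedPeptide]
) -> NTerminalAssignment:
    status = "no_presequence" if mature_start <= NO_PRESEQUENCE_MAX_START else "processed"
    # The presequence string requires the protein sequence; it is attached by
    # classify_presequence_status when a proteome is available.
    return NTerminalAssignment(
        accession=accession,
        mature_start=mature_start,
        presequence="?" * (mature_start - 1),
        status=status,
        evidence_peptides=list(evidence),
    )


def classify_presequence_status(
    assignment: NTerminalAssignment,
    protein: ProteinRecord | None = None,
) -> NTerminalAssignment:
    """Finalize the processed / no-presequence call and attach the presequence.

    ``no_presequence`` iff the mature start is at position 1 or 2; when the
    protein sequence is supplied the presequence string (residues
    1..mature_start-1) is attached for processed proteins.
    """
    status = (
        "no_presequence"
        if assignment.mature_start <= NO_PRESEQUENCE_MAX_START
        else "processed"
    )
    if protein is not None:
        preseq = protein.sequence[: assignment.mature_start - 1]
    else:
        preseq = assignment.presequence
    return NTerminalAssignment(
        accession=assignment.accession,
        mature_start=assignment.mature_start,
        presequence=preseq,
        status=status,
        evidence_peptides=assignment.evidence_peptides,
    )


def run_filters(
    peptides: Sequence[QuantifiedPeptide],
    localization_map: Mapping[str, str],
    proteins: Mapping[str, ProteinRecord] | None = None,
    required_label: str = "mitochondrial",
    max_start: int = DEFAULT_MAX_START,
    differential_threshold: float = DEFAULT_DIFFERENTIAL_THRESHOLD,
) -> tuple[list[NTerminalAssignment], list[QuantifiedPeptide], FilterReport]:
    """Apply the three curation criteria in order and build assignments."""
    report = FilterReport(n_input=len(peptides))
    kept, disc = filter_localization(peptides, localization_map, required_label)
    report.discarded.extend(disc)
    report.n_after_localization = len(kept)

    kept, disc = filter_start_position(kept, max_start)
    report.discarded.extend(disc)
    report.n_after_position = len(kept)

    assignments, retained, dropped = select_representative_ntermini(
        kept, differential_threshold
    )
    report.discarded.extend(dropped)
    report.n_final = len(retained)
    report.validate()

    if proteins is not None:
        assignments = [
            classify_presequence_status(a, proteins.get(a.accession))
            for a in assignments
        ]
    return assignments, retained, report


def write_assignments(
    assignments: Iterable[NTerminalAssignment], path: str | Path
) -> None:
    rows = [
        {
            "accession": a.accession,
            "mature_start": a.mature_start,
            "status": a.status,
            "presequence": a.presequence,
        }
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
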