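"""Shared data model and readers/writers for the formats the pipeline touches.

The pipeline works on four kinds of tabular/sequence inputs:

* a protein sequence collection (FASTA),
* quantified N-terminal peptide tables (tab-separated; one row per identified
  N-terminally blocked peptide with its mutant/wild-type abundance ratio),
* a subcellular-localization table (accession -> consensus location label),
* optional cleavage-site prediction tables (accession -> predicted position).

Coordinates are 1-based and inclusive on both ends throughout, so a peptide
spanning residues 44..56 of its protein has ``start=44, end=56`` and
``protein.sequence[43:56] == peptide``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids plus 'X' for unknown residues.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_ALPHABET = frozenset(AMINO_ACIDS + "X")

PEPTIDE_TABLE_COLUMNS = [
    "accession",
    "peptide",
    "nterm_mod",
    "comparison_id",
    "ratio_mut_over_wt",
]


class ParseError(ValueError):
    """Raised when an input file violates the documented format."""


class MappingError(ValueError):
    """Raised when a peptide cannot be placed uniquely on its protein."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional localization annotation."""

    accession: str
    sequence: str
    description: str = ""
    location_label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ParseError(
                f"{self.accession}: invalid residues {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"{self.accession}: position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass
class QuantifiedPeptide:
    """One identified N-terminally blocked peptide with its quantification.

    ``ratio_mut_over_wt`` is oriented mutant/wild-type throughout the package:
    a peptide "upregulated in the knockout" has ratio >= threshold, one
    "downregulated" has ratio <= 1/threshold.
    """

    accession: str
    peptide: str
    nterm_mod: str  # "dimethyl" or "acetyl"
    comparison_id: str  # e.g. "icp55", "oct1_1", "oct1_2"
    ratio_mut_over_wt: float
    start: int | None = None  # 1-based position of the first residue
    end: int | None = None  # 1-based inclusive last position
    confidence: bool = True

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ParseError(f"{self.accession}: empty peptide")
        bad = set(self.peptide) - VALID_ALPHABET
        if bad:
            raise ParseError(
                f"{self.accession}: invalid residues {sorted(bad)} in peptide"
            )
        if not self.ratio_mut_over_wt > 0:
            raise ParseError(
                f"{self.accession} {self.peptide}: ratio must be > 0, "
                f"got {self.ratio_mut_over_wt}"
            )
        if self.start is not None and self.start < 1:
            raise ParseError(f"{self.accession}: start must be >= 1")

    @property
    def fold_change(self) -> float:
        """Magnitude of change regardless of direction (always >= 1)."""
        r = self.ratio_mut_over_wt
        return max(r, 1.0 / r)

    @property
    def direction(self) -> str:
        """'up' if more abundant in the mutant, 'down' if less, 'flat' if equal."""
        if self.ratio_mut_over_wt > 1.0:
            return "up"
        if self.ratio_mut_over_wt < 1.0:
            return "down"
        return "flat"


@dataclass
class NTerminalAssignment:
    """A protein's inferred mature N-terminus.

    ``status`` is ``no_presequence`` iff the mature start is at position 1 or 2
    (the initiator methionine, or the residue exposed by its removal);
    otherwise the protein is ``processed`` and ``presequence`` holds residues
    1..mature_start-1.
    """

    accession: str
    mature_start: int
    presequence: str
    status: str
    evidence_peptides: list[QuantifiedPeptide] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.presequence) != self.mature_start - 1:
            raise ValueError(
                f"{self.accession}: presequence length {len(self.presequence)} "
                f"inconsistent with mature_start {self.mature_start}"
            )
        expected = "no_presequence" if self.mature_start <= 2 else "processed"
        if self.status != expected:
            raise ValueError(
                f"{self.accession}: status {self.status!r} inconsistent with "
                f"mature_start {self.mature_start}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The accession is the first whitespace-delimited token of the header;
    the remainder of the header becomes the description. Sequences are
    uppercased on read. Duplicate accessions are an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate accession {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(
            ProteinRecord(
                accession=rec.id,
                sequence=str(rec.seq).upper(),
                description=desc,
            )
        )
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Peptide tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_peptide_table(
    path: str | Path,
) -> tuple[list[QuantifiedPeptide], list[tuple[dict, str]]]:
    """Read a tab-separated quantified peptide table.

    Required columns: accession, peptide, nterm_mod, comparison_id,
    ratio_mut_over_wt. Optional: start. Lines beginning with '#' are ignored.

    Returns ``(peptides, rejected)`` where ``rejected`` holds the raw row
    and the reason it failed validation; rejected rows are also logged.
    """
    df = _read_table(path)
    missing = [c for c in PEPTIDE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    peptides: list[QuantifiedPeptide] = []
    rejected: list[tuple[dict, str]] = []
    for _, row in df.iterrows():
        raw = row.to_dict()
        try:
            ratio = float(row["ratio_mut_over_wt"])
            start = None
            if "start" in df.columns and pd.notna(row.get("start")):
                start = int(float(row["start"]))
            pep = QuantifiedPeptide(
                accession=str(row["accession"]),
                peptide=str(row["peptide"]),
                nterm_mod=str(row["nterm_mod"]),
                comparison_id=str(row["comparison_id"]),
                ratio_mut_over_wt=ratio,
                start=start,
            )
        except (ParseError, TypeError, ValueError) as exc:
            logger.warning("rejected row %s: %s", raw, exc)
            rejected.append((raw, str(exc)))
            continue
        peptides.append(pep)
    return peptides, rejected


def write_peptide_table(peptides: Iterable[QuantifiedPeptide], path: str | Path) -> None:
    rows = []
    for p in peptides:
        rows.append(
            {
                "accession": p.accession,
                "peptide": p.peptide,
                "nterm_mod": p.nterm_mod,
                "comparison_id": p.comparison_id,
                "ratio_mut_over_wt": p.ratio_mut_over_wt,
                "start": p.start,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Peptide-to-protein mapping
# ---------------------------------------------------------------------------

def map_peptide_to_protein(
    peptide: QuantifiedPeptide,
    protein: ProteinRecord,
    collapse_il: bool = False,
) -> QuantifiedPeptide:
    """Locate a peptide on its protein by unique exact substring match.

    I and L are distinct by default (``collapse_il=False``); collapsing them
    is available for databases where isobaric residues were merged upstream,
    at the cost of possible false ambiguities.

    Raises :class:`MappingError` if the peptide does not occur, or occurs
    more than once, in the protein sequence.
    """
    seq, query = protein.sequence, peptide.peptide
    if collapse_il:
        seq = seq.replace("L", "I")
        query = query.replace("L", "I")
    first = seq.find(query)
    if first < 0:
        raise MappingError(
            f"{peptide.peptide} not found in {protein.accession}"
        )
    second = seq.find(query, first + 1)
    if second >= 0:
        raise MappingError(
            f"{peptide.peptide} matches {protein.accession} at positions "
            f"{first + 1} and {second + 1}: ambiguous"
        )
    return replace(peptide, start=first + 1, end=first + len(query))


def map_peptides(
    peptides: Iterable[QuantifiedPeptide],
    proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
) -> tuple[list[QuantifiedPeptide], list[tuple[QuantifiedPeptide, str]]]:
    """Map a collection of peptides onto their proteins by accession.

    Peptides whose accession is absent, or whose sequence is unmappable or
    ambiguous, are excluded and returned with a diagnostic.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.accession: p for p in proteins}
    mapped: list[QuantifiedPeptide] = []
    excluded: list[tuple[QuantifiedPeptide, str]] = []
    for pep in peptides:
        prot = proteins.get(pep.accession)
        if prot is None:
            excluded.append((pep, "accession not in proteome"))
            continue
        try:
            mapped.append(map_peptide_to_protein(pep, prot))
        except MappingError as exc:
            logger.warning("excluded peptide %s: %s", pep.peptide, exc)
            excluded.append((pep, str(exc)))
    return mapped, excluded


# ---------------------------------------------------------------------------
# Localization and prediction tables
# ---------------------------------------------------------------------------

def read_localization_table(path: str | Path) -> dict[str, str]:
    """Read a two-column accession -> location table (SUBAcon-style).

    Labels are normalized to lowercase. A duplicated accession with a
    conflicting label is an error; a consistent duplicate is tolerated.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (accession, location)")
    acc_col, loc_col = df.columns[:2]
    table: dict[str, str] = {}
    for _, row in df.iterrows():
        acc = str(row[acc_col]).strip()
        label = str(row[loc_col]).strip().lower()
        if acc in table and table[acc] != label:
            raise ParseError(
                f"{path}: conflicting localization for {acc}: "
                f"{table[acc]!r} vs {label!r}"
            )
        table[acc] = label
    return table


def write_localization_table(table: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.items()), columns=["accession", "location"]
    ).to_csv(path, sep="\t", index=False)


def read_prediction_table(path: str | Path) -> dict[str, int]:
    """Read an accession -> predicted cleavage position table.

    The position is the 1-based first residue of the predicted mature protein
    (TargetP-style output, pre-converted to two tab-separated columns).
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (accession, position)")
    acc_col, pos_col = df.columns[:2]
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        acc = str(row[acc_col]).strip()
        if acc in out:
            raise ParseError(f"{path}: duplicate accession {acc}")
        out[acc] = int(row[pos_col])
    return out
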