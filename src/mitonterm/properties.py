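"""Targeting-peptide property statistics and cross-study N-termini comparison.

Covers the descriptive statistics used to compare presequence groups
(plant mitochondrial, yeast mitochondrial, chloroplast transit peptides,
dual-targeted signals): length, net charge at a stated pH, amino-acid
composition, a Welch two-sample test for group differences, a tolerance-based
accuracy score for cleavage-site predictors, and a set comparison of mature
N-termini between studies.

Net charge follows the Henderson-Hasselbalch partial-charge model: at pH
``p`` a basic group with dissociation constant ``pKa`` contributes
``1/(1+10^(p-pKa))`` positive charge and an acidic group contributes
``1/(1+10^(pKa-p))`` negative charge. The pKa set is configuration; the
default uses common side-chain values (D 3.65, E 4.25, C 8.3, Y 10.07, H 6.0,
K 10.53, R 12.48) with free termini (N-term 8.0, C-term 3.1) included, since
the quantities of interest are bare excised peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AMINO_ACIDS, ParseError

POSITIVE_RESIDUES = "KRH"
NEGATIVE_RESIDUES = "DECY"


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa values used for net-charge calculation."""

    pka: Mapping[str, float] = field(
        default_factory=lambda: {
            "D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.07,
            "H": 6.0, "K": 10.53, "R": 12.48,
        }
    )
    n_terminus: float = 8.0
    c_terminus: float = 3.1
    include_n_terminus: bool = True
    include_c_terminus: bool = True

    def __post_init__(self) -> None:
        values = list(self.pka.values()) + [self.n_terminus, self.c_terminus]
        if not all(0 < v < 14 for v in values):
            raise ValueError("pKa values must lie in (0, 14)")


@dataclass
class PresequenceRecord:
    """A targeting-signal sequence with its group label and derived properties."""

    accession: str
    group: str  # e.g. at_mito / sc_mito / at_chloro / at_dual
    sequence: str
    length: int = 0
    net_charge: float = 0.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty presequence")
        self.length = len(self.sequence)


def net_charge(
    sequence: str, pH: float = 7.0, pka: PkaSet | None = None
) -> float:
    """Net charge of a peptide at the given pH.

    Unknown residues ('X') contribute nothing. Terminal groups are included
    according to the flags on the :class:`PkaSet`.
    """
    pka = pka or PkaSet()

    def positive(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def negative(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pk - pH))

    charge = 0.0
    for aa in sequence:
        if aa in POSITIVE_RESIDUES:
            charge += positive(pka.pka[aa])
        elif aa in NEGATIVE_RESIDUES:
            charge -= negative(pka.pka[aa])
    if pka.include_n_terminus:
        charge += positive(pka.n_terminus)
    if pka.include_c_terminus:
        charge -= negative(pka.c_terminus)
    return charge


def group_stats(
    records: Sequence[PresequenceRecord],
    pH: float = 7.0,
    pka: PkaSet | None = None,
) -> pd.DataFrame:
    """Per-group summary: n, length stats, mean net charge, residue frequencies.

    Residue frequencies are counts over all residues pooled within the group
    (so longer presequences weigh more), matching how composition is usually
    reported for targeting signals.
    """
    if not records:
        raise ValueError("no presequence records")
    rows = {}
    for group in sorted({r.group for r in records}):
        members = [r for r in records if r.group == group]
        lengths = np.array([r.length for r in members], dtype=float)
        charges = np.array(
            [net_charge(r.sequence, pH=pH, pka=pka) for r in members]
        )
        pooled = "".join(r.sequence for r in members)
        total = sum(pooled.count(aa) for aa in AMINO_ACIDS)
        freqs = {f"freq_{aa}": pooled.count(aa) / total for aa in AMINO_ACIDS}
        rows[group] = {
            "n": len(members),
            "mean_length": lengths.mean(),
            "min_length": lengths.min(),
            "max_length": lengths.max(),
            "mean_net_charge": charges.mean(),
            **freqs,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch two-sample t-test on a property between two groups.

    Degenerate identical zero-variance groups return (0.0, 1.0) by
    convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if a.std() == 0 and b.std() == 0 and len(a) == len(b) and np.allclose(
        np.sort(a), np.sort(b)
    ):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def score_cleavage_predictions(
    predicted: Mapping[str, int],
    truth: Mapping[str, int],
    tolerance: int = 1,
) -> float:
    """Fraction of proteins whose predicted cleavage site is within tolerance.

    Scored over the accessions present in ``truth``; a protein without a
    prediction counts as incorrect. Raises if the maps share no accession.
    """
    shared = set(predicted) & set(truth)
    if not shared:
        raise ValueError("prediction and truth share no accessions")
    correct = sum(
        1
        for acc in truth
        if acc in predicted and abs(predicted[acc] - truth[acc]) <= tolerance
    )
    return correct / len(truth)


def compare_nterm_sets(
    current: Mapping[str, int],
    previous: Mapping[str, int],
) -> tuple[int, int, int, dict[str, int]]:
    """Compare mature-N-terminus positions between two studies.

    Returns ``(n_shared, n_identical, n_different, offsets)`` where
    ``offsets`` maps each differing accession to current - previous.
    """
    shared = set(current) & set(previous)
    offsets = {
        acc: current[acc] - previous[acc]
        for acc in sorted(shared)
        if current[acc] != previous[acc]
    }
    n_shared = len(shared)
    n_different = len(offsets)
    return n_shared, n_shared - n_different, n_different, offsets


def read_presequence_table(path: str | Path) -> list[PresequenceRecord]:
    """Read a tab-separated accession / group / presequence table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["accession", "group", "presequence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return [
        PresequenceRecord(
            accession=str(r["accession"]),
            group=str(r["group"]),
            sequence=str(r["presequence"]).upper(),
        )
        for _, r in df.iterrows()
    ]


def presequence_records_from_assignments(
    assignments: Iterable, group: str
) -> list[PresequenceRecord]:
    """Build presequence records from processed N-terminal assignments."""
    out = []
    for a in assignments:
        if a.status == "processed" and a.presequence and "?" not in a.presequence:
            out.append(
                PresequenceRecord(
                    accession=a.accession, group=group, sequence=a.presequence
                )
            )
    return out
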