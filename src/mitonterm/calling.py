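"""Calling ICP55 and OCT1 substrates from differential N-terminal peptides.

The logic mirrors how intermediate-peptidase substrates betray themselves in a
knockout-vs-wild-type N-terminome. For a substrate of ICP55 (which trims one,
occasionally two, residues off the MPP-generated intermediate):

* in the knockout the *intermediate* N-terminus accumulates (peptide
  upregulated), and/or
* the *mature* N-terminus disappears (peptide downregulated).

Three evidence classes are recognised, in decreasing strength:

``paired``
    Both termini observed, 1-2 residues apart, with the upstream peptide up
    or the downstream peptide down. The removed residues are read directly
    off the protein sequence between the two starts.
``single_down``
    Only the mature terminus observed, downregulated in the knockout; the
    residue immediately preceding it must be destabilizing (N-end rule) for
    the loss to be attributable to a missing trimming step.
``single_up``
    Only the intermediate observed, upregulated, and its first residue is
    destabilizing (the reason the cell trims it).

OCT1 removes a longer stretch (eight residues in yeast, variable here), so
pairing allows offsets up to 20, and evidence from two independent knockout
lines is tracked. Sequential trimming leaves ladders of termini at
consecutive positions whose regulation flips from up (upstream) to down
(downstream); these are detected separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import ProteinRecord, QuantifiedPeptide

#: Classical N-end-rule destabilizing residues (primary, secondary and
#: tertiary classes): bulky hydrophobics, basics, acidics and their amides.
DEFAULT_UNSTABLE = frozenset("FLWYIRKHDENQ")

DEFAULT_PRIMARY_FOLD = 3.0
DEFAULT_SECONDARY_FOLD = 1.5
ICP55_MAX_OFFSET = 2
OCT1_MAX_OFFSET = 20

_EVIDENCE_PRIORITY = {"paired": 3, "ladder": 3, "single_down": 2, "single_up": 1}


@dataclass(frozen=True)
class StabilityTable:
    """Residue -> stable/unstable classification under the N-end rule.

    The classification is configuration, not a claim: plant N-end-rule
    destabilizing sets are not settled, and observed trimmed residues
    occasionally include M and C, so :meth:`with_unstable` lets an analysis
    widen the default set.
    """

    unstable: frozenset[str] = DEFAULT_UNSTABLE

    def __post_init__(self) -> None:
        bad = set(self.unstable) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise ValueError(f"not amino acids: {sorted(bad)}")

    def is_unstable(self, residue: str) -> bool:
        return residue in self.unstable

    def category(self, residue: str) -> str:
        return "unstable" if residue in self.unstable else "stable"

    def with_unstable(self, residues: str) -> "StabilityTable":
        return StabilityTable(self.unstable | set(residues))


@dataclass
class SubstrateCall:
    """A peptidase-substrate verdict for one protein."""

    accession: str
    peptidase: str  # "ICP55" or "OCT1"
    tier: str  # "primary" (fold >= 3) or "secondary" (1.5 <= fold < 3)
    evidence: str  # "paired" / "single_up" / "single_down" / "ladder"
    removed: str  # residues removed by the peptidase ("" if not inferable)
    intermediate_start: int | None
    mature_start: int | None
    fold: float = 1.0
    comparisons_supporting: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.intermediate_start is not None and self.mature_start is not None:
            span = self.mature_start - self.intermediate_start
            if span < 1:
                raise ValueError(
                    f"{self.accession}: mature_start must exceed intermediate_start"
                )
            if len(self.removed) != span:
                raise ValueError(
                    f"{self.accession}: removed {self.removed!r} does not span "
                    f"{self.intermediate_start}..{self.mature_start}"
                )


@dataclass
class Ladder:
    """A chain of >=3 near-consecutive termini with up->down regulation."""

    accession: str
    starts: list[int]
    directions: list[str]
    removed_path: list[str]


def pair_candidate_termini(
    peptides: Sequence[QuantifiedPeptide], max_offset: int
) -> list[tuple[QuantifiedPeptide, QuantifiedPeptide, int]]:
    """All ordered (upstream, downstream) pairs with 1 <= offset <= max_offset."""
    pairs = []
    ordered = sorted(peptides, key=lambda p: (p.start, p.peptide))
    for i, up in enumerate(ordered):
        for down in ordered[i + 1:]:
            offset = down.start - up.start
            if 1 <= offset <= max_offset:
                pairs.append((up, down, offset))
    return pairs


def _tier(fold: float, primary_fold: float) -> str:
    return "primary" if fold >= primary_fold else "secondary"


def _usable(peptides: Iterable[QuantifiedPeptide],
            include_acetylated: bool) -> list[QuantifiedPeptide]:
    out = []
    for p in peptides:
        if p.start is None:
            raise ValueError(f"{p.accession} {p.peptide}: peptide not mapped")
        if p.nterm_mod == "acetyl" and not include_acetylated:
            continue
        out.append(p)
    return out


def call_icp55(
    peptides: Sequence[QuantifiedPeptide],
    protein: ProteinRecord,
    stability: StabilityTable | None = None,
    primary_fold: float = DEFAULT_PRIMARY_FOLD,
    secondary_fold: float = DEFAULT_SECONDARY_FOLD,
    include_acetylated: bool = False,
) -> list[SubstrateCall]:
    """Apply the ICP55 substrate rules to one protein's peptides.

    Returns at most one call (candidate evidence is deduplicated keeping
    paired > single_down > single_up, then the larger fold change).
    Acetylated termini mark in-vivo-blocked N-termini rather than free
    processing intermediates and are excluded by default.
    """
    stability = stability or StabilityTable()
    peps = sorted(_usable(peptides, include_acetylated),
                  key=lambda p: (p.start, p.peptide))
    if not peps:
        return []
    candidates: list[SubstrateCall] = []

    paired_members: set[int] = set()
    for up, down, offset in pair_candidate_termini(peps, ICP55_MAX_OFFSET):
        supporting = []
        if up.ratio_mut_over_wt >= secondary_fold:
            supporting.append(up.ratio_mut_over_wt)
        if down.ratio_mut_over_wt <= 1.0 / secondary_fold:
            supporting.append(1.0 / down.ratio_mut_over_wt)
        if not supporting:
            continue
        fold = max(supporting)
        removed = protein.sequence[up.start - 1: down.start - 1]
        candidates.append(
            SubstrateCall(
                accession=protein.accession,
                peptidase="ICP55",
                tier=_tier(fold, primary_fold),
                evidence="paired",
                removed=removed,
                intermediate_start=up.start,
                mature_start=down.start,
                fold=fold,
                comparisons_supporting=sorted(
                    {up.comparison_id, down.comparison_id}
                ),
            )
        )
        paired_members.update({id(up), id(down)})

    for pep in peps:
        if id(pep) in paired_members:
            continue  # already explained by paired evidence
        r = pep.ratio_mut_over_wt
        if r >= secondary_fold and stability.is_unstable(pep.peptide[0]):
            candidates.append(
                SubstrateCall(
                    accession=protein.accession,
                    peptidase="ICP55",
                    tier=_tier(r, primary_fold),
                    evidence="single_up",
                    removed=pep.peptide[0],
                    intermediate_start=pep.start,
                    mature_start=pep.start + 1,
                    fold=r,
                    comparisons_supporting=[pep.comparison_id],
                )
            )
        elif r <= 1.0 / secondary_fold:
            if pep.start == 1:
                continue  # no preceding residue to attribute the loss to
            preceding = protein.sequence[pep.start - 2]
            if stability.is_unstable(preceding):
                fold = 1.0 / r
                candidates.append(
                    SubstrateCall(
                        accession=protein.accession,
                        peptidase="ICP55",
                        tier=_tier(fold, primary_fold),
                        evidence="single_down",
                        removed=preceding,
                        intermediate_start=pep.start - 1,
                        mature_start=pep.start,
                        fold=fold,
                        comparisons_supporting=[pep.comparison_id],
                    )
                )
    return _dedup(candidates)


def _dedup(candidates: list[SubstrateCall]) -> list[SubstrateCall]:
    if not candidates:
        return []
    best = max(
        candidates, key=lambda c: (_EVIDENCE_PRIORITY[c.evidence], c.fold)
    )
    return [best]


def call_oct1(
    peptides: Sequence[QuantifiedPeptide],
    protein: ProteinRecord,
    fold: float = DEFAULT_PRIMARY_FOLD,
    min_lines: int = 1,
    max_offset: int = OCT1_MAX_OFFSET,
    include_acetylated: bool = False,
) -> list[SubstrateCall]:
    """Apply the OCT1 substrate rules across both knockout-line comparisons.

    A protein is called when at least ``min_lines`` knockout lines show a
    peptide at >= ``fold`` up or down. The removed stretch is read off the
    sequence when an up/down terminus pair within ``max_offset`` residues
    exists; a single regulated terminus leaves ``removed`` empty (strict
    mode ``min_lines=2`` requires both lines to agree).
    """
    peps = _usable(peptides, include_acetylated)
    if not peps:
        return []

    # Per terminus position: which lines support, in which direction.
    by_start: dict[int, dict[str, list[str]]] = {}
    strongest: dict[int, float] = {}
    for p in peps:
        d = by_start.setdefault(p.start, {"up": [], "down": []})
        if p.ratio_mut_over_wt >= fold:
            d["up"].append(p.comparison_id)
        elif p.ratio_mut_over_wt <= 1.0 / fold:
            d["down"].append(p.comparison_id)
        strongest[p.start] = max(strongest.get(p.start, 1.0), p.fold_change)

    regulated = {
        s: d for s, d in by_start.items()
        if len(set(d["up"])) >= min_lines or len(set(d["down"])) >= min_lines
    }
    if not regulated:
        return []

    ups = sorted(s for s, d in regulated.items() if d["up"])
    downs = sorted(s for s, d in regulated.items() if d["down"])

    # Paired evidence: most upstream accumulated intermediate vs most
    # downstream lost mature terminus.
    for u in ups:
        cand = [d for d in downs if 1 <= d - u <= max_offset]
        if cand:
            d = max(cand)
            lines = sorted(set(regulated[u]["up"]) | set(regulated[d]["down"]))
            return [
                SubstrateCall(
                    accession=protein.accession,
                    peptidase="OCT1",
                    tier="primary",
                    evidence="paired",
                    removed=protein.sequence[u - 1: d - 1],
                    intermediate_start=u,
                    mature_start=d,
                    fold=max(strongest[u], strongest[d]),
                    comparisons_supporting=lines,
                )
            ]

    if downs:
        s = max(downs, key=lambda x: strongest[x])
        return [
            SubstrateCall(
                accession=protein.accession,
                peptidase="OCT1",
                tier="primary",
                evidence="single_down",
                removed="",
                intermediate_start=None,
                mature_start=s,
                fold=strongest[s],
                comparisons_supporting=sorted(set(regulated[s]["down"])),
            )
        ]
    s = max(ups, key=lambda x: strongest[x])
    return [
        SubstrateCall(
            accession=protein.accession,
            peptidase="OCT1",
            tier="primary",
            evidence="single_up",
            removed="",
            intermediate_start=s,
            mature_start=None,
            fold=strongest[s],
            comparisons_supporting=sorted(set(regulated[s]["up"])),
        )
    ]


def detect_ladders(
    peptides: Sequence[QuantifiedPeptide],
    protein: ProteinRecord,
    fold: float = DEFAULT_PRIMARY_FOLD,
    max_gap: int = 2,
) -> list[Ladder]:
    """Find sequential-cleavage ladders among one protein's termini.

    A ladder is a maximal chain of >=3 termini at near-consecutive starts
    (gap <= ``max_gap``) whose regulation is non-increasing downstream:
    upregulated (accumulating intermediates), then optionally unchanged,
    then downregulated (lost mature forms).
    """
    by_start: dict[int, float] = {}
    for p in peptides:
        if p.start is None:
            raise ValueError(f"{p.accession} {p.peptide}: peptide not mapped")
        # keep the strongest regulation seen at each terminus
        prev = by_start.get(p.start)
        if prev is None or p.fold_change > max(prev, 1 / prev):
            by_start[p.start] = p.ratio_mut_over_wt

    def label(ratio: float) -> int:
        if ratio >= fold:
            return 2  # up
        if ratio <= 1.0 / fold:
            return 0  # down
        return 1  # flat

    starts = sorted(by_start)
    ladders: list[Ladder] = []
    i = 0
    while i < len(starts):
        chain = [starts[i]]
        j = i
        while (
            j + 1 < len(starts)
            and starts[j + 1] - starts[j] <= max_gap
            and label(by_start[starts[j + 1]]) <= label(by_start[starts[j]])
        ):
            chain.append(starts[j + 1])
            j += 1
        if len(chain) >= 3:
            names = {2: "up", 1: "flat", 0: "down"}
            ladders.append(
                Ladder(
                    accession=protein.accession,
                    starts=chain,
                    directions=[names[label(by_start[s])] for s in chain],
                    removed_path=[
                        protein.sequence[a - 1: b - 1]
                        for a, b in zip(chain, chain[1:])
                    ],
                )
            )
        i = j + 1
    return ladders


# ---------------------------------------------------------------------------
# Whole-table drivers
# ---------------------------------------------------------------------------

def call_icp55_all(
    peptides: Sequence[QuantifiedPeptide],
    proteins: Mapping[str, ProteinRecord],
    **kwargs,
) -> list[SubstrateCall]:
    """Run the ICP55 caller over every protein in a peptide table."""
    by_acc: dict[str, list[QuantifiedPeptide]] = {}
    for p in peptides:
        by_acc.setdefault(p.accession, []).append(p)
    calls: list[SubstrateCall] = []
    for acc in sorted(by_acc):
        calls.extend(call_icp55(by_acc[acc], proteins[acc], **kwargs))
    return calls


def call_oct1_all(
    peptides: Sequence[QuantifiedPeptide],
    proteins: Mapping[str, ProteinRecord],
    **kwargs,
) -> list[SubstrateCall]:
    """Run the OCT1 caller over every protein in a peptide table."""
    by_acc: dict[str, list[QuantifiedPeptide]] = {}
    for p in peptides:
        by_acc.setdefault(p.accession, []).append(p)
    calls: list[SubstrateCall] = []
    for acc in sorted(by_acc):
        calls.extend(call_oct1(by_acc[acc], proteins[acc], **kwargs))
    return calls


def write_calls(calls: Iterable[SubstrateCall], path: str | Path) -> None:
    rows = [
        {
            "accession": c.accession,
            "peptidase": c.peptidase,
            "tier": c.tier,
            "evidence": c.evidence,
            "removed": c.removed,
            "intermediate_start": c.intermediate_start,
            "mature_start": c.mature_start,
            "fold": c.fold,
            "comparisons": ",".join(c.comparisons_supporting),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
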