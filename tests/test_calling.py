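from __future__ import annotations

import itertools
import random

import pytest

from mitonterm.calling import (
    StabilityTable,
    call_icp55,
    call_oct1,
    detect_ladders,
    pair_candidate_termini,
)
from mitonterm.io import ProteinRecord, QuantifiedPeptide

UNSTABLE = StabilityTable().unstable


def _pep(start, ratio, seq, accession="P1", comparison="icp55",
         mod="dimethyl"):
    return QuantifiedPeptide(
        accession=accession, peptide=seq, nterm_mod=mod,
        comparison_id=comparison, ratio_mut_over_wt=ratio,
        start=start, end=start + len(seq) - 1,
    )


def _protein(seq, accession="P1"):
    return ProteinRecord(accession, seq)


# An Oxa1-like context: residues 44..56 are FSTPSDLDSELTR.
OXA1 = _protein("M" + "A" * 42 + "FSTPSDLDSELTR" + "GGK" * 5)


class TestPairing:
    def test_adjacent_termini_pair_once(self):
        peps = [_pep(44, 60.0, "FSTPSDLDSELTR"), _pep(45, 0.02, "STPSDLDSELTR")]
        pairs = pair_candidate_termini(peps, max_offset=2)
        assert len(pairs) == 1 and pairs[0][2] == 1

    def test_three_termini_give_three_pairs(self):
        peps = [_pep(38, 100.0, "FTSEAAADGGQDQILSR"),
                _pep(39, 0.1, "TSEAAADGGQDQILSR"),
                _pep(40, 0.01, "SEAAADGGQDQILSR")]
        offsets = {(u.start, d.start): o
                   for u, d, o in pair_candidate_termini(peps, 2)}
        assert offsets == {(38, 39): 1, (38, 40): 2, (39, 40): 1}

    def test_single_terminus_gives_no_pair(self):
        assert pair_candidate_termini([_pep(10, 5.0, "FSSGSVPER")], 2) == []


class TestIcp55Rules:
    def test_paired_up_and_down_terminus(self):
        peps = [_pep(44, 60.0, "FSTPSDLDSELTR"), _pep(45, 0.02, "STPSDLDSELTR")]
        (call,) = call_icp55(peps, OXA1)
        assert call.evidence == "paired"
        assert call.removed == "F"
        assert call.tier == "primary"
        assert (call.intermediate_start, call.mature_start) == (44, 45)

    def test_paired_with_only_downstream_regulated(self):
        # biotin-synthase-like: the upstream form unchanged, the mature
        # terminus 100x down in the knockout
        seq = "M" + "A" * 24 + "YSSLSAASAEAER" + "KKK"
        prot = _protein(seq)
        peps = [_pep(26, 1.0, "YSSLSAASAEAER"), _pep(27, 0.01, "SSLSAASAEAER")]
        (call,) = call_icp55(peps, prot)
        assert call.evidence == "paired" and call.removed == "Y"

    def test_lone_up_peptide_needs_unstable_first_residue(self):
        seq = "M" + "A" * 20 + "ASESVPDRKKK"
        prot = _protein(seq)
        assert call_icp55([_pep(22, 5.0, "ASESVPDR")], prot) == []

    def test_lone_down_peptide_with_unstable_preceding_residue(self):
        seq = "M" + "A" * 19 + "Y" + "STSFREER" + "KKK"
        prot = _protein(seq)
        (call,) = call_icp55([_pep(22, 0.2, "STSFREER")], prot)
        assert call.evidence == "single_down"
        assert call.removed == "Y" and call.tier == "primary"

    def test_lone_down_at_protein_start_skipped(self):
        prot = _protein("STSFREERKKK")
        assert call_icp55([_pep(1, 0.1, "STSFREER")], prot) == []

    def test_two_residue_removal_via_offset_two_pair(self):
        seq = "M" + "A" * 22 + "FCSQSQFPKESENPSQEQR" + "KK"
        prot = _protein(seq)
        peps = [_pep(24, 10.0, "FCSQSQFPKESENPSQEQR"),
                _pep(26, 0.1, "SQSQFPKESENPSQEQR")]
        (call,) = call_icp55(peps, prot)
        assert call.removed == "FC"

    def test_secondary_tier_for_moderate_fold(self):
        seq = "M" + "A" * 20 + "FSSGSVPERKK"
        prot = _protein(seq)
        (call,) = call_icp55([_pep(22, 2.0, "FSSGSVPER")], prot)
        assert call.tier == "secondary"

    def test_acetylated_termini_excluded_by_default(self):
        seq = "M" + "A" * 20 + "FSSGSVPERKK"
        prot = _protein(seq)
        pep = _pep(22, 10.0, "FSSGSVPER", mod="acetyl")
        assert call_icp55([pep], prot) == []
        assert call_icp55([pep], prot, include_acetylated=True)

    def test_removed_string_matches_protein_subsequence(self):
        peps = [_pep(44, 60.0, "FSTPSDLDSELTR"), _pep(45, 0.02, "STPSDLDSELTR")]
        (call,) = call_icp55(peps, OXA1)
        assert call.removed == OXA1.sequence[
            call.intermediate_start - 1: call.mature_start - 1]

    def test_raising_primary_fold_never_adds_primary_calls(self):
        rng = random.Random(3)
        prot, groups = _random_protein_and_peptides(rng, n_groups=30)
        for peps in groups:
            lo = call_icp55(peps, prot, primary_fold=3.0)
            hi = call_icp55(peps, prot, primary_fold=5.0)
            lo_primary = {c.accession for c in lo if c.tier == "primary"}
            hi_primary = {c.accession for c in hi if c.tier == "primary"}
            assert hi_primary <= lo_primary


# ---------------------------------------------------------------------------
# Brute-force oracle: a literal, enumeration-style restatement of the rules
# ---------------------------------------------------------------------------

def oracle_icp55(peps, protein, primary=3.0, secondary=1.5):
    """Enumerate every candidate evidence item and pick the strongest."""
    peps = sorted((p for p in peps if p.nterm_mod != "acetyl"),
                  key=lambda p: (p.start, p.peptide))
    evidence = []  # (priority, fold, evidence_name, removed)
    in_pair = set()
    for up, down in itertools.permutations(peps, 2):
        off = down.start - up.start
        if not 1 <= off <= 2:
            continue
        folds = []
        if up.ratio_mut_over_wt >= secondary:
            folds.append(up.ratio_mut_over_wt)
        if down.ratio_mut_over_wt <= 1 / secondary:
            folds.append(1 / down.ratio_mut_over_wt)
        if folds:
            evidence.append((3, max(folds), "paired",
                             protein.sequence[up.start - 1: down.start - 1]))
            in_pair.update({(up.start, up.peptide), (down.start, down.peptide)})
    for p in peps:
        if (p.start, p.peptide) in in_pair:
            continue
        if p.ratio_mut_over_wt >= secondary and p.peptide[0] in UNSTABLE:
            evidence.append((1, p.ratio_mut_over_wt, "single_up", p.peptide[0]))
        elif p.ratio_mut_over_wt <= 1 / secondary and p.start > 1:
            prev = protein.sequence[p.start - 2]
            if prev in UNSTABLE:
                evidence.append((2, 1 / p.ratio_mut_over_wt, "single_down",
                                 prev))
    if not evidence:
        return None
    prio, fold, name, removed = max(evidence, key=lambda e: (e[0], e[1]))
    tier = "primary" if fold >= primary else "secondary"
    return (name, removed, tier)


def _random_protein_and_peptides(rng, n_groups=50):
    body = "".join(rng.choice("ASTGVFYLIDEKNQ") for _ in range(120)) + "R"
    prot = _protein("M" + body)
    groups = []
    for _ in range(n_groups):
        n = rng.randint(1, 6)
        starts = rng.sample(range(2, 60), n)
        peps = []
        for s in starts:
            length = rng.randint(7, 12)
            ratio = rng.choice([0.01, 0.1, 0.4, 0.8, 1.0, 1.6, 2.0, 4.0, 50.0])
            peps.append(_pep(s, ratio, prot.sequence[s - 1: s - 1 + length]))
        groups.append(peps)
    return prot, groups


class TestOracleEquivalence:
    def test_caller_matches_literal_enumeration(self):
        """For proteins with <=6 peptides the caller must equal a
        brute-force application of the rule definitions."""
        rng = random.Random(42)
        prot, groups = _random_protein_and_peptides(rng, n_groups=200)
        for peps in groups:
            calls = call_icp55(peps, prot)
            expected = oracle_icp55(peps, prot)
            if expected is None:
                assert calls == []
            else:
                (call,) = calls
                assert (call.evidence, call.removed, call.tier) == expected


class TestOct1Rules:
    B13 = _protein("M" + "FSDLNASTQKLVGSDAQTV" + "AKVKQTTGIVGLDVVPNAR" + "KK",
                   "AT5G52840")

    def test_down_in_both_lines_called(self):
        peps = [
            _pep(21, 0.1, "AKVKQTTGIVGLDVVPNAR", "AT5G52840", "oct1_1"),
            _pep(21, 0.12, "AKVKQTTGIVGLDVVPNAR", "AT5G52840", "oct1_2"),
        ]
        (call,) = call_oct1(peps, self.B13)
        assert call.evidence == "single_down"
        assert call.comparisons_supporting == ["oct1_1", "oct1_2"]

    def test_single_line_evidence_accepted_by_default(self):
        peps = [_pep(21, 1.0, "AKVKQTTGIVGLDVVPNAR", "AT5G52840", "oct1_1"),
                _pep(21, 4.0, "AKVKQTTGIVGLDVVPNAR", "AT5G52840", "oct1_2")]
        (call,) = call_oct1(peps, self.B13)
        assert call.comparisons_supporting == ["oct1_2"]

    def test_strict_mode_requires_both_lines(self):
        peps = [_pep(21, 1.0, "AKVKQTTGIVGLDVVPNAR", "AT5G52840", "oct1_1"),
                _pep(21, 4.0, "AKVKQTTGIVGLDVVPNAR", "AT5G52840", "oct1_2")]
        assert call_oct1(peps, self.B13, min_lines=2) == []

    def test_subthreshold_ratios_not_called(self):
        peps = [_pep(21, 1.2, "AKVKQTTGIVGLDVVPNAR", "AT5G52840", "oct1_1"),
                _pep(21, 1.4, "AKVKQTTGIVGLDVVPNAR", "AT5G52840", "oct1_2")]
        assert call_oct1(peps, self.B13) == []

    def test_paired_up_down_infers_removed_stretch(self):
        seq = "M" + "A" * 20 + "FQKDLVTSE" + "SIGELDKTTR" + "KK"
        prot = _protein(seq)
        peps = [_pep(22, 8.0, "FQKDLVTSESIGELDKTTR", comparison="oct1_1"),
                _pep(31, 0.1, "SIGELDKTTR", comparison="oct1_1")]
        (call,) = call_oct1(peps, prot)
        assert call.evidence == "paired"
        assert call.removed == "FQKDLVTSE"
        assert len(call.removed) == call.mature_start - call.intermediate_start


class TestLadders:
    def test_sequential_cleavage_chain_detected(self):
        # acyl-carrier-protein-3-like: 100x up, 10x down, 100x down at
        # three consecutive starts
        seq = "M" + "A" * 36 + "FTSEAAADGGQDQILSR" + "KK"
        prot = _protein(seq)
        peps = [_pep(38, 100.0, "FTSEAAADGGQDQILSR"),
                _pep(39, 0.1, "TSEAAADGGQDQILSR"),
                _pep(40, 0.01, "SEAAADGGQDQILSR")]
        (ladder,) = detect_ladders(peps, prot)
        assert ladder.starts == [38, 39, 40]
        assert ladder.removed_path == ["F", "T"]
        assert ladder.directions == ["up", "down", "down"]

    def test_five_terminus_chain_spans_up_then_down(self):
        seq = "M" + "A" * 23 + "MVSQAGFAISESSERR" + "TIHFQSGPLDFRKK"
        prot = _protein(seq)
        ratios = {25: 10.0, 26: 10.0, 27: 10.0, 29: 0.1, 30: 0.1}
        peps = [_pep(s, r, prot.sequence[s - 1: s + 9])
                for s, r in ratios.items()]
        (ladder,) = detect_ladders(peps, prot)
        assert ladder.starts == [25, 26, 27, 29, 30]

    def test_distant_termini_form_no_ladder(self):
        seq = "M" + "A" * 10 + "F" * 50 + "R"
        prot = _protein(seq)
        peps = [_pep(s, 10.0, prot.sequence[s - 1: s + 8])
                for s in (10, 30, 50)]
        assert detect_ladders(peps, prot) == []
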