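from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from mitonterm.simulate import (
    ConfigurationError,
    SimConfig,
    generate_proteome,
    nterm_peptide,
    simulate_dataset,
    simulate_observations,
    simulate_processing,
)


class TestConfig:
    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(fraction_mito=1.5)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(mpp_class_weights=(0.5, 0.5, 0.5))

    def test_cap_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(ratio_cap=0.5)


class TestGenerateProteome:
    def test_forced_minus3r_substrate_has_motif(self):
        cfg = SimConfig(
            n_proteins=1, fraction_mito=1.0, fraction_no_presequence=0.0,
            fraction_icp55_substrate=1.0, fraction_oct1_substrate=0.0,
            mpp_class_weights=(1.0, 0.0, 0.0), seed=7,
        )
        (prot,) = generate_proteome(cfg)
        assert prot.mpp_class == "-3R"
        assert prot.sequence[prot.mpp_site - 4] == "R"  # -3 relative to site
        assert prot.icp55_removed
        assert prot.sequence[prot.mpp_site - 1] in "FYLI"  # unstable at site

    def test_seeded_runs_are_identical(self):
        cfg = SimConfig(n_proteins=500, seed=1)
        a, b = generate_proteome(cfg), generate_proteome(cfg)
        assert [(p.accession, p.sequence, p.mpp_site, p.icp55_removed,
                 p.oct1_removed_len, p.met_removed) for p in a] == \
               [(p.accession, p.sequence, p.mpp_site, p.icp55_removed,
                 p.oct1_removed_len, p.met_removed) for p in b]

    def test_substrate_fraction_matches_binomial_expectation(self):
        # with p=0.5 over ~n trials the observed fraction should sit inside
        # the 95% binomial interval, +- ~0.03 at n=2000 eligible proteins
        cfg = SimConfig(
            n_proteins=2000, fraction_mito=1.0, fraction_no_presequence=0.0,
            fraction_icp55_substrate=0.5, fraction_oct1_substrate=0.0, seed=1,
        )
        prots = generate_proteome(cfg)
        frac = sum(p.is_icp55_substrate for p in prots) / len(prots)
        assert abs(frac - 0.5) < 0.03

    def test_presequences_enriched_in_rsal(self):
        cfg = SimConfig(n_proteins=300, fraction_mito=1.0,
                        fraction_no_presequence=0.0, seed=3)
        prots = generate_proteome(cfg)
        pre = "".join(p.sequence[: p.mpp_site - 1] for p in prots
                      if p.mpp_site)
        mature = "".join(p.sequence[p.wt_mature_start - 1:] for p in prots)
        for aa in "RSAL":
            assert pre.count(aa) / len(pre) > mature.count(aa) / len(mature)

    def test_presequence_lengths_within_bounds(self):
        cfg = SimConfig(n_proteins=400, fraction_mito=1.0,
                        fraction_no_presequence=0.0, seed=4)
        lengths = [p.mpp_site - 1 for p in generate_proteome(cfg) if p.mpp_site]
        assert min(lengths) >= cfg.preseq_min
        assert max(lengths) <= cfg.preseq_max
        assert 35 < np.mean(lengths) < 52  # around the configured mean


class TestSimulateProcessing:
    @pytest.fixture()
    def icp55_protein(self):
        cfg = SimConfig(
            n_proteins=1, fraction_mito=1.0, fraction_no_presequence=0.0,
            fraction_icp55_substrate=1.0, fraction_oct1_substrate=0.0,
            mpp_class_weights=(0.0, 1.0, 0.0), seed=11,
        )
        (prot,) = generate_proteome(cfg)
        assert len(prot.icp55_removed) == 1
        return prot

    def test_wt_dominant_is_fully_processed(self, icp55_protein):
        p = icp55_protein
        (dom, ab), *_ = simulate_processing(p, "WT")
        assert dom == p.mpp_site + 1 and ab == pytest.approx(0.98)

    def test_knockout_dominant_is_mpp_intermediate(self, icp55_protein):
        p = icp55_protein
        (dom, _), *_ = simulate_processing(p, "icp55")
        assert dom == p.mpp_site

    def test_mpp_independent_oct1_precursor_accumulates(self):
        # B13-style: no MPP site, a short stretch removed from position 2;
        # in the knockout only the precursor-like form remains
        cfg = SimConfig(
            n_proteins=40, fraction_mito=1.0, fraction_no_presequence=1.0,
            fraction_oct1_substrate=1.0, seed=5,
        )
        prots = [p for p in generate_proteome(cfg)
                 if p.mpp_site is None and p.oct1_removed_len]
        assert prots
        p = prots[0]
        (dom, _), *_ = simulate_processing(p, "oct1")
        assert dom == 2
        (wt_dom, _), *_ = simulate_processing(p, "WT")
        assert wt_dom == 2 + p.oct1_removed_len

    def test_non_substrate_identical_across_genotypes(self):
        cfg = SimConfig(n_proteins=30, fraction_icp55_substrate=0.0,
                        fraction_oct1_substrate=0.0, seed=6)
        for p in generate_proteome(cfg):
            wt = simulate_processing(p, "WT")
            assert simulate_processing(p, "icp55") == wt
            assert simulate_processing(p, "oct1") == wt

    def test_abundances_sum_to_one(self, icp55_protein):
        for g in ("WT", "icp55", "oct1"):
            total = sum(ab for _, ab in simulate_processing(icp55_protein, g))
            assert total == pytest.approx(1.0)

    def test_unknown_genotype_raises(self, icp55_protein):
        with pytest.raises(ValueError, match="genotype"):
            simulate_processing(icp55_protein, "oct2")


class TestSimulateObservations:
    def _observe(self, protein, wt, mut, noise_sd=0.0, seed=0, cap=100.0):
        cfg = SimConfig(ratio_noise_sd=noise_sd, ratio_cap=cap, seed=seed)
        rng = np.random.default_rng(seed)
        return simulate_observations(
            {protein.accession: wt}, {protein.accession: mut},
            {protein.accession: protein}, "icp55", cfg, rng,
        )

    @pytest.fixture()
    def protein(self):
        cfg = SimConfig(n_proteins=1, fraction_mito=1.0,
                        fraction_no_presequence=0.0,
                        fraction_icp55_substrate=0.0,
                        fraction_oct1_substrate=0.0, seed=2)
        return generate_proteome(cfg)[0]

    def test_equal_abundance_no_noise_gives_ratio_one(self, protein):
        (pep,) = self._observe(protein, [(protein.mpp_site, 0.98)],
                               [(protein.mpp_site, 0.98)])
        assert pep.ratio_mut_over_wt == pytest.approx(1.0)

    def test_absent_wt_channel_reported_at_cap(self, protein):
        (pep,) = self._observe(protein, [], [(protein.mpp_site, 1.0)])
        assert pep.ratio_mut_over_wt == pytest.approx(100.0)

    def test_absent_mut_channel_reported_at_inverse_cap(self, protein):
        (pep,) = self._observe(protein, [(protein.mpp_site, 1.0)], [])
        assert pep.ratio_mut_over_wt == pytest.approx(0.01)

    def test_nondifferential_noise_rarely_reaches_threefold(self):
        # log2(3)/0.2 ~ 7.9 sd: the Gaussian tail gives essentially zero
        # spurious 3-fold calls among 1000 unchanged termini
        expected_tail = 2 * stats.norm.sf(np.log2(3.0) / 0.2)
        assert expected_tail < 1e-3
        cfg = SimConfig(n_proteins=500, fraction_icp55_substrate=0.0,
                        fraction_oct1_substrate=0.0, ratio_noise_sd=0.2,
                        seed=8)
        ds = simulate_dataset(cfg)
        ratios = [p.ratio_mut_over_wt for p in ds.peptides["icp55"]]
        assert len(ratios) >= 500
        frac = np.mean([r >= 3.0 or r <= 1 / 3.0 for r in ratios])
        assert frac < 1e-3

    def test_terminus_beyond_sequence_end_raises(self, protein):
        with pytest.raises(ValueError, match="beyond"):
            self._observe(protein, [(len(protein.sequence) + 5, 1.0)], [])

    def test_peptide_starts_roundtrip_to_simulated_termini(self):
        cfg = SimConfig(n_proteins=100, seed=9)
        ds = simulate_dataset(cfg)
        truth = {
            p.accession: {pos for g in ("WT", "icp55")
                          for pos, _ in simulate_processing(p, g, cfg.leak)}
            for p in ds.proteins
        }
        for pep in ds.peptides["icp55"]:
            assert pep.start in truth[pep.accession]
            prot = next(p for p in ds.proteins if p.accession == pep.accession)
            assert prot.sequence[pep.start - 1: pep.end] == pep.peptide


class TestDigestion:
    def test_peptide_ends_at_first_qualifying_arginine(self):
        seq = "MAAAAAAAARGGGGGGGR"
        assert nterm_peptide(seq, 1) == "MAAAAAAAAR"

    def test_short_first_arginine_skipped_for_minimum_length(self):
        seq = "MAARGGGGGGGGR"  # first R gives a 4-mer, below the minimum
        assert nterm_peptide(seq, 1) == "MAARGGGGGGGGR"

    def test_no_arginine_truncates_at_max_length(self):
        seq = "A" * 60
        assert nterm_peptide(seq, 1) == "A" * 45
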