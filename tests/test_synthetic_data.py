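import numpy as np
import pytest

from thermotrait.seqio import AA_STANDARD
from thermotrait.synthetic_data import (
    BASE_AA_FREQ, CohortSpec, CommunitySpec, ExpressionSpec,
    shift_frequencies, simulate_class_fractions, simulate_cohort,
    simulate_community, simulate_counts, simulate_proteome,
)
from thermotrait.community import relative_abundance
from thermotrait.expression import fpkm_matrix, overall_expressed_fraction
from thermotrait.thermo_profile import DEFAULT_CLASS_MAP, aa_usage


class TestShiftFrequencies:
    def test_shift_moves_class_fractions_exactly(self):
        shifted = shift_frequencies(
            BASE_AA_FREQ, {"charged": 0.04, "polar": -0.04})
        _, base_cf, _ = _class_frac(BASE_AA_FREQ)
        _, new_cf, _ = _class_frac(shifted)
        assert new_cf["charged"] - base_cf["charged"] == pytest.approx(
            0.04, abs=1e-12)
        assert sum(shifted.values()) == pytest.approx(1.0, abs=1e-12)

    def test_within_class_proportions_preserved(self):
        shifted = shift_frequencies(BASE_AA_FREQ, {"charged": 0.04,
                                                   "polar": -0.04})
        assert (shifted["D"] / shifted["E"]
                == pytest.approx(BASE_AA_FREQ["D"] / BASE_AA_FREQ["E"]))

    def test_infeasible_shift_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            shift_frequencies(BASE_AA_FREQ, {"polar": -0.9,
                                             "charged": 0.9})


def _class_frac(freq):
    cf = {"polar": 0.0, "nonpolar": 0.0, "charged": 0.0}
    for l, f in freq.items():
        cf[DEFAULT_CLASS_MAP.class_of[l]] += f
    return freq, cf, 1


class TestSimulateProteome:
    def test_point_mass_gives_single_letter_proteome(self, rng):
        freq = {l: (1.0 if l == "A" else 0.0) for l in AA_STANDARD}
        prots = simulate_proteome(freq, 100, 5, rng)
        assert all(set(p.seq) == {"A"} for p in prots)
        assert sum(len(p) for p in prots) == 100

    def test_uniform_frequencies_recovered_within_3se(self, rng):
        freq = {l: 0.05 for l in AA_STANDARD}
        prots = simulate_proteome(freq, 50_000, 40, rng)
        emp, _, n = aa_usage(prots)
        se = np.sqrt(0.05 * 0.95 / 50_000)
        for l in AA_STANDARD:
            assert abs(emp[l] - 0.05) <= 3 * se

    def test_seed_determinism(self):
        a = simulate_proteome(BASE_AA_FREQ, 500, 7,
                              np.random.default_rng(3))
        b = simulate_proteome(BASE_AA_FREQ, 500, 7,
                              np.random.default_rng(3))
        assert a == b


class TestSimulateCohort:
    def test_zero_delta_groups_share_the_model(self):
        spec = CohortSpec(n_thermal=2, n_nonthermal=2,
                          delta_charged=0, delta_polar=0,
                          delta_nonpolar=0,
                          residues_per_genome=500, seed=5)
        proteomes, labels = simulate_cohort(spec)
        assert len(proteomes) == 4
        assert sorted(set(labels.values()), key=str) != []

    def test_shift_recovered_in_mean_class_fraction(self):
        spec = CohortSpec(delta_charged=0.04, delta_polar=-0.04,
                          delta_nonpolar=0.0,
                          residues_per_genome=20_000,
                          proteins_per_genome=20, seed=11)
        proteomes, labels = simulate_cohort(spec)
        charged = {"thermal": [], "non_thermal": []}
        for gid, prots in proteomes.items():
            _, cf, _ = aa_usage(prots)
            charged[labels[gid].value].append(cf["charged"])
        diff = np.mean(charged["thermal"]) - np.mean(
            charged["non_thermal"])
        p = 0.29  # approximate charged fraction
        se = np.sqrt(p * (1 - p) / 20_000) * np.sqrt(1 / 12 + 1 / 18)
        assert diff == pytest.approx(0.04, abs=3 * se)

    def test_deltas_must_sum_to_zero(self):
        with pytest.raises(ValueError, match="sum to 0"):
            CohortSpec(delta_charged=0.05, delta_polar=0.0,
                       delta_nonpolar=0.0)

    def test_with_genomes_emits_assemblies(self):
        spec = CohortSpec(n_thermal=1, n_nonthermal=1,
                          residues_per_genome=200,
                          proteins_per_genome=2,
                          size_mean_thermal=20_000,
                          size_sd_thermal=100,
                          size_mean_nonthermal=30_000,
                          size_sd_nonthermal=100, seed=2)
        _, _, genomes = simulate_cohort(spec, with_genomes=True)
        sizes = {g.habitat.value: sum(len(c) for c in g.contigs)
                 for g in genomes.values()}
        assert 15_000 < sizes["thermal"] < 25_000
        assert 25_000 < sizes["non_thermal"] < 35_000


class TestSimulateClassFractions:
    def test_shape_and_normalization(self, rng):
        fracs = simulate_class_fractions(30, BASE_AA_FREQ, 2000, rng,
                                         n_reps=5)
        assert fracs.shape == (5, 30, 3)
        np.testing.assert_allclose(fracs.sum(axis=-1), 1.0, atol=1e-12)

    def test_means_match_model_classes(self, rng):
        fracs = simulate_class_fractions(200, BASE_AA_FREQ, 5000, rng)
        _, cf, _ = _class_frac(BASE_AA_FREQ)
        np.testing.assert_allclose(
            fracs.mean(axis=(0, 1)),
            [cf["polar"], cf["nonpolar"], cf["charged"]], atol=0.003)


class TestSimulateCommunity:
    def test_single_bin_community_is_100_percent(self):
        spec = CommunitySpec(n_bins=1, frac_unbinned=0.0, seed=1)
        cov, bins, truth = simulate_community(spec)
        ra = relative_abundance(cov, bins)
        for s in cov.samples:
            assert ra.loc["bin1", s] == pytest.approx(100.0)

    def test_recovery_is_an_arithmetic_identity(self):
        cov, bins, truth = simulate_community(CommunitySpec(seed=7))
        ra = relative_abundance(cov, bins)
        for s in cov.samples:
            for b, expected in truth[s].items():
                assert ra.loc[b, s] == pytest.approx(expected,
                                                     abs=1e-9)

    def test_seed_determinism(self):
        a = simulate_community(CommunitySpec(seed=9))[0]
        b = simulate_community(CommunitySpec(seed=9))[0]
        assert a.depth == b.depth and a.contig_len == b.contig_len


class TestSimulateCounts:
    def test_expressed_fraction_recovered_exactly(self):
        spec = ExpressionSpec(
            genes_per_genome={"g1": 400, "g2": 600},
            expressed_fraction=0.10, n_samples=2, seed=3)
        tables, gene_len, genome_of, expressed = simulate_counts(spec)
        assert len(expressed) == 100
        m = fpkm_matrix(tables)
        n, total, pct = overall_expressed_fraction(m)
        assert (n, total, pct) == (100, 1000, 10.0)

    def test_structural_zeros_are_zero_everywhere(self):
        spec = ExpressionSpec(genes_per_genome={"g1": 100},
                              expressed_fraction=0.2, seed=4)
        tables, _, _, expressed = simulate_counts(spec)
        for t in tables:
            for g, c in t.counts.items():
                if g not in expressed:
                    assert c == 0
                else:
                    assert c >= 1

    def test_empty_library_rejected(self):
        spec = ExpressionSpec(genes_per_genome={"g1": 50},
                              expressed_fraction=0.0, seed=5)
        with pytest.raises(ValueError, match="empty"):
            simulate_counts(spec)
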