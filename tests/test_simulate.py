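"""Generator contracts: determinism, conservation, planted structure."""

import numpy as np
import pytest

from haplopop.distances import pairwise_distances
from haplopop.genotypes import read_vcf, write_vcf
from haplopop.io import write_bed, write_fasta
from haplopop.simulate import (
    ClonemateGroup,
    CompositionCounts,
    DuplicationEvent,
    PopulationModel,
    make_composition_vcf,
    simulate_depth,
    simulate_population,
    simulate_reference,
)
from haplopop.variants import classify_variants


def small_model(**kw):
    defaults = dict(seed=1, chrom_length=100_000, strains_per_clade=(5, 5), n_genes=20)
    defaults.update(kw)
    return PopulationModel(**defaults)


class TestReference:
    def test_two_chromosomes_of_stated_length(self):
        model = small_model(n_chromosomes=2, chrom_length=50_000)
        ref, _ = simulate_reference(model)
        assert list(ref) == ["chr1", "chr2"]
        assert all(len(s) == 50_000 for s in ref.values())
        assert set("".join(ref.values())) <= set("ACGT")

    def test_genes_non_overlapping_within_bounds(self):
        model = small_model(n_genes=50, gene_length=999)
        _, genes = simulate_reference(model)
        assert len(genes) == 50
        genes = sorted(genes, key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start
        assert genes[-1].end <= model.chrom_length

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        for run in ("a", "b"):
            model = small_model(seed=9)
            ref, genes = simulate_reference(model)
            write_fasta(ref, tmp_path / f"{run}.fa")
            write_bed(genes, tmp_path / f"{run}.bed")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()

    def test_too_many_genes_rejected(self):
        with pytest.raises(ValueError, match="cannot place"):
            simulate_reference(small_model(chrom_length=5000, n_genes=50, gene_length=999))


class TestPopulation:
    def test_record_count_matches_truth(self, tmp_path):
        model = small_model()
        ref, _ = simulate_reference(model)
        m, truth = simulate_population(model, ref, vcf_path=tmp_path / "p.vcf")
        # conservation: one VCF record per planted variant
        assert m.n_sites == len(truth.site_pi)
        assert read_vcf(tmp_path / "p.vcf").n_sites == m.n_sites

    def test_clonemate_pairwise_below_break(self):
        model = small_model(
            clonemate_groups=(ClonemateGroup(0, 3, 300),),
            within_clade_divergence=1000,
            clade_divergence=4000,
        )
        ref, _ = simulate_reference(model)
        m, truth = simulate_population(model, ref)
        group = truth.clonemate_groups[0]
        d = truth.pairwise_diff.loc[group, group].to_numpy()
        iu = np.triu_indices(len(group), 1)
        assert (d[iu] < 725).all()
        assert (d[iu] <= 300).all()

    def test_between_clade_pairs_above_break(self):
        model = small_model(clade_divergence=5000, within_clade_divergence=1000)
        ref, _ = simulate_reference(model)
        m, truth = simulate_population(model, ref)
        a = [s for s in m.strains if s.startswith("c1")]
        b = [s for s in m.strains if s.startswith("c2")]
        assert (truth.pairwise_diff.loc[a, b].to_numpy() >= 2533).all()

    def test_singleton_count_within_poisson_3_sigma(self):
        # within_clade_divergence = 2 * singleton_rate leaves no lineage-
        # private variants, so singletons come from the Poisson draws alone
        model = PopulationModel(
            seed=21,
            chrom_length=500_000,
            n_clades=2,
            strains_per_clade=(10, 10),
            clade_divergence=3000,
            within_clade_divergence=20,
            singleton_rate=10.0,
        )
        ref, _ = simulate_reference(model)
        m, truth = simulate_population(model, ref)
        s = classify_variants(m)
        expected = 20 * 10.0
        assert abs(s.n_singleton - expected) <= 3 * np.sqrt(expected)
        assert truth.n_singletons == s.n_singleton

    def test_truth_pairwise_matches_distance_module(self):
        model = small_model()
        ref, _ = simulate_reference(model)
        m, truth = simulate_population(model, ref)
        d = pairwise_distances(m)
        assert np.array_equal(d.counts, truth.pairwise_diff.to_numpy())

    def test_expected_pi_matches_matrix(self):
        model = small_model()
        ref, _ = simulate_reference(model)
        m, truth = simulate_population(model, ref)
        from haplopop.popgen import nucleotide_diversity

        _, pi, _ = nucleotide_diversity(m, 10_000, {"chr1": model.chrom_length})
        assert pi == pytest.approx(truth.expected_pi, rel=1e-12)

    def test_divergence_exceeding_sites_rejected(self):
        model = small_model(
            chrom_length=2000, clade_divergence=100_000, within_clade_divergence=50_000,
            n_genes=1,
        )
        ref, _ = simulate_reference(model)
        with pytest.raises(ValueError, match="available"):
            simulate_population(model, ref)

    def test_indels_emitted_at_requested_fraction(self):
        model = small_model(indel_fraction=0.2, seed=6)
        ref, _ = simulate_reference(model)
        m, _ = simulate_population(model, ref)
        s = classify_variants(m)
        frac = s.n_indel / s.n_total
        assert frac == pytest.approx(0.2, abs=0.03)
        lens = (m.sites["ref"].str.len() - m.sites["alt"].str.len()).abs()
        assert lens.max() <= 10


class TestDepth:
    def test_noiseless_track_constant_at_mean(self):
        model = small_model(depth_noise="none", strains_per_clade=(1, 1))
        ref, genes = simulate_reference(model)
        tracks = simulate_depth(model, ref, genes)
        track = tracks["c1s1"]
        assert track.mean_depth == pytest.approx(model.mean_depth)
        assert np.all(track.depths["chr1"] == model.mean_depth)

    def test_full_duplication_doubles_depth(self):
        ev = DuplicationEvent("c1s1", "chr1", 10_000, 20_000, 2, 1.0)
        model = small_model(depth_noise="none", duplication_events=(ev,), strains_per_clade=(1, 1))
        ref, _ = simulate_reference(model)
        d = simulate_depth(model, ref)["c1s1"].depths["chr1"]
        assert d[15_000] == 60.0 and d[5_000] == 30.0

    def test_subclonal_duplication_ratio_1_4(self):
        ev = DuplicationEvent("c1s1", "chr1", 10_000, 20_000, 2, 0.4)
        model = small_model(depth_noise="none", duplication_events=(ev,), strains_per_clade=(1, 1))
        ref, _ = simulate_reference(model)
        d = simulate_depth(model, ref)["c1s1"].depths["chr1"]
        assert d[15_000] == pytest.approx(42.0)
        assert d[15_000] / model.mean_depth == pytest.approx(1.4)

    def test_poisson_mean_within_3_sigma(self):
        model = small_model(strains_per_clade=(1, 1))
        ref, _ = simulate_reference(model)
        track = simulate_depth(model, ref)["c1s1"]
        n = model.chrom_length
        sigma = np.sqrt(model.mean_depth / n)
        assert abs(track.mean_depth - model.mean_depth) <= 3 * sigma

    def test_overlapping_events_rejected(self):
        evs = (
            DuplicationEvent("c1s1", "chr1", 0, 10_000, 2),
            DuplicationEvent("c1s1", "chr1", 5_000, 15_000, 2),
        )
        model = small_model(duplication_events=evs, strains_per_clade=(1, 1))
        ref, _ = simulate_reference(model)
        with pytest.raises(ValueError, match="overlapping"):
            simulate_depth(model, ref)

    def test_invalid_event_parameters(self):
        with pytest.raises(ValueError):
            DuplicationEvent("s", "chr1", 0, 100, 1)  # copy_number < 2
        with pytest.raises(ValueError):
            DuplicationEvent("s", "chr1", 0, 100, 2, 0.0)  # cell_fraction


class TestCompositionFixture:
    def test_round_trip_totals_exact(self, tmp_path):
        counts = CompositionCounts(50, 20, 10, 12, 4, 2)
        p = tmp_path / "c.vcf"
        make_composition_vcf(counts, p, n_strains=4, seed=3)
        s = classify_variants(read_vcf(p))
        assert (s.n_snp, s.n_insertion, s.n_deletion) == (50, 20, 10)
        assert (s.n_snp_singleton, s.n_insertion_singleton, s.n_deletion_singleton) == (12, 4, 2)

    def test_all_zero_counts_empty_body(self, tmp_path):
        p = tmp_path / "z.vcf"
        make_composition_vcf(CompositionCounts(0, 0, 0), p, seed=0)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert lines == []
        assert read_vcf(p).n_sites == 0

    def test_byte_identical_for_same_seed(self, tmp_path):
        c = CompositionCounts(2, 1, 0, 1, 0, 0)
        make_composition_vcf(c, tmp_path / "a.vcf", n_strains=3, seed=5)
        make_composition_vcf(c, tmp_path / "b.vcf", n_strains=3, seed=5)
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_singleton_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            CompositionCounts(5, 0, 0, 6, 0, 0)


class TestModelValidation:
    def test_clonemate_diff_must_be_below_clade_divergence(self):
        with pytest.raises(ValueError, match="below clade_divergence"):
            small_model(clonemate_groups=(ClonemateGroup(0, 2, 5000),), clade_divergence=4000)

    def test_group_larger_than_clade_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            small_model(clonemate_groups=(ClonemateGroup(0, 9, 300),), strains_per_clade=(3, 3))

    def test_vcf_determinism_end_to_end(self, tmp_path):
        for run in ("a", "b"):
            model = small_model(seed=33)
            ref, _ = simulate_reference(model)
            simulate_population(model, ref, vcf_path=tmp_path / f"{run}.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()
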