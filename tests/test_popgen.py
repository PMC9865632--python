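"""Diversity statistics against brute-force pairwise oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from haplopop.genotypes import MISSING
from haplopop.popgen import (
    dxy,
    fst,
    ld_decay,
    maf_spectrum,
    nucleotide_diversity,
    site_density_per_kb,
)

from conftest import make_matrix, random_matrix


# ---- independent brute-force oracles -----------------------------------


def brute_pi(m, genome_length):
    """Mean per-pair Hamming distance over pairwise-complete sites / L."""
    total = 0.0
    cols = range(m.n_strains)
    n_pairs = 0
    for i, j in itertools.combinations(cols, 2):
        n_pairs += 1
    per_site = np.zeros(m.n_sites)
    for s in range(m.n_sites):
        row = m.calls[s]
        diff = same = 0
        for i, j in itertools.combinations(cols, 2):
            if row[i] != MISSING and row[j] != MISSING:
                if row[i] != row[j]:
                    diff += 1
                same += 1
        per_site[s] = diff / same if same else 0.0
    return per_site.sum() / genome_length


def brute_dxy(m, a_cols, b_cols, genome_length):
    total = 0.0
    for s in range(m.n_sites):
        row = m.calls[s]
        diff = pairs = 0
        for i in a_cols:
            for j in b_cols:
                if row[i] != MISSING and row[j] != MISSING:
                    pairs += 1
                    diff += row[i] != row[j]
        if pairs:
            total += diff / pairs
    return total / genome_length


def brute_fst(m, a_cols, b_cols):
    """Hudson from within/between pair-difference probabilities."""
    hw_sum = hb_sum = 0.0
    for s in range(m.n_sites):
        row = m.calls[s]

        def mean_diff(pairs):
            diff = tot = 0
            for i, j in pairs:
                if row[i] != MISSING and row[j] != MISSING:
                    tot += 1
                    diff += row[i] != row[j]
            return (diff / tot if tot else None), tot

        wa, na = mean_diff(list(itertools.combinations(a_cols, 2)))
        wb, nb = mean_diff(list(itertools.combinations(b_cols, 2)))
        hb, nab = mean_diff([(i, j) for i in a_cols for j in b_cols])
        called_a = sum(row[i] != MISSING for i in a_cols)
        called_b = sum(row[j] != MISSING for j in b_cols)
        if called_a < 2 or called_b < 2 or hb is None:
            continue
        hw_sum += (wa + wb) / 2
        hb_sum += hb
    return 1 - hw_sum / hb_sum if hb_sum > 0 else float("nan")


# ---- nucleotide diversity ----------------------------------------------


class TestPi:
    def test_single_site_hand_value(self):
        m = make_matrix([[0, 0, 1, 1]])
        table, genome_pi, _ = nucleotide_diversity(m, window=10, chrom_lengths={"chr1": 10})
        assert table.loc[0, "pi"] == pytest.approx(4 / 6 / 10)
        assert genome_pi == pytest.approx(0.0667, abs=1e-4)

    def test_monomorphic_window_is_zero(self):
        m = make_matrix([[0, 0, 0]])
        table, genome_pi, _ = nucleotide_diversity(m, window=10, chrom_lengths={"chr1": 10})
        assert genome_pi == 0.0

    def test_matches_brute_force_all_pairs(self, rng):
        for _ in range(10):
            m = random_matrix(rng, n_sites=50, n_strains=10, span=2000)
            _, genome_pi, _ = nucleotide_diversity(m, 500, {"chr1": 2000})
            assert genome_pi == pytest.approx(brute_pi(m, 2000), rel=1e-12)

    def test_invariant_under_strain_relabeling(self, rng):
        m = random_matrix(rng, n_sites=30, n_strains=8)
        perm = list(rng.permutation(m.strains))
        _, a, _ = nucleotide_diversity(m, 1000, {"chr1": 5000})
        _, b, _ = nucleotide_diversity(m.take_strains(perm), 1000, {"chr1": 5000})
        assert a == pytest.approx(b)

    def test_low_call_sites_counted(self):
        m = make_matrix([[0, MISSING, MISSING]])
        _, genome_pi, n_low = nucleotide_diversity(m, 10, {"chr1": 10})
        assert genome_pi == 0.0 and n_low == 1

    def test_bad_window_rejected(self):
        m = make_matrix([[0, 1]])
        with pytest.raises(ValueError):
            nucleotide_diversity(m, window=0)


class TestDxy:
    def test_fixed_ref_both_pops_zero(self):
        m = make_matrix([[0, 0, 0, 0]])
        _, g, _ = dxy(m, ["s1", "s2"], ["s3", "s4"], window=5, chrom_lengths={"chr1": 5})
        assert g == 0.0

    def test_hand_value(self):
        m = make_matrix([[0, 1, 0, 0]])
        _, g, _ = dxy(m, ["s1", "s2"], ["s3", "s4"], window=5, chrom_lengths={"chr1": 5})
        assert g == pytest.approx(0.5 / 5)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            m = random_matrix(rng, n_sites=30, n_strains=9, span=1000)
            a, b = m.strains[:4], m.strains[4:]
            _, g, _ = dxy(m, a, b, 500, {"chr1": 1000})
            assert g == pytest.approx(
                brute_dxy(m, range(4), range(4, 9), 1000), rel=1e-12
            )

    def test_overlapping_pops_rejected(self):
        m = make_matrix([[0, 1]])
        with pytest.raises(ValueError):
            dxy(m, ["s1"], ["s1", "s2"])


class TestFst:
    def test_fixed_difference_is_one(self):
        m = make_matrix([[0, 0, 0, 0, 1, 1, 1, 1]])
        _, g = fst(m, [f"s{i}" for i in range(1, 5)], [f"s{i}" for i in range(5, 9)])
        assert g == pytest.approx(1.0)

    def test_one_site_plugin_value(self):
        # pA=1/4, pB=1: Hw = [2*(1/4)(3/4)(4/3) + 0]/2 = 1/4, Hb = 3/4
        m = make_matrix([[0, 0, 0, 1, 1, 1, 1, 1]])
        _, g = fst(m, [f"s{i}" for i in range(1, 5)], [f"s{i}" for i in range(5, 9)])
        assert g == pytest.approx(1 - (1 / 4) / (3 / 4))

    def test_null_split_of_panmictic_population(self):
        rng = np.random.default_rng(11)
        freqs = rng.uniform(0.1, 0.9, 200)
        calls = (rng.random((200, 100)) < freqs[:, None]).astype(np.int8)
        m = make_matrix(calls, positions=np.arange(1, 201))
        _, g = fst(m, m.strains[:50], m.strains[50:], window=10_000)
        assert abs(g) < 0.05

    def test_symmetric_in_populations(self, rng):
        m = random_matrix(rng, n_sites=40, n_strains=10)
        a, b = m.strains[:5], m.strains[5:]
        assert fst(m, a, b)[1] == pytest.approx(fst(m, b, a)[1])

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            m = random_matrix(rng, n_sites=40, n_strains=10, span=1000)
            _, g = fst(m, m.strains[:5], m.strains[5:], 2000, {"chr1": 1000})
            expected = brute_fst(m, range(5), range(5, 10))
            assert g == pytest.approx(expected, rel=1e-9)

    def test_small_pop_rejected(self):
        m = make_matrix([[0, 1, 1]])
        with pytest.raises(ValueError):
            fst(m, ["s1"], ["s2", "s3"])


# ---- LD decay -----------------------------------------------------------


class TestLD:
    def test_identical_vectors_r2_one(self):
        m = make_matrix([[0, 0, 1, 1], [0, 0, 1, 1]], positions=[1, 101])
        ld = ld_decay(m)
        assert ld.table.loc[0, "distance"] == 100
        assert ld.table.loc[0, "mean_r2"] == pytest.approx(1.0)

    def test_hand_correlations(self):
        m = make_matrix([[0, 0, 1, 1], [0, 1, 0, 1], [0, 1, 1, 1]], positions=[1, 2, 3])
        ld = ld_decay(m)
        by_pair = {
            (1, 2): 0.0,  # orthogonal
            (1, 3): 1 / 3,
            (2, 3): 1 / 3,
        }
        # distances: (1,2)->1, (2,3)->1, (1,3)->2
        d1 = ld.table.set_index("distance")
        assert d1.loc[1, "mean_r2"] == pytest.approx((0.0 + 1 / 3) / 2)
        assert d1.loc[2, "mean_r2"] == pytest.approx(1 / 3)

    def test_zero_variance_pairs_skipped(self):
        m = make_matrix([[0, 0, 0, 1], [0, 0, 0, 0]], positions=[1, 5])
        ld = ld_decay(m)
        assert len(ld.table) == 0 and ld.ld_half is None

    def test_recovers_planted_half_decay_distance(self):
        """Markov haplotypes with r2(d) = 2^(-d/50): half-decay at 50 bp."""
        half = 50
        p = (1 - 2 ** (-1 / (2 * half))) / 2
        rng = np.random.default_rng(8)
        n_strains, n_sites = 150, 400
        positions = np.sort(rng.choice(np.arange(1, 4001), n_sites, replace=False))
        calls = np.empty((n_sites, n_strains), dtype=np.int8)
        calls[0] = rng.integers(0, 2, n_strains)
        for k in range(1, n_sites):
            d = positions[k] - positions[k - 1]
            flip = rng.random(n_strains) < (1 - (1 - 2 * p) ** d) / 2
            calls[k] = calls[k - 1] ^ flip
        m = make_matrix(calls, positions=positions)
        ld = ld_decay(m, max_dist=2000)
        assert ld.ld_half == pytest.approx(half, abs=15)


class TestMafSpectrum:
    def test_all_singletons(self):
        calls = np.zeros((5, 56), dtype=np.int8)
        calls[np.arange(5), np.arange(5)] = 1
        m = make_matrix(calls)
        assert maf_spectrum(m, (0.05,))[0.05] == 1.0

    def test_empty_matrix(self):
        m = make_matrix(np.empty((0, 4), dtype=np.int8))
        assert len(maf_spectrum(m)) == 0

    def test_matches_brute_force(self, rng):
        m = random_matrix(rng, n_sites=50, n_strains=12)
        out = maf_spectrum(m, (0.1, 0.3))
        for t in (0.1, 0.3):
            count = 0
            for s in range(m.n_sites):
                row = m.calls[s]
                called = row[row != MISSING]
                p = (called == 1).mean()
                count += min(p, 1 - p) <= t
            assert out[t] == pytest.approx(count / m.n_sites)


def test_site_density_per_kb():
    assert site_density_per_kb(77, 32_114) == pytest.approx(2.4, abs=0.01)
    with pytest.raises(ValueError):
        site_density_per_kb(1, 0)
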