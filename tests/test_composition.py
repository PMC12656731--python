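"""Composition, dinucleotide odds and codon-pair bias against hand counts
and brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cubkit.composition import (
    DINUCLEOTIDES,
    codon_pair_bias,
    composition_profile,
    dinucleotide_odds,
    group_composition,
)
from cubkit.genetic_code import CODON_TO_AA
from cubkit.seq_io import CodingSequence, validate_cds
from tests.conftest import random_cds


class TestCompositionProfile:
    def test_homopolymer(self):
        p = composition_profile(CodingSequence("x", "AAAAAA"))
        assert (p.a, p.gc, p.a3, p.gc3, p.gc12) == (100.0, 0.0, 100.0, 0.0, 0.0)

    def test_hand_counted_two_codons(self):
        p = composition_profile(CodingSequence("x", "ATGGCA"))
        assert p.a == pytest.approx(100 * 2 / 6)
        assert p.u == pytest.approx(100 * 1 / 6)
        assert (p.gc1, p.gc2, p.gc3, p.gc12) == (50.0, 50.0, 50.0, 50.0)

    def test_percentages_sum_to_100(self, rng):
        for i in range(25):
            p = composition_profile(random_cds(rng, 30, f"s{i}"))
            assert p.a + p.c + p.g + p.u == pytest.approx(100.0, abs=1e-9)
            assert p.a3 + p.c3 + p.g3 + p.u3 == pytest.approx(100.0, abs=1e-9)
            assert p.au + p.gc == pytest.approx(100.0, abs=1e-9)
            assert p.gc12 == pytest.approx((p.gc1 + p.gc2) / 2, abs=0)


class TestGroupComposition:
    def make(self, seqs_hosts):
        return [
            validate_cds(CodingSequence(f"s{i}", seq, host=h, region="CP"))
            for i, (seq, h) in enumerate(seqs_hosts)
        ]

    def test_identical_sequences_have_zero_sd(self):
        seqs = self.make([("ATGGCA", "h"), ("ATGGCA", "h")])
        tab = group_composition(seqs, ("host",))
        assert (tab["sd"] == 0).all()

    def test_sample_sd_uses_n_minus_1(self):
        # A3 = 100 vs A3 = 0 -> mean 50, sample SD 70.71
        seqs = self.make([("GGAGGA", "h"), ("GGGGGG", "h")])
        tab = group_composition(seqs, ("host",)).set_index("metric")
        assert tab.loc["a3", "mean"] == pytest.approx(50.0)
        assert tab.loc["a3", "sd"] == pytest.approx(100 / math.sqrt(2))

    def test_singleton_group_flagged_with_zero_sd(self):
        tab = group_composition(self.make([("ATGGCA", "h")]), ("host",))
        assert tab["singleton"].all() and (tab["sd"] == 0).all()


class TestDinucleotideOdds:
    def test_hand_counted_acacac(self):
        tab = dinucleotide_odds("ACACAC").set_index("dinucleotide")
        assert tab.loc["AC", "f_obs"] == pytest.approx(0.6)
        assert tab.loc["AC", "rho"] == pytest.approx(2.4)
        assert tab.loc["CA", "f_obs"] == pytest.approx(0.4)

    def test_observed_frequencies_sum_to_one(self, rng):
        tab = dinucleotide_odds(random_cds(rng, 50))
        assert tab["f_obs"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_undefined_when_base_absent(self):
        tab = dinucleotide_odds("AAAAAA").set_index("dinucleotide")
        assert not tab.loc["CG", "defined"]
        assert np.isnan(tab.loc["CG", "rho"])

    def test_iid_uniform_limit_rho_near_one(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        tab = dinucleotide_odds(seq)
        assert np.allclose(tab["rho"], 1.0, atol=0.05)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 200))))
        tab = dinucleotide_odds(seq).set_index("dinucleotide")
        L = len(seq)
        mono = Counter(seq)
        for d in DINUCLEOTIDES:
            obs = sum(seq[i : i + 2] == d for i in range(L - 1)) / (L - 1)
            exp = (mono[d[0]] / L) * (mono[d[1]] / L)
            assert tab.loc[d, "f_obs"] == pytest.approx(obs, abs=1e-12)
            if exp > 0:
                assert tab.loc[d, "rho"] == pytest.approx(obs / exp, rel=1e-9)

    def test_frame_policies_partition_sites(self, rng):
        s = random_cds(rng, 40)
        n_all = dinucleotide_odds(s, "all")["observed"].sum()
        parts = sum(
            dinucleotide_odds(s, p)["observed"].sum()
            for p in ("p1p2", "p2p3", "p3p1")
        )
        assert parts == n_all


def brute_force_cps(corpus):
    """Direct tabulation of all F terms of the amino-acid-conditioned
    codon pair score, independent of the implementation."""
    cod, aa, pair, aapair = Counter(), Counter(), Counter(), Counter()
    for s in corpus:
        cs = [s.seq[i : i + 3] for i in range(0, len(s.seq), 3)]
        for c in cs:
            cod[c] += 1
            aa[CODON_TO_AA[c]] += 1
        for a, b in zip(cs, cs[1:]):
            pair[(a, b)] += 1
            aapair[(CODON_TO_AA[a], CODON_TO_AA[b])] += 1
    out = {}
    for (a, b), n in pair.items():
        num = n * aa[CODON_TO_AA[a]] * aa[CODON_TO_AA[b]]
        den = cod[a] * cod[b] * aapair[(CODON_TO_AA[a], CODON_TO_AA[b])]
        out[(a, b)] = math.log(num / den)
    return out


class TestCodonPairBias:
    def test_uniform_pair_usage_gives_zero_cps(self):
        # single Phe-family corpus: every pair TTT/TTC combination equally
        seqs = [
            validate_cds(CodingSequence(f"s{i}", a + b))
            for i, (a, b) in enumerate(
                [("TTT", "TTT"), ("TTT", "TTC"), ("TTC", "TTT"), ("TTC", "TTC")]
            )
        ]
        stats = codon_pair_bias(seqs)
        assert np.allclose(stats.pair_table["cps"], 0.0, atol=1e-12)
        assert stats.cpb == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_toy_corpus(self, rng):
        for trial in range(20):
            seqs = [random_cds(rng, int(rng.integers(2, 30)), f"s{i}") for i in range(4)]
            stats = codon_pair_bias(seqs)
            oracle = brute_force_cps(seqs)
            got = {
                (r.codon_a, r.codon_b): r.cps
                for r in stats.pair_table.itertuples()
                if r.defined
            }
            assert set(got) == set(oracle)
            for k in oracle:
                assert got[k] == pytest.approx(oracle[k], rel=1e-9, abs=1e-12)

    def test_invariant_under_sequence_reordering(self, rng):
        seqs = [random_cds(rng, 25, f"s{i}") for i in range(6)]
        a = codon_pair_bias(seqs)
        b = codon_pair_bias(list(reversed(seqs)))
        assert a.cpb == pytest.approx(b.cpb, rel=1e-12)

    def test_all_cps_finite_for_observed_pairs(self, rng):
        seqs = [random_cds(rng, 40, f"s{i}") for i in range(5)]
        stats = codon_pair_bias(seqs)
        defined = stats.pair_table.loc[stats.pair_table["defined"], "cps"]
        assert np.isfinite(defined).all()
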