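"""Codon counting, RSCU and Wright's ENC against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cubkit.codon_metrics import (
    CodonCounts,
    classify_value,
    count_codons,
    enc,
    group_enc,
    group_rscu,
    rscu,
)
from cubkit.genetic_code import FAMILY_SIZE, SCORED_CODONS, SYN_FAMILIES
from cubkit.seq_io import CodingSequence, validate_cds
from tests.conftest import random_cds, random_counts


class TestCountCodons:
    def test_met_trp_excluded(self):
        s = validate_cds(CodingSequence("x", "ATGTTTTGG"))
        counts = count_codons(s)
        assert counts.counts == {"TTT": 1}

    def test_pooling_is_additive(self):
        s = validate_cds(CodingSequence("x", "TTTGCAGCA"))
        pooled = count_codons([s, s], pooling="pooled")
        single = count_codons(s)
        assert pooled.counts == {c: 2 * v for c, v in single.counts.items()}

    def test_one_of_each_informative_codon(self, one_of_each_cds):
        counts = count_codons(one_of_each_cds)
        assert counts.counts == {c: 1 for c in SCORED_CODONS}


def brute_force_rscu(counts: CodonCounts) -> dict[str, float]:
    out = {}
    for aa, codons in SYN_FAMILIES.items():
        tot = sum(counts.counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = len(codons) * counts.counts.get(c, 0) / tot if tot else float("nan")
    return out


class TestRSCU:
    def test_hand_example_phe(self):
        t = rscu(CodonCounts(counts={"TTT": 2, "TTC": 1}))
        assert t.values["TTT"] == pytest.approx(4 / 3, abs=5e-5)
        assert t.values["TTC"] == pytest.approx(2 / 3, abs=5e-5)

    def test_uniform_usage_gives_all_ones(self, one_of_each_cds):
        t = rscu(count_codons(one_of_each_cds))
        assert np.allclose([t.values[c] for c in SCORED_CODONS], 1.0)

    def test_zero_family_is_undefined_not_zero(self):
        t = rscu(CodonCounts(counts={"TTT": 3}))
        assert np.isnan(t.values["GGA"])
        assert t.classes["GGA"] == "undefined"
        assert "G" in t.undefined_families

    def test_family_sums_equal_family_sizes(self, rng):
        for _ in range(50):
            t = rscu(random_counts(rng))
            for aa, codons in SYN_FAMILIES.items():
                total = sum(t.values[c] for c in codons)
                assert total == pytest.approx(FAMILY_SIZE[aa], rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            counts = random_counts(rng)
            t = rscu(counts)
            oracle = brute_force_rscu(counts)
            for c in SCORED_CODONS:
                assert t.values[c] == pytest.approx(oracle[c], rel=1e-9, abs=1e-12)


class TestClassifyRSCU:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.94, "over"),
            (0.06, "under"),
            (1.6, "neutral"),  # strict > on the upper threshold
            (0.6, "neutral"),  # strict < on the lower threshold
            (1.0, "neutral"),
            (float("nan"), "undefined"),
        ],
    )
    def test_threshold_conventions(self, value, expected):
        assert classify_value(value) == expected


def brute_force_enc(counts: CodonCounts) -> float:
    """Wright's estimator recomputed family-by-family, independent of the
    implementation (explicit loops, separate repair logic)."""
    per_class = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in SYN_FAMILIES.items():
        obs = [counts.counts.get(c, 0) for c in codons]
        n = sum(obs)
        if n <= 1:
            continue
        s = sum((x / n) ** 2 for x in obs)
        per_class[len(codons)].append((n * s - 1) / (n - 1))
    means = {k: sum(v) / len(v) for k, v in per_class.items() if v}
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    if any(k not in means or means[k] <= 0 for k in (2, 3, 4, 6)):
        return float("nan")
    val = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(val, 61.0)


class TestENC:
    def test_single_codon_per_family_gives_20(self):
        counts = {cods[0]: 100 for cods in SYN_FAMILIES.values()}
        assert enc(CodonCounts(counts=counts)).enc == pytest.approx(20.0, abs=1e-9)

    def test_uniform_usage_approaches_61(self):
        counts = {c: 10_000 for c in SCORED_CODONS}
        e = enc(CodonCounts(counts=counts))
        assert e.enc == pytest.approx(61.0, abs=0.5)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            counts = random_counts(rng)
            got = enc(counts).enc
            want = brute_force_enc(counts)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-6)

    def test_range_clamped_and_flagged(self, rng):
        for _ in range(200):
            e = enc(random_counts(rng, max_count=8))
            if e.defined:
                assert 20.0 - 1e-9 <= e.enc <= 61.0 + 1e-12

    def test_missing_threefold_class_repaired(self):
        counts = {c: 10 for c in SCORED_CODONS if c not in SYN_FAMILIES["I"]}
        e = enc(CodonCounts(counts=counts))
        assert e.defined and e.repaired == (3,)

    def test_too_sparse_counts_undefined_not_infinite(self):
        e = enc(CodonCounts(counts={"TTT": 5, "TTC": 5}))
        assert not e.defined and np.isnan(e.enc)

    @given(st.integers(2, 20))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance_limit(self, k):
        """Multiplying counts by k moves ENC toward the multinomial limit
        2 + sum_classes(weight / mean_k(sum p^2)) monotonically in n."""
        base = {c: (i % 5) + 1 for i, c in enumerate(SCORED_CODONS)}
        small = enc(CodonCounts(counts=base)).enc
        big = enc(CodonCounts(counts={c: v * k for c, v in base.items()})).enc
        # closed-form limit as counts -> infinity
        per_class = {2: [], 3: [], 4: [], 6: []}
        for aa, codons in SYN_FAMILIES.items():
            obs = np.array([base[c] for c in codons], float)
            p = obs / obs.sum()
            per_class[len(codons)].append(float(np.sum(p**2)))
        limit = 2 + sum(
            w / np.mean(per_class[c]) for c, w in ((2, 9), (3, 1), (4, 5), (6, 3))
        )
        assert abs(big - limit) <= abs(small - limit) + 1e-9

    def test_monotone_in_concentration(self, rng):
        """Concentrating usage onto one codon per family never raises ENC."""
        prev = None
        for lam in (0.0, 0.3, 0.6, 0.9, 0.99):
            counts = {}
            for codons in SYN_FAMILIES.values():
                k = len(codons)
                uniform = np.full(k, 1000.0 / k)
                point = np.zeros(k)
                point[0] = 1000.0
                mix = (1 - lam) * uniform + lam * point
                counts.update({c: int(round(v)) for c, v in zip(codons, mix) if v >= 1})
            e = enc(CodonCounts(counts=counts)).enc
            if prev is not None:
                assert e <= prev + 1e-6
            prev = e


class TestGroups:
    def make_group(self, rng):
        seqs = []
        for i, host in enumerate(["citrus"] * 3 + ["Actinidia"] * 3):
            s = random_cds(rng, 120, f"s{i}")
            from dataclasses import replace

            seqs.append(replace(s, host=host, region="MP"))
        return seqs

    def test_group_enc_is_unweighted_mean(self, rng):
        seqs = self.make_group(rng)
        from cubkit.codon_metrics import enc_table

        per_seq = enc_table(seqs)
        grp = group_enc(seqs, ("host",)).set_index("host")
        for host in ("citrus", "Actinidia"):
            want = per_seq.loc[per_seq["host"] == host, "enc"].mean()
            assert grp.loc[host, "mean_enc"] == pytest.approx(want, rel=1e-12)

    def test_group_rscu_pools_counts(self, rng):
        seqs = self.make_group(rng)
        mat = group_rscu(seqs, ("host",))
        pooled = count_codons(
            [s for s in seqs if s.host == "citrus"], pooling="pooled"
        )
        want = rscu(pooled)
        from cubkit.genetic_code import to_rna

        got = dict(zip(mat["codon"], mat["citrus"]))
        for c in SCORED_CODONS:
            assert got[to_rna(c)] == pytest.approx(want.values[c], rel=1e-12)
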