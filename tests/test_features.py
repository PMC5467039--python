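"""Feature statistics vs independent oracles; full-vector recomputation."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editml import (FEATURE_NAMES, IntervalIndex, Observation, PileupColumn,
                    ReferenceGenome, build_interval_index, extract_candidates,
                    featurize, homopolymer_length, read_position_stats,
                    sequence_context, strand_bias_p)
from editml.errors import DegenerateDataError, InputFormatError


def fisher_exact_oracle(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration (Fractions)."""
    r1, r2, cs = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = math.comb(n, cs)

    def weight(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, cs - x), denom)

    lo, hi = max(0, cs - r2), min(r1, cs)
    p_obs = weight(a)
    total = sum(weight(x) for x in range(lo, hi + 1) if weight(x) <= p_obs)
    return float(min(total, Fraction(1)))


class TestIntervalIndex:
    def test_half_open_boundaries(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("c\t10\t20\n")
        idx = build_interval_index(str(bed))
        assert idx.contains("c", 10)
        assert idx.contains("c", 19)
        assert not idx.contains("c", 20)
        assert not idx.contains("c", 9)
        assert not idx.contains("other", 15)

    def test_malformed_bed_reports_line(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("c\t10\t20\nc\tten\t20\n")
        with pytest.raises(InputFormatError, match=":2"):
            build_interval_index(str(bed))

    @given(st.lists(st.tuples(st.integers(0, 1000), st.integers(1, 50)),
                    min_size=1, max_size=100),
           st.lists(st.integers(0, 1100), min_size=1, max_size=100))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_agrees_with_linear_scan(self, raw, queries):
        intervals = [(s, s + ln) for s, ln in raw]
        idx = IntervalIndex()
        for s, e in intervals:
            idx.add("c", s, e)
        for q in queries:
            expected = any(s <= q < e for s, e in intervals)
            assert idx.contains("c", q) == expected


class TestStrandBias:
    def test_balanced_table_is_one(self):
        assert strand_bias_p(5, 5, 5, 5) == pytest.approx(1.0)

    def test_all_zero_defined_as_one(self):
        assert strand_bias_p(0, 0, 0, 0) == 1.0

    def test_extreme_table_matches_enumeration(self):
        p = strand_bias_p(10, 0, 0, 10)
        assert p == pytest.approx(fisher_exact_oracle(10, 0, 0, 10), abs=1e-10)
        assert p == pytest.approx(1.0825088224469085e-05, rel=1e-6)

    @pytest.mark.parametrize("table", [(3, 1, 1, 3), (2, 7, 5, 0),
                                       (0, 0, 3, 9), (12, 1, 1, 12)])
    def test_matches_enumeration(self, table):
        assert strand_bias_p(*table) == pytest.approx(
            fisher_exact_oracle(*table), abs=1e-10)

    @given(st.tuples(*[st.integers(0, 25)] * 4))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_transposition_symmetry(self, table):
        rp, rm, ap, am = table
        # swapping strand columns together with ref/alt rows = transposition
        assert strand_bias_p(rp, rm, ap, am) == pytest.approx(
            strand_bias_p(rp, ap, rm, am), abs=1e-12)


class TestReadPositionStats:
    def test_constant_list(self):
        mean, sd, frac = read_position_stats([0.5, 0.5], [10, 10])
        assert (mean, sd, frac) == (0.5, 0.0, 0.0)

    def test_near_end_fraction(self):
        _, _, frac = read_position_stats([0.1, 0.5, 0.9], [2, 10, 3])
        assert frac == pytest.approx(2 / 3)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        rel = rng.random(30).tolist()
        dist = rng.integers(0, 40, 30).tolist()
        mean, sd, frac = read_position_stats(rel, dist)
        assert mean == pytest.approx(sum(rel) / 30)
        assert sd == pytest.approx(
            (sum((x - sum(rel) / 30) ** 2 for x in rel) / 30) ** 0.5)
        assert frac == pytest.approx(sum(d <= 5 for d in dist) / 30)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateDataError):
            read_position_stats([], [])


class TestSequenceHelpers:
    REF = ReferenceGenome({"c": "CAAAAGTACGT"})

    def test_homopolymer_visible_run(self):
        for pos in (1, 2, 3, 4):
            assert homopolymer_length(self.REF, "c", pos) == 4
        assert homopolymer_length(self.REF, "c", 0) == 1

    def test_homopolymer_matches_scanning_oracle(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        ref = ReferenceGenome({"c": seq})
        for pos in rng.integers(0, 1000, 100):
            pos = int(pos)
            left = pos
            while left > 0 and seq[left - 1] == seq[pos]:
                left -= 1
            right = pos
            while right + 1 < len(seq) and seq[right + 1] == seq[pos]:
                right += 1
            assert homopolymer_length(ref, "c", pos) == right - left + 1

    def test_context_read_off(self):
        ref = ReferenceGenome({"c": "TAG"})
        vec = sequence_context(ref, "c", 1)
        # 5' = T one-hot, 3' = G one-hot
        assert vec.tolist() == [0, 0, 0, 1, 0, 0, 1, 0]

    def test_context_one_hot_identity(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 500))
        ref = ReferenceGenome({"c": seq})
        for pos in rng.integers(1, 499, 50):
            vec = sequence_context(ref, "c", int(pos))
            assert vec[:4].sum() == 1.0 and vec[4:].sum() == 1.0

    def test_contig_edge_gives_all_zero_group(self):
        ref = ReferenceGenome({"c": "ACGTACGT"})
        vec = sequence_context(ref, "c", 0)
        assert vec[:4].sum() == 0.0 and vec[4:].sum() == 1.0


def build_fixture_column():
    """A 20-observation column with a planted A>G variant."""
    rng = np.random.default_rng(11)
    obs = []
    for i in range(20):
        base = "G" if i < 6 else "A"
        obs.append(Observation(
            base=base,
            baseq=int(rng.integers(20, 41)),
            mapq=int(rng.integers(30, 61)),
            relpos=float(rng.random()),
            end_dist=int(rng.integers(0, 50)),
            mismatches=int(rng.integers(0, 4)),
            softclip_frac=float(rng.random() * 0.2),
            strand="+" if rng.random() < 0.6 else "-",
            splice_dist=int(rng.integers(0, 100)),
        ))
    return PileupColumn("c", 50, "A", obs)


class TestFeaturize:
    REF = ReferenceGenome({"c": "ACGT" * 30})

    def _vector(self, column, alu=None, repeats=None):
        (site,) = extract_candidates([column], 1, 0.01, 1)
        return featurize(site, column, alu or IntervalIndex(),
                         repeats or IntervalIndex(), self.REF), site

    def test_length_and_order_stability(self):
        vec, _ = self._vector(build_fixture_column())
        assert vec.shape == (28,)
        assert len(FEATURE_NAMES) == 28

    def test_type_and_membership_flags(self):
        alu = IntervalIndex()
        alu.add("c", 40, 60)
        vec, _ = self._vector(build_fixture_column(), alu=alu)
        names = dict(zip(FEATURE_NAMES, vec))
        assert (names["is_ag"], names["is_tc"], names["is_a_to_i"]) == (1, 0, 1)
        assert names["alu"] == 1.0

    def test_non_a_to_i_flags_zero(self):
        obs = [Observation("T" if i < 5 else "C", 30, 60, 0.5, 20, 0, 0.0,
                           "+", 10**9) for i in range(20)]
        col = PileupColumn("c", 50, "C", obs)  # C>T substitution
        vec, site = self._vector(col)
        names = dict(zip(FEATURE_NAMES, vec))
        assert site.substitution == "C>T"
        assert (names["is_ag"], names["is_tc"], names["is_a_to_i"]) == (0, 0, 0)

    def test_every_entry_matches_independent_recomputation(self):
        col = build_fixture_column()
        alu = IntervalIndex()
        repeats = IntervalIndex()
        repeats.add("c", 50, 51)
        vec, site = self._vector(col, repeats=repeats)
        var = [o for o in col.obs if o.base == "G"]
        ref_o = [o for o in col.obs if o.base == "A"]
        rel = [o.relpos for o in var]
        expected = {
            "var_reads": 6,
            "coverage": 20,
            "editing_level": 6 / 20,
            "mapq_var_mean": sum(o.mapq for o in var) / 6,
            "mapq_all_mean": sum(o.mapq for o in col.obs) / 20,
            "baseq_var_mean": sum(o.baseq for o in var) / 6,
            "relpos_var_mean": sum(rel) / 6,
            "relpos_var_sd": (sum((x - sum(rel) / 6) ** 2 for x in rel) / 6) ** 0.5,
            "near_end_frac": sum(o.end_dist <= 5 for o in var) / 6,
            "strand_bias_p": fisher_exact_oracle(
                sum(o.strand == "+" for o in ref_o),
                sum(o.strand == "-" for o in ref_o),
                sum(o.strand == "+" for o in var),
                sum(o.strand == "-" for o in var)),
            "var_plus_frac": sum(o.strand == "+" for o in var) / 6,
            "simple_repeat": 1.0,
            "homopolymer_len": 1.0,
            "mismatch_var_mean": sum(o.mismatches for o in var) / 6,
            "softclip_var_mean": sum(o.softclip_frac for o in var) / 6,
            "near_splice": float(any(o.splice_dist <= 4 for o in col.obs)),
            "is_ag": 1.0, "is_tc": 0.0, "is_a_to_i": 1.0, "alu": 0.0,
            # pos0 50 in "ACGT"*30: 5' = C (index 49), 3' = T (index 51)
            "up_A": 0.0, "up_C": 1.0, "up_G": 0.0, "up_T": 0.0,
            "down_A": 0.0, "down_C": 0.0, "down_G": 0.0, "down_T": 1.0,
        }
        got = dict(zip(FEATURE_NAMES, vec))
        for name in FEATURE_NAMES:
            assert got[name] == pytest.approx(expected[name], abs=1e-9), name

    def test_invariants_bounds(self):
        vec, _ = self._vector(build_fixture_column())
        names = dict(zip(FEATURE_NAMES, vec))
        assert 0.0 <= names["editing_level"] <= 1.0
        assert 0.0 < names["strand_bias_p"] <= 1.0
        for flag in ("simple_repeat", "near_splice", "is_ag", "is_tc",
                     "is_a_to_i", "alu"):
            assert names[flag] in (0.0, 1.0)
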