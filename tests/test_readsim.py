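"""Sampling plans, pair drawing, ligation attenuation and noise models."""

import numpy as np
import pytest

from svforge.forge import apply_edit, forge, reverse_complement
from svforge.formats import LibrarySpec, VariantSpec
from svforge.readsim import (
    PlanEntry,
    apply_errors,
    attenuated,
    build_sampling_plan,
    implied_reference_insert,
    lift_interval,
    read_depth,
    reference_read_depth,
    sample_pairs,
    simulate_plan,
)

from conftest import random_sequence

LIB = LibrarySpec(insert_mean=400, insert_sd=50, read_len=100, coverage=30.0)


def _forged_del(rng, n=5000, pos=2001, dlen=500, fraction=0.5, hom=False):
    seq = random_sequence(rng, n)
    v = VariantSpec(vid="d", chrom="c", pos=pos, del_len=dlen, fraction=fraction,
                    ploidy=2, haplotypes=frozenset({1, 2}) if hom else frozenset({1}),
                    svtype="DEL")
    return forge(seq, v, offset=1)


class TestSamplingPlan:
    def test_fully_clonal_homozygous_uses_only_altered_contigs(self, rng):
        pair = _forged_del(rng, fraction=1.0, hom=True)
        entries = build_sampling_plan(pair, [LIB], 1.0, "c_t0")
        kinds = {(e.kind, e.hap): e.coverage for e in entries}
        assert kinds == {("alt", 1): 15.0, ("alt", 2): 15.0}

    def test_fraction_zero_looks_like_noop(self, rng):
        pair = _forged_del(rng, fraction=0.0)
        entries = build_sampling_plan(pair, [LIB], 0.0, "c_t0")
        assert len(entries) == 1
        assert entries[0].kind == "org" and entries[0].coverage == 30.0

    def test_expected_counts_follow_contig_length(self, rng):
        # deletion of half the contig: altered contig yields half the pairs
        pair = _forged_del(rng, n=4000, pos=1001, dlen=2000, fraction=0.5, hom=True)
        entries = build_sampling_plan(pair, [LIB], 0.5, "c_t0")
        org = next(e for e in entries if e.kind == "org")
        alts = [e for e in entries if e.kind == "alt"]
        L, R = 4000, LIB.read_len
        assert org.expected_pairs == pytest.approx(0.5 * 30 * L / (2 * R))
        for e in alts:
            assert e.expected_pairs == pytest.approx(0.25 * 30 * (L - 2000) / (2 * R))

    def test_haplotype_weights_sum_to_one(self, rng):
        for fraction in (0.0, 0.3, 1.0):
            pair = _forged_del(rng, fraction=fraction)
            entries = build_sampling_plan(pair, [LIB], fraction, "p")
            per_hap = LIB.coverage / pair.ploidy
            total = sum(e.coverage for e in entries)
            assert total == pytest.approx(LIB.coverage)
            alt_cov = sum(e.coverage for e in entries if e.kind == "alt")
            assert alt_cov == pytest.approx(per_hap * fraction)

    def test_multiple_libraries_each_get_entries(self, rng):
        pair = _forged_del(rng, fraction=0.5)
        lib2 = LibrarySpec(3000, 300, 100, 10.0)
        entries = build_sampling_plan(pair, [LIB, lib2], 0.5, "p")
        assert {e.library.insert_mean for e in entries} == {400, 3000}


class TestSamplePairs:
    def _entry(self, rng, n=6000, zones=(), coverage=30.0, lib=LIB):
        seq = random_sequence(rng, n)
        return PlanEntry("c_t0_org", seq, coverage, lib, zones=zones)

    def test_pair_geometry_and_orientation(self, rng):
        entry = self._entry(rng)
        pairs = sample_pairs(entry, rng)
        assert len(pairs) > 0
        for p in pairs[:50]:
            assert len(p.seq1) == len(p.seq2) == LIB.read_len
            assert 2 * LIB.read_len <= p.insert <= len(entry.seq)
            assert 0 <= p.frag_start <= len(entry.seq) - p.insert
            frag = entry.seq[p.frag_start : p.frag_start + p.insert]
            fwd, rev = frag[: LIB.read_len], reverse_complement(frag[-LIB.read_len :])
            assert (p.seq1, p.seq2) == ((fwd, rev) if p.read1_forward else (rev, fwd))

    def test_realized_count_near_expectation(self, rng):
        entry = self._entry(rng, n=50_000, coverage=60.0)
        pairs = sample_pairs(entry, rng)
        expected = entry.expected_pairs
        assert abs(len(pairs) - expected) < 4 * np.sqrt(expected)

    def test_contig_shorter_than_insert_warns_and_yields_nothing(self, rng):
        entry = self._entry(rng, n=150)
        with pytest.warns(UserWarning, match="shorter"):
            assert sample_pairs(entry, rng) == []

    def test_zero_coverage_yields_empty_stream(self, rng):
        entry = self._entry(rng, coverage=0.0)
        assert sample_pairs(entry, rng) == []

    def test_deterministic_for_fixed_seed(self):
        seq = random_sequence(np.random.Generator(np.random.PCG64(0)), 6000)
        entry = PlanEntry("x", seq, 30.0, LIB)
        a = sample_pairs(entry, np.random.Generator(np.random.PCG64(9)))
        b = sample_pairs(entry, np.random.Generator(np.random.PCG64(9)))
        assert a == b

    def test_attenuation_predicate_requires_containment(self):
        zones = ((0, 1000),)
        assert attenuated(10, 900, zones)
        assert not attenuated(10, 1100, zones), "straddling fragments keep full rate"
        assert not attenuated(1500, 1900, zones)

    def test_ligation_zone_depth_is_half_interior(self, rng):
        entry = self._entry(rng, n=10_000, coverage=120.0,
                            zones=((0, 1000), (9000, 10_000)),
                            lib=LibrarySpec(300, 50, 150, 120.0))
        pairs = sample_pairs(entry, rng)
        depth = read_depth(pairs, 10_000)
        interior = depth[1000:9000].mean()
        zone = (depth[:1000].mean() + depth[9000:].mean()) / 2
        assert zone / interior == pytest.approx(0.5, abs=0.06)


class TestErrorsAndSmallVariants:
    def test_zero_error_rate_is_identity(self, rng):
        entry = PlanEntry("x", random_sequence(rng, 4000), 10.0, LIB)
        for p in sample_pairs(entry, rng)[:10]:
            assert apply_errors(p, LIB, rng) == p

    def test_substitution_rate_matches_binomial_expectation(self, rng):
        lib = LibrarySpec(400, 50, 100, 60.0, base_error=0.01)
        seq = random_sequence(rng, 20_000)
        entry = PlanEntry("x", seq, 60.0, lib)
        pairs = [apply_errors(p, lib, rng) for p in sample_pairs(entry, rng)]
        mismatches = bases = 0
        for p in pairs:
            (s1, e1), (s2, e2) = p.read_intervals()
            t1 = seq[s1:e1]
            t2 = reverse_complement(seq[s2:e2])
            r1, r2 = (p.seq1, p.seq2) if p.read1_forward else (p.seq2, p.seq1)
            mismatches += sum(a != b for a, b in zip(r1, t1))
            mismatches += sum(a != b for a, b in zip(r2, t2))
            bases += len(r1) + len(r2)
        rate = mismatches / bases
        se = np.sqrt(0.01 * 0.99 / bases)
        assert abs(rate - 0.01) < 3 * se

    def test_error_quality_encoding(self, rng):
        lib = LibrarySpec(400, 50, 100, 5.0, base_error=0.01)
        entry = PlanEntry("x", random_sequence(rng, 4000), 5.0, lib)
        (p, *_) = sample_pairs(entry, rng)
        assert p.qual1 == chr(20 + 33) * 100  # Q20 for 1% error

    def test_planted_snvs_shared_across_overlapping_reads(self, rng):
        lib = LibrarySpec(400, 50, 100, 80.0, snv_rate=0.002)
        seq = random_sequence(rng, 8000)
        entry = PlanEntry("x", seq, 80.0, lib)
        pairs = simulate_plan([entry], rng)
        # reconstruct the per-position consensus of read bases; planted SNVs
        # must be unanimous across all reads covering the site
        votes: dict[int, set] = {}
        for p in pairs:
            (s1, e1), (s2, e2) = p.read_intervals()
            r1, r2 = (p.seq1, p.seq2) if p.read1_forward else (p.seq2, p.seq1)
            for (s, e), bases in (((s1, e1), r1), ((s2, e2), reverse_complement(r2))):
                for k in range(s, e):
                    votes.setdefault(k, set()).add(bases[k - s])
        differing = {k for k, vs in votes.items() if seq[k] not in vs or len(vs) > 1}
        # all multi-covered differing sites agree on one substituted base
        for k in differing:
            assert len(votes[k]) == 1
        assert len(differing) > 0, "with 8000 bp at 0.2% some SNVs must land"


class TestReferenceFrame:
    def test_lift_through_deletion(self):
        _, pieces, _ = apply_edit("A" * 1000, "DEL", 401, 100, "")
        assert lift_interval(pieces, 0, 400) == [(0, 400)]
        assert lift_interval(pieces, 400, 500) == [(500, 600)]
        assert lift_interval(pieces, 350, 450) == [(350, 400), (500, 550)]

    def test_lift_through_inversion_reverses_coordinates(self):
        _, pieces, _ = apply_edit("A" * 100, "INV", 41, 20, "")
        assert lift_interval(pieces, 40, 45) == [(55, 60)]

    def test_implied_insert_across_deletion(self, rng):
        pair_obj = _forged_del(rng, n=5000, pos=2001, dlen=500, fraction=1.0, hom=True)
        entry = PlanEntry("x", pair_obj.altered, 60.0, LIB, pieces=pair_obj.pieces,
                          kind="alt", hap=1)
        inserts = []
        for p in sample_pairs(entry, rng):
            (s1, e1), (s2, e2) = p.read_intervals()
            implied = implied_reference_insert(p, entry.pieces)
            if implied is None:
                continue
            straddles = s1 + LIB.read_len <= 2000 <= s2
            if straddles:
                inserts.append(implied)
                assert implied == p.insert + 500
            else:
                assert implied == p.insert
        assert inserts, "some pairs must straddle the deletion"

    def test_reference_depth_zero_inside_full_deletion(self, rng):
        pair_obj = _forged_del(rng, n=5000, pos=2001, dlen=500, fraction=1.0, hom=True)
        entry = PlanEntry("x", pair_obj.altered, 60.0, LIB, pieces=pair_obj.pieces,
                          kind="alt", hap=1)
        pairs = sample_pairs(entry, rng)
        depth = reference_read_depth(pairs, entry.pieces, 5000)
        assert depth[2000:2500].max() == 0
        assert depth[500:1500].mean() > 0
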