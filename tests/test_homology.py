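"""Builtin aligner, hit filtering, pair selection, and the tabular cache."""

import difflib

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from genodraw.errors import ConfigError, ParseError
from genodraw.fixtures import FixtureSpec, PlantedHomology, generate
from genodraw.homology import (
    HomologyConfig,
    HomologyHit,
    builtin_search,
    cache_hits,
    compute_homology,
    filter_hits,
    load_cached_hits,
    select_pairs,
)
from genodraw.seqio import SequenceRecord, parse_genbank


def _rec(rid, residues, active=True):
    return SequenceRecord(
        record_id=rid,
        display_name=rid,
        length_bp=len(residues),
        residues=residues,
        active=active,
    )


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class TestBuiltinSearch:
    def test_planted_exact_repeat_recovered_at_full_identity(self):
        rng = np.random.default_rng(0)
        a = _random_seq(rng, 3000)
        b = _random_seq(rng, 3000)
        b = b[:1200] + a[500:1000] + b[1700:]  # exact 500 bp copy
        q, s = _rec("A", a), _rec("B", b)
        hits = [h for h in builtin_search(q, s, seed_length=11) if h.align_length >= 400]
        assert len(hits) == 1
        hit = hits[0]
        assert hit.percent_identity == 100.0
        assert not hit.inverted
        # agrees with the brute-force longest-common-substring oracle
        sm = difflib.SequenceMatcher(None, a, b, autojunk=False)
        m = sm.find_longest_match(0, len(a), 0, len(b))
        assert hit.q_start <= m.a and hit.q_end >= m.a + m.size
        assert hit.s_start <= m.b and hit.s_end >= m.b + m.size

    def test_reverse_complement_copy_is_flagged_inverted(self):
        rng = np.random.default_rng(1)
        a = _random_seq(rng, 3000)
        b = _random_seq(rng, 3000)
        b = b[:800] + reverse_complement(a[1000:1500]) + b[1300:]
        hits = [
            h
            for h in builtin_search(_rec("A", a), _rec("B", b), seed_length=11)
            if h.align_length >= 400
        ]
        assert len(hits) == 1
        hit = hits[0]
        assert hit.inverted
        # covers the planted region; x-drop extension may add a few
        # chance-matching background bases at either end
        assert hit.q_start <= 1000 and hit.q_end >= 1500
        assert hit.s_start <= 800 and hit.s_end >= 1300
        assert 1000 - hit.q_start <= 25 and hit.q_end - 1500 <= 25
        assert 800 - hit.s_start <= 25 and hit.s_end - 1300 <= 25

    def test_self_pair_reports_full_length_identity_hit(self):
        rng = np.random.default_rng(2)
        a = _random_seq(rng, 2000)
        rec = _rec("A", a)
        hits = builtin_search(rec, rec, seed_length=11)
        full = [h for h in hits if h.q_start == 0 and h.q_end == 2000 and not h.inverted]
        assert full and full[0].percent_identity == 100.0

    def test_sequences_without_shared_seeds_give_no_hits(self):
        q = _rec("A", "A" * 500)
        s = _rec("B", "C" * 500)
        assert builtin_search(q, s, seed_length=11) == []

    def test_short_seed_rejected(self):
        rec = _rec("A", "ACGTACGT")
        with pytest.raises(ConfigError, match="seed_length"):
            builtin_search(rec, rec, seed_length=3)

    def test_feature_only_record_rejected_with_clear_error(self):
        rec = SequenceRecord(record_id="A", display_name="A", length_bp=100)
        with pytest.raises(ParseError, match="no residues"):
            builtin_search(rec, _rec("B", "ACGT" * 30))

    def test_inversion_symmetry_against_reverse_complemented_subject(self):
        rng = np.random.default_rng(3)
        a = _random_seq(rng, 2500)
        b = _random_seq(rng, 2500)
        b = b[:500] + a[200:900] + b[1200:]
        q = _rec("A", a)
        direct = builtin_search(q, _rec("B", b), seed_length=11)
        flipped = builtin_search(q, _rec("Brc", reverse_complement(b)), seed_length=11)
        n = len(b)
        direct_set = {
            (h.q_start, h.q_end, h.s_start, h.s_end, h.inverted) for h in direct
        }
        reflected = {
            (h.q_start, h.q_end, n - h.s_end, n - h.s_start, not h.inverted)
            for h in flipped
        }
        assert direct_set == reflected

    def test_mutated_copy_recovered_with_expected_identity(self, tmp_path):
        spec = FixtureSpec(
            n_records=2,
            min_length_bp=5000,
            max_length_bp=5000,
            homologies=[PlantedHomology(0, 1, length=1000, identity=95.0)],
            seed=11,
            file_stem="mut",
        )
        paths, truth = generate(spec, tmp_path)
        recs = [r for p in paths for r in parse_genbank(p)]
        gt = truth.homologies[0]
        hits = [h for h in builtin_search(recs[0], recs[1]) if h.align_length >= 800]
        assert len(hits) == 1
        hit = hits[0]
        overlap = min(hit.q_end, gt.q_end) - max(hit.q_start, gt.q_start)
        assert overlap / (gt.q_end - gt.q_start) >= 0.95
        assert abs(hit.percent_identity - gt.identity) < 1.5


class TestFilterHits:
    def _hit(self, length=100, identity=90.0, evalue=1e-5):
        return HomologyHit(
            query_id="A",
            subject_id="B",
            q_start=0,
            q_end=length,
            s_start=0,
            s_end=length,
            percent_identity=identity,
            align_length=length,
            evalue=evalue,
            bitscore=float(length),
        )

    def _random_hits(self, rng, n=200):
        return [
            self._hit(
                length=int(rng.integers(20, 5000)),
                identity=float(np.round(rng.uniform(40, 100), 2)),
                evalue=float(10.0 ** rng.uniform(-30, 1)),
            )
            for _ in range(n)
        ]

    def test_impossible_identity_threshold_empties_the_list(self):
        cfg = HomologyConfig(min_identity=101)
        assert filter_hits([self._hit()], cfg) == []

    def test_vacuous_thresholds_return_input_unchanged(self):
        hits = [self._hit(), self._hit(length=5, identity=1.0, evalue=9.0)]
        cfg = HomologyConfig(min_length=0, min_identity=0, max_evalue=1e9)
        assert filter_hits(hits, cfg) == hits

    def test_matches_brute_force_predicate_on_random_hits(self):
        rng = np.random.default_rng(4)
        hits = self._random_hits(rng)
        cfg = HomologyConfig(min_length=300, min_identity=80.0, max_evalue=1e-3)
        expected = [
            h
            for h in hits
            if h.align_length >= 300
            and h.percent_identity >= 80.0
            and h.evalue <= 1e-3
        ]
        assert filter_hits(hits, cfg) == expected

    def test_filtering_is_monotone_in_every_threshold(self):
        rng = np.random.default_rng(5)
        hits = self._random_hits(rng)
        base = HomologyConfig(min_length=100, min_identity=70.0, max_evalue=1e-2)
        n0 = len(filter_hits(hits, base))
        for tighter in (
            HomologyConfig(min_length=500, min_identity=70.0, max_evalue=1e-2),
            HomologyConfig(min_length=100, min_identity=90.0, max_evalue=1e-2),
            HomologyConfig(min_length=100, min_identity=70.0, max_evalue=1e-8),
        ):
            assert len(filter_hits(hits, tighter)) <= n0

    def test_builtin_sentinel_evalue_always_passes(self):
        hit = self._hit(evalue=0.0)
        assert filter_hits([hit], HomologyConfig(max_evalue=1e-30)) == [hit]


class TestSelectPairs:
    def _records(self, n, inactive=()):
        return [
            _rec(f"R{i}", "ACGT" * 10, active=i not in inactive) for i in range(1, n + 1)
        ]

    def test_adjacent_mode_pairs_consecutive_active_records(self):
        cfg = HomologyConfig(pairing="adjacent")
        assert select_pairs(self._records(4), cfg) == [
            ("R1", "R2"),
            ("R2", "R3"),
            ("R3", "R4"),
        ]

    def test_custom_pairs_drop_entries_with_inactive_members(self):
        cfg = HomologyConfig(
            pairing="custom", custom_pairs=[("R1", "R3"), ("R2", "R5")]
        )
        assert select_pairs(self._records(5, inactive={5}), cfg) == [("R1", "R3")]

    def test_custom_pairs_are_exactly_the_listed_ones(self):
        # non-adjacent comparisons only, as when pairing cassette elements
        # against distant donor sequences: no adjacent pairs sneak in
        cfg = HomologyConfig(
            pairing="custom", custom_pairs=[("R1", "R4"), ("R2", "R4")]
        )
        assert select_pairs(self._records(4), cfg) == [("R1", "R4"), ("R2", "R4")]

    def test_custom_pair_with_unknown_record_is_a_config_error(self):
        cfg = HomologyConfig(pairing="custom", custom_pairs=[("R1", "Rx")])
        with pytest.raises(ConfigError, match="Rx"):
            select_pairs(self._records(2), cfg)


class TestCache:
    def _hits(self):
        return [
            HomologyHit("A", "B", 10, 500, 200, 690, 97.5, 490, 1e-20, 850.0, False),
            HomologyHit("A", "B", 900, 1200, 50, 350, 88.123, 300, 0.001, 210.5, True),
            HomologyHit("B", "C", 0, 90, 10, 100, 100.0, 90, 0.0, 90.0, False),
        ]

    def test_write_then_read_is_field_identical(self, tmp_path):
        path = tmp_path / "cache.tsv"
        cache_hits(self._hits(), path, program="builtin")
        assert load_cached_hits(path) == self._hits()

    def test_caching_is_idempotent(self, tmp_path):
        p1, p2 = tmp_path / "c1.tsv", tmp_path / "c2.tsv"
        cache_hits(self._hits(), p1)
        once = load_cached_hits(p1)
        cache_hits(once, p2)
        assert load_cached_hits(p2) == once

    def test_empty_hit_list_round_trips_through_header_only_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        cache_hits([], path, program="blastn")
        text = path.read_text()
        assert text.startswith("#") and "blastn" in text
        assert load_cached_hits(path) == []

    def test_malformed_line_is_a_parse_error_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# header\nA\tB\tnot-enough-columns\n")
        with pytest.raises(ParseError, match="line 2"):
            load_cached_hits(path)

    def test_inverted_hits_survive_the_blast_coordinate_encoding(self, tmp_path):
        path = tmp_path / "inv.tsv"
        original = [h for h in self._hits() if h.inverted]
        cache_hits(original, path)
        raw = path.read_text().splitlines()[1].split("\t")
        assert int(raw[8]) > int(raw[9])  # sstart > send encodes the inversion
        assert load_cached_hits(path) == original


class TestComputeHomology:
    def test_results_are_cached_per_pair_and_reused(self, tmp_path, demo_records):
        cfg = HomologyConfig(program="builtin", cache_path=str(tmp_path / "cache"))
        first = compute_homology(demo_records, cfg)
        files = sorted(p.name for p in (tmp_path / "cache").glob("*.tsv"))
        assert files == [
            "DEMO01__DEMO02__builtin.tsv",
            "DEMO02__DEMO03__builtin.tsv",
        ]
        # poison one cache file: reuse must read it rather than re-search
        target = tmp_path / "cache" / "DEMO01__DEMO02__builtin.tsv"
        target.write_text("# genodraw homology cache program=builtin records=\n")
        second = compute_homology(demo_records, cfg)
        assert second[("DEMO01", "DEMO02")] == []
        assert second[("DEMO02", "DEMO03")] == first[("DEMO02", "DEMO03")]
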