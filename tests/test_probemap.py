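import numpy as np
import pytest

from anchorprobe import (
    CoverageError,
    OligoProbe,
    ProbeHit,
    ProbesetMapping,
    TemplateLengthError,
    build_mappings,
    coverage_fraction,
    map_probes,
    rank_probesets,
    reverse_complement,
    select_template,
)
from anchorprobe.probemap import PROBE_LENGTH


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def naive_map(probes, transcripts, allow_antisense=True):
    """Position-by-position oracle for exact probe matching."""
    hits = set()
    for tid, seq in transcripts.items():
        for p in probes:
            rc = reverse_complement(p.sequence)
            for i in range(len(seq) - PROBE_LENGTH + 1):
                window = seq[i : i + PROBE_LENGTH]
                if window == p.sequence:
                    hits.add((p.probeset_id, p.probe_index, tid, i, "sense"))
                if allow_antisense and window == rc:
                    hits.add((p.probeset_id, p.probe_index, tid, i, "antisense"))
    return hits


class TestMapProbes:
    def test_planted_substring_found_at_exact_position(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 400)
        probe = OligoProbe("ps", 0, seq[100:125])
        hits = map_probes([probe], {"t": seq})
        assert [(h.start, h.end, h.orientation) for h in hits] == [
            (100, 125, "sense")
        ]

    def test_antisense_probe_reported_with_transcript_coordinates(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 200)
        probe = OligoProbe("ps", 0, reverse_complement(seq[40:65]))
        hits = map_probes([probe], {"t": seq}, allow_antisense=True)
        assert [(h.start, h.end, h.orientation) for h in hits] == [
            (40, 65, "antisense")
        ]
        assert map_probes([probe], {"t": seq}, allow_antisense=False) == []

    def test_fixture_probes_found_at_truth_coordinates(self, tx_fixture):
        transcripts, probes, truth = tx_fixture
        hits = map_probes(probes, transcripts)
        found = {
            (h.probeset_id, h.probe_index, h.transcript_id, h.start, h.orientation)
            for h in hits
        }
        expected = {
            (pid, idx, tid, start, orient)
            for pid, (tid, coords) in truth.planted_probesets.items()
            for idx, start, end, orient in coords
        }
        assert found == expected

    def test_every_hit_reextracts_to_the_probe(self, tx_fixture):
        transcripts, probes, _ = tx_fixture
        probe_seq = {(p.probeset_id, p.probe_index): p.sequence for p in probes}
        for h in map_probes(probes, transcripts):
            sub = transcripts[h.transcript_id][h.start : h.end]
            expected = probe_seq[(h.probeset_id, h.probe_index)]
            if h.orientation == "antisense":
                expected = reverse_complement(expected)
            assert sub == expected

    def test_agrees_with_naive_scan_on_random_transcriptome(self):
        rng = np.random.default_rng(99)
        transcripts = {f"t{i}": _random_seq(rng, 1000) for i in range(20)}
        probes = []
        # half planted (guaranteed hits, some antisense), half random decoys
        for i in range(10):
            tid = f"t{rng.integers(0, 20)}"
            pos = int(rng.integers(0, 1000 - PROBE_LENGTH))
            sub = transcripts[tid][pos : pos + PROBE_LENGTH]
            if i % 2:
                sub = reverse_complement(sub)
            probes.append(OligoProbe(f"ps{i % 3}", i, sub))
        for i in range(10, 20):
            probes.append(OligoProbe(f"ps{i % 3}", i, _random_seq(rng, PROBE_LENGTH)))
        hits = map_probes(probes, transcripts)
        got = {
            (h.probeset_id, h.probe_index, h.transcript_id, h.start, h.orientation)
            for h in hits
        }
        assert got == naive_map(probes, transcripts)


class TestCoverage:
    @pytest.mark.parametrize(
        "n_hit, size, frac", [(9, 11, 9 / 11), (8, 11, 8 / 11), (11, 11, 1.0)]
    )
    def test_distinct_probe_fraction(self, n_hit, size, frac):
        hits = [
            ProbeHit("ps", i, "t", i * 30, i * 30 + PROBE_LENGTH, "sense")
            for i in range(n_hit)
        ]
        assert coverage_fraction(hits, size) == pytest.approx(frac)
        # duplicate hits of one probe do not inflate coverage
        assert coverage_fraction(hits + hits[:3], size) == pytest.approx(frac)

    def test_eighty_percent_rule_boundary(self):
        assert coverage_fraction(
            [ProbeHit("ps", i, "t", 0, 25, "sense") for i in range(9)], 11
        ) >= 0.8
        assert coverage_fraction(
            [ProbeHit("ps", i, "t", 0, 25, "sense") for i in range(8)], 11
        ) < 0.8


def _mapping(tid, positions, size=11):
    hits = tuple(
        ProbeHit("ps", i, tid, p, p + PROBE_LENGTH, "sense")
        for i, p in enumerate(positions)
    )
    return ProbesetMapping("ps", tid, hits, len(positions) / size)


class TestSelectTemplate:
    def test_low_coverage_rejected(self):
        rng = np.random.default_rng(2)
        ts = {"t": _random_seq(rng, 2000)}
        with pytest.raises(CoverageError):
            select_template(ts, _mapping("t", [100, 200, 300], size=11))

    def test_short_transcript_rejected(self):
        rng = np.random.default_rng(3)
        ts = {"t": _random_seq(rng, 400)}
        with pytest.raises(TemplateLengthError):
            select_template(ts, _mapping("t", [10, 40, 70], size=3))

    def test_span_within_product_range_returned_unchanged(self):
        rng = np.random.default_rng(4)
        ts = {"t": _random_seq(rng, 3000)}
        positions = [1000, 1475]  # span exactly [1000, 1500)
        region = select_template(ts, _mapping("t", positions, size=2))
        assert (region.start, region.end) == (1000, 1500)

    def test_narrow_span_extended_toward_three_prime(self):
        rng = np.random.default_rng(5)
        ts = {"t": _random_seq(rng, 3000)}
        region = select_template(ts, _mapping("t", [1000, 1375], size=2))
        # span [1000, 1400) grows 3' to the template maximum
        assert region.start <= 1000 and region.end >= 1400
        assert 500 <= region.length <= 800
        assert region.end - 1400 >= 1000 - region.start  # 3' bias
        assert region.probe_span == (1000, 1400)

    def test_extension_clipped_at_transcript_end(self):
        rng = np.random.default_rng(6)
        ts = {"t": _random_seq(rng, 1500)}
        region = select_template(ts, _mapping("t", [1300, 1450], size=2))
        assert region.end == 1500
        assert 500 <= region.length <= 800
        assert region.start <= 1300

    def test_wide_span_window_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        ts = {"t": _random_seq(rng, 3000)}
        positions = [100, 400, 700, 900, 1100, 1300, 1500, 1700, 1800, 1900, 2050]
        mapping = _mapping("t", positions)
        region = select_template(ts, mapping)
        assert region.length == 800

        def window_count(end):
            start = end - 800
            return sum(
                1 for p in positions if p >= start and p + PROBE_LENGTH <= end
            )

        best = max(
            ((window_count(e), e) for e in range(800, 3001)),
            key=lambda t: t,
        )
        assert (region.covered_probe_count, region.end) == best

    def test_repeated_calls_identical(self, tx_fixture, tx_mappings):
        transcripts, _, _ = tx_fixture
        for m in tx_mappings:
            assert select_template(transcripts, m) == select_template(transcripts, m)


class TestRankProbesets:
    def test_coverage_then_three_prime_then_id(self):
        a = _mapping("t", [100, 130], size=2)                 # cov 1.0, end 155
        b = _mapping("t", [2000, 2030], size=2)               # cov 1.0, end 2055
        c = _mapping("t", [100, 130, 160], size=11)           # cov 3/11
        order = rank_probesets([c, a, b])
        assert [m.span[1] for m in order[:2]] == [2055, 155]
        assert order[2].coverage_fraction < 1.0

    def test_single_mapping_identity(self):
        m = _mapping("t", [10, 40], size=2)
        assert rank_probesets([m]) == [m]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_probesets([])


class TestOligoProbeValidation:
    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            OligoProbe("ps", 0, "ACGT")

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError):
            OligoProbe("ps", 0, "N" * 25)
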