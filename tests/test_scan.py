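"""Exact motif scanning: examples, brute-force oracle, counter invariants."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from slimscreen import (
    ProbeLibrary,
    ProteinRecord,
    classify_by_distinct,
    classify_p_proteins,
    load_probe_library,
    probe_frequency_table,
    profile_proteome,
    scan_sequence,
)
from slimscreen.errors import SlimScreenError


def brute_force_scan(sequence: str, library: ProbeLibrary):
    """Independent oracle: check every 3-residue window against every probe."""
    seq = sequence.upper()
    out = []
    for start0 in range(max(len(seq) - 2, 0)):
        for pid, pep in library:
            if seq[start0:start0 + 3] == pep:
                out.append((pid, start0 + 1))
    return out


class TestScanSequence:
    def test_overlapping_and_repeated_occurrences(self, two_probe_library):
        hits = scan_sequence("MNFWLFFNFW", two_probe_library)
        assert [(m.probe_id, m.start, m.end) for m in hits] == [
            ("P17", 2, 4),
            ("P3", 5, 7),
            ("P17", 8, 10),
        ]

    def test_short_sequence_and_ambiguity_letter(self, two_probe_library):
        assert scan_sequence("NF", two_probe_library) == []
        assert scan_sequence("NXW", two_probe_library) == []

    def test_adjacent_starts_both_reported(self):
        # two probes at starts s and s+1, as for adjacent motifs at 256/257
        lib = load_probe_library("Pa NNW\nPb NWY\n")
        hits = scan_sequence("ANNWYA", lib)
        assert [(m.probe_id, m.start) for m in hits] == [("Pa", 2), ("Pb", 3)]

    def test_self_overlapping_occurrences_all_counted(self):
        lib = load_probe_library("Pw WWW\n")
        hits = scan_sequence("WWWWW", lib)
        assert [m.start for m in hits] == [1, 2, 3]

    def test_same_start_ties_break_by_library_order(self):
        lib = load_probe_library("Pb LFF\nPa NFW\n")
        hits = scan_sequence("NFWLFF", lib)
        assert [(m.probe_id, m.start) for m in hits] == [("Pa", 1), ("Pb", 4)]

    def test_matches_brute_force_on_random_inputs(self):
        rng = random.Random(20260920)
        aa20 = "ACDEFGHIKLMNPQRSTVWY"
        for trial in range(300):
            alphabet = "ACDF" if trial % 2 else aa20
            n_probes = rng.randint(1, 6)
            peptides = set()
            while len(peptides) < n_probes:
                peptides.add("".join(rng.choices(alphabet, k=3)))
            lib = ProbeLibrary(tuple((f"P{i}", p) for i, p in enumerate(sorted(peptides))))
            seq = "".join(rng.choices(alphabet + "X", k=rng.randint(0, 200)))
            got = {(m.probe_id, m.start) for m in scan_sequence(seq, lib)}
            assert got == set(brute_force_scan(seq, lib))


class TestProfiles:
    def test_total_vs_distinct_counters(self, two_probe_library):
        # 6 occurrences of 2 distinct probes vs 2 occurrences of 2 distinct
        recs = [
            ProteinRecord(accession="A", sequence="NFWNFWNFWLFFLFFLFF"),
            ProteinRecord(accession="B", sequence="NFWLFFAAA"),
        ]
        pa, pb = profile_proteome(recs, two_probe_library)
        assert (pa.total_occurrences, pa.distinct_probe_count) == (6, 2)
        assert (pb.total_occurrences, pb.distinct_probe_count) == (2, 2)

    def test_receptor_kinase_style_profile(self):
        # five different probes, one occurring twice, with two
        # adjacent-start overlap pairs (256/257 and 371/372):
        # total 6 occurrences, 5 distinct probes
        lib = load_probe_library("P1 CMW\nP12 NNW\nP13 NWY\nP10 WFC\nP2 FCW\n")
        seq = ["A"] * 1200
        for pos, pep in [(194, "CMW"), (256, "NNWY"), (371, "WFCW"), (1167, "NWY")]:
            seq[pos - 1:pos - 1 + len(pep)] = list(pep)
        (prof,) = profile_proteome(
            [ProteinRecord(accession="METL", sequence="".join(seq))], lib
        )
        got = {(m.probe_id, m.start) for m in prof.matches}
        assert got == {("P1", 194), ("P12", 256), ("P13", 257),
                       ("P10", 371), ("P2", 372), ("P13", 1167)}
        assert prof.total_occurrences == 6
        assert prof.distinct_probe_count == 5
        assert prof.per_probe_counts["P13"] == 2

    def test_zero_match_proteins_profiled(self, tiny_proteome, two_probe_library):
        profiles = profile_proteome(tiny_proteome, two_probe_library)
        assert len(profiles) == 3
        assert profiles[1].total_occurrences == 0
        assert profiles[1].per_probe_counts == {"P17": 0, "P3": 0}

    def test_empty_proteome(self, two_probe_library):
        assert profile_proteome([], two_probe_library) == []

    @given(st.lists(st.text(alphabet="NFWLA", min_size=0, max_size=60), max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_counter_invariants_hold(self, seqs):
        lib = load_probe_library("P17 NFW\nP3 LFF\nP9 AAA\n")
        recs = [
            ProteinRecord(accession=f"S{i}", sequence=s or "A")
            for i, s in enumerate(seqs)
        ]
        for prof in profile_proteome(recs, lib):
            assert prof.total_occurrences == sum(prof.per_probe_counts.values())
            assert prof.distinct_probe_count == sum(
                1 for c in prof.per_probe_counts.values() if c > 0
            )
            assert prof.distinct_probe_count <= min(prof.total_occurrences, len(lib)) \
                or prof.total_occurrences == 0


class TestClassification:
    def test_thresholds(self):
        lib = load_probe_library("P17 NFW\nP3 LFF\n")
        recs = [
            ProteinRecord(accession="A", sequence="AAAA"),
            ProteinRecord(accession="B", sequence="NFWA"),
            ProteinRecord(accession="C", sequence="NFWNFWNFWNFW"),
        ]
        profiles = profile_proteome(recs, lib)
        assert classify_p_proteins(profiles, 1) == {"B", "C"}
        assert classify_p_proteins(profiles, 4) == {"C"}
        assert classify_by_distinct(profiles, 2) == set()

    def test_monotone_in_threshold(self, tiny_proteome, two_probe_library):
        profiles = profile_proteome(tiny_proteome, two_probe_library)
        sizes = [len(classify_p_proteins(profiles, k)) for k in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_bad_threshold(self, tiny_proteome, two_probe_library):
        profiles = profile_proteome(tiny_proteome, two_probe_library)
        with pytest.raises(SlimScreenError):
            classify_p_proteins(profiles, 0)


class TestFrequencyTable:
    def test_per_window_arithmetic(self):
        lib = load_probe_library("PX NFW\n")
        # 2 proteins of length 10 -> 16 windows; 4 total occurrences
        recs = [
            ProteinRecord(accession="A", sequence="NFWAAAANFW"),
            ProteinRecord(accession="B", sequence="NFWAAAANFW"),
        ]
        table = probe_frequency_table(profile_proteome(recs, lib), recs)
        assert table.total_windows == 16
        assert table.total_occurrences["PX"] == 4
        assert table.proteins_containing["PX"] == 2
        assert table.per_window_frequency["PX"] == pytest.approx(0.25)

    def test_absent_probe_has_zero_frequency(self, tiny_proteome):
        lib = load_probe_library("PY WWW\n")
        table = probe_frequency_table(profile_proteome(tiny_proteome, lib), tiny_proteome)
        assert table.per_window_frequency["PY"] == 0.0

    def test_conservation_against_profiles(self, tiny_proteome, two_probe_library):
        profiles = profile_proteome(tiny_proteome, two_probe_library)
        table = probe_frequency_table(profiles, tiny_proteome)
        for pid in two_probe_library.ids:
            assert table.total_occurrences[pid] == sum(
                p.per_probe_counts[pid] for p in profiles
            )

    def test_no_scannable_window_errors(self, two_probe_library):
        recs = [ProteinRecord(accession="A", sequence="NF")]
        with pytest.raises(SlimScreenError):
            probe_frequency_table(profile_proteome(recs, two_probe_library), recs)
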