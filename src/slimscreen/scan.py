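"""Exact tripeptide scanning and per-protein match profiles.

Every occurrence of every probe is reported, including overlapping
occurrences of different probes (adjacent starts s and s+1 are both kept)
and multiple occurrences of the same probe.  Positions are 1-based
inclusive; a match spans ``[start, start+2]``.  Output order is
deterministic: ascending start, then library order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SlimScreenError, ValidationError
from .io import ProbeLibrary, ProteinRecord


@dataclass(frozen=True)
class MotifMatch:
    """One exact probe occurrence; ``end == start + 2``."""

    accession: str
    probe_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self):
        if self.end != self.start + 2 or self.start < 1:
            raise ValidationError(f"bad match span ({self.start}, {self.end})")


@dataclass(frozen=True)
class ProteinMatchProfile:
    """Occurrence counters for one protein.

    ``total_occurrences`` counts matches (the quantitative ">=4 matches"
    counter); ``distinct_probe_count`` counts different probes (the
    qualitative ">=4 different tripeptides" counter).  The two are kept
    separate throughout.
    """

    accession: str
    total_occurrences: int
    distinct_probe_count: int
    per_probe_counts: Mapping[str, int]
    matches: tuple[MotifMatch, ...]

    def __post_init__(self):
        if self.total_occurrences != sum(self.per_probe_counts.values()):
            raise ValidationError(f"{self.accession}: total != sum of per-probe counts")
        distinct = sum(1 for c in self.per_probe_counts.values() if c > 0)
        if self.distinct_probe_count != distinct:
            raise ValidationError(f"{self.accession}: distinct counter inconsistent")


def scan_sequence(
    sequence: str, library: ProbeLibrary, accession: str = ""
) -> list[MotifMatch]:
    """Find every exact occurrence of every probe in *sequence*.

    Scanning is case-insensitive (the sequence is uppercased first).
    Ambiguity letters never match because probes are defined over the 20
    standard letters only.  Sequences shorter than 3 yield no matches.
    """
    seq = sequence.upper()
    hits: list[tuple[int, int, str]] = []  # (start0, lib_index, probe_id)
    for lib_index, (probe_id, pep) in enumerate(library):
        pos = seq.find(pep)
        while pos != -1:
            hits.append((pos, lib_index, probe_id))
            pos = seq.find(pep, pos + 1)
    hits.sort()
    return [
        MotifMatch(accession=accession, probe_id=pid, start=p + 1, end=p + 3)
        for p, _, pid in hits
    ]


def profile_protein(record: ProteinRecord, library: ProbeLibrary) -> ProteinMatchProfile:
    matches = tuple(scan_sequence(record.sequence, library, record.accession))
    counts = {pid: 0 for pid in library.ids}
    for m in matches:
        counts[m.probe_id] += 1
    return ProteinMatchProfile(
        accession=record.accession,
        total_occurrences=len(matches),
        distinct_probe_count=sum(1 for c in counts.values() if c > 0),
        per_probe_counts=counts,
        matches=matches,
    )


def profile_proteome(
    proteome: Iterable[ProteinRecord], library: ProbeLibrary
) -> list[ProteinMatchProfile]:
    """One profile per protein, zero-match proteins included."""
    return [profile_protein(rec, library) for rec in proteome]


def classify_p_proteins(
    profiles: Iterable[ProteinMatchProfile], min_occurrences: int = 1
) -> set[str]:
    """Accessions with at least *min_occurrences* total probe occurrences.

    With the default threshold of 1 this is the P-protein set: proteins
    containing at least one probe tripeptide.
    """
    if min_occurrences < 1:
        raise SlimScreenError(f"min_occurrences must be >= 1, got {min_occurrences}")
    return {p.accession for p in profiles if p.total_occurrences >= min_occurrences}


def classify_by_distinct(
    profiles: Iterable[ProteinMatchProfile], min_distinct: int = 4
) -> set[str]:
    """Accessions matching at least *min_distinct* different probes."""
    if min_distinct < 1:
        raise SlimScreenError(f"min_distinct must be >= 1, got {min_distinct}")
    return {p.accession for p in profiles if p.distinct_probe_count >= min_distinct}


@dataclass(frozen=True)
class ProbeFrequencyTable:
    """Per-probe occurrence totals over a proteome.

    ``per_window_frequency`` divides total occurrences by the number of
    scannable 3-residue windows, sum of (L - 2) over proteins with L >= 3.
    Raw totals are exported alongside because "frequency" has no single
    canonical denominator for overlapping windows.
    """

    total_occurrences: Mapping[str, int]
    proteins_containing: Mapping[str, int]
    per_window_frequency: Mapping[str, float]
    total_windows: int

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.total_occurrences)
        return pd.DataFrame(
            {
                "probe_id": ids,
                "total_occurrences": [self.total_occurrences[i] for i in ids],
                "proteins_containing": [self.proteins_containing[i] for i in ids],
                "per_window_frequency": [self.per_window_frequency[i] for i in ids],
            }
        )


def probe_frequency_table(
    profiles: Sequence[ProteinMatchProfile], proteome: Sequence[ProteinRecord]
) -> ProbeFrequencyTable:
    windows = sum(rec.length - 2 for rec in proteome if rec.length >= 3)
    if windows == 0:
        raise SlimScreenError("proteome has no scannable 3-residue window")
    probe_ids = list(profiles[0].per_probe_counts) if profiles else []
    totals = {pid: 0 for pid in probe_ids}
    containing = {pid: 0 for pid in probe_ids}
    for prof in profiles:
        for pid, c in prof.per_probe_counts.items():
            totals[pid] += c
            if c > 0:
                containing[pid] += 1
    freqs = {pid: totals[pid] / windows for pid in probe_ids}
    return ProbeFrequencyTable(
        total_occurrences=totals,
        proteins_containing=containing,
        per_window_frequency=freqs,
        total_windows=windows,
    )


def matches_to_frame(profiles: Iterable[ProteinMatchProfile]) -> pd.DataFrame:
    rows = [
        (m.accession, m.probe_id, m.start, m.end)
        for prof in profiles
        for m in prof.matches
    ]
    return pd.DataFrame(rows, columns=["accession", "probe_id", "start", "end"])


def profiles_to_frame(profiles: Sequence[ProteinMatchProfile]) -> pd.DataFrame:
    probe_ids = list(profiles[0].per_probe_counts) if profiles else []
    rows = []
    for p in profiles:
        row = {
            "accession": p.accession,
            "total_occurrences": p.total_occurrences,
            "distinct_probe_count": p.distinct_probe_count,
        }
        row.update({f"n_{pid}": p.per_probe_counts[pid] for pid in probe_ids})
        rows.append(row)
    return pd.DataFrame(rows)
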