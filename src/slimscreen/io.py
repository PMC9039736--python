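"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* proteome FASTA — UniProt header dialect ``>db|ACCESSION|ENTRY_NAME desc
  GN=SYMBOL`` with a bare ``>ID desc`` fallback;
* probe library — two-column whitespace/tab table (probe_id, tripeptide),
  ``#`` comments allowed;
* gene sets — standard GMT (name TAB description TAB member...);
* hallmark map — JSON object ``{hallmark: [pathway_id, ...]}`` or TSV rows
  ``hallmark TAB pathway_id`` (one pathway per row);
* domain / variant annotations — TSV, 1-based inclusive coordinates.

All loaders validate strictly and raise (:mod:`slimscreen.errors`) rather
than silently repairing bad input.  Coordinates everywhere in the package
are 1-based inclusive.
"""

from __future__ import annotations

import io as _io
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import BindingError, ParseError, ValidationError

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity/rare-translation letters accepted in sequences; they can never
#: match a probe.
AMBIGUOUS_AA = frozenset("XBZUOJ")
ALLOWED_AA = STANDARD_AA | AMBIGUOUS_AA

_UNIPROT_HEADER = re.compile(r"^(?P<db>\w+)\|(?P<acc>[^|\s]+)\|(?P<entry>\S+)(?:\s+(?P<desc>.*))?$")
_GN_FIELD = re.compile(r"\bGN=(\S+)")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry; ``sequence`` is uppercase amino-acid letters."""

    accession: str
    sequence: str
    entry_name: str = ""
    gene_symbol: str | None = None
    description: str | None = None

    def __post_init__(self):
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - ALLOWED_AA
        if bad:
            raise ValidationError(
                f"{self.accession}: invalid residue letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProbeLibrary:
    """Ordered collection of named tripeptide probes (P1 ... Pn)."""

    probes: tuple[tuple[str, str], ...]

    def __post_init__(self):
        seen_ids: set[str] = set()
        seen_pep: set[str] = set()
        for probe_id, pep in self.probes:
            if not probe_id:
                raise ValidationError("empty probe id")
            if len(pep) != 3:
                raise ValidationError(f"{probe_id}: peptide {pep!r} is not 3 residues")
            bad = set(pep) - STANDARD_AA
            if bad:
                raise ValidationError(
                    f"{probe_id}: non-standard letters {sorted(bad)} in {pep!r}"
                )
            if probe_id in seen_ids:
                raise ValidationError(f"duplicate probe id {probe_id}")
            if pep in seen_pep:
                raise ValidationError(f"duplicate peptide {pep}")
            seen_ids.add(probe_id)
            seen_pep.add(pep)

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.probes)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.probes)

    @property
    def peptides(self) -> tuple[str, ...]:
        return tuple(pep for _, pep in self.probes)

    def subset(self, probe_ids: Sequence[str]) -> "ProbeLibrary":
        wanted = set(probe_ids)
        missing = wanted - set(self.ids)
        if missing:
            raise ValidationError(f"unknown probe ids {sorted(missing)}")
        return ProbeLibrary(tuple(p for p in self.probes if p[0] in wanted))


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping pathway_id -> (pathway name, member identifiers).

    Members may be accessions or gene symbols; resolution against a
    proteome tries accession first, then gene symbol.
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self):
        for pid, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {pid} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.sets

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]


@dataclass(frozen=True)
class HallmarkMap:
    """Mapping cancer-hallmark name -> ordered pathway ids."""

    hallmarks: Mapping[str, tuple[str, ...]]

    def __iter__(self) -> Iterator[str]:
        return iter(self.hallmarks)

    def __len__(self) -> int:
        return len(self.hallmarks)

    def pathways(self, hallmark: str) -> tuple[str, ...]:
        return self.hallmarks[hallmark]

    def validate_binding(self, gene_sets: GeneSetCollection) -> None:
        """Raise :class:`BindingError` if any pathway id is absent."""
        unknown = [
            pid
            for paths in self.hallmarks.values()
            for pid in paths
            if pid not in gene_sets
        ]
        if unknown:
            raise BindingError(f"pathway ids not in gene sets: {sorted(set(unknown))}")


@dataclass(frozen=True)
class DomainAnnotation:
    accession: str
    domain_name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.accession}/{self.domain_name}: bad interval "
                f"({self.start}, {self.end})"
            )


@dataclass(frozen=True)
class VariantRecord:
    accession: str
    position: int  # 1-based residue index
    ref_aa: str
    alt_label: str  # substitution letter or truncation label like F90Lfs*3
    source: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"{self.accession}: non-positive position")
        if self.ref_aa not in STANDARD_AA:
            raise ValidationError(f"{self.accession}: ref_aa {self.ref_aa!r} not standard")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _as_lines(stream: str | TextIO | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        return iter(_io.StringIO(stream))
    return iter(stream)


def parse_uniprot_fasta(stream: str | TextIO | Iterable[str]) -> list[ProteinRecord]:
    """Parse a FASTA proteome with UniProt-dialect or bare-ID headers.

    Sequences are uppercased and whitespace-folded; parsing is insensitive
    to line-wrap width and terminal newline.  Duplicate accessions are
    rejected.  Record splitting is done with explicit line tracking so
    malformed headers and empty sequences report their line number.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"entry {header!r} has an empty sequence", header_line)
        rec = _record_from_header(header, seq, header_line)
        if rec.accession in seen:
            raise ValidationError(f"duplicate accession {rec.accession}")
        seen.add(rec.accession)
        records.append(rec)

    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            header_line = lineno
            chunks = []
            if not header:
                raise ParseError("header with no identifier", lineno)
        elif line.strip():
            if header is None:
                raise ParseError("sequence data before any header", lineno)
            chunks.append("".join(line.split()))
    flush()
    return records


def _record_from_header(header: str, seq: str, lineno: int) -> ProteinRecord:
    m = _UNIPROT_HEADER.match(header)
    if m:
        accession = m.group("acc")
        entry_name = m.group("entry")
        desc = m.group("desc") or ""
    else:
        parts = header.split(None, 1)
        accession = parts[0]
        entry_name = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
    if not accession:
        raise ParseError("header with no identifier", lineno)
    gm = _GN_FIELD.search(desc)
    try:
        return ProteinRecord(
            accession=accession,
            entry_name=entry_name,
            gene_symbol=gm.group(1) if gm else None,
            description=desc or None,
            sequence=seq,
        )
    except ValidationError as exc:
        raise ParseError(str(exc), lineno) from exc


def read_proteome(path) -> list[ProteinRecord]:
    with open(path) as fh:
        return parse_uniprot_fasta(fh)


def write_fasta(records: Iterable[ProteinRecord], handle: TextIO) -> None:
    """Write records in the UniProt header dialect (via Biopython)."""
    seqrecords = []
    for rec in records:
        desc = rec.description or ""
        if rec.gene_symbol and f"GN={rec.gene_symbol}" not in desc:
            desc = (desc + f" GN={rec.gene_symbol}").strip()
        seqrecords.append(
            SeqRecord(
                Seq(rec.sequence),
                id=f"sp|{rec.accession}|{rec.entry_name or rec.accession}",
                description=desc,
            )
        )
    SeqIO.write(seqrecords, handle, "fasta")


def proteome_to_fasta(records: Iterable[ProteinRecord]) -> str:
    buf = _io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# probe library
# ---------------------------------------------------------------------------

def load_probe_library(stream: str | TextIO | Iterable[str]) -> ProbeLibrary:
    """Load a two-column (probe_id, tripeptide) table, preserving order."""
    probes: list[tuple[str, str]] = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ParseError(f"expected 2 columns, got {len(fields)}", lineno)
        probes.append((fields[0], fields[1].upper()))
    return ProbeLibrary(tuple(probes))


def default_probe_library() -> ProbeLibrary:
    """The packaged default 19-probe library.

    Synthetic stand-in: only two of the original probes (P3=LFF, P17=NFW)
    and the first residues of P2/P12/P13 are public knowledge; the rest
    are constructed rare-amino-acid tripeptides.
    """
    text = resources.files("slimscreen.data").joinpath(
        "probes_synthetic_default.tsv"
    ).read_text()
    return load_probe_library(text)


# ---------------------------------------------------------------------------
# gene sets / hallmark map
# ---------------------------------------------------------------------------

def load_gene_sets_gmt(stream: str | TextIO | Iterable[str]) -> GeneSetCollection:
    """Load standard GMT: ``name TAB description TAB member...`` per line."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"GMT line needs >=3 tab-separated fields, got {len(fields)}", lineno
            )
        pid, name = fields[0], fields[1]
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise ParseError(f"gene set {pid} has no members", lineno)
        if pid in sets:
            raise ValidationError(f"duplicate pathway id {pid}")
        sets[pid] = (name, members)
    return GeneSetCollection(sets)


def load_hallmark_map(
    stream: str | TextIO | Iterable[str],
    gene_sets: GeneSetCollection | None = None,
) -> HallmarkMap:
    """Load a hallmark -> pathway_ids map from JSON or TSV.

    JSON: object mapping hallmark name to a list of pathway ids.
    TSV: one ``hallmark TAB pathway_id`` row per pathway; rows for the
    same hallmark accumulate in file order.  If *gene_sets* is given the
    binding is validated immediately.
    """
    if not isinstance(stream, str):
        stream = "".join(stream.read() if hasattr(stream, "read") else stream)
    text = stream.strip()
    mapping: dict[str, tuple[str, ...]] = {}
    if text.startswith("{"):
        obj = json.loads(text)
        for hallmark, pids in obj.items():
            if hallmark in mapping:
                raise ValidationError(f"duplicate hallmark {hallmark!r}")
            mapping[hallmark] = tuple(pids)
    else:
        acc: dict[str, list[str]] = {}
        order: list[str] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"expected 2 tab-separated fields", lineno)
            hallmark, pid = fields[0].strip(), fields[1].strip()
            if hallmark not in acc:
                acc[hallmark] = []
                order.append(hallmark)
            if pid in acc[hallmark]:
                raise ValidationError(f"duplicate pathway {pid} under {hallmark!r}")
            acc[hallmark].append(pid)
        mapping = {h: tuple(acc[h]) for h in order}
    hmap = HallmarkMap(mapping)
    if gene_sets is not None:
        hmap.validate_binding(gene_sets)
    return hmap


def default_hallmark_map() -> HallmarkMap:
    """The packaged ten-hallmark -> Reactome-pathway mapping."""
    text = resources.files("slimscreen.data").joinpath(
        "hallmarks_default.tsv"
    ).read_text()
    return load_hallmark_map(text)


# ---------------------------------------------------------------------------
# domain / variant tables
# ---------------------------------------------------------------------------

def load_annotation_table(
    stream: str | TextIO | Iterable[str], kind: str
) -> list[DomainAnnotation] | list[VariantRecord]:
    """Load a domain or variant TSV.

    ``kind='domain'`` columns: accession, domain_name, start, end.
    ``kind='variant'`` columns: accession, position, ref_aa, alt_label
    [, source].  Coordinates are 1-based inclusive.
    """
    if kind not in ("domain", "variant"):
        raise ValueError(f"kind must be 'domain' or 'variant', got {kind!r}")
    out: list = []
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            if kind == "domain":
                if len(fields) != 4:
                    raise ParseError("domain rows need 4 columns", lineno)
                out.append(
                    DomainAnnotation(
                        accession=fields[0],
                        domain_name=fields[1],
                        start=int(fields[2]),
                        end=int(fields[3]),
                    )
                )
            else:
                if len(fields) not in (4, 5):
                    raise ParseError("variant rows need 4 or 5 columns", lineno)
                out.append(
                    VariantRecord(
                        accession=fields[0],
                        position=int(fields[1]),
                        ref_aa=fields[2],
                        alt_label=fields[3],
                        source=fields[4] if len(fields) == 5 else "",
                    )
                )
        except (ValueError, ValidationError) as exc:
            if isinstance(exc, ParseError):
                raise
            raise ValidationError(f"line {lineno}: {exc}") from exc
    return out
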