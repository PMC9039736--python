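"""Screening funnel and candidate prioritization.

The funnel stages mirror the screening procedure: whole proteome ->
proteins with >=1 probe occurrence (P-proteins) -> hallmark-associated
P-proteins -> proteins with >=k different probes (default k=4) -> the
intersection of the last two.  Candidate annotation localizes matches
within annotated domains and overlaps somatic variants with match spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enrich import round_percentage
from .errors import SlimScreenError
from .io import DomainAnnotation, VariantRecord
from .scan import MotifMatch, ProteinMatchProfile


@dataclass(frozen=True)
class FunnelSummary:
    """Counts and percentages at each screening stage.

    Percentages are one-decimal, half-up.  ``degenerate`` flags an empty
    proteome, where every percentage is reported as 0.
    """

    n_proteome: int
    n_p_proteins: int
    n_hallmark_p: int
    n_min_distinct: int
    n_min_distinct_hallmark: int
    k_distinct: int
    pct_p_of_proteome: float
    pct_hallmark_of_proteome: float
    pct_hallmark_of_p: float
    degenerate: bool = False

    def __post_init__(self):
        ok = (
            self.n_min_distinct_hallmark
            <= self.n_min_distinct
            <= self.n_p_proteins
            <= self.n_proteome
            and self.n_hallmark_p <= self.n_p_proteins
        )
        if not ok:
            raise SlimScreenError("funnel counts violate the monotonicity chain")

    @classmethod
    def from_counts(
        cls,
        n_proteome: int,
        n_p_proteins: int,
        n_hallmark_p: int,
        n_min_distinct: int = 0,
        n_min_distinct_hallmark: int = 0,
        k_distinct: int = 4,
    ) -> "FunnelSummary":
        degenerate = n_proteome == 0
        pct = round_percentage
        return cls(
            n_proteome=n_proteome,
            n_p_proteins=n_p_proteins,
            n_hallmark_p=n_hallmark_p,
            n_min_distinct=n_min_distinct,
            n_min_distinct_hallmark=n_min_distinct_hallmark,
            k_distinct=k_distinct,
            pct_p_of_proteome=0.0 if degenerate else pct(n_p_proteins, n_proteome),
            pct_hallmark_of_proteome=0.0 if degenerate else pct(n_hallmark_p, n_proteome),
            pct_hallmark_of_p=(
                0.0 if n_p_proteins == 0 else pct(n_hallmark_p, n_p_proteins)
            ),
            degenerate=degenerate,
        )

    def to_dict(self) -> dict:
        return {
            "n_proteome": self.n_proteome,
            "n_p_proteins": self.n_p_proteins,
            "n_hallmark_p": self.n_hallmark_p,
            "n_min_distinct": self.n_min_distinct,
            "n_min_distinct_hallmark": self.n_min_distinct_hallmark,
            "k_distinct": self.k_distinct,
            "pct_p_of_proteome": self.pct_p_of_proteome,
            "pct_hallmark_of_proteome": self.pct_hallmark_of_proteome,
            "pct_hallmark_of_p": self.pct_hallmark_of_p,
            "degenerate": self.degenerate,
        }


def _flatten_membership(
    hallmark_membership: Mapping[str, frozenset[str]] | set[str] | frozenset[str]
) -> set[str]:
    if isinstance(hallmark_membership, (set, frozenset)):
        return set(hallmark_membership)
    out: set[str] = set()
    for members in hallmark_membership.values():
        out |= set(members)
    return out


def apply_funnel(
    profiles: Sequence[ProteinMatchProfile],
    hallmark_membership: Mapping[str, frozenset[str]] | set[str],
    k_distinct: int = 4,
    min_occurrences: int = 1,
) -> FunnelSummary:
    """Compute all funnel stages from match profiles.

    The headline >=k stage counts *different* probes (distinct-probe
    count), not occurrences; the P-protein stage counts occurrences.
    """
    if k_distinct < 1:
        raise SlimScreenError(f"k_distinct must be >= 1, got {k_distinct}")
    hallmark_set = _flatten_membership(hallmark_membership)
    p_set = {p.accession for p in profiles if p.total_occurrences >= min_occurrences}
    distinct_set = {p.accession for p in profiles if p.distinct_probe_count >= k_distinct}
    return FunnelSummary.from_counts(
        n_proteome=len(profiles),
        n_p_proteins=len(p_set),
        n_hallmark_p=len(p_set & hallmark_set),
        n_min_distinct=len(distinct_set),
        n_min_distinct_hallmark=len(distinct_set & hallmark_set),
        k_distinct=k_distinct,
    )


# ---------------------------------------------------------------------------
# domain / variant overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainOverlap:
    """A match labelled against the domain annotations of its protein.

    ``status`` is ``inside`` (span fully within some domain), ``partial``
    (span crosses a domain boundary) or ``outside``; inside takes
    precedence over partial when several domains apply.  ``domain_names``
    lists every domain the match touches.
    """

    match: MotifMatch
    status: str
    domain_names: tuple[str, ...]


def domain_overlap(
    matches: Iterable[MotifMatch], domains: Iterable[DomainAnnotation]
) -> list[DomainOverlap]:
    by_acc: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_acc.setdefault(d.accession, []).append(d)
    out: list[DomainOverlap] = []
    for m in matches:
        inside, partial = [], []
        for d in sorted(by_acc.get(m.accession, []), key=lambda d: (d.start, d.end, d.domain_name)):
            if d.start <= m.start and m.end <= d.end:
                inside.append(d.domain_name)
            elif m.start <= d.end and d.start <= m.end:
                partial.append(d.domain_name)
        if inside:
            out.append(DomainOverlap(m, "inside", tuple(inside)))
        elif partial:
            out.append(DomainOverlap(m, "partial", tuple(partial)))
        else:
            out.append(DomainOverlap(m, "outside", ()))
    return out


@dataclass(frozen=True)
class VariantHit:
    """A somatic variant falling within a match span.

    ``offset`` is the variant's 0-based position within the tripeptide
    (0, 1 or 2).  Truncating variants are treated as point positions at
    their stated residue.
    """

    variant: VariantRecord
    match: MotifMatch
    offset: int


def variant_overlap(
    matches: Iterable[MotifMatch], variants: Iterable[VariantRecord]
) -> list[VariantHit]:
    by_acc: dict[str, list[MotifMatch]] = {}
    for m in matches:
        by_acc.setdefault(m.accession, []).append(m)
    hits: list[VariantHit] = []
    for v in sorted(variants, key=lambda v: (v.accession, v.position, v.alt_label)):
        for m in sorted(by_acc.get(v.accession, []), key=lambda m: (m.start, m.probe_id)):
            if m.start <= v.position <= m.end:
                hits.append(VariantHit(v, m, v.position - m.start))
    return hits


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateRow:
    accession: str
    gene_symbol: str | None
    distinct_probe_count: int
    total_occurrences: int
    hallmarks: tuple[str, ...]
    domain_hits: int   # matches fully inside an annotated domain
    variant_hits: int  # variants overlapping a match span
    rank_key: tuple


def rank_candidates(
    profiles: Sequence[ProteinMatchProfile],
    hallmark_membership: Mapping[str, frozenset[str]],
    domains: Sequence[DomainAnnotation] = (),
    variants: Sequence[VariantRecord] = (),
    k_distinct: int = 4,
    gene_symbols: Mapping[str, str] | None = None,
) -> list[CandidateRow]:
    """Filter and order candidate interactor proteins.

    Kept: proteins with >= *k_distinct* different probes, OR hallmark
    members with at least one match fully inside an annotated domain.
    Ordered descending by (number of hallmarks, distinct probes, domain
    hits, variant hits), ties broken by accession — a deterministic,
    documented stand-in for manual relevance judgement.
    """
    all_matches = [m for p in profiles for m in p.matches]
    dom = domain_overlap(all_matches, domains)
    inside_counts: dict[str, int] = {}
    for o in dom:
        if o.status == "inside":
            inside_counts[o.match.accession] = inside_counts.get(o.match.accession, 0) + 1
    var_counts: dict[str, int] = {}
    for h in variant_overlap(all_matches, variants):
        var_counts[h.variant.accession] = var_counts.get(h.variant.accession, 0) + 1
    hallmarks_of: dict[str, list[str]] = {}
    for hallmark, members in hallmark_membership.items():
        for acc in members:
            hallmarks_of.setdefault(acc, []).append(hallmark)

    rows: list[CandidateRow] = []
    for p in profiles:
        hms = tuple(sorted(hallmarks_of.get(p.accession, [])))
        d_hits = inside_counts.get(p.accession, 0)
        keep = p.distinct_probe_count >= k_distinct or (hms and d_hits >= 1)
        if not keep:
            continue
        v_hits = var_counts.get(p.accession, 0)
        key = (len(hms), p.distinct_probe_count, d_hits, v_hits)
        rows.append(
            CandidateRow(
                accession=p.accession,
                gene_symbol=(gene_symbols or {}).get(p.accession),
                distinct_probe_count=p.distinct_probe_count,
                total_occurrences=p.total_occurrences,
                hallmarks=hms,
                domain_hits=d_hits,
                variant_hits=v_hits,
                rank_key=key,
            )
        )
    rows.sort(key=lambda r: (tuple(-k for k in r.rank_key), r.accession))
    return rows


def candidates_to_frame(rows: Sequence[CandidateRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [r.accession for r in rows],
            "gene_symbol": [r.gene_symbol or "" for r in rows],
            "distinct_probe_count": [r.distinct_probe_count for r in rows],
            "total_occurrences": [r.total_occurrences for r in rows],
            "hallmarks": [";".join(r.hallmarks) for r in rows],
            "domain_hits": [r.domain_hits for r in rows],
            "variant_hits": [r.variant_hits for r in rows],
        }
    )
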