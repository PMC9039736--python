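"""Cancer-hallmark enrichment of P-proteins.

Pathway gene sets are rolled up into hallmark clusters (deduplicated
union over the hallmark's pathways); per hallmark the P-protein count,
percentage and a one-sided hypergeometric enrichment p-value are
computed, with Benjamini–Hochberg q-values across the hallmark rows.

Percentages are rounded half-up to one decimal place (rendered with two
decimals in reports); the rounding convention is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import BindingError, SlimScreenError, ValidationError
from .io import GeneSetCollection, HallmarkMap, ProteinRecord

#: Hallmarks at or above this percentage are flagged as "highest" rows.
HIGH_PERCENTAGE_FLAG = 45.0


def round_percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up at *ndigits* decimals.

    Computed on exact rationals (Decimal) so 38.775 rounds to 38.8 rather
    than falling to binary-float representation error.
    """
    if denominator <= 0:
        raise SlimScreenError("percentage of an empty denominator is undefined")
    q = Decimal(100 * numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def pathway_fraction(n_total: int, n_p: int) -> float:
    """Percentage of P-proteins among a pathway cluster's proteins."""
    if n_total == 0:
        raise SlimScreenError("pathway with zero proteins has no P-protein fraction")
    if not 0 <= n_p <= n_total:
        raise ValidationError(f"n_p={n_p} outside [0, {n_total}]")
    return round_percentage(n_p, n_total)


def resolve_members(
    members: Iterable[str], proteome: Sequence[ProteinRecord]
) -> set[str]:
    """Resolve gene-set members to proteome accessions.

    Tries accession first, then gene symbol (GMT files in the wild use
    symbols).  Unresolvable members are dropped.
    """
    by_acc = {rec.accession for rec in proteome}
    by_gene: dict[str, list[str]] = {}
    for rec in proteome:
        if rec.gene_symbol:
            by_gene.setdefault(rec.gene_symbol, []).append(rec.accession)
    out: set[str] = set()
    for m in members:
        if m in by_acc:
            out.add(m)
        elif m in by_gene:
            out.update(by_gene[m])
    return out


def hallmark_membership(
    gene_sets: GeneSetCollection,
    hallmark_map: HallmarkMap,
    proteome: Sequence[ProteinRecord] | None = None,
) -> dict[str, frozenset[str]]:
    """Per hallmark, the deduplicated union of member proteins.

    A protein may belong to several hallmarks.  If *proteome* is given,
    members are resolved to accessions (accession first, then gene
    symbol); otherwise member identifiers are used verbatim.
    """
    hallmark_map.validate_binding(gene_sets)
    out: dict[str, frozenset[str]] = {}
    for hallmark in hallmark_map:
        union: set[str] = set()
        for pid in hallmark_map.pathways(hallmark):
            union |= gene_sets.members(pid)
        if proteome is not None:
            union = resolve_members(union, proteome)
        out[hallmark] = frozenset(union)
    return out


def hypergeometric_enrichment(
    n_p_in_set: int, n_set: int, n_p_background: int, n_background: int
) -> float:
    """Upper-tail hypergeometric P(X >= n_p_in_set).

    Probability that a uniformly drawn size-*n_set* subset of the
    background contains at least the observed number of P-proteins.
    """
    if n_set > n_background or n_p_background > n_background:
        raise ValidationError("set or P-protein count exceeds background")
    if not 0 <= n_p_in_set <= min(n_set, n_p_background):
        raise ValidationError(
            f"n_p_in_set={n_p_in_set} inconsistent with "
            f"(n_set={n_set}, n_p_background={n_p_background})"
        )
    return float(stats.hypergeom.sf(n_p_in_set - 1, n_background, n_p_background, n_set))


@dataclass(frozen=True)
class EnrichmentRow:
    hallmark: str
    pathway_ids: tuple[str, ...]
    n_total: int
    n_p: int
    percentage: float
    hypergeom_p: float
    bh_q: float
    flagged: bool


def enrichment_table(
    gene_sets: GeneSetCollection,
    hallmark_map: HallmarkMap,
    p_protein_set: set[str],
    background: set[str],
    proteome: Sequence[ProteinRecord] | None = None,
    flag_threshold: float = HIGH_PERCENTAGE_FLAG,
) -> list[EnrichmentRow]:
    """One enrichment row per hallmark, sorted by percentage descending.

    *background* is the full screened proteome (accession set); hallmark
    members outside the background are ignored so all counts nest.
    """
    members = hallmark_membership(gene_sets, hallmark_map, proteome)
    p_in_bg = p_protein_set & background
    n_bg, n_p_bg = len(background), len(p_in_bg)
    rows: list[EnrichmentRow] = []
    raw: list[tuple[str, tuple[str, ...], int, int]] = []
    for hallmark in hallmark_map:
        cluster = members[hallmark] & background
        raw.append(
            (hallmark, hallmark_map.pathways(hallmark), len(cluster), len(cluster & p_in_bg))
        )
    pvals = [
        hypergeometric_enrichment(n_p, n_total, n_p_bg, n_bg) if n_total else 1.0
        for _, _, n_total, n_p in raw
    ]
    qvals = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    for (hallmark, pids, n_total, n_p), p, q in zip(raw, pvals, qvals):
        pct = pathway_fraction(n_total, n_p) if n_total else 0.0
        rows.append(
            EnrichmentRow(
                hallmark=hallmark,
                pathway_ids=pids,
                n_total=n_total,
                n_p=n_p,
                percentage=pct,
                hypergeom_p=float(p),
                bh_q=float(q),
                flagged=pct >= flag_threshold,
            )
        )
    rows.sort(key=lambda r: (-r.percentage, r.hallmark))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hallmark": [r.hallmark for r in rows],
            "pathway_ids": [";".join(r.pathway_ids) for r in rows],
            "n_total": [r.n_total for r in rows],
            "n_p": [r.n_p for r in rows],
            # Table-style two-decimal rendering of the one-decimal percentage
            "percentage": [f"{r.percentage:.2f}" for r in rows],
            "hypergeom_p": [r.hypergeom_p for r in rows],
            "bh_q": [r.bh_q for r in rows],
            "flagged": [r.flagged for r in rows],
        }
    )
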