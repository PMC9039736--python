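"""TSV/JSON report writers shared by the CLI subcommands."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .enrich import EnrichmentRow, enrichment_to_frame
from .null import NullSummary
from .prioritize import CandidateRow, FunnelSummary, candidates_to_frame
from .scan import ProteinMatchProfile, matches_to_frame, profiles_to_frame


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_matches(profiles: Sequence[ProteinMatchProfile], path) -> None:
    write_tsv(matches_to_frame(profiles), path)


def write_profiles(profiles: Sequence[ProteinMatchProfile], path) -> None:
    write_tsv(profiles_to_frame(profiles), path)


def write_enrichment(rows: Sequence[EnrichmentRow], path) -> None:
    write_tsv(enrichment_to_frame(rows), path)


def write_candidates(rows: Sequence[CandidateRow], path) -> None:
    write_tsv(candidates_to_frame(rows), path)


def write_funnel(summary: FunnelSummary, path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")


def write_null_summary(summary: NullSummary, path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")


def render_funnel(summary: FunnelSummary) -> str:
    """Human-readable multi-line funnel summary."""
    d = summary.to_dict()
    lines = [
        f"proteome:                         {d['n_proteome']}",
        f"P-proteins (>=1 occurrence):      {d['n_p_proteins']} "
        f"({d['pct_p_of_proteome']}% of proteome)",
        f"hallmark-associated P-proteins:   {d['n_hallmark_p']} "
        f"({d['pct_hallmark_of_proteome']}% of proteome, "
        f"{d['pct_hallmark_of_p']}% of P-proteins)",
        f">= {d['k_distinct']} different probes:           {d['n_min_distinct']}",
        f"... and hallmark-associated:      {d['n_min_distinct_hallmark']}",
    ]
    return "\n".join(lines)
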