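"""Null models for probe occurrence: are the tripeptides stochastically
distributed in the proteome?

Two complementary nulls are provided and reported side by side, because
the question "how many proteins would contain a probe by chance?" has no
single canonical construction:

* an analytic composition model — per-window match probability
  ``q = sum over probes of the product of residue frequencies`` (a
  first-order union bound over the probe set) with the per-protein
  >=1-match probability ``1 - (1-q)**(L-2)`` treating windows as
  independent; and
* a per-protein shuffle Monte-Carlo null, which preserves each protein's
  exact residue composition and length.

The codon-degeneracy analysis relates each probe's observed frequency to
the number of sense codons encoding its residues (sum and product modes,
since "total number of codons" is ambiguous between the two).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .errors import SlimScreenError
from .io import AMBIGUOUS_AA, STANDARD_AA, ProbeLibrary, ProteinRecord
from .scan import ProbeFrequencyTable, scan_sequence


def _standard_codon_counts() -> dict[str, int]:
    # 61 sense codons of the standard genetic code (NCBI table 1).
    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    counts = Counter(fwd.values())
    return {aa: counts[aa] for aa in sorted(STANDARD_AA)}


#: Sense-codon count per standard amino acid (W=1, M=1, L=6, ...).
CODON_COUNTS: dict[str, int] = _standard_codon_counts()


@dataclass(frozen=True)
class BackgroundModel:
    """Residue background: per-letter frequencies plus codon counts."""

    aa_frequencies: Mapping[str, float]
    source: str = "user"
    codon_counts: Mapping[str, int] = field(default_factory=lambda: dict(CODON_COUNTS))

    def __post_init__(self):
        total = sum(self.aa_frequencies.values())
        if any(f < 0 for f in self.aa_frequencies.values()):
            raise SlimScreenError("negative amino-acid frequency")
        if abs(total - 1.0) > 1e-9:
            raise SlimScreenError(f"frequencies sum to {total}, not 1")

    def frequency(self, aa: str) -> float:
        return self.aa_frequencies.get(aa, 0.0)


def uniform_background() -> BackgroundModel:
    return BackgroundModel(
        {aa: 1.0 / 20.0 for aa in sorted(STANDARD_AA)}, source="uniform"
    )


def codon_usage_background() -> BackgroundModel:
    """Frequencies proportional to sense-codon counts (f = codons / 61)."""
    return BackgroundModel(
        {aa: c / 61.0 for aa, c in CODON_COUNTS.items()}, source="codon-usage"
    )


def estimate_aa_frequencies(proteome: Iterable[ProteinRecord]) -> BackgroundModel:
    """Estimate letter frequencies from a proteome.

    Ambiguity letters (X, B, Z, U, O, J) are excluded from both numerator
    and denominator.
    """
    counts: Counter[str] = Counter()
    for rec in proteome:
        counts.update(rec.sequence)
    for amb in AMBIGUOUS_AA:
        counts.pop(amb, None)
    total = sum(counts.values())
    if total == 0:
        raise SlimScreenError("no standard residues in proteome")
    freqs = {aa: counts.get(aa, 0) / total for aa in sorted(STANDARD_AA)}
    return BackgroundModel(freqs, source="proteome-estimated")


def per_window_match_probability(library: ProbeLibrary, model: BackgroundModel) -> float:
    """q = sum over probes of the product of their residue frequencies.

    A first-order (union-bound) approximation: probe peptides are unique,
    so distinct probes cannot co-occur in one window and the sum is exact
    per window; dependence only enters across overlapping windows.
    """
    q = 0.0
    for _, pep in library:
        p = 1.0
        for aa in pep:
            p *= model.frequency(aa)
        q += p
    return q


def expected_p_protein_fraction(lengths: Sequence[int], q: float) -> float:
    """Mean over proteins of 1 - (1-q)^(L-2); L < 3 contributes 0."""
    if not 0.0 <= q <= 1.0:
        raise SlimScreenError(f"q={q} outside [0, 1]")
    if len(lengths) == 0:
        return 0.0
    arr = np.asarray(lengths, dtype=np.int64)
    windows = np.clip(arr - 2, 0, None)
    return float(np.mean(-np.expm1(np.log1p(-q) * windows))) if q < 1.0 else float(
        np.mean(windows > 0)
    )


def shuffle_null_mc(
    proteome: Sequence[ProteinRecord],
    library: ProbeLibrary,
    replicates: int,
    seed: int,
    min_occurrences: int = 1,
) -> np.ndarray:
    """Empirical null distribution of the P-protein fraction.

    Each replicate independently permutes every protein's residues
    (preserving composition and length exactly) and recomputes the
    fraction of proteins with >= *min_occurrences* probe occurrences.
    """
    if replicates < 1:
        raise SlimScreenError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(seed)
    n = len(proteome)
    seqs = [np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8) for rec in proteome]
    fractions = np.empty(replicates)
    for r in range(replicates):
        hits = 0
        for arr in seqs:
            shuffled = rng.permutation(arr).tobytes().decode("ascii")
            if len(scan_sequence(shuffled, library)) >= min_occurrences:
                hits += 1
        fractions[r] = hits / n if n else 0.0
    return fractions


@dataclass(frozen=True)
class NullSummary:
    """Observed-vs-expected comparison of the P-protein fraction."""

    observed_count: int
    n_proteins: int
    expected_fraction: float
    observed_fraction: float
    test_statistic: float  # normal-approximation z-score
    p_value: float
    alternative: str
    per_window_match_prob: float | None = None
    mc_replicates: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "observed_count": self.observed_count,
            "n_proteins": self.n_proteins,
            "expected_fraction": self.expected_fraction,
            "observed_fraction": self.observed_fraction,
            "z_score": self.test_statistic,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "per_window_match_prob": self.per_window_match_prob,
            "mc_replicates": self.mc_replicates,
            "seed": self.seed,
        }


def observed_vs_expected_test(
    observed: int,
    n_proteins: int,
    expected_fraction: float,
    alternative: str = "two-sided",
    *,
    per_window_match_prob: float | None = None,
    mc_replicates: int = 0,
    seed: int | None = None,
) -> NullSummary:
    """Exact binomial test of the observed P-protein count.

    Two-sided p-values use the tail-doubling convention
    ``min(1, 2 * min(P(X <= k), P(X >= k)))``; ``alternative='less'``
    gives the one-sided lower tail (is the observed fraction lower than
    expected?).  A z-score without continuity correction is reported
    alongside.
    """
    if not 0 <= observed <= n_proteins:
        raise SlimScreenError(f"observed={observed} outside [0, {n_proteins}]")
    if alternative not in ("two-sided", "less", "greater"):
        raise SlimScreenError(f"unknown alternative {alternative!r}")
    p0 = expected_fraction
    if p0 <= 0.0 or p0 >= 1.0:
        # degenerate null: only an exactly matching observation is allowed
        if (p0 <= 0.0 and observed != 0) or (p0 >= 1.0 and observed != n_proteins):
            raise SlimScreenError(
                f"expected fraction {p0} is degenerate but observed {observed}/{n_proteins}"
            )
        pval, z = 1.0, 0.0
    else:
        lower = stats.binom.cdf(observed, n_proteins, p0)
        upper = stats.binom.sf(observed - 1, n_proteins, p0)
        if alternative == "less":
            pval = float(lower)
        elif alternative == "greater":
            pval = float(upper)
        else:
            pval = float(min(1.0, 2.0 * min(lower, upper)))
        z = float(
            (observed - n_proteins * p0) / np.sqrt(n_proteins * p0 * (1.0 - p0))
        )
    return NullSummary(
        observed_count=observed,
        n_proteins=n_proteins,
        expected_fraction=float(p0),
        observed_fraction=observed / n_proteins if n_proteins else 0.0,
        test_statistic=z,
        p_value=pval,
        alternative=alternative,
        per_window_match_prob=per_window_match_prob,
        mc_replicates=mc_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# codon degeneracy
# ---------------------------------------------------------------------------

def codon_weight(peptide: str, mode: str = "sum") -> int:
    """Sum or product of sense-codon counts over a peptide's residues.

    For tripeptides the sum lies in [3, 18] and the product in [1, 216];
    both are invariant under residue reordering.
    """
    if mode not in ("sum", "product"):
        raise SlimScreenError(f"mode must be 'sum' or 'product', got {mode!r}")
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise SlimScreenError(f"non-standard letters {sorted(bad)} in {peptide!r}")
    counts = [CODON_COUNTS[aa] for aa in peptide]
    if mode == "sum":
        return sum(counts)
    out = 1
    for c in counts:
        out *= c
    return out


def codon_weight_table(
    freq_table: ProbeFrequencyTable, library: ProbeLibrary
) -> pd.DataFrame:
    """Per-probe codon weights (both modes) joined with observed frequency."""
    rows = []
    for probe_id, pep in library:
        rows.append(
            {
                "probe_id": probe_id,
                "peptide": pep,
                "sum_weight": codon_weight(pep, "sum"),
                "product_weight": codon_weight(pep, "product"),
                "total_occurrences": freq_table.total_occurrences[probe_id],
                "per_window_frequency": freq_table.per_window_frequency[probe_id],
            }
        )
    return pd.DataFrame(rows)


def frequency_codon_correlation(
    frequencies: Sequence[float], weights: Sequence[int]
) -> tuple[float, float]:
    """Spearman rank correlation of probe frequency vs codon weight.

    Ties are mid-ranked (scipy default).  Zero variance in either vector
    makes the correlation undefined; (nan, nan) is returned.
    """
    if len(frequencies) != len(weights):
        raise SlimScreenError("frequency and weight vectors differ in length")
    if len(frequencies) < 3:
        raise SlimScreenError("need at least 3 probes for a rank correlation")
    if len(set(frequencies)) < 2 or len(set(weights)) < 2:
        return (float("nan"), float("nan"))
    res = stats.spearmanr(frequencies, weights)
    return (float(res.statistic), float(res.pvalue))
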