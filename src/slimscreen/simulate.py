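"""Synthetic proteomes, gene sets and variant tables with known ground truth.

The generators emulate the statistical structure the screen assumes: a
proteome of i.i.d. residues drawn from a configurable background, with a
log-normal length distribution resembling human protein lengths (median
375, sigma 0.6) by default; gene sets with a controllable P-protein
enrichment factor; planted probe motifs; and variants placed inside or
outside match spans at a stated fraction.  Everything is bit-reproducible
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import SlimScreenError
from .io import (
    GeneSetCollection,
    HallmarkMap,
    ProbeLibrary,
    ProteinRecord,
    VariantRecord,
    STANDARD_AA,
)
from .null import BackgroundModel, codon_usage_background, uniform_background
from .scan import MotifMatch

_AA = "".join(sorted(STANDARD_AA))

#: Default length distribution: log-normal, median 375 residues, sigma 0.6.
DEFAULT_LENGTH_DIST = ("lognormal", 375.0, 0.6)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic screen.

    ``length_dist`` is ``("fixed", L)`` or ``("lognormal", median, sigma)``.
    ``aa_frequencies`` is a BackgroundModel, or the presets ``"uniform"``
    / ``"codon_usage"`` (f proportional to sense-codon counts).
    """

    n_proteins: int
    length_dist: tuple = DEFAULT_LENGTH_DIST
    aa_frequencies: str | BackgroundModel = "uniform"
    seed: int = 0

    def background(self) -> BackgroundModel:
        if isinstance(self.aa_frequencies, BackgroundModel):
            return self.aa_frequencies
        if self.aa_frequencies == "uniform":
            return uniform_background()
        if self.aa_frequencies == "codon_usage":
            return codon_usage_background()
        raise SlimScreenError(f"unknown frequency preset {self.aa_frequencies!r}")


def _draw_lengths(rng: np.random.Generator, n: int, length_dist: tuple) -> np.ndarray:
    kind = length_dist[0]
    if kind == "fixed":
        return np.full(n, int(length_dist[1]), dtype=np.int64)
    if kind == "lognormal":
        median, sigma = float(length_dist[1]), float(length_dist[2])
        draws = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
        return np.maximum(np.round(draws).astype(np.int64), 1)
    raise SlimScreenError(f"unknown length distribution {kind!r}")


def generate_proteome(
    config: SimulationConfig | None = None,
    *,
    n_proteins: int | None = None,
    length_dist: tuple | None = None,
    aa_frequencies: str | BackgroundModel | None = None,
    seed: int | None = None,
) -> list[ProteinRecord]:
    """Generate ``n_proteins`` records with i.i.d. residues.

    Accessions are SYN000001, SYN000002, ...; deterministic given the
    config and seed.
    """
    if config is None:
        config = SimulationConfig(
            n_proteins=n_proteins if n_proteins is not None else 0,
            length_dist=length_dist or DEFAULT_LENGTH_DIST,
            aa_frequencies=aa_frequencies if aa_frequencies is not None else "uniform",
            seed=seed if seed is not None else 0,
        )
    model = config.background()
    probs = np.array([model.frequency(aa) for aa in _AA])
    if config.n_proteins < 0:
        raise SlimScreenError("n_proteins must be >= 0")
    rng = np.random.default_rng(config.seed)
    lengths = _draw_lengths(rng, config.n_proteins, config.length_dist)
    letters = np.frombuffer(_AA.encode("ascii"), dtype=np.uint8)
    records: list[ProteinRecord] = []
    for i, L in enumerate(lengths, start=1):
        idx = rng.choice(20, size=int(L), p=probs)
        seq = letters[idx].tobytes().decode("ascii")
        acc = f"SYN{i:06d}"
        records.append(
            ProteinRecord(accession=acc, entry_name=f"{acc}_SYN", sequence=seq,
                          gene_symbol=f"G{i:06d}")
        )
    return records


# ---------------------------------------------------------------------------
# planted motifs
# ---------------------------------------------------------------------------

def plant_motifs(
    proteome: Sequence[ProteinRecord],
    plants: Sequence[tuple],
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[MotifMatch]]:
    """Overwrite 3-residue windows with probe peptides.

    Each plant is ``(peptide, accession_or_None, position_or_None)``;
    position is the 1-based start, ``None`` meaning random, and ``None``
    accession meaning a random protein.  Plants overwrite (never insert),
    keeping lengths stable.  Overlapping plants and positions beyond
    L - 2 are rejected.  Returns the edited proteome plus the ground-truth
    match list (probe_id left empty; compare by peptide/position).
    """
    rng = np.random.default_rng(seed)
    seqs = {rec.accession: list(rec.sequence) for rec in proteome}
    order = [rec.accession for rec in proteome]
    occupied: dict[str, set[int]] = {acc: set() for acc in order}
    truth: list[MotifMatch] = []

    for plant in plants:
        pep, acc, pos = plant[0], plant[1], plant[2]
        if len(pep) != 3 or set(pep) - STANDARD_AA:
            raise SlimScreenError(f"plant peptide {pep!r} is not a standard tripeptide")
        if acc is None:
            candidates = [a for a in order if len(seqs[a]) >= 3]
            if not candidates:
                raise SlimScreenError("no protein long enough for a plant")
            acc = candidates[rng.integers(len(candidates))]
        if acc not in seqs:
            raise SlimScreenError(f"unknown accession {acc}")
        L = len(seqs[acc])
        if L < 3:
            raise SlimScreenError(f"{acc}: length {L} cannot host a tripeptide")
        if pos is None:
            free = [
                s for s in range(1, L - 1)
                if not occupied[acc] & {s, s + 1, s + 2}
            ]
            if not free:
                raise SlimScreenError(f"{acc}: no collision-free position left")
            pos = int(free[rng.integers(len(free))])
        if not 1 <= pos <= L - 2:
            raise SlimScreenError(f"{acc}: plant position {pos} beyond L-2={L-2}")
        span = {pos, pos + 1, pos + 2}
        if occupied[acc] & span:
            raise SlimScreenError(f"{acc}: overlapping plant at position {pos}")
        occupied[acc] |= span
        seqs[acc][pos - 1:pos + 2] = list(pep)
        truth.append(MotifMatch(accession=acc, probe_id=pep, start=pos, end=pos + 2))

    edited = [
        ProteinRecord(
            accession=rec.accession,
            entry_name=rec.entry_name,
            gene_symbol=rec.gene_symbol,
            description=rec.description,
            sequence="".join(seqs[rec.accession]),
        )
        for rec in proteome
    ]
    return edited, truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def generate_gene_sets(
    proteome: Sequence[ProteinRecord],
    p_protein_set: set[str],
    n_sets: int,
    set_size: int,
    enrichment_factor: float,
    n_enriched: int = 0,
    sets_per_hallmark: int = 1,
    seed: int = 0,
) -> tuple[GeneSetCollection, HallmarkMap]:
    """Gene sets sampled with controllable P-protein enrichment.

    The first *n_enriched* sets draw members without replacement with
    sampling weight ``enrichment_factor`` for P-proteins and 1 otherwise
    (factor 0 excludes P-proteins entirely; factor 1 is uniform); the
    remaining sets sample uniformly.  Sets are grouped into hallmarks of
    *sets_per_hallmark* consecutive sets.
    """
    if enrichment_factor < 0:
        raise SlimScreenError("enrichment factor must be >= 0")
    if set_size > len(proteome):
        raise SlimScreenError("set size exceeds proteome size")
    rng = np.random.default_rng(seed)
    accs = np.array([rec.accession for rec in proteome])
    is_p = np.array([acc in p_protein_set for acc in accs])
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for j in range(n_sets):
        if j < n_enriched:
            w = np.where(is_p, enrichment_factor, 1.0)
            if w.sum() == 0 or np.count_nonzero(w) < set_size:
                raise SlimScreenError("not enough eligible proteins for enriched set")
            members = rng.choice(accs, size=set_size, replace=False, p=w / w.sum())
        else:
            members = rng.choice(accs, size=set_size, replace=False)
        pid = f"SET{j + 1:04d}"
        sets[pid] = (f"Synthetic set {j + 1}", frozenset(members.tolist()))
    gene_sets = GeneSetCollection(sets)
    hallmarks: dict[str, tuple[str, ...]] = {}
    pids = list(sets)
    for h, i in enumerate(range(0, n_sets, sets_per_hallmark), start=1):
        hallmarks[f"hallmark_{h}"] = tuple(pids[i:i + sets_per_hallmark])
    return gene_sets, HallmarkMap(hallmarks)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def generate_variants(
    match_list: Sequence[MotifMatch],
    proteome: Sequence[ProteinRecord],
    n_variants: int,
    fraction_in_motif: float,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[bool]]:
    """Variants placed inside match spans at a stated fraction.

    The first ``round(n * fraction)`` variants land uniformly on (match,
    offset) pairs; the rest land uniformly on residues outside every
    match span.  Returns the records plus ground-truth in-motif labels.
    """
    if not 0.0 <= fraction_in_motif <= 1.0:
        raise SlimScreenError("fraction_in_motif must be in [0, 1]")
    if n_variants < 0:
        raise SlimScreenError("n_variants must be >= 0")
    n_in = int(round(n_variants * fraction_in_motif))
    if n_in > 0 and not match_list:
        raise SlimScreenError("cannot place in-motif variants without matches")
    rng = np.random.default_rng(seed)
    seq_of = {rec.accession: rec.sequence for rec in proteome}
    motif_positions: dict[str, set[int]] = {}
    for m in match_list:
        motif_positions.setdefault(m.accession, set()).update(
            range(m.start, m.end + 1)
        )
    out: list[VariantRecord] = []
    labels: list[bool] = []
    aa_pool = _AA
    for i in range(n_variants):
        if i < n_in:
            m = match_list[rng.integers(len(match_list))]
            offset = int(rng.integers(3))
            pos = m.start + offset
            acc = m.accession
            in_motif = True
        else:
            # rejection-sample a residue outside every match span
            for _ in range(10000):
                rec = proteome[rng.integers(len(proteome))]
                pos = int(rng.integers(1, rec.length + 1))
                acc = rec.accession
                if pos not in motif_positions.get(acc, ()):
                    break
            else:
                raise SlimScreenError("could not place an out-of-motif variant")
            in_motif = False
        ref = seq_of[acc][pos - 1]
        alts = [a for a in aa_pool if a != ref]
        alt = alts[rng.integers(len(alts))]
        out.append(
            VariantRecord(
                accession=acc,
                position=pos,
                ref_aa=ref if ref in STANDARD_AA else "A",
                alt_label=alt,
                source=f"synthetic:seed={seed}",
            )
        )
        labels.append(in_motif)
    return out, labels
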