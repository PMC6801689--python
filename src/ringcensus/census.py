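"""Genome-level census: per-type / per-chromosome tallies, protein stats,
intronless genes and tandem duplicate clusters."""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import Align

from .scanner import RingMatch

logger = logging.getLogger(__name__)

#: Chromosome labels flagged as excluded from downstream statistics.
EXCLUDED_CHROMOSOMES = frozenset({"0", "chr0", "unplaced"})


@dataclass(frozen=True)
class GeneModel:
    """A gene model from GFF3: coordinates, strand, exon structure."""

    gene_id: str
    protein_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    exon_count: int
    cds: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon count must be >= 1")


@dataclass(frozen=True)
class ProteinRow:
    protein_id: str
    chromosome: str
    n_complete: int
    n_incomplete: int
    types: tuple[str, ...]
    excluded: bool


@dataclass
class CensusTable:
    rows: tuple[ProteinRow, ...]
    per_type: dict[str, int]
    per_chromosome: dict[str, int]  # complete domains per chromosome
    n_single_domain: int
    n_multi_domain: int
    n_intronless: int | None

    @property
    def n_complete_domains(self) -> int:
        return sum(self.per_type.values())

    @property
    def n_ring_proteins(self) -> int:
        return self.n_single_domain + self.n_multi_domain


def build_census(
    matches: Iterable[RingMatch],
    gene_models: Sequence[GeneModel] | None = None,
) -> CensusTable:
    """Aggregate scan output into a census table.

    Proteins without a gene model are tallied under chromosome "unplaced";
    entries on chromosome "0"/"unplaced" are flagged excluded from
    downstream statistics (but still counted in the totals, so the
    conservation identities hold).
    """
    gene_models = list(gene_models or [])
    gm_by_protein = {g.protein_id: g for g in gene_models}

    by_protein: dict[str, list[RingMatch]] = defaultdict(list)
    for m in matches:
        by_protein[m.protein_id].append(m)

    rows = []
    per_type: Counter = Counter()
    per_chromosome: Counter = Counter()
    n_single = n_multi = 0
    ring_gene_ids = []
    for pid, ms in by_protein.items():
        complete = [m for m in ms if m.is_complete]
        gm = gm_by_protein.get(pid)
        chrom = gm.chromosome if gm is not None else "unplaced"
        excluded = chrom in EXCLUDED_CHROMOSOMES
        types = tuple(m.type_name for m in sorted(complete, key=lambda m: m.ml_positions[0]))
        rows.append(
            ProteinRow(pid, chrom, len(complete), len(ms) - len(complete), types, excluded)
        )
        per_type.update(types)
        per_chromosome[chrom] += len(complete)
        if len(complete) == 1:
            n_single += 1
        elif len(complete) >= 2:
            n_multi += 1
        if complete and gm is not None and not excluded:
            ring_gene_ids.append(gm.gene_id)

    n_intronless = (
        count_intronless(gene_models, ring_gene_ids) if gene_models else None
    )
    table = CensusTable(
        rows=tuple(sorted(rows, key=lambda r: r.protein_id)),
        per_type=dict(sorted(per_type.items())),
        per_chromosome=dict(sorted(per_chromosome.items())),
        n_single_domain=n_single,
        n_multi_domain=n_multi,
        n_intronless=n_intronless,
    )
    logger.info(
        "SUMMARY census domains=%d proteins=%d single=%d multi=%d intronless=%s",
        table.n_complete_domains,
        table.n_ring_proteins,
        n_single,
        n_multi,
        n_intronless,
    )
    return table


def count_intronless(
    gene_models: Iterable[GeneModel], ring_gene_ids: Iterable[str]
) -> int:
    """Number of the given genes whose model has a single exon."""
    wanted = set(ring_gene_ids)
    return sum(1 for g in gene_models if g.gene_id in wanted and g.exon_count == 1)


# ---------------------------------------------------------------------------
# Protein statistics

# Average (isotope-weighted) residue masses, Da; free protein adds one water.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.0153
_MEAN_RESIDUE_MASS = sum(_RESIDUE_MASS.values()) / len(_RESIDUE_MASS)

# Ionisable-group pKa values (EMBOSS set): termini plus D, E, C, Y, H, K, R.
_PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


class ProteinStats(NamedTuple):
    length: int
    molecular_weight: float  # Da
    isoelectric_point: float


def _net_charge(counts: Mapping[str, int], ph: float) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE["nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE["cterm"] - ph))
    for residue, pka in _PKA_POSITIVE.items():
        if residue != "nterm" and counts.get(residue):
            charge += counts[residue] / (1.0 + 10 ** (ph - pka))
    for residue, pka in _PKA_NEGATIVE.items():
        if residue != "cterm" and counts.get(residue):
            charge -= counts[residue] / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, tolerance: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection over pH 0..14.

    The net-charge function is strictly decreasing in pH, so the zero is
    unique; bisection runs until ``|charge| < tolerance``.
    """
    counts = Counter(sequence.upper())
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        charge = _net_charge(counts, mid)
        if abs(charge) < tolerance:
            return mid
        if charge > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_stats(sequence: str) -> ProteinStats:
    """(length, molecular weight in Da, isoelectric point) for a protein.

    Non-standard letters contribute the mean residue mass and trigger a
    warning.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = sequence.upper()
    mass = _WATER_MASS
    nonstandard = 0
    for r in seq:
        residue_mass = _RESIDUE_MASS.get(r)
        if residue_mass is None:
            nonstandard += 1
            residue_mass = _MEAN_RESIDUE_MASS
        mass += residue_mass
    if nonstandard:
        warnings.warn(
            f"{nonstandard} non-standard residue(s) assigned the mean residue mass",
            stacklevel=2,
        )
    return ProteinStats(len(seq), mass, isoelectric_point(seq))


# ---------------------------------------------------------------------------
# Pairwise identity and tandem clustering

_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=-1.0,
    extend_gap_score=-1.0,
)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Identical positions / alignment length under global alignment.

    Scoring: match +1, mismatch 0, gap -1.  Arguments are canonically
    ordered before aligning, so the result is symmetric even among
    co-optimal alignments.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    x, y = sorted((seq_a.upper(), seq_b.upper()))
    alignment = _ALIGNER.align(x, y)[0]
    identities = alignment.counts().identities
    return identities / alignment.length


@dataclass(frozen=True)
class TandemParams:
    max_intervening: int = 1
    max_distance: int = 100_000  # bp
    min_identity: float = 0.7


@dataclass(frozen=True)
class TandemCluster:
    chromosome: str
    gene_ids: tuple[str, ...]
    params: TandemParams


def find_tandem_clusters(
    ring_genes: Iterable[GeneModel],
    all_genes: Iterable[GeneModel],
    sequences: Mapping[str, str],
    params: TandemParams = TandemParams(),
) -> list[TandemCluster]:
    """Runs of nearby, mutually similar RING genes on one chromosome.

    Consecutive members must be separated by at most ``max_intervening``
    non-RING genes *or* at most ``max_distance`` bp, and every member must
    reach ``min_identity`` protein identity with all current members.
    Clusters have >= 2 members.  The result is invariant to input row order
    (genes are sorted by coordinates internally).
    """
    ring_ids = {g.gene_id for g in ring_genes}
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in all_genes:
        by_chrom[g.chromosome].append(g)

    clusters: list[TandemCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        indexed_ring = [(i, g) for i, g in enumerate(genes) if g.gene_id in ring_ids]
        run: list[tuple[int, GeneModel]] = []

        def flush() -> None:
            if len(run) >= 2:
                clusters.append(
                    TandemCluster(chrom, tuple(g.gene_id for _, g in run), params)
                )

        for idx, gene in indexed_ring:
            if run:
                prev_idx, prev_gene = run[-1]
                intervening = idx - prev_idx - 1
                distance = max(0, gene.start - prev_gene.end)
                near = intervening <= params.max_intervening or distance <= params.max_distance
                similar = near and all(
                    pairwise_identity(
                        sequences[gene.protein_id], sequences[member.protein_id]
                    )
                    >= params.min_identity
                    for _, member in run
                )
                if not similar:
                    flush()
                    run = []
            run.append((idx, gene))
        flush()
    return clusters
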