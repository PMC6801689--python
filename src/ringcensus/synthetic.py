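"""Synthetic proteomes, gene models and CDS pairs with planted ground truth.

The generator inverts the consensus grammar: it instantiates domain strings
that classify as a requested type, plants them (and near-miss decoys with
knocked-out metal-ligands) into background sequence drawn from a filler
alphabet that by default excludes C, H, S and G, and emits matching gene
models on 12 chromosomes, optional coding sequences, and a complete truth
table.  Everything is byte-deterministic for a fixed (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log
from typing import Mapping, Sequence

import numpy as np

from .census import GeneModel
from .evolution import _FORWARD, _STOPS, codons_of
from .ring_model import TYPE_NAMES, RingTypeSpec, spec_by_name
from .scanner import ProteinRecord

#: Default filler alphabet: the 20 standard residues minus {C, H, S, G}, so
#: planted octets are the only spec-satisfying octets in their neighbourhood.
SAFE_FILLER = "ADEFIKLMNPQRTVWY"

#: Default type mix, proportional to the census per-type tallies.
DEFAULT_TYPE_WEIGHTS: dict[str, float] = {
    "RING-H2": 248,
    "RING-HCa": 142,
    "RING-HCb": 21,
    "RING-v": 40,
    "RING-C2": 20,
    "RING-S/T": 2,
    "RING-G": 1,
}

_AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_FORWARD.items()):
    _AA_TO_CODONS.setdefault(_aa, ())
    _AA_TO_CODONS[_aa] += (_codon,)
_NON_STOP_CODONS = tuple(sorted(_FORWARD))


class InfeasibleConfigError(ValueError):
    """The requested synthetic design cannot be realised."""


@dataclass(frozen=True)
class PlantedDomain:
    protein_id: str
    ml1_index: int  # 0-based index of ml1 in the protein sequence
    type_name: str
    gaps: tuple[int, ...]

    @property
    def length(self) -> int:
        return 8 + sum(self.gaps)


@dataclass(frozen=True)
class PlantedDecoy:
    protein_id: str
    ml1_index: int
    type_name: str  # the type the intact octet would have had
    gaps: tuple[int, ...]
    knocked_ml: tuple[int, ...]  # 1-based metal-ligand numbers replaced

    @property
    def n_knockouts(self) -> int:
        return len(self.knocked_ml)


@dataclass(frozen=True)
class CdsMutationRecord:
    pair_id: str
    n_synonymous: int
    n_nonsynonymous: int
    changes: tuple[tuple[int, str, str, str], ...] = ()  # (nt index, old, new, kind)


@dataclass(frozen=True)
class ProteomeConfig:
    n_proteins: int = 50
    n_domains: int = 30
    type_weights: Mapping[str, float] | None = None
    n_decoys: int = 0
    decoy_knockouts: int = 1
    intronless_fraction: float = 0.21
    n_chromosomes: int = 12
    length_range: tuple[int, int] = (60, 1888)
    tandem_clusters: tuple[int, ...] = ()
    background_alphabet: str = SAFE_FILLER
    background_weights: tuple[float, ...] | None = None
    flank: int = 5
    # Default spacing exceeds the largest distance a single (possibly
    # violated) gap can bridge, so octets never chimerise across items.
    inter_domain_spacing: tuple[int, int] = (80, 140)
    with_cds: bool = True


@dataclass(frozen=True)
class SyntheticTruth:
    seed: int
    config: ProteomeConfig
    domains: tuple[PlantedDomain, ...]
    decoys: tuple[PlantedDecoy, ...]
    tandem: tuple[tuple[str, ...], ...] = ()
    cds_mutations: tuple[CdsMutationRecord, ...] = ()


def instantiate_consensus(
    type_name: str,
    gaps: Sequence[int] | str = "random",
    filler: str | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Build a domain string (ml1..ml8 plus gap filler) of the given type.

    ``gaps`` is either an explicit 7-vector inside the type's gap sets or
    ``"random"`` to sample each gap uniformly from its set.  ``filler`` is a
    single letter (used verbatim) or an alphabet to sample from; the default
    alphabet excludes C, H, S and G.
    """
    spec = spec_by_name(type_name)
    rng = np.random.default_rng(0) if rng is None else rng
    if isinstance(gaps, str):
        if gaps != "random":
            raise ValueError(f"gaps must be a 7-vector or 'random', got {gaps!r}")
        gap_vec = tuple(
            int(sorted(gs)[rng.integers(len(gs))]) for gs in spec.gap_sets
        )
    else:
        gap_vec = tuple(int(g) for g in gaps)
        if len(gap_vec) != 7:
            raise ValueError("gap vector must have 7 entries")
        for g, allowed in zip(gap_vec, spec.gap_sets):
            if g not in allowed:
                raise ValueError(
                    f"{type_name}: gap {g} outside allowed set {sorted(allowed)}"
                )

    residues = []
    for rs in spec.residue_sets:
        options = sorted(rs)
        residues.append(options[rng.integers(len(options))] if len(options) > 1 else options[0])
    if spec.require_serine and residues[1] != "S" and residues[5] != "S":
        slot = (1, 5)[int(rng.integers(2))]
        if "S" in spec.residue_sets[slot]:
            residues[slot] = "S"
        else:
            residues[1 if "S" in spec.residue_sets[1] else 5] = "S"

    if filler is None:
        alphabet = SAFE_FILLER
    elif len(filler) == 1:
        alphabet = filler
    else:
        alphabet = filler

    def fill(n: int) -> str:
        if n == 0:
            return ""
        if len(alphabet) == 1:
            return alphabet * n
        return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))

    parts = [residues[0]]
    for gap, residue in zip(gap_vec, residues[1:]):
        parts.append(fill(gap))
        parts.append(residue)
    return "".join(parts)


def _background_sampler(config: ProteomeConfig, rng: np.random.Generator):
    alphabet = config.background_alphabet
    if config.background_weights is not None:
        weights = np.asarray(config.background_weights, dtype=float)
        if len(weights) != len(alphabet):
            raise InfeasibleConfigError("background_weights length mismatch")
        probs = weights / weights.sum()

        def sample(n: int) -> str:
            if n == 0:
                return ""
            idx = rng.choice(len(alphabet), size=n, p=probs)
            return "".join(alphabet[i] for i in idx)

    else:

        def sample(n: int) -> str:
            if n == 0:
                return ""
            return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))

    return sample


def _type_weight_vector(config: ProteomeConfig) -> tuple[np.ndarray, tuple[str, ...]]:
    weights = dict(DEFAULT_TYPE_WEIGHTS)
    if config.type_weights is not None:
        weights = {name: float(config.type_weights.get(name, 0.0)) for name in TYPE_NAMES}
    vec = np.array([max(0.0, float(weights.get(n, 0.0))) for n in TYPE_NAMES])
    if vec.sum() <= 0:
        raise InfeasibleConfigError("type weights sum to zero")
    return vec / vec.sum(), TYPE_NAMES


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """A random CDS (no stop codon) encoding the given protein."""
    codons = []
    for aa in protein.upper():
        options = _AA_TO_CODONS.get(aa)
        if options is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random valid CDS of ``n_codons`` codons (no stops)."""
    return "".join(
        _NON_STOP_CODONS[i] for i in rng.integers(len(_NON_STOP_CODONS), size=n_codons)
    )


def generate_proteome(
    config: ProteomeConfig, seed: int
) -> tuple[list[ProteinRecord], list[GeneModel], SyntheticTruth]:
    """Generate (protein records, gene models, truth table) for a config.

    Deterministic for a fixed (config, seed); every planted domain is
    flanked by at least ``config.flank`` filler residues.
    """
    if config.n_domains > 2 * config.n_proteins:
        raise InfeasibleConfigError(
            f"{config.n_domains} domains exceed 2 per protein over "
            f"{config.n_proteins} proteins"
        )
    if not 0.0 <= config.intronless_fraction <= 1.0:
        raise InfeasibleConfigError("intronless_fraction must be in [0, 1]")
    if config.flank < 5:
        raise InfeasibleConfigError("flank must be >= 5")
    lo, hi = config.length_range
    if lo < 1 or hi < lo:
        raise InfeasibleConfigError(f"bad length range {config.length_range}")

    rng = np.random.default_rng(seed)
    background = _background_sampler(config, rng)
    probs, names = _type_weight_vector(config)
    names_arr = np.array(names)

    # Target lengths: log-uniform over the configured range.
    lengths = np.exp(rng.uniform(log(lo), log(hi), size=config.n_proteins))
    lengths = [int(round(x)) for x in lengths]

    # Assign domain slots (<= 2 per protein) and types (each type at least
    # once when the budget allows, so small censuses still cover the grammar).
    slot_pool = np.repeat(np.arange(config.n_proteins), 2)
    rng.shuffle(slot_pool)
    hosts = [int(h) for h in slot_pool[: config.n_domains]]
    type_list = list(names) if config.n_domains >= len(names) else []
    remaining = config.n_domains - len(type_list)
    if remaining > 0:
        type_list += [str(t) for t in rng.choice(names_arr, size=remaining, p=probs)]
    type_list = [type_list[i] for i in rng.permutation(len(type_list))]

    domains_by_protein: dict[int, list[str]] = {}
    for host, type_name in zip(hosts, type_list):
        domains_by_protein.setdefault(host, []).append(type_name)

    if config.n_decoys <= config.n_proteins:
        decoy_hosts = [
            int(h)
            for h in rng.choice(config.n_proteins, size=config.n_decoys, replace=False)
        ]
    else:
        decoy_hosts = [
            int(h) for h in rng.integers(0, config.n_proteins, size=config.n_decoys)
        ]
    decoy_types = [str(t) for t in rng.choice(names_arr, size=config.n_decoys, p=probs)]
    decoy_knocks = [
        tuple(int(k) + 1 for k in sorted(rng.choice(8, size=config.decoy_knockouts, replace=False)))
        for _ in range(config.n_decoys)
    ]
    decoys_by_protein: dict[int, list[int]] = {}
    for j, host in enumerate(decoy_hosts):
        decoys_by_protein.setdefault(host, []).append(j)

    records: list[ProteinRecord] = []
    planted: list[PlantedDomain] = []
    decoys: list[PlantedDecoy] = []

    for i in range(config.n_proteins):
        protein_id = f"prot{i + 1:05d}"
        items: list[tuple[str, object]] = [
            ("domain", t) for t in domains_by_protein.get(i, [])
        ] + [("decoy", j) for j in decoys_by_protein.get(i, [])]

        parts: list[str] = []
        pos = 0
        lead = config.flank + int(rng.integers(0, 6))
        for kind, payload in items:
            parts.append(background(lead))
            pos += lead
            if kind == "domain":
                type_name = str(payload)
                domain = instantiate_consensus(type_name, "random", None, rng)
                gaps = _gaps_of_domain(domain, type_name)
                planted.append(PlantedDomain(protein_id, pos, type_name, gaps))
            else:
                j = int(payload)
                type_name = decoy_types[j]
                gaps = _decoy_gap_vector(type_name, decoy_knocks[j], rng)
                domain = instantiate_consensus(type_name, gaps, None, rng)
                domain = _knock_out(domain, gaps, decoy_knocks[j])
                decoys.append(
                    PlantedDecoy(protein_id, pos, type_name, gaps, decoy_knocks[j])
                )
            parts.append(domain)
            pos += len(domain)
            lead = int(rng.integers(*config.inter_domain_spacing))
        needed = pos + config.flank
        if needed > hi:
            raise InfeasibleConfigError(
                f"protein {protein_id} needs {needed} residues, above the "
                f"maximum length {hi}"
            )
        tail = max(config.flank, lengths[i] - pos)
        parts.append(background(tail))
        records.append(ProteinRecord(protein_id, "".join(parts)))

    # Gene models: round-robin chromosomes, monotone per-chromosome cursors.
    cursors = {f"chr{c + 1}": 10_000 for c in range(config.n_chromosomes)}
    gene_models: list[GeneModel] = []
    for i, record in enumerate(records):
        chrom = f"chr{(i % config.n_chromosomes) + 1}"
        exon_count = 1 if rng.random() < config.intronless_fraction else int(rng.integers(2, 9))
        strand = "+" if rng.random() < 0.5 else "-"
        span = 3 * len(record.sequence) + 400 * (exon_count - 1)
        start = cursors[chrom]
        end = start + span - 1
        cursors[chrom] = end + int(rng.integers(2_000, 50_000))
        cds = reverse_translate(record.sequence, rng) if config.with_cds else None
        gene_models.append(
            GeneModel(
                gene_id=f"gene{i + 1:05d}",
                protein_id=record.id,
                chromosome=chrom,
                start=start,
                end=end,
                strand=strand,
                exon_count=exon_count,
                cds=cds,
            )
        )

    # Tandem clusters: extra near-identical RING genes placed consecutively.
    tandem_groups: list[tuple[str, ...]] = []
    index = config.n_proteins
    for size in config.tandem_clusters:
        if size < 2:
            raise InfeasibleConfigError("tandem clusters need >= 2 members")
        chrom = f"chr{int(rng.integers(1, config.n_chromosomes + 1))}"
        type_name = str(rng.choice(names_arr, p=probs))
        domain = instantiate_consensus(type_name, "random", None, rng)
        gaps = _gaps_of_domain(domain, type_name)
        lead = config.flank + int(rng.integers(0, 6))
        tail = int(rng.integers(60, 140))
        base_seq = background(lead) + domain + background(tail)
        ml1 = lead
        member_gene_ids = []
        for m in range(size):
            seq = base_seq if m == 0 else _mutate_background(
                base_seq, (ml1, ml1 + len(domain) - 1), rng
            )
            protein_id = f"prot{index + 1:05d}"
            records.append(ProteinRecord(protein_id, seq))
            planted.append(PlantedDomain(protein_id, ml1, type_name, gaps))
            exon_count = 1 if rng.random() < config.intronless_fraction else int(rng.integers(2, 9))
            strand = "+" if rng.random() < 0.5 else "-"
            span = 3 * len(seq) + 400 * (exon_count - 1)
            start = cursors[chrom]
            end = start + span - 1
            cursors[chrom] = end + int(rng.integers(500, 3_000))
            cds = reverse_translate(seq, rng) if config.with_cds else None
            gene_id = f"gene{index + 1:05d}"
            gene_models.append(
                GeneModel(gene_id, protein_id, chrom, start, end, strand, exon_count, cds)
            )
            member_gene_ids.append(gene_id)
            index += 1
        tandem_groups.append(tuple(member_gene_ids))

    truth = SyntheticTruth(
        seed=seed,
        config=config,
        domains=tuple(planted),
        decoys=tuple(decoys),
        tandem=tuple(tandem_groups),
    )
    return records, gene_models, truth


def _gaps_of_domain(domain: str, type_name: str) -> tuple[int, ...]:
    """Recover the gap vector of an instantiated domain string."""
    spec = spec_by_name(type_name)
    ligand_letters = set().union(*spec.residue_sets)
    positions = [i for i, r in enumerate(domain) if r in ligand_letters]
    if len(positions) != 8:
        raise RuntimeError("instantiated domain contains stray ligand letters")
    return tuple(positions[i + 1] - positions[i] - 1 for i in range(7))


def _decoy_gap_vector(
    type_name: str, knocked_ml: tuple[int, ...], rng: np.random.Generator
) -> tuple[int, ...]:
    """Sample a gap vector whose knocked octet has a unique frame.

    A knocked-out terminal ligand (ml1 or ml8) admits an alternative
    single-violation frame shifted into the adjacent variable gap; pinning
    that gap to its minimum makes the shifted frame violate the gap grammar,
    so the decoy is reported at its planted coordinates.
    """
    spec = spec_by_name(type_name)
    gaps = [int(sorted(gs)[rng.integers(len(gs))]) for gs in spec.gap_sets]
    if 1 in knocked_ml:
        gaps[1] = min(spec.gap_sets[1])
    if 8 in knocked_ml:
        gaps[6] = min(spec.gap_sets[6])
    return tuple(gaps)


def _knock_out(domain: str, gaps: tuple[int, ...], knocked_ml: tuple[int, ...]) -> str:
    """Replace the given 1-based metal-ligand positions with alanine."""
    positions = [0]
    for g in gaps:
        positions.append(positions[-1] + g + 1)
    chars = list(domain)
    for ml in knocked_ml:
        chars[positions[ml - 1]] = "A"
    return "".join(chars)


def _mutate_background(
    seq: str, domain_span: tuple[int, int], rng: np.random.Generator
) -> str:
    """Substitute a few background residues outside the planted domain."""
    lo, hi = domain_span
    editable = [i for i in range(len(seq)) if i < lo or i > hi]
    n_edits = max(1, len(editable) // 60)
    chosen = rng.choice(len(editable), size=min(n_edits, len(editable)), replace=False)
    chars = list(seq)
    for c in sorted(int(x) for x in chosen):
        i = editable[c]
        options = [a for a in SAFE_FILLER if a != chars[i]]
        chars[i] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def mutate_cds(
    cds: str,
    n_synonymous: int,
    n_nonsynonymous: int,
    rng: np.random.Generator,
    pair_id: str = "",
) -> tuple[str, CdsMutationRecord]:
    """Apply exact counts of single-nucleotide synonymous / nonsynonymous
    changes, never introducing stops and never touching a codon twice."""
    codons = codons_of(cds)
    syn_options: list[list[tuple[int, str]]] = []
    non_options: list[list[tuple[int, str]]] = []
    for codon in codons:
        syn: list[tuple[int, str]] = []
        non: list[tuple[int, str]] = []
        for position in range(3):
            for base in "ACGT":
                if base == codon[position]:
                    continue
                mutant = codon[:position] + base + codon[position + 1 :]
                if mutant in _STOPS:
                    continue
                if _FORWARD[mutant] == _FORWARD[codon]:
                    syn.append((position, base))
                else:
                    non.append((position, base))
        syn_options.append(syn)
        non_options.append(non)

    syn_pool = [i for i, opts in enumerate(syn_options) if opts]
    if len(syn_pool) < n_synonymous:
        raise InfeasibleConfigError(
            f"only {len(syn_pool)} codons admit a synonymous change, "
            f"{n_synonymous} requested"
        )
    syn_codons = sorted(
        int(i)
        for i in rng.choice(len(syn_pool), size=n_synonymous, replace=False)
    ) if n_synonymous else []
    syn_chosen = {syn_pool[i] for i in syn_codons}

    non_pool = [i for i, opts in enumerate(non_options) if opts and i not in syn_chosen]
    if len(non_pool) < n_nonsynonymous:
        raise InfeasibleConfigError(
            f"only {len(non_pool)} remaining codons admit a nonsynonymous "
            f"change, {n_nonsynonymous} requested"
        )
    non_chosen = (
        {non_pool[int(i)] for i in rng.choice(len(non_pool), size=n_nonsynonymous, replace=False)}
        if n_nonsynonymous
        else set()
    )

    changes: list[tuple[int, str, str, str]] = []
    mutated = list(codons)
    for i in sorted(syn_chosen | non_chosen):
        kind = "synonymous" if i in syn_chosen else "nonsynonymous"
        options = syn_options[i] if i in syn_chosen else non_options[i]
        position, base = options[int(rng.integers(len(options)))]
        old = mutated[i]
        mutated[i] = old[:position] + base + old[position + 1 :]
        changes.append((3 * i + position, old[position], base, kind))

    record = CdsMutationRecord(pair_id, n_synonymous, n_nonsynonymous, tuple(changes))
    return "".join(mutated), record
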