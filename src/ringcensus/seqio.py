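"""Readers and writers: FASTA, GFF3, TSV reports, key-value configs.

All writers are deterministic given identical inputs.  Reports use 1-based
inclusive coordinates; everything internal stays 0-based.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .census import CensusTable, GeneModel, TandemCluster
from .domain_stats import ConservationProfile, SpacingHistogram, format_percent
from .scanner import ProteinRecord, RingMatch
from .synthetic import SyntheticTruth


def read_fasta(path: str) -> list[ProteinRecord]:
    """Read a protein FASTA; trailing '*' stripped, duplicate ids rejected."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        sequence = str(rec.seq).strip().strip("*")
        records.append(ProteinRecord(rec.id, sequence))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def write_cds_fasta(gene_models: Iterable[GeneModel], path: str, width: int = 60) -> None:
    with open(path, "w") as handle:
        for gm in gene_models:
            if gm.cds is None:
                continue
            handle.write(f">{gm.protein_id}\n")
            for i in range(0, len(gm.cds), width):
                handle.write(gm.cds[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        if "=" in chunk:
            key, value = chunk.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff3(path: str) -> list[GeneModel]:
    """Parse gene/mRNA/exon features into one GeneModel per mRNA.

    Coordinates are 1-based inclusive.  Only ID/Parent attributes are
    interpreted; an mRNA with no exon features gets exon count 1.  Lines
    with the wrong column count are an error.
    """
    genes: dict[str, tuple[str, int, int, str]] = {}
    mrnas: dict[str, tuple[str, str, int, int, str]] = {}  # id -> (parent, chrom, ...)
    exon_counts: dict[str, int] = {}
    with open(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{line_no}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            seqid, _, ftype, start, end, _, strand, _, attrs_text = fields
            attrs = _parse_attributes(attrs_text)
            if ftype == "gene":
                genes[attrs.get("ID", f"gene@{line_no}")] = (
                    seqid,
                    int(start),
                    int(end),
                    strand,
                )
            elif ftype == "mRNA":
                mrnas[attrs.get("ID", f"mRNA@{line_no}")] = (
                    attrs.get("Parent", ""),
                    seqid,
                    int(start),
                    int(end),
                    strand,
                )
            elif ftype == "exon":
                parent = attrs.get("Parent", "")
                exon_counts[parent] = exon_counts.get(parent, 0) + 1
    models = []
    for mrna_id, (parent, seqid, start, end, strand) in mrnas.items():
        if parent in genes:
            gchrom, gstart, gend, gstrand = genes[parent]
            gene_id = parent
        else:
            gchrom, gstart, gend, gstrand = seqid, start, end, strand
            gene_id = mrna_id
        models.append(
            GeneModel(
                gene_id=gene_id,
                protein_id=mrna_id,
                chromosome=gchrom,
                start=gstart,
                end=gend,
                strand=gstrand,
                exon_count=max(1, exon_counts.get(mrna_id, 0)),
            )
        )
    return models


def write_gff3(gene_models: Sequence[GeneModel], path: str) -> None:
    """Write gene + mRNA + exon features; round-trips through read_gff3."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gm in gene_models:
            row = [
                gm.chromosome,
                "ringcensus",
                "gene",
                str(gm.start),
                str(gm.end),
                ".",
                gm.strand,
                ".",
                f"ID={gm.gene_id}",
            ]
            handle.write("\t".join(row) + "\n")
            row[2] = "mRNA"
            row[8] = f"ID={gm.protein_id};Parent={gm.gene_id}"
            handle.write("\t".join(row) + "\n")
            for start, end in _exon_layout(gm):
                row = [
                    gm.chromosome,
                    "ringcensus",
                    "exon",
                    str(start),
                    str(end),
                    ".",
                    gm.strand,
                    ".",
                    f"Parent={gm.protein_id}",
                ]
                handle.write("\t".join(row) + "\n")


def _exon_layout(gm: GeneModel) -> list[tuple[int, int]]:
    """Split the gene span into exon_count exons separated by short introns."""
    span = gm.end - gm.start + 1
    n = gm.exon_count
    if n == 1:
        return [(gm.start, gm.end)]
    intron = max(1, min(100, (span - n) // max(1, n - 1) - 1))
    exon_total = span - intron * (n - 1)
    base, extra = divmod(exon_total, n)
    exons = []
    pos = gm.start
    for i in range(n):
        length = base + (1 if i < extra else 0)
        exons.append((pos, pos + length - 1))
        pos += length + intron
    return exons


# ---------------------------------------------------------------------------
# Reports


def match_rows(
    matches: Iterable[RingMatch], chromosome_of: Mapping[str, str] | None = None
) -> list[list[str]]:
    chromosome_of = chromosome_of or {}
    rows = []
    for m in matches:
        rows.append(
            [
                m.protein_id,
                chromosome_of.get(m.protein_id, "unplaced"),
                m.type_name,
                "complete" if m.is_complete else "incomplete",
                ",".join(str(p + 1) for p in m.ml_positions),  # 1-based
                ",".join(str(g) for g in m.gaps),
                "".join(m.residues),
                ",".join(f"ml{v}" for v in m.violations),
            ]
        )
    return rows


_MATCH_HEADER = [
    "protein_id",
    "chromosome",
    "type",
    "status",
    "ml_positions_1based",
    "gaps",
    "ml_residues",
    "violations",
]


def write_matches(
    matches: Sequence[RingMatch],
    path: str,
    chromosome_of: Mapping[str, str] | None = None,
) -> None:
    _write_tsv(path, _MATCH_HEADER, match_rows(matches, chromosome_of))


def _write_tsv(path: str, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def write_reports(
    census: CensusTable,
    matches: Sequence[RingMatch],
    out_dir: str,
    spacing: Sequence[SpacingHistogram] = (),
    profile: ConservationProfile | None = None,
    tandem: Sequence[TandemCluster] = (),
) -> list[str]:
    """Write the census report tables; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []

    def emit(name: str, header: Sequence[str], rows: Iterable[Sequence[str]]) -> None:
        path = os.path.join(out_dir, name)
        _write_tsv(path, header, rows)
        paths.append(path)

    chromosome_of = {row.protein_id: row.chromosome for row in census.rows}
    emit("matches.tsv", _MATCH_HEADER, match_rows(matches, chromosome_of))
    emit(
        "census_per_type.tsv",
        ["type", "n_domains", "percent"],
        [
            [name, n, format_percent(n / census.n_complete_domains) if census.n_complete_domains else "0.0"]
            for name, n in census.per_type.items()
        ],
    )
    emit(
        "census_per_chromosome.tsv",
        ["chromosome", "n_domains", "excluded"],
        [
            [chrom, n, "yes" if chrom in {"0", "chr0", "unplaced"} else "no"]
            for chrom, n in census.per_chromosome.items()
        ],
    )
    emit(
        "census_proteins.tsv",
        ["protein_id", "chromosome", "n_complete", "n_incomplete", "types", "excluded"],
        [
            [r.protein_id, r.chromosome, r.n_complete, r.n_incomplete, ",".join(r.types), "yes" if r.excluded else "no"]
            for r in census.rows
        ],
    )
    emit(
        "census_summary.tsv",
        ["key", "value"],
        [
            ["total_complete_domains", census.n_complete_domains],
            ["ring_proteins", census.n_ring_proteins],
            ["single_domain_proteins", census.n_single_domain],
            ["multi_domain_proteins", census.n_multi_domain],
            ["intronless_ring_genes", census.n_intronless if census.n_intronless is not None else "NA"],
        ],
    )
    if spacing:
        emit(
            "spacing.tsv",
            ["pair", "type_filter", "gap", "n_domains"],
            [
                [h.pair, h.type_filter or "all", gap, n]
                for h in spacing
                for gap, n in sorted(h.counts.items())
            ],
        )
    if profile is not None:
        emit(
            "conservation_profile.tsv",
            ["ring_type", "ml", "offset", "residue", "frequency", "n_domains"],
            [
                [profile.ring_type, ml, offset, residue, f"{freq:.6f}", profile.support[(ml, offset)]]
                for (ml, offset), vector in profile.frequencies.items()
                for residue, freq in vector.items()
            ],
        )
    if tandem:
        emit(
            "tandem_clusters.tsv",
            ["chromosome", "n_members", "gene_ids"],
            [[c.chromosome, len(c.gene_ids), ",".join(c.gene_ids)] for c in tandem],
        )
    return paths


def write_truth(truth: SyntheticTruth, path: str) -> None:
    """Flat TSV of the planted ground truth (domains, decoys, tandem)."""
    rows: list[list[str]] = []
    for d in truth.domains:
        rows.append(
            ["domain", d.protein_id, str(d.ml1_index), d.type_name, ",".join(map(str, d.gaps)), ""]
        )
    for d in truth.decoys:
        rows.append(
            [
                "decoy",
                d.protein_id,
                str(d.ml1_index),
                d.type_name,
                ",".join(map(str, d.gaps)),
                ",".join(f"ml{k}" for k in d.knocked_ml),
            ]
        )
    for group in truth.tandem:
        rows.append(["tandem", ",".join(group), "", "", "", ""])
    _write_tsv(
        path,
        ["kind", "protein_or_genes", "ml1_index_0based", "type", "gaps", "knocked"],
        rows,
    )


def write_config(values: Mapping[str, object], path: str) -> None:
    """Write a flat ``key = value`` provenance file, sorted by key."""
    with open(path, "w") as handle:
        for key in sorted(values):
            handle.write(f"{key} = {values[key]}\n")
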