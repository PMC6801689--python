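"""Nei-Gojobori (1986) Ka/Ks estimation for pre-aligned coding sequences.

Synonymous/nonsynonymous *sites* are counted per codon position as the
fraction of the three single-nucleotide changes that preserve the encoded
amino acid (changes to stop codons count as nonsynonymous).  *Differences*
between two codons are averaged over all orderings of the differing
positions, excluding pathways that pass through a stop codon.  Proportions
are corrected for multiple hits with the Jukes-Cantor formula
``K = -(3/4) ln(1 - 4p/3)``; proportions at or beyond the 3/4 ceiling are
reported uncorrected with a saturation flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log
from typing import Sequence

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


def codons_of(cds: str) -> list[str]:
    """Validate a CDS and split it into codons.

    Requires length divisible by 3, unambiguous ACGT bases, and no stop
    codons anywhere (trim a trailing stop before calling).
    """
    seq = cds.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty coding sequence")
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    if set(seq) - set(_BASES):
        raise ValueError(f"invalid bases in CDS: {sorted(set(seq) - set(_BASES))}")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, codon in enumerate(codons):
        if codon in _STOPS:
            raise ValueError(f"stop codon {codon} at codon position {i}")
    return codons


def _syn_fraction(codon: str, position: int) -> float:
    """Fraction of the three changes at *position* that are synonymous."""
    aa = _FORWARD[codon]
    syn = 0
    for base in _BASES:
        if base == codon[position]:
            continue
        mutant = codon[:position] + base + codon[position + 1 :]
        if mutant not in _STOPS and _FORWARD[mutant] == aa:
            syn += 1
    return syn / 3.0


def ng86_sites(cds: str) -> tuple[float, float]:
    """(synonymous sites S, nonsynonymous sites N); S + N == len(cds)."""
    s_sites = 0.0
    for codon in codons_of(cds):
        for position in range(3):
            s_sites += _syn_fraction(codon, position)
    return s_sites, len(cds) - s_sites


def _pathway_counts(codon1: str, codon2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) steps over mutation pathways.

    All orderings of the differing positions are weighted equally; orderings
    whose intermediate codons are stops are excluded.  If every ordering is
    blocked, all orderings are used with steps into/out of stops counted as
    nonsynonymous.
    """
    diff = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool):
        syn = non = 0
        current = codon1
        for position in order:
            nxt = current[:position] + codon2[position] + current[position + 1 :]
            if nxt in _STOPS or current in _STOPS:
                if not allow_stops:
                    return None
                non += 1
            elif _FORWARD[current] == _FORWARD[nxt]:
                syn += 1
            else:
                non += 1
            current = nxt
        return syn, non

    orders = list(permutations(diff))
    results = [r for r in (walk(o, False) for o in orders) if r is not None]
    if not results:
        results = [walk(o, True) for o in orders]
    syn_total = sum(r[0] for r in results)
    non_total = sum(r[1] for r in results)
    return syn_total / len(results), non_total / len(results)


@dataclass(frozen=True)
class KaKsResult:
    s_sites: float  # synonymous sites (averaged over the pair)
    n_sites: float
    sd: float  # synonymous differences
    nd: float
    ps: float  # proportions sd/S, nd/N
    pn: float
    ka: float | None  # Jukes-Cantor corrected rates; None when saturated
    ks: float | None
    ratio: float | None  # Ka/Ks; None when Ks == 0 or undefined
    saturated: bool


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0) + 0.0  # avoid -0.0 at p == 0


def ng86_kaks(cds1: str, cds2: str) -> KaKsResult:
    """NG86 Ka/Ks between two equal-length, pre-aligned coding sequences."""
    codons1 = codons_of(cds1)
    codons2 = codons_of(cds2)
    if len(codons1) != len(codons2):
        raise ValueError(
            f"coding sequences differ in length ({len(cds1)} vs {len(cds2)})"
        )
    s1, _ = ng86_sites(cds1)
    s2, _ = ng86_sites(cds2)
    s_sites = (s1 + s2) / 2.0
    n_sites = len(cds1) - s_sites

    sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        syn, non = _pathway_counts(c1, c2)
        sd += syn
        nd += non

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    saturated = ks is None or ka is None
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(s_sites, n_sites, sd, nd, ps, pn, ka, ks, ratio, saturated)


def classify_selection(result: KaKsResult) -> str:
    """'purifying' (<1), 'neutral' (=1), 'positive' (>1) or 'undefined'."""
    if result.ratio is None:
        return "undefined"
    if result.ratio < 1.0:
        return "purifying"
    if result.ratio > 1.0:
        return "positive"
    return "neutral"
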