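"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with different code paths from the
package: a stack-based octet enumerator, a min()-per-round selection rule,
and an NG86 implementation built on Bio.Seq.translate.
"""

from __future__ import annotations

from itertools import permutations
from math import log

from Bio.Seq import Seq


def brute_octets(seq: str, specs) -> list[tuple[tuple[int, ...], str]]:
    """Every (positions, type name) octet satisfying some spec, stack DFS."""
    seq = seq.upper()
    n = len(seq)
    found = []
    for spec in specs:
        stack = [(pos,) for pos in range(n) if seq[pos] in spec.residue_sets[0]]
        while stack:
            partial = stack.pop()
            level = len(partial)
            if level == 8:
                if (
                    spec.require_serine
                    and seq[partial[1]] != "S"
                    and seq[partial[5]] != "S"
                ):
                    continue
                found.append((partial, spec.name))
                continue
            for gap in sorted(spec.gap_sets[level - 1], reverse=True):
                nxt = partial[-1] + gap + 1
                if nxt < n and seq[nxt] in spec.residue_sets[level]:
                    stack.append(partial + (nxt,))
    return found


def select_by_rule(
    candidates: list[tuple[tuple[int, ...], str]], type_order: tuple[str, ...]
) -> list[tuple[tuple[int, ...], str]]:
    """The documented overlap-resolution rule, applied literally.

    Repeatedly take the candidate with the leftmost ml1, breaking ties by
    smaller span then type order; discard everything overlapping it.
    """
    rank = {name: i for i, name in enumerate(type_order)}
    pool = list(candidates)
    chosen = []
    while pool:
        best = min(
            pool, key=lambda c: (c[0][0], c[0][7] - c[0][0], rank[c[1]])
        )
        chosen.append(best)
        lo, hi = best[0][0], best[0][7]
        pool = [c for c in pool if c[0][7] < lo or c[0][0] > hi]
    return chosen


# ---------------------------------------------------------------------------
# NG86 oracle


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stops


def oracle_sites(cds: str) -> tuple[float, float]:
    syn_sites = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if _aa(mutant) != "*" and _aa(mutant) == _aa(codon):
                    syn_sites += 1.0 / 3.0
    return syn_sites, len(cds) - syn_sites


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    pathway_results = []
    for order in permutations(diff):
        current = c1
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if _aa(nxt) == "*":
                blocked = True
                break
            if _aa(nxt) == _aa(current):
                syn += 1
            else:
                non += 1
            current = nxt
        if not blocked:
            pathway_results.append((syn, non))
    if not pathway_results:  # every ordering passes through a stop
        for order in permutations(diff):
            current = c1
            syn = non = 0
            for pos in order:
                nxt = current[:pos] + c2[pos] + current[pos + 1 :]
                if _aa(nxt) == "*" or _aa(current) == "*" or _aa(nxt) != _aa(current):
                    non += 1
                else:
                    syn += 1
                current = nxt
            pathway_results.append((syn, non))
    k = len(pathway_results)
    return (
        sum(r[0] for r in pathway_results) / k,
        sum(r[1] for r in pathway_results) / k,
    )


def oracle_kaks(cds1: str, cds2: str):
    """(S, N, Sd, Nd, Ka, Ks) by literal NG86 arithmetic; rates None if
    the Jukes-Cantor correction is impossible."""
    s1, _ = oracle_sites(cds1)
    s2, _ = oracle_sites(cds2)
    s_sites = (s1 + s2) / 2.0
    n_sites = len(cds1) - s_sites
    sd = nd = 0.0
    for i in range(0, len(cds1), 3):
        syn, non = _codon_differences(cds1[i : i + 3], cds2[i : i + 3])
        sd += syn
        nd += non
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks = None if ps >= 0.75 else -0.75 * log(1 - 4 * ps / 3) + 0.0
    ka = None if pn >= 0.75 else -0.75 * log(1 - 4 * pn / 3) + 0.0
    return s_sites, n_sites, sd, nd, ka, ks
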