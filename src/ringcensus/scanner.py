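"""Scanning protein sequences for complete and incomplete RING domains.

The scanner enumerates every metal-ligand octet that satisfies some type
spec (:func:`enumerate_octets`), resolves overlaps into a deterministic
maximal non-overlapping set (:func:`scan_protein`), and separately reports
*incomplete* domains: octets whose gap structure fits a spec but whose
residues violate exactly one metal-ligand constraint (:func:`find_incomplete`).

Coordinates are 0-based internally; the report layer converts to 1-based.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .ring_model import (
    INCOMPLETE,
    OctetCandidate,
    RingTypeSpec,
    builtin_specs,
    classify_octet,
    match_spec,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with optional genomic placement."""

    id: str
    sequence: str
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class RingMatch:
    """One detected RING domain.

    ``ml_positions`` are eight strictly increasing 0-based indices into the
    protein sequence; ``gaps[i] == ml_positions[i+1] - ml_positions[i] - 1``.
    Complete matches carry a type name and no violations; incomplete matches
    carry ``type_name == "incomplete"`` and the 1-based metal-ligand numbers
    whose residue constraint failed.
    """

    protein_id: str
    ml_positions: tuple[int, ...]
    residues: tuple[str, ...]
    gaps: tuple[int, ...]
    type_name: str
    violations: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        expected = tuple(
            self.ml_positions[i + 1] - self.ml_positions[i] - 1 for i in range(7)
        )
        if expected != self.gaps:
            raise ValueError("gaps inconsistent with ml_positions")
        if self.type_name == INCOMPLETE:
            if not self.violations:
                raise ValueError("incomplete match must carry >=1 violation")
        elif self.violations:
            raise ValueError("complete match cannot carry violations")

    @property
    def span(self) -> tuple[int, int]:
        """Inclusive 0-based [ml1, ml8] interval."""
        return (self.ml_positions[0], self.ml_positions[7])

    @property
    def is_complete(self) -> bool:
        return self.type_name != INCOMPLETE


class OctetHit(NamedTuple):
    positions: tuple[int, ...]
    candidate: OctetCandidate
    type_name: str


def _gaps_of(positions: Sequence[int]) -> tuple[int, ...]:
    return tuple(positions[i + 1] - positions[i] - 1 for i in range(7))


def _walk(seq: str, spec: RingTypeSpec, max_violations: int):
    """Depth-first enumeration of octet position tuples for one spec.

    Gap constraints are always enforced; up to ``max_violations`` residue
    constraints may fail.  Yields ``(positions, violated_levels)`` with
    0-based levels.
    """
    n = len(seq)
    rsets = spec.residue_sets
    gap_lists = tuple(sorted(gs) for gs in spec.gap_sets)
    path = [0] * 8
    out: list[tuple[tuple[int, ...], tuple[int, ...]]] = []

    def rec(level: int, pos: int, viol: tuple[int, ...]) -> None:
        if level == 8:
            out.append((tuple(path), viol))
            return
        allowed = rsets[level]
        for g in gap_lists[level - 1]:
            j = pos + g + 1
            if j >= n:
                break
            if seq[j] in allowed:
                path[level] = j
                rec(level + 1, j, viol)
            elif len(viol) < max_violations:
                path[level] = j
                rec(level + 1, j, viol + (level,))

    for i in range(n):
        if seq[i] in rsets[0]:
            path[0] = i
            rec(1, i, ())
        elif max_violations >= 1:
            path[0] = i
            rec(1, i, (0,))
    return out


def _serine_rule_ok(
    spec: RingTypeSpec, seq: str, positions: Sequence[int], violated: Sequence[int]
) -> bool:
    if not spec.require_serine:
        return True
    if 1 in violated or 5 in violated:  # the rule cannot bind a knocked-out site
        return True
    return seq[positions[1]] == "S" or seq[positions[5]] == "S"


def enumerate_octets(
    sequence: str, specs: Sequence[RingTypeSpec] | None = None
) -> list[OctetHit]:
    """Every octet (including overlapping alternatives) matching some spec.

    Output is ordered by ml1 position, then span length, then spec order;
    this is also the greedy selection order used by :func:`scan_protein`.
    """
    seq = sequence.upper()
    specs = builtin_specs() if specs is None else tuple(specs)
    rank = {s.name: i for i, s in enumerate(specs)}
    hits: dict[tuple[int, ...], OctetHit] = {}
    for spec in specs:
        for positions, _ in _walk(seq, spec, max_violations=0):
            cand = OctetCandidate(
                tuple(seq[p] for p in positions), _gaps_of(positions)
            )
            if not match_spec(spec, cand):  # enforces the serine rule
                continue
            prev = hits.get(positions)
            if prev is not None and prev.type_name != spec.name:
                raise RuntimeError(
                    f"octet at {positions} matches both {prev.type_name} "
                    f"and {spec.name}"
                )
            hits[positions] = OctetHit(positions, cand, spec.name)
    return sorted(
        hits.values(),
        key=lambda h: (h.positions[0], h.positions[7] - h.positions[0], rank[h.type_name]),
    )


def _select_non_overlapping(ordered: Sequence) -> list:
    """Greedy selection: leftmost ml1, then smallest span, then spec order.

    ``ordered`` must already be sorted by that key; items need a
    ``positions`` attribute.  Selected items never share a residue index in
    their inclusive [ml1, ml8] spans.
    """
    chosen = []
    pool = list(ordered)
    while pool:
        best = pool[0]
        chosen.append(best)
        lo, hi = best.positions[0], best.positions[7]
        pool = [h for h in pool[1:] if h.positions[7] < lo or h.positions[0] > hi]
    return chosen


def scan_protein(
    record: ProteinRecord, specs: Sequence[RingTypeSpec] | None = None
) -> list[RingMatch]:
    """Maximal non-overlapping set of complete RING domains in one protein."""
    hits = enumerate_octets(record.sequence, specs)
    return [
        RingMatch(record.id, h.positions, h.candidate.residues, h.candidate.gaps, h.type_name)
        for h in _select_non_overlapping(hits)
    ]


def find_incomplete(
    record: ProteinRecord,
    complete: Sequence[RingMatch],
    specs: Sequence[RingTypeSpec] | None = None,
    max_violations: int = 1,
) -> list[RingMatch]:
    """Octets violating 1..``max_violations`` residue constraints of some spec.

    Gap constraints are enforced strictly (a lacking ligand is modelled as a
    residue mismatch, not a deleted position).  Candidates overlapping a
    complete match are dropped, and survivors are made mutually
    non-overlapping by the same greedy rule as :func:`scan_protein`.
    """
    if max_violations < 1:
        return []
    seq = record.sequence.upper()
    specs = builtin_specs() if specs is None else tuple(specs)
    # positions -> (n_violations, spec rank, violated levels)
    best: dict[tuple[int, ...], tuple[int, int, tuple[int, ...]]] = {}
    for spec_rank, spec in enumerate(specs):
        for positions, violated in _walk(seq, spec, max_violations):
            if not violated:
                continue
            if not _serine_rule_ok(spec, seq, positions, violated):
                continue
            key = (len(violated), spec_rank, violated)
            prev = best.get(positions)
            if prev is None or key < prev:
                best[positions] = key

    taken = [m.span for m in complete]

    def overlaps_complete(positions: tuple[int, ...]) -> bool:
        lo, hi = positions[0], positions[7]
        return any(not (hi < a or lo > b) for a, b in taken)

    candidates = []
    for positions, (n_viol, spec_rank, violated) in best.items():
        cand = OctetCandidate(tuple(seq[p] for p in positions), _gaps_of(positions))
        if classify_octet(cand, specs) is not None:
            continue  # complete under some other spec; not "incomplete"
        if overlaps_complete(positions):
            continue
        candidates.append((positions, cand, n_viol, spec_rank, violated))
    # Fewest violations, then most compact frame, then leftmost: a knocked-out
    # terminal ligand admits a re-framed candidate 3 residues wider, which a
    # position-first greedy would wrongly prefer.
    candidates.sort(key=lambda c: (c[2], c[0][7] - c[0][0], c[0][0], c[3]))

    class _Item(NamedTuple):
        positions: tuple[int, ...]
        candidate: OctetCandidate
        violated: tuple[int, ...]

    items = [_Item(p, c, v) for p, c, _, _, v in candidates]
    return [
        RingMatch(
            record.id,
            it.positions,
            it.candidate.residues,
            it.candidate.gaps,
            INCOMPLETE,
            violations=tuple(level + 1 for level in it.violated),
        )
        for it in _select_non_overlapping(items)
    ]


def scan_proteome(
    records: Iterable[ProteinRecord],
    specs: Sequence[RingTypeSpec] | None = None,
    include_incomplete: bool = True,
    max_violations: int = 1,
) -> list[RingMatch]:
    """Scan every protein; deterministic order (input order, then ml1).

    Raises :class:`ValueError` on duplicate protein ids.  Logs a
    machine-parseable per-type tally line.
    """
    records = list(records)
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate protein id {r.id!r}")
        seen.add(r.id)

    matches: list[RingMatch] = []
    for record in records:
        complete = scan_protein(record, specs)
        per_protein = list(complete)
        if include_incomplete:
            per_protein.extend(
                find_incomplete(record, complete, specs, max_violations)
            )
        per_protein.sort(key=lambda m: m.ml_positions[0])
        matches.extend(per_protein)

    tally = Counter(m.type_name for m in matches)
    summary = " ".join(f"{name}={tally.get(name, 0)}" for name in sorted(tally))
    logger.info("SUMMARY scan proteins=%d matches=%d %s", len(records), len(matches), summary)
    return matches
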