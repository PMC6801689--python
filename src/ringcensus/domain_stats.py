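"""Spacing-variation statistics and positional conservation profiles.

Spacing histograms count the residues between consecutive metal-ligands over
a set of complete matches.  Conservation profiles tally residue frequencies
at signed offsets anchored on each metal-ligand individually, so variable
gap lengths never misalign columns.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .ring_model import PAIR_LABELS
from .scanner import RingMatch


def _pair_index(pair: str) -> int:
    try:
        return PAIR_LABELS.index(pair)
    except ValueError:
        raise ValueError(f"unknown metal-ligand pair label {pair!r}") from None


@dataclass
class SpacingHistogram:
    """Gap-length tally for one metal-ligand pair."""

    pair: str
    counts: dict[int, int]
    type_filter: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _complete(matches: Iterable[RingMatch]) -> list[RingMatch]:
    return [m for m in matches if m.is_complete]


def spacing_histogram(
    matches: Iterable[RingMatch], pair: str, type_filter: str | None = None
) -> SpacingHistogram:
    """Exact tally of ``gaps[pair]`` over (optionally type-filtered) matches."""
    idx = _pair_index(pair)
    selected = _complete(matches)
    if type_filter is not None:
        selected = [m for m in selected if m.type_name == type_filter]
    return SpacingHistogram(pair, dict(Counter(m.gaps[idx] for m in selected)), type_filter)


def modal_spacing(hist: SpacingHistogram) -> tuple[int, int]:
    """(gap, count) with the highest count; ties break to the smaller gap."""
    if not hist.counts:
        raise ValueError(f"empty spacing histogram for {hist.pair}")
    gap, count = min(hist.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return gap, count


def spacing_fraction(
    matches: Iterable[RingMatch], pair: str, values: Iterable[int]
) -> Fraction:
    """Exact share of matches whose gap at *pair* lies in *values*."""
    idx = _pair_index(pair)
    selected = _complete(matches)
    if not selected:
        raise ValueError("spacing_fraction needs a non-empty match set")
    value_set = frozenset(values)
    hits = sum(1 for m in selected if m.gaps[idx] in value_set)
    return Fraction(hits, len(selected))


def format_percent(fraction: Fraction | float) -> str:
    """One-decimal percentage string, e.g. ``'97.7'``."""
    return f"{float(fraction) * 100:.1f}"


@dataclass
class ConservationProfile:
    """Residue frequencies at signed offsets around each metal-ligand.

    ``frequencies`` maps ``(ml_number, offset)`` (ml_number 1-based,
    offset 0 = the ligand itself) to a residue->frequency mapping; each
    vector sums to 1 over the domains whose gap structure contains that
    cell.  ``support`` records that domain count.
    """

    ring_type: str
    window: tuple[int, int]
    frequencies: dict[tuple[int, int], dict[str, float]]
    support: dict[tuple[int, int], int]


def conservation_profile(
    matches: Iterable[RingMatch],
    sequences: Mapping[str, str],
    window: tuple[int, int] = (-2, 4),
    ring_type: str | None = None,
) -> ConservationProfile:
    """Positional residue frequencies anchored per metal-ligand.

    Offsets that would cross into an adjacent metal-ligand position, or fall
    outside the protein, are skipped for that domain.
    """
    lo, hi = window
    if lo > 0 or hi < 0:
        raise ValueError("window must contain offset 0")
    selected = _complete(matches)
    if ring_type is not None:
        selected = [m for m in selected if m.type_name == ring_type]
    counts: dict[tuple[int, int], Counter] = defaultdict(Counter)
    for m in selected:
        if m.protein_id not in sequences:
            raise KeyError(f"no sequence available for protein {m.protein_id!r}")
        seq = sequences[m.protein_id].upper()
        pos = m.ml_positions
        for k in range(8):
            for offset in range(lo, hi + 1):
                p = pos[k] + offset
                if p < 0 or p >= len(seq):
                    continue
                if offset > 0 and k < 7 and p >= pos[k + 1]:
                    continue
                if offset < 0 and k > 0 and p <= pos[k - 1]:
                    continue
                counts[(k + 1, offset)][seq[p]] += 1
    frequencies = {}
    support = {}
    for cell, tally in sorted(counts.items()):
        total = sum(tally.values())
        frequencies[cell] = {r: n / total for r, n in sorted(tally.items())}
        support[cell] = total
    return ConservationProfile(ring_type or "all", window, frequencies, support)


def information_content(
    frequencies: Mapping[str, float] | Sequence[float], alphabet_size: int = 20
) -> float:
    """Information content in bits: log2(alphabet) minus Shannon entropy."""
    values = (
        list(frequencies.values())
        if isinstance(frequencies, Mapping)
        else list(frequencies)
    )
    if any(v < 0 for v in values):
        raise ValueError("frequencies must be non-negative")
    total = sum(values)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequency vector sums to {total}, not 1")
    entropy = -sum(v * math.log2(v) for v in values if v > 0)
    return math.log2(alphabet_size) - entropy
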