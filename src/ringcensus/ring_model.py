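"""Consensus grammar for RING zinc-finger domains.

A RING domain is modelled as an octet of metal-ligand residues (ml1..ml8)
separated by seven inner gap regions of constrained length.  Each domain type
is a :class:`RingTypeSpec`: eight allowed-residue sets plus seven allowed-gap
sets, where a *gap* is the number of residues strictly between two consecutive
metal-ligands.

Seven built-in types ship with the package (RING-H2, RING-HCa, RING-HCb,
RING-v, RING-C2, RING-S/T and RING-G).  They are pairwise exclusive: no
(residues, gaps) octet can satisfy two of them, which is verified structurally
when the registry is built.  Custom grammars can be serialised to / loaded
from a plain-text key-value profile (:func:`dump_specs` / :func:`load_specs`).
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Labels of the seven inter-ligand gaps, in order.
PAIR_LABELS = (
    "ml1-ml2",
    "ml2-ml3",
    "ml3-ml4",
    "ml4-ml5",
    "ml5-ml6",
    "ml6-ml7",
    "ml7-ml8",
)

INCOMPLETE = "incomplete"


class SpecRegistryError(RuntimeError):
    """A spec registry is corrupted: two specs accept the same octet."""


@dataclass(frozen=True)
class RingTypeSpec:
    """One RING domain type: residue and spacing constraints.

    Parameters
    ----------
    name:
        Type label, e.g. ``"RING-H2"``.
    residue_sets:
        Eight frozensets of allowed one-letter residues, one per metal-ligand
        position ml1..ml8.
    gap_sets:
        Seven frozensets of allowed gap lengths (residues strictly between
        consecutive metal-ligands), ml1-ml2 through ml7-ml8.
    require_serine:
        If true, at least one of ml2/ml6 must actually be a serine for a
        candidate to match (the RING-S/T rule, which alternation of the
        residue sets alone cannot express).
    """

    name: str
    residue_sets: tuple[frozenset[str], ...]
    gap_sets: tuple[frozenset[int], ...]
    require_serine: bool = False

    def __post_init__(self) -> None:
        if len(self.residue_sets) != 8:
            raise ValueError("a RING spec needs exactly 8 residue constraints")
        if len(self.gap_sets) != 7:
            raise ValueError("a RING spec needs exactly 7 gap constraints")
        for rs in self.residue_sets:
            if not rs or not rs <= AMINO_ACIDS:
                raise ValueError(f"{self.name}: invalid residue set {rs!r}")
        for gs in self.gap_sets:
            if not gs or any(g < 0 for g in gs):
                raise ValueError(f"{self.name}: invalid gap set {gs!r}")

    def gap_set(self, pair: str) -> frozenset[int]:
        """Allowed gap lengths for a pair label such as ``"ml2-ml3"``."""
        return self.gap_sets[PAIR_LABELS.index(pair)]

    @property
    def min_span(self) -> int:
        return 8 + sum(min(g) for g in self.gap_sets)

    @property
    def max_span(self) -> int:
        return 8 + sum(max(g) for g in self.gap_sets)


@dataclass(frozen=True)
class OctetCandidate:
    """A candidate metal-ligand octet: eight residues and seven gaps."""

    residues: tuple[str, ...]
    gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.residues) != 8:
            raise ValueError("an octet has exactly 8 residues")
        if len(self.gaps) != 7:
            raise ValueError("an octet has exactly 7 gaps")
        if any((not isinstance(g, int)) or g < 0 for g in self.gaps):
            raise ValueError("gaps must be non-negative integers")


def _rs(letters: str) -> frozenset[str]:
    return frozenset(letters)


def _g(*values: int) -> frozenset[int]:
    return frozenset(values)


def _gr(lo: int, hi: int, *extra: int) -> frozenset[int]:
    return frozenset(range(lo, hi + 1)) | frozenset(extra)


def _build_builtin_specs() -> tuple[RingTypeSpec, ...]:
    C, H, G, CS, S = _rs("C"), _rs("H"), _rs("G"), _rs("CS"), _rs("CS")
    specs = (
        RingTypeSpec(
            "RING-H2",
            (C, C, C, H, H, C, C, C),
            (_g(2), _gr(11, 33), _g(1), _g(2, 3), _g(2), _gr(7, 64), _g(2)),
        ),
        RingTypeSpec(
            "RING-HCa",
            (C, C, C, H, C, C, C, C),
            (_g(2), _gr(10, 33), _gr(1, 3), _g(2, 3), _g(2), _gr(6, 30), _g(2)),
        ),
        RingTypeSpec(
            "RING-HCb",
            (C, C, C, H, C, C, C, C),
            (_g(2), _gr(11, 18), _g(1, 2), _g(2), _g(2), _gr(7, 19), _g(3, 4)),
        ),
        RingTypeSpec(
            "RING-v",
            (C, C, C, C, H, C, C, C),
            (_g(2), _gr(8, 29), _gr(1, 4), _gr(4, 7, 9), _g(2), _gr(9, 36), _g(2)),
        ),
        RingTypeSpec(
            "RING-C2",
            (C, C, C, C, C, C, C, C),
            (_g(2), _gr(7, 16), _gr(1, 3), _g(4), _g(2), _gr(10, 16), _g(2)),
        ),
        RingTypeSpec(
            "RING-S/T",
            (C, CS, C, H, C, S, C, C),
            (_g(2), _g(11, 14), _g(1), _g(2, 3), _g(2), _g(10, 14), _g(2)),
            require_serine=True,
        ),
        RingTypeSpec(
            "RING-G",
            (C, C, C, H, G, C, C, C),
            (_g(2), _g(16), _g(1), _g(2), _g(2), _g(13), _g(2)),
        ),
    )
    _assert_pairwise_exclusive(specs)
    return specs


def _provably_disjoint(a: RingTypeSpec, b: RingTypeSpec) -> bool:
    """True if no octet can satisfy both *a* and *b* (structural proof)."""
    for ra, rb in zip(a.residue_sets, b.residue_sets):
        if not ra & rb:
            return True
    for ga, gb in zip(a.gap_sets, b.gap_sets):
        if not ga & gb:
            return True
    # The serine rule separates RING-S/T from any spec whose ml2 and ml6
    # residue sets both exclude serine.
    for x, y in ((a, b), (b, a)):
        if x.require_serine and "S" not in (y.residue_sets[1] | y.residue_sets[5]):
            return True
    return False


def _assert_pairwise_exclusive(specs: Sequence[RingTypeSpec]) -> None:
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            if not _provably_disjoint(a, b):
                raise SpecRegistryError(
                    f"specs {a.name!r} and {b.name!r} are not provably exclusive"
                )


_BUILTIN_SPECS: tuple[RingTypeSpec, ...] = _build_builtin_specs()
_BUILTIN_BY_NAME = {s.name: s for s in _BUILTIN_SPECS}

#: Fixed reporting order of the seven built-in types (not a matching priority).
TYPE_NAMES = tuple(s.name for s in _BUILTIN_SPECS)


def builtin_specs() -> tuple[RingTypeSpec, ...]:
    """Return the seven built-in RING type specs, RING-H2 first."""
    return _BUILTIN_SPECS


def spec_by_name(name: str) -> RingTypeSpec:
    try:
        return _BUILTIN_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown RING type {name!r}") from None


def ring_d_stub() -> None:
    """Disabled placeholder for the RING-D type.

    RING-D is absent from this proteome's census and no gap grammar is
    defined for it here; the stub exists so a future profile can register one
    via :func:`load_specs` without touching the built-in registry.
    """
    return None


def match_spec(spec: RingTypeSpec, cand: OctetCandidate) -> bool:
    """True iff *cand* satisfies every residue and gap constraint of *spec*.

    Residues are upper-cased before matching; non-standard letters (X, B, Z,
    U, ``*``) never satisfy a metal-ligand constraint.
    """
    residues = tuple(r.upper() for r in cand.residues)
    for r, allowed in zip(residues, spec.residue_sets):
        if r not in allowed:
            return False
    for g, allowed in zip(cand.gaps, spec.gap_sets):
        if g not in allowed:
            return False
    if spec.require_serine and residues[1] != "S" and residues[5] != "S":
        return False
    return True


def classify_octet(
    cand: OctetCandidate, specs: Sequence[RingTypeSpec] | None = None
) -> str | None:
    """Name of the unique spec matching *cand*, or ``None``.

    Raises :class:`SpecRegistryError` if more than one spec matches, which
    would indicate a corrupted (non-exclusive) registry.
    """
    specs = _BUILTIN_SPECS if specs is None else tuple(specs)
    hits = [s.name for s in specs if match_spec(s, cand)]
    if len(hits) > 1:
        raise SpecRegistryError(f"octet matches multiple specs: {hits}")
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# Plain-text profile (de)serialisation


def _format_gap_set(gs: frozenset[int]) -> str:
    values = sorted(gs)
    parts: list[str] = []
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[j + 1] == values[j] + 1:
            j += 1
        if j > i + 1:
            parts.append(f"{values[i]}-{values[j]}")
            i = j + 1
        else:
            parts.append(str(values[i]))
            i += 1
    return ",".join(parts)


def _parse_gap_set(text: str) -> frozenset[int]:
    out: set[int] = set()
    for token in text.replace(" ", "").split(","):
        if not token:
            continue
        if "-" in token:
            lo, hi = token.split("-", 1)
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(token))
    if not out:
        raise ValueError(f"empty gap set: {text!r}")
    return frozenset(out)


def dump_specs(specs: Iterable[RingTypeSpec]) -> str:
    """Serialise specs to a plain-text key-value profile."""
    parser = configparser.ConfigParser()
    for spec in specs:
        parser[spec.name] = {
            "ml": " ".join("/".join(sorted(rs)) for rs in spec.residue_sets),
            "gaps": " ".join(_format_gap_set(gs) for gs in spec.gap_sets),
            "require_serine": str(spec.require_serine).lower(),
        }
    buf = io.StringIO()
    parser.write(buf)
    return buf.getvalue()


def load_specs(text: str) -> tuple[RingTypeSpec, ...]:
    """Parse a plain-text profile back into a validated, exclusive registry."""
    parser = configparser.ConfigParser()
    parser.read_string(text)
    specs = []
    for name in parser.sections():
        section = parser[name]
        residue_sets = tuple(
            frozenset(tok.upper().split("/")) for tok in section["ml"].split()
        )
        gap_sets = tuple(_parse_gap_set(tok) for tok in section["gaps"].split())
        specs.append(
            RingTypeSpec(
                name,
                residue_sets,
                gap_sets,
                require_serine=section.getboolean("require_serine", fallback=False),
            )
        )
    result = tuple(specs)
    _assert_pairwise_exclusive(result)
    return result
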