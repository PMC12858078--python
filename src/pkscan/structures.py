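"""Sequences, pseudoknotted secondary structures, loops and sections.

A structure is a normalized RNA sequence plus two disjoint pair sets: the
nested ``secondary_pairs`` (representable without crossing lines) and the
``pseudoknot_pairs`` that cross them.  Sections — maximal runs of bases left
unpaired by the secondary structure — are the nodes of all downstream
analyses; each carries the identity of the loop it sits in, because two
sections of the same loop cannot form a pseudoknot (such pairs would be
nested, not crossing).

Readers/writers cover layered dot-bracket, CT and BPSEQ.  CT/BPSEQ carry no
layer annotation, so their pair sets are split by :func:`decompose_layers`,
which keeps a maximum-cardinality non-crossing subset as the secondary layer.

Coordinates are 0-based half-open internally; CT/BPSEQ I/O is 1-based.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, NamedTuple

__all__ = [
    "BasePair",
    "Loop",
    "Section",
    "PseudoknottedStructure",
    "StructureError",
    "normalize_sequence",
    "parse_dotbracket",
    "iter_dotbracket",
    "write_dotbracket",
    "parse_ct",
    "write_ct",
    "parse_bpseq",
    "write_bpseq",
    "decompose_layers",
    "assign_loops",
    "identify_sections",
]


class StructureError(ValueError):
    """Malformed structure file or inconsistent pair set."""


class BasePair(NamedTuple):
    pos5: int
    pos3: int


@dataclass(frozen=True)
class Loop:
    id: int
    kind: str  # hairpin | interior | multi | exterior
    closing_pair: BasePair | None


@dataclass(frozen=True)
class Section:
    """Maximal secondary-structure-unpaired run [start, end) with its loop."""

    index: int
    start: int
    end: int
    loop_id: int

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def positions(self) -> range:
        return range(self.start, self.end)


def normalize_sequence(seq: str) -> str:
    """Uppercase and T→U normalize; other IUPAC codes survive unpaired."""
    s = seq.strip().upper().replace("T", "U")
    if not s:
        raise StructureError("empty sequence")
    return s


def _crosses(a: BasePair, b: BasePair) -> bool:
    return (a.pos5 < b.pos5 < a.pos3 < b.pos3) or (b.pos5 < a.pos5 < b.pos3 < a.pos3)


@dataclass(frozen=True)
class PseudoknottedStructure:
    sequence: str
    secondary_pairs: frozenset[BasePair]
    pseudoknot_pairs: frozenset[BasePair]

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        object.__setattr__(self, "secondary_pairs", frozenset(BasePair(*p) for p in self.secondary_pairs))
        object.__setattr__(self, "pseudoknot_pairs", frozenset(BasePair(*p) for p in self.pseudoknot_pairs))
        self._validate()

    def _validate(self) -> None:
        L = len(self.sequence)
        seen: set[int] = set()
        for p in self.all_pairs:
            if not (0 <= p.pos5 < p.pos3 < L):
                raise StructureError(f"pair {p} out of range for length {L}")
            for pos in p:
                if pos in seen:
                    raise StructureError(f"base {pos} paired twice")
                seen.add(pos)
        sec = sorted(self.secondary_pairs)
        for i, a in enumerate(sec):
            for b in sec[i + 1:]:
                if b.pos5 > a.pos3:
                    break
                if _crosses(a, b):
                    raise StructureError(f"secondary pairs {a} and {b} cross")
        others = sorted(self.all_pairs)
        for p in sorted(self.pseudoknot_pairs):
            if not any(q != p and _crosses(p, q) for q in others):
                raise StructureError(
                    f"pseudoknot pair {p} crosses nothing (belongs in the secondary layer)")

    @property
    def all_pairs(self) -> frozenset[BasePair]:
        return self.secondary_pairs | self.pseudoknot_pairs

    def __len__(self) -> int:
        return len(self.sequence)


# --- layered dot-bracket -------------------------------------------------

_LAYER_SYMBOLS: list[tuple[str, str]] = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")] + [
    (chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)
]
_OPEN = {o: k for k, (o, _) in enumerate(_LAYER_SYMBOLS)}
_CLOSE = {c: k for k, (_, c) in enumerate(_LAYER_SYMBOLS)}


def _pairs_from_brackets(db: str) -> dict[int, list[BasePair]]:
    stacks: dict[int, list[int]] = {}
    layers: dict[int, list[BasePair]] = {}
    for pos, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN[ch], []).append(pos)
        elif ch in _CLOSE:
            layer = _CLOSE[ch]
            if not stacks.get(layer):
                raise StructureError(f"unbalanced bracket {ch!r} at position {pos}")
            layers.setdefault(layer, []).append(BasePair(stacks[layer].pop(), pos))
        else:
            raise StructureError(f"unknown structure character {ch!r} at position {pos}")
    for layer, stack in stacks.items():
        if stack:
            raise StructureError(
                f"unbalanced bracket {_LAYER_SYMBOLS[layer][0]!r} at position {stack[-1]}")
    return layers


def iter_dotbracket(text: str) -> Iterator[PseudoknottedStructure]:
    """Yield structures from two-line records with optional ``>`` headers."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if lines[i].startswith(">"):
            i += 1
            continue
        if i + 1 >= len(lines):
            raise StructureError("dot-bracket record missing its structure line")
        seq, db = lines[i], lines[i + 1]
        i += 2
        if len(seq) != len(db):
            raise StructureError(
                f"sequence length {len(seq)} != structure length {len(db)}")
        layers = _pairs_from_brackets(db)
        secondary = layers.pop(0, [])
        pk = [p for layer in sorted(layers) for p in layers[layer]]
        yield PseudoknottedStructure(seq, frozenset(secondary), frozenset(pk))


def parse_dotbracket(text: str) -> PseudoknottedStructure:
    """Parse a single two-line dot-bracket record (layer 0 = secondary)."""
    structures = list(iter_dotbracket(text))
    if len(structures) != 1:
        raise StructureError(f"expected one dot-bracket record, found {len(structures)}")
    return structures[0]


def write_dotbracket(structure: PseudoknottedStructure, header: str | None = None) -> str:
    """Serialize with nested pairs as ``()`` and pseudoknot layers greedily
    packed into further bracket alphabets (non-crossing within each layer)."""
    chars = ["."] * len(structure)
    layers: list[list[BasePair]] = [sorted(structure.secondary_pairs)]
    for p in sorted(structure.pseudoknot_pairs):
        for k in range(1, len(_LAYER_SYMBOLS)):
            if k >= len(layers):
                layers.append([])
            if not any(_crosses(p, q) for q in layers[k]):
                layers[k].append(p)
                break
        else:  # pragma: no cover - >29 mutually crossing layers
            raise StructureError("ran out of bracket alphabets")
    for k, layer in enumerate(layers):
        o, c = _LAYER_SYMBOLS[k]
        for p in layer:
            chars[p.pos5], chars[p.pos3] = o, c
    head = f"{header}\n" if header else ""
    return f"{head}{structure.sequence}\n{''.join(chars)}\n"


# --- CT / BPSEQ ----------------------------------------------------------

def _pairs_from_partners(partners: dict[int, int], n: int, what: str) -> frozenset[BasePair]:
    pairs = set()
    for i, j in partners.items():
        if j == 0:
            continue
        if not 1 <= j <= n:
            raise StructureError(f"{what}: partner index {j} of base {i} out of range")
        if partners.get(j) != i:
            raise StructureError(f"{what}: partners of bases {i} and {j} are not reciprocal")
        if i < j:
            pairs.add(BasePair(i - 1, j - 1))
    return frozenset(pairs)


def _structure_from_pairs(seq: str, pairs: frozenset[BasePair]) -> PseudoknottedStructure:
    secondary, pk = decompose_layers(pairs)
    return PseudoknottedStructure(seq, frozenset(secondary), frozenset(pk))


def parse_ct(text: str) -> PseudoknottedStructure:
    """Standard 6-column CT (1-based; 0 = unpaired)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureError("empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise StructureError("CT header must start with the base count") from exc
    if len(lines) - 1 < n:
        raise StructureError(f"CT declares {n} bases but has {len(lines) - 1} rows")
    seq, partners = [], {}
    for ln in lines[1:n + 1]:
        cols = ln.split()
        if len(cols) < 6:
            raise StructureError(f"CT row has {len(cols)} columns, expected 6: {ln!r}")
        idx, base, partner = int(cols[0]), cols[1], int(cols[4])
        if idx != len(seq) + 1:
            raise StructureError(f"CT rows out of order at index {idx}")
        seq.append(base)
        partners[idx] = partner
    return _structure_from_pairs("".join(seq), _pairs_from_partners(partners, n, "CT"))


def write_ct(structure: PseudoknottedStructure, title: str = "") -> str:
    n = len(structure)
    partner = [0] * (n + 1)
    for p in structure.all_pairs:
        partner[p.pos5 + 1] = p.pos3 + 1
        partner[p.pos3 + 1] = p.pos5 + 1
    out = [f"{n} {title}".rstrip()]
    for i, base in enumerate(structure.sequence, start=1):
        out.append(f"{i} {base} {i - 1} {(i + 1) % (n + 1)} {partner[i]} {i}")
    return "\n".join(out) + "\n"


def parse_bpseq(text: str) -> PseudoknottedStructure:
    """Standard 3-column BPSEQ (1-based; 0 = unpaired)."""
    seq, partners = [], {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split()
        if len(cols) != 3:
            raise StructureError(f"BPSEQ row has {len(cols)} columns, expected 3: {ln!r}")
        idx, base, partner = int(cols[0]), cols[1], int(cols[2])
        if idx != len(seq) + 1:
            raise StructureError(f"BPSEQ rows out of order at index {idx}")
        seq.append(base)
        partners[idx] = partner
    if not seq:
        raise StructureError("empty BPSEQ file")
    return _structure_from_pairs("".join(seq), _pairs_from_partners(partners, len(seq), "BPSEQ"))


def write_bpseq(structure: PseudoknottedStructure) -> str:
    n = len(structure)
    partner = [0] * (n + 1)
    for p in structure.all_pairs:
        partner[p.pos5 + 1] = p.pos3 + 1
        partner[p.pos3 + 1] = p.pos5 + 1
    return "\n".join(
        f"{i} {b} {partner[i]}" for i, b in enumerate(structure.sequence, start=1)) + "\n"


# --- layer decomposition -------------------------------------------------

def decompose_layers(pairs: Iterable[BasePair]) -> tuple[list[BasePair], list[BasePair]]:
    """Split a one-partner-per-base pair set into a maximum-cardinality
    mutually non-crossing (secondary) subset and the crossing remainder.

    Ties in cardinality are broken toward minimum total pair span, then the
    lexicographically smallest pair list, so output is deterministic.
    """
    pairs = sorted({BasePair(*p) for p in pairs})
    seen: set[int] = set()
    for p in pairs:
        for pos in p:
            if pos in seen:
                raise StructureError(f"base {pos} paired twice")
            seen.add(pos)
    if not pairs:
        return [], []
    points = sorted(seen)
    idx = {pos: k for k, pos in enumerate(points)}
    open_at = {idx[p.pos5]: p for p in pairs}

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * len(points) + 100))

    @lru_cache(maxsize=None)
    def best(lo: int, hi: int) -> tuple[int, int]:
        """(count, -span) of the best non-crossing subset within points[lo..hi]."""
        if lo > hi:
            return (0, 0)
        value = best(lo + 1, hi)
        p = open_at.get(lo)
        if p is not None and idx[p.pos3] <= hi:
            k = idx[p.pos3]
            inside, after = best(lo + 1, k - 1), best(k + 1, hi)
            take = (1 + inside[0] + after[0], -(p.pos3 - p.pos5) + inside[1] + after[1])
            value = max(value, take)
        return value

    chosen: list[BasePair] = []

    def trace(lo: int, hi: int) -> None:
        while lo <= hi:
            p = open_at.get(lo)
            if p is not None and idx[p.pos3] <= hi:
                k = idx[p.pos3]
                inside, after = best(lo + 1, k - 1), best(k + 1, hi)
                take = (1 + inside[0] + after[0], -(p.pos3 - p.pos5) + inside[1] + after[1])
                # on ties, taking the 5'-most pair gives the lexicographically
                # smallest pair list
                if take >= best(lo + 1, hi):
                    chosen.append(p)
                    trace(lo + 1, k - 1)
                    lo = k + 1
                    continue
            lo += 1

    trace(0, len(points) - 1)
    best.cache_clear()
    secondary = sorted(chosen)
    rest = sorted(set(pairs) - set(secondary))
    return secondary, rest


# --- loops and sections --------------------------------------------------

def assign_loops(structure: PseudoknottedStructure) -> dict[int, Loop]:
    """Map each secondary-unpaired position to the loop that holds it.

    A position's loop is closed by the tightest enclosing secondary pair
    (the single exterior loop, id 0, if none).  Loop kind follows the number
    of helices meeting at the loop: hairpin (1), interior/bulge (2),
    multi (>=3); ids are assigned in 5' order of the closing pairs.
    """
    partner: dict[int, int] = {}
    for p in structure.secondary_pairs:
        partner[p.pos5] = p.pos3
        partner[p.pos3] = p.pos5
    stack: list[BasePair] = []
    enclosing: dict[int, BasePair | None] = {}
    children: dict[BasePair | None, int] = {None: 0}
    for pos in range(len(structure)):
        if pos in partner:
            if partner[pos] > pos:
                pair = BasePair(pos, partner[pos])
                parent = stack[-1] if stack else None
                children[parent] = children.get(parent, 0) + 1
                children.setdefault(pair, 0)
                stack.append(pair)
            else:
                opened = stack.pop()
                if opened.pos5 != partner[pos]:
                    raise StructureError(
                        f"secondary pairs cross at position {pos}")
        else:
            enclosing[pos] = stack[-1] if stack else None

    closings = sorted({c for c in enclosing.values() if c is not None})
    loop_of: dict[BasePair | None, Loop] = {
        None: Loop(0, "exterior", None)}
    for lid, closing in enumerate(closings, start=1):
        h = 1 + children.get(closing, 0)
        kind = "hairpin" if h == 1 else ("interior" if h == 2 else "multi")
        loop_of[closing] = Loop(lid, kind, closing)
    return {pos: loop_of[c] for pos, c in enclosing.items()}


def identify_sections(structure: PseudoknottedStructure) -> list[Section]:
    """Maximal unpaired runs w.r.t. the secondary layer only.

    Pseudoknot pairs do not break sections: sections are defined on the
    secondary scaffold before pseudoknots are considered, so a base that is
    pseudoknot-paired in the reference structure still sits in a section.
    """
    loops = assign_loops(structure)
    paired = {pos for p in structure.secondary_pairs for pos in p}
    sections: list[Section] = []
    start = None
    for pos in range(len(structure) + 1):
        unpaired = pos < len(structure) and pos not in paired
        if unpaired and start is None:
            start = pos
        elif not unpaired and start is not None:
            sections.append(Section(len(sections), start, pos, loops[start].id))
            start = None
    return sections
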