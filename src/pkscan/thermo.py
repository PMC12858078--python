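"""Nearest-neighbor thermodynamic parameters for section-pair duplexes.

The energy model assigns free-energy increments (kcal/mol, 37 °C) to stacked
base pairs and to the bulge/interior loops that separate consecutive pairs of
an antiparallel duplex.  Only loops made entirely of pseudoknot base pairs are
scored; loops containing secondary-structure pairs are excluded by the
hierarchical model, so hairpin and multiloop terms are carried for
documentation only and never enter the duplex recursion.

Tables are plain whitespace-delimited text (one file per term) bundled under
``pkscan/data``; a user may point :func:`load_parameters` at a directory with
the same layout.  Loaded values are validated against the model's published
ranges: stacking in [−3.4, +1.5], interior-loop initiation in [4.1, 7.4],
bulge initiation in [3.9, 6.7], terminal mismatches in [−2.7, +0.2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

__all__ = [
    "PairType",
    "NNParameterSet",
    "ParameterError",
    "load_parameters",
    "pair_type",
    "stacking_energy",
    "bulge_energy",
    "interior_energy",
    "RT37",
]

#: Gas constant times temperature at 37 °C, kcal/mol.
RT37 = 0.0019872 * 310.15

#: Jacobson–Stockmayer coefficient for loop lengths beyond the table (1.75·RT).
JS_COEFF = 1.75 * RT37

MAX_TABULATED_LOOP = 30

BASES = "ACGU"


class PairType(Enum):
    """Canonical (Watson–Crick + wobble) pair codes; everything else is NONE."""

    AU = "AU"
    UA = "UA"
    CG = "CG"
    GC = "GC"
    GU = "GU"
    UG = "UG"
    NONE = "NONE"

    @property
    def pairable(self) -> bool:
        return self is not PairType.NONE


PAIR_ORDER = [PairType.AU, PairType.UA, PairType.CG, PairType.GC, PairType.GU, PairType.UG]

_PAIR_LOOKUP = {p.value: p for p in PAIR_ORDER}

#: The 16 ordered mismatch codes (first base on the section1 strand,
#: second on the section2 strand).
MISMATCH_CODES = [x + y for x in BASES for y in BASES]


def pair_type(base1: str, base2: str) -> PairType:
    """Canonical pair type of two bases, NONE for anything non-canonical."""
    return _PAIR_LOOKUP.get(base1 + base2, PairType.NONE)


class ParameterError(ValueError):
    """Malformed or out-of-range parameter table."""


@dataclass(frozen=True)
class NNParameterSet:
    """Validated nearest-neighbor parameter tables (all energies kcal/mol)."""

    stacking: dict[tuple[PairType, PairType], float]
    bulge_init: dict[int, float]
    interior_init: dict[int, float]
    hairpin_init: dict[int, float]
    terminal_mismatch: dict[tuple[PairType, str], float]
    asymmetry_coeff: float = 0.5
    extrapolation_coeff: float = JS_COEFF
    #: multiloop offset / per-branch / per-unpaired-base penalties; carried for
    #: completeness of the loop-based model, unused by the duplex recursion.
    multiloop_params: tuple[float, float, float] = (3.4, 0.4, 0.0)

    def validate(self) -> "NNParameterSet":
        def _check(cond: bool, msg: str) -> None:
            if not cond:
                raise ParameterError(msg)

        _check(len(self.stacking) == 36, "stacking table must cover 6x6 pair types")
        sv = list(self.stacking.values())
        _check(all(math.isfinite(v) for v in sv), "non-finite stacking energy")
        _check(min(sv) == -3.4, f"min stacking {min(sv)} != -3.4 kcal/mol")
        _check(max(sv) == 1.5, f"max stacking {max(sv)} != +1.5 kcal/mol")
        for table, lo, hi, name in [
            (self.bulge_init, 3.9, 6.7, "bulge"),
            (self.interior_init, 4.1, 7.4, "interior"),
        ]:
            _check(set(table) == set(range(1, MAX_TABULATED_LOOP + 1)),
                   f"{name} initiation must cover lengths 1-30")
            for n, v in table.items():
                _check(math.isfinite(v) and lo <= v <= hi,
                       f"{name} initiation [{n}] = {v} outside [{lo}, {hi}]")
        _check(len(self.terminal_mismatch) == 96,
               "terminal mismatch table must cover 6 pairs x 16 mismatches")
        for (p, m), v in self.terminal_mismatch.items():
            _check(math.isfinite(v) and -2.7 <= v <= 0.2,
                   f"terminal mismatch [{p.value},{m}] = {v} outside [-2.7, 0.2]")
        return self


def _data_lines(path: Path) -> list[list[str]]:
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            rows.append([str(lineno)] + line.split())
    return rows


def _parse_stacking(path: Path) -> dict[tuple[PairType, PairType], float]:
    rows = _data_lines(path)
    if not rows or rows[0][1] != "pair":
        raise ParameterError(f"{path}: missing header row")
    cols = [_PAIR_LOOKUP.get(c) for c in rows[0][2:]]
    if len(cols) != 6 or any(c is None for c in cols):
        raise ParameterError(f"{path}:{rows[0][0]}: header must list the 6 pair codes")
    table: dict[tuple[PairType, PairType], float] = {}
    for row in rows[1:]:
        lineno, code, *vals = row
        outer = _PAIR_LOOKUP.get(code)
        if outer is None or len(vals) != 6:
            raise ParameterError(f"{path}:{lineno}: bad stacking row {code!r}")
        for inner, v in zip(cols, vals):
            try:
                table[(outer, inner)] = float(v)
            except ValueError as exc:
                raise ParameterError(f"{path}:{lineno}: non-numeric entry {v!r}") from exc
    return table


def _parse_loops(path: Path) -> tuple[dict[int, float], dict[int, float], dict[int, float]]:
    rows = _data_lines(path)
    if not rows or rows[0][1] != "length":
        raise ParameterError(f"{path}: missing header row")
    bulge, interior, hairpin = {}, {}, {}
    for row in rows[1:]:
        lineno = row[0]
        if len(row) != 5:
            raise ParameterError(f"{path}:{lineno}: expected 4 columns")
        try:
            n = int(row[1])
            bulge[n], interior[n], hairpin[n] = (float(x) for x in row[2:])
        except ValueError as exc:
            raise ParameterError(f"{path}:{lineno}: non-numeric entry") from exc
    return bulge, interior, hairpin


def _parse_terminal_mismatch(path: Path) -> dict[tuple[PairType, str], float]:
    rows = _data_lines(path)
    if not rows or rows[0][1] != "pair":
        raise ParameterError(f"{path}: missing header row")
    cols = rows[0][2:]
    if sorted(cols) != sorted(MISMATCH_CODES):
        raise ParameterError(f"{path}:{rows[0][0]}: header must list the 16 mismatch codes")
    table: dict[tuple[PairType, str], float] = {}
    for row in rows[1:]:
        lineno, code, *vals = row
        closing = _PAIR_LOOKUP.get(code)
        if closing is None or len(vals) != 16:
            raise ParameterError(f"{path}:{lineno}: bad mismatch row {code!r}")
        for mm, v in zip(cols, vals):
            try:
                table[(closing, mm)] = float(v)
            except ValueError as exc:
                raise ParameterError(f"{path}:{lineno}: non-numeric entry {v!r}") from exc
    return table


def load_parameters(source: str | Path = "default") -> NNParameterSet:
    """Load and validate a nearest-neighbor parameter set.

    ``source`` is either the built-in identifier ``"default"`` (the bundled
    tables) or a directory containing ``stacking.tsv``, ``loops.tsv`` and
    ``terminal_mismatch.tsv`` in the documented layout.
    """
    if source == "default":
        root = Path(str(resources.files("pkscan").joinpath("data")))
    else:
        root = Path(source)
        if not root.is_dir():
            raise ParameterError(f"parameter source {source!r} is not a directory")
    stacking = _parse_stacking(root / "stacking.tsv")
    bulge, interior, hairpin = _parse_loops(root / "loops.tsv")
    tm = _parse_terminal_mismatch(root / "terminal_mismatch.tsv")
    return NNParameterSet(
        stacking=stacking,
        bulge_init=bulge,
        interior_init=interior,
        hairpin_init=hairpin,
        terminal_mismatch=tm,
    ).validate()


def _require_pairable(*pairs: PairType) -> None:
    for p in pairs:
        if not p.pairable:
            raise ValueError("NONE pair type has no energy; caller must guard")


def stacking_energy(params: NNParameterSet, outer: PairType, inner: PairType) -> float:
    """Stacking increment for the motif 5'-outer·inner-3' / 3'-…-5'."""
    _require_pairable(outer, inner)
    return params.stacking[(outer, inner)]


def _loop_init(table: dict[int, float], length: int, extrapolation: float) -> float:
    if length <= MAX_TABULATED_LOOP:
        return table[length]
    # Jacobson-Stockmayer logarithmic extension beyond the tabulated range
    return table[MAX_TABULATED_LOOP] + extrapolation * math.log(length / MAX_TABULATED_LOOP)


def bulge_energy(
    params: NNParameterSet,
    length: int,
    outer: PairType,
    inner: PairType,
    mm_outer: str | None = None,
    mm_inner: str | None = None,
) -> float:
    """Bulge-loop increment for ``length`` unpaired bases on one strand.

    A length-1 bulge keeps helix continuity, so the flanking stack is added.
    Mismatch codes are accepted for signature compatibility with the recursion
    but carry no bonus for bulges.
    """
    if length < 1:
        raise ValueError("bulge length must be >= 1")
    _require_pairable(outer, inner)
    e = _loop_init(params.bulge_init, length, params.extrapolation_coeff)
    if length == 1:
        e += stacking_energy(params, outer, inner)
    return e


def interior_energy(
    params: NNParameterSet,
    len1: int,
    len2: int,
    outer: PairType,
    inner: PairType,
    mm_outer: str,
    mm_inner: str,
) -> float:
    """Interior-loop increment: initiation by total length, asymmetry penalty,
    and terminal-mismatch bonuses at both closing pairs."""
    if len1 < 1 or len2 < 1:
        raise ValueError("interior loop side lengths must be >= 1")
    _require_pairable(outer, inner)
    e = _loop_init(params.interior_init, len1 + len2, params.extrapolation_coeff)
    e += params.asymmetry_coeff * abs(len1 - len2)
    # unknown mismatch codes (non-ACGU loop residues) carry no bonus
    e += params.terminal_mismatch.get((outer, mm_outer), 0.0)
    e += params.terminal_mismatch.get((inner, mm_inner), 0.0)
    return e
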