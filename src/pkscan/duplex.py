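"""Minimum-free-energy pseudoknot duplexes between two sections.

The central recursion: for sections of lengths l1, l2, a matrix C is filled
where C(i, j) is the minimum free-energy contribution over duplex structures
in which base i of section1 pairs base j of section2 and no earlier base of
section1 (i' < i) or later base of section2 (j' > j) participates — i.e.
(i, j) is the outermost pair of the structure counted by that entry.  Pairs
within a section pair may not cross, and the strands run antiparallel, so a
structure is a list of pairs with i strictly increasing and j strictly
decreasing.  Each entry extends an inner structure by a stacked pair, a bulge
on either strand, or an interior loop; a lone pair contributes 0.  The MFE of
the section pair is min(0, min C), hence always <= 0; a strictly negative MFE
is the prediction that the two sections connect.

Work per section pair is O(l1^2 * l2^2), dominated by the interior-loop case;
the inner double loop is evaluated with vectorized arithmetic and the number
of candidate transitions examined is recorded on the matrix for scaling
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .structures import BasePair, Section
from .thermo import (
    MAX_TABULATED_LOOP,
    NNParameterSet,
    PairType,
    bulge_energy,
    interior_energy,
    pair_type,
    stacking_energy,
)

__all__ = [
    "CMatrix",
    "DuplexStructure",
    "SectionPairResult",
    "SameLoopError",
    "can_pair",
    "build_c_matrix",
    "section_pair_mfe",
    "section_pair_mfe_masked",
    "traceback_cooptimal",
    "duplex_energy",
    "COOPT_TOL",
]

#: Co-optimality tolerance for tracebacks, kcal/mol.
COOPT_TOL = 1e-6

#: Default cap on the number of co-optimal structures returned.
DEFAULT_CAP = 64


class SameLoopError(ValueError):
    """Sections of the same loop cannot form pseudoknots."""


# alias kept for discoverability next to the recursion
can_pair = pair_type


@dataclass
class DuplexStructure:
    """An antiparallel, non-crossing pseudoknot duplex between two sections.

    ``pairs`` holds (i, j) with i indexing section1 and j section2, both
    0-based within their section; i strictly increases while j strictly
    decreases along the list.
    """

    pairs: tuple[tuple[int, int], ...]
    energy: float

    def __post_init__(self):
        self.pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if not (i1 < i2 and j1 > j2):
                raise ValueError(f"duplex pairs not antiparallel/non-crossing: {self.pairs}")

    def global_pairs(self, sec1: Section, sec2: Section) -> list[BasePair]:
        return [BasePair(sec1.start + i, sec2.start + j) for i, j in self.pairs]


@dataclass
class CMatrix:
    entries: np.ndarray  # (l1, l2), kcal/mol, +inf where bases cannot pair
    sec1: Section
    sec2: Section
    bases1: str
    bases2: str
    ptypes: list[list[PairType]]
    ops: int  # number of recursion candidates examined


def _tm(params: NNParameterSet, closing: PairType, code: str) -> float:
    # unknown codes (non-ACGU residues inside a loop) carry no bonus
    return params.terminal_mismatch.get((closing, code), 0.0)


def _loop_arrays(params: NNParameterSet, max_size: int) -> tuple[np.ndarray, np.ndarray]:
    from .thermo import _loop_init  # shared extrapolation rule

    bulge = np.empty(max_size + 1)
    interior = np.empty(max_size + 1)
    bulge[0] = interior[0] = np.inf  # length 0 never queried
    for n in range(1, max_size + 1):
        bulge[n] = _loop_init(params.bulge_init, n, params.extrapolation_coeff)
        interior[n] = _loop_init(params.interior_init, n, params.extrapolation_coeff)
    return bulge, interior


def build_c_matrix(
    seq: str,
    sec1: Section,
    sec2: Section,
    params: NNParameterSet,
    mask: Iterable[int] = (),
) -> CMatrix:
    """Fill the section-pair DP matrix.

    ``mask`` lists global sequence positions that may not pair (bases already
    claimed by another duplex); masked bases still occupy space, so they count
    toward bulge/interior loop lengths.
    """
    if sec1.loop_id == sec2.loop_id:
        raise SameLoopError(
            f"sections {sec1.index} and {sec2.index} share loop {sec1.loop_id}")
    if sec1.start >= sec2.start:
        raise ValueError("sec1 must precede sec2 in the sequence")
    mask = frozenset(mask)
    b1 = seq[sec1.start:sec1.end]
    b2 = seq[sec2.start:sec2.end]
    l1, l2 = len(b1), len(b2)
    pt = [
        [
            PairType.NONE
            if (sec1.start + i in mask or sec2.start + j in mask)
            else pair_type(b1[i], b2[j])
            for j in range(l2)
        ]
        for i in range(l1)
    ]

    stack = params.stacking
    asym = params.asymmetry_coeff
    bulge_arr, interior_arr = _loop_arrays(params, l1 + l2)
    # interior terminal-mismatch bonus attached to the inner closing pair at
    # (x, y): unpaired neighbours are (x-1) on strand 1 and (y+1) on strand 2
    tmi = np.zeros((l1, l2))
    for x in range(1, l1):
        for y in range(l2 - 1):
            if pt[x][y].pairable:
                tmi[x, y] = _tm(params, pt[x][y], b1[x - 1] + b2[y + 1])

    C = np.full((l1, l2), np.inf)
    ops = 0
    for i in range(l1 - 1, -1, -1):
        row_up = C[i + 1] if i + 1 < l1 else None
        for j in range(l2):
            cur = pt[i][j]
            if not cur.pairable:
                continue
            ops += 1  # innermost-pair base case
            best = 0.0
            # stacked pair
            if i < l1 - 1 and j > 0:
                ops += 1
                inner = pt[i + 1][j - 1]
                if inner.pairable and np.isfinite(row_up[j - 1]):
                    best = min(best, row_up[j - 1] + stack[(cur, inner)])
            # bulge on section2: inner pair (i+1, j-d), d = 2..j
            if i < l1 - 1 and j >= 2:
                ops += j - 1
                inner = pt[i + 1][j - 2]
                if inner.pairable and np.isfinite(row_up[j - 2]):
                    best = min(best, row_up[j - 2] + bulge_arr[1] + stack[(cur, inner)])
                if j >= 3:
                    lens = j - np.arange(0, j - 2) - 1  # bulge lengths >= 2
                    cand = row_up[0:j - 2] + bulge_arr[lens]
                    best = min(best, float(cand.min()))
            # bulge on section1: inner pair (i+d, j-1), d = 2..l1-1-i
            if j > 0 and i <= l1 - 3:
                ops += l1 - 2 - i
                inner = pt[i + 2][j - 1]
                if inner.pairable and np.isfinite(C[i + 2, j - 1]):
                    best = min(best, C[i + 2, j - 1] + bulge_arr[1] + stack[(cur, inner)])
                if i <= l1 - 4:
                    lens = np.arange(3, l1 - i) - 1  # bulge lengths >= 2
                    cand = C[i + 3:l1, j - 1] + bulge_arr[lens]
                    best = min(best, float(cand.min()))
            # interior loop: inner pair (i+d1, j-d2), d1, d2 >= 2
            if i <= l1 - 3 and j >= 2:
                sub = C[i + 2:l1, 0:j - 1]
                ops += sub.size
                if np.isfinite(sub).any():
                    d1 = np.arange(2, l1 - i)[:, None]
                    d2 = (j - np.arange(0, j - 1))[None, :]
                    cand = (
                        sub
                        + interior_arr[d1 + d2 - 2]
                        + asym * np.abs(d1 - d2)
                        + tmi[i + 2:l1, 0:j - 1]
                        + _tm(params, cur, b1[i + 1] + b2[j - 1])
                    )
                    best = min(best, float(cand.min()))
            C[i, j] = best
    return CMatrix(C, sec1, sec2, b1, b2, pt, ops)


@dataclass
class SectionPairResult:
    sec1: Section
    sec2: Section
    admissible: bool
    mfe: float | None = None
    structures: list[DuplexStructure] = field(default_factory=list)
    matrix: CMatrix | None = None

    @property
    def gain(self) -> float:
        """MFE gain |mfe|; 0 for inadmissible pairs."""
        return abs(self.mfe) if self.mfe is not None else 0.0

    @property
    def connected_predicted(self) -> bool:
        return self.mfe is not None and self.mfe < 0


def section_pair_mfe(
    seq: str,
    sec1: Section,
    sec2: Section,
    params: NNParameterSet,
    *,
    mask: Iterable[int] = (),
    cap: int = DEFAULT_CAP,
    traceback: bool = True,
) -> SectionPairResult:
    """MFE and (optionally) all co-optimal duplexes for one section pair.

    Returns an inadmissible result instead of raising when the sections share
    a loop; the MFE is min(0, min C), so it is never positive, and a pair is
    predicted connected exactly when its MFE is negative.
    """
    try:
        cm = build_c_matrix(seq, sec1, sec2, params, mask)
    except SameLoopError:
        return SectionPairResult(sec1, sec2, admissible=False)
    mfe = float(min(0.0, cm.entries.min())) if cm.entries.size else 0.0
    structures = traceback_cooptimal(cm, params, cap=cap) if traceback else []
    return SectionPairResult(sec1, sec2, True, mfe, structures, cm)


def section_pair_mfe_masked(
    seq: str,
    sec1: Section,
    sec2: Section,
    params: NNParameterSet,
    mask: Iterable[int],
    *,
    cap: int = DEFAULT_CAP,
    traceback: bool = True,
) -> SectionPairResult:
    """:func:`section_pair_mfe` with the given global positions unpairable."""
    return section_pair_mfe(
        seq, sec1, sec2, params, mask=mask, cap=cap, traceback=traceback)


def traceback_cooptimal(
    cm: CMatrix,
    params: NNParameterSet,
    cap: int = DEFAULT_CAP,
    tol: float = COOPT_TOL,
) -> list[DuplexStructure]:
    """All distinct duplexes achieving the MFE within ``tol``, up to ``cap``,
    in deterministic (lexicographic) order.  MFE = 0 yields no structures."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    C = cm.entries
    if C.size == 0:
        return []
    mfe = float(min(0.0, C.min()))
    if mfe >= -tol:
        return []
    l1, l2 = C.shape
    pt = cm.ptypes
    stack = params.stacking
    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def expand(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        key = (i, j)
        if key in memo:
            return memo[key]
        val = C[i, j]
        out: list[tuple[tuple[int, int], ...]] = []
        if abs(val) <= tol:
            out.append(((i, j),))
        cur = pt[i][j]

        def follow(x: int, y: int, term: float) -> None:
            if len(out) >= cap:
                return
            if np.isfinite(C[x, y]) and abs(C[x, y] + term - val) <= tol:
                for rest in expand(x, y):
                    out.append(((i, j),) + rest)
                    if len(out) >= cap:
                        return

        if i < l1 - 1 and j > 0 and pt[i + 1][j - 1].pairable:
            follow(i + 1, j - 1, stack[(cur, pt[i + 1][j - 1])])
        if i < l1 - 1:
            for d in range(2, j + 1):
                if pt[i + 1][j - d].pairable:
                    follow(i + 1, j - d,
                           bulge_energy(params, d - 1, cur, pt[i + 1][j - d]))
        if j > 0:
            for d in range(2, l1 - 1 - i + 1):
                if pt[i + d][j - 1].pairable:
                    follow(i + d, j - 1,
                           bulge_energy(params, d - 1, cur, pt[i + d][j - 1]))
        for d1 in range(2, l1 - 1 - i + 1):
            for d2 in range(2, j + 1):
                inner = pt[i + d1][j - d2]
                if inner.pairable:
                    term = interior_energy(
                        params, d1 - 1, d2 - 1, cur, inner,
                        cm.bases1[i + 1] + cm.bases2[j - 1],
                        cm.bases1[i + d1 - 1] + cm.bases2[j - d2 + 1],
                    )
                    follow(i + d1, j - d2, term)
        memo[key] = sorted(set(out))[:cap]
        return memo[key]

    seeds = sorted(map(tuple, np.argwhere(np.abs(C - mfe) <= tol)))
    all_structs: set[tuple[tuple[int, int], ...]] = set()
    for i, j in seeds:
        all_structs.update(expand(int(i), int(j)))
    ordered = sorted(all_structs)[:cap]
    return [DuplexStructure(pairs, mfe) for pairs in ordered]


def duplex_energy(
    seq: str,
    sec1: Section,
    sec2: Section,
    params: NNParameterSet,
    pairs: Sequence[tuple[int, int]],
) -> float:
    """Re-score a duplex by summing the loop terms between consecutive pairs
    (the innermost pair contributes 0); empty structures score 0."""
    if not pairs:
        return 0.0
    b1 = seq[sec1.start:sec1.end]
    b2 = seq[sec2.start:sec2.end]
    total = 0.0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        outer = pair_type(b1[i1], b2[j1])
        inner = pair_type(b1[i2], b2[j2])
        d1, d2 = i2 - i1, j1 - j2
        if d1 < 1 or d2 < 1:
            raise ValueError("pairs must advance antiparallel")
        if d1 == 1 and d2 == 1:
            total += stacking_energy(params, outer, inner)
        elif d1 == 1:
            total += bulge_energy(params, d2 - 1, outer, inner)
        elif d2 == 1:
            total += bulge_energy(params, d1 - 1, outer, inner)
        else:
            total += interior_energy(
                params, d1 - 1, d2 - 1, outer, inner,
                b1[i1 + 1] + b2[j1 - 1], b1[i2 - 1] + b2[j2 + 1])
    return total
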