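"""Deterministic synthetic structures, gain samplers, and brute-force oracles.

The generator emulates the features the section-pair machinery consumes: a
nested scaffold of hairpins separated by exterior linkers, with pseudoknot
helices implanted as reverse-complementary stretches between sections of
different loops (hairpin-loop <-> linker for 2-clusters; hairpin-loop,
linker, next hairpin-loop for type-1 3-clusters).  Implants at "perfect"
complementarity are re-verified at build time: the section-pair DP must have
a unique MFE structure equal to the implant, so downstream TPR = PPV = 1 is a
meaningful check rather than an accident.  "noisy" implants carry an injected
mismatch; "decoy" implants add the complementary stretch without marking the
pair connected, emulating high-gain section pairs that do not actually form.

Everything is a pure function of its seed.

The gain sampler draws MFE gains from the independent-pairing model: the
number of base pairs in a duplex is geometric with continuation probability
p0 and each pair contributes ~1.0 kcal/mol, so frequency(gain) decays as
p0^gain and a log-linear fit recovers p0.

The exhaustive oracles enumerate every antiparallel non-crossing set of
canonical pairs between two (or three) small sections and score it by the
same loop-term definitions the recursion optimizes, providing an independent
check of the DP and of the joint 3-cluster search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .duplex import section_pair_mfe
from .structures import (
    BasePair,
    PseudoknottedStructure,
    Section,
    identify_sections,
    write_dotbracket,
)
from .thermo import (
    NNParameterSet,
    bulge_energy,
    interior_energy,
    pair_type,
    stacking_energy,
)

__all__ = [
    "Implant",
    "FixtureSpec",
    "GainSampleSpec",
    "Fixture",
    "GenerationError",
    "generate_structure",
    "generate_corpus",
    "sample_gains",
    "oracle_duplex_mfe",
    "oracle_triplex_mfe",
    "write_fixture",
]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


class GenerationError(RuntimeError):
    """Requested fixture cannot be built (e.g. sections too short)."""


@dataclass(frozen=True)
class Implant:
    kind: str  # 2cluster | type1-3cluster | decoy
    helix_len: int = 6
    level: str = "perfect"  # perfect | noisy


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_hairpins: int = 2
    stem_len: tuple[int, int] = (4, 8)
    section_mean: float = 6.0
    section_max: int = 30
    implants: tuple[Implant, ...] = (Implant("2cluster", 6, "perfect"),)
    max_attempts: int = 50


@dataclass(frozen=True)
class GainSampleSpec:
    seed: int
    n: int = 100_000
    p0: float = 39 / 64
    per_pair_energy: float = 1.0

    def __post_init__(self):
        if not 0 < self.p0 < 1:
            raise ValueError("continuation probability p0 must be in (0, 1)")


@dataclass(frozen=True)
class ImplantRecord:
    kind: str
    level: str
    section_indices: tuple[int, ...]
    pairs: tuple[BasePair, ...]  # global coordinates; empty for decoys


@dataclass
class Fixture:
    spec: FixtureSpec
    structure: PseudoknottedStructure
    sections: list[Section]
    implants: list[ImplantRecord]

    @property
    def truth_pairs(self) -> frozenset[BasePair]:
        return self.structure.pseudoknot_pairs


def _draw_len(rng: np.random.Generator, mean: float, cap: int, floor: int) -> int:
    n = int(rng.geometric(1.0 / mean))
    return max(floor, min(n, cap))


def _rand_bases(rng: np.random.Generator, n: int, gc_bias: float = 0.0) -> str:
    p_gc = 0.25 + gc_bias / 2
    p_au = 0.25 - gc_bias / 2
    return "".join(rng.choice(list("ACGU"), size=n, p=[p_au, p_gc, p_gc, p_au]))


def _helix_pairs(a_start: int, b_start: int, h: int) -> list[BasePair]:
    # base t of the 5' block pairs base h-1-t of the 3' block (antiparallel)
    return [BasePair(a_start + t, b_start + h - 1 - t) for t in range(h)]


def _build_candidate(spec: FixtureSpec, rng: np.random.Generator) -> Fixture:
    # allocate implants to hairpins: a 3-cluster spans two consecutive hairpins
    slots: list[tuple[Implant, int]] = []
    hp = 0
    for imp in spec.implants:
        if imp.helix_len < 2:
            raise GenerationError("implant helix must be >= 2 bp")
        slots.append((imp, hp))
        hp += 2 if imp.kind == "type1-3cluster" else 1
    n_hairpins = max(spec.n_hairpins, hp)

    loop_need = [3] * n_hairpins   # hairpin-loop section lengths (min 3)
    link_need = [1] * (n_hairpins + 1)  # tail5, linkers..., tail3
    for imp, h in slots:
        if imp.kind in ("2cluster", "decoy"):
            loop_need[h] = max(loop_need[h], imp.helix_len + 2)
            link_need[h + 1] = max(link_need[h + 1], imp.helix_len + 2)
        else:
            loop_need[h] = max(loop_need[h], imp.helix_len + 2)
            loop_need[h + 1] = max(loop_need[h + 1], imp.helix_len + 2)
            link_need[h + 1] = max(link_need[h + 1], 2 * imp.helix_len + 1)
    if max(loop_need + link_need) > spec.section_max:
        raise GenerationError(
            f"sections too short: implant needs {max(loop_need + link_need)} nt, "
            f"section_max is {spec.section_max}")

    loop_len = [max(n, _draw_len(rng, spec.section_mean, spec.section_max, 3))
                for n in loop_need]
    link_len = [max(n, _draw_len(rng, spec.section_mean, spec.section_max, 1))
                for n in link_need]
    stems = [int(rng.integers(spec.stem_len[0], spec.stem_len[1] + 1))
             for _ in range(n_hairpins)]

    seq: list[str] = []
    secondary: list[BasePair] = []
    loop_span: list[tuple[int, int]] = []
    link_span: list[tuple[int, int]] = []

    def emit(n: int) -> tuple[int, int]:
        start = len(seq)
        seq.extend(_rand_bases(rng, n))
        return (start, len(seq))

    link_span.append(emit(link_len[0]))
    for h in range(n_hairpins):
        s = stems[h]
        left = _rand_bases(rng, s, gc_bias=0.3)
        start = len(seq)
        seq.extend(left)
        loop_span.append(emit(loop_len[h]))
        close = len(seq)
        seq.extend(_COMPLEMENT[b] for b in reversed(left))
        secondary.extend(BasePair(start + t, close + s - 1 - t) for t in range(s))
        link_span.append(emit(link_len[h + 1]))

    def implant_helix(a_span: tuple[int, int], b_span: tuple[int, int],
                      h: int, level: str) -> list[BasePair]:
        a0, a1 = a_span
        b0, b1 = b_span
        a_start = a0 + int(rng.integers(0, a1 - a0 - h + 1))
        b_start = b0 + int(rng.integers(0, b1 - b0 - h + 1))
        helix = _rand_bases(rng, h, gc_bias=0.4)
        for t in range(h):
            seq[a_start + t] = helix[t]
            seq[b_start + h - 1 - t] = _COMPLEMENT[helix[t]]
        if level == "noisy" and h >= 3:
            t = int(rng.integers(1, h - 1))
            bad = [b for b in "ACGU"
                   if not pair_type(seq[a_start + t], b).pairable]
            seq[b_start + h - 1 - t] = str(rng.choice(bad))
        return _helix_pairs(a_start, b_start, h)

    pk_pairs: list[BasePair] = []
    raw_records: list[tuple[Implant, list[BasePair]]] = []
    for imp, h in slots:
        if imp.kind in ("2cluster", "decoy"):
            pairs = implant_helix(loop_span[h], link_span[h + 1], imp.helix_len, imp.level)
        else:
            lk = link_span[h + 1]
            mid = (lk[0] + lk[1]) // 2
            former = implant_helix(loop_span[h], (lk[0], mid), imp.helix_len, imp.level)
            latter = implant_helix((mid, lk[1]), loop_span[h + 1], imp.helix_len, imp.level)
            pairs = former + latter
        raw_records.append((imp, pairs))
        if imp.kind != "decoy":
            pk_pairs.extend(pairs)

    structure = PseudoknottedStructure(
        "".join(seq), frozenset(secondary), frozenset(pk_pairs))
    sections = identify_sections(structure)
    owner = {pos: s.index for s in sections for pos in s.positions}
    records = [
        ImplantRecord(
            imp.kind, imp.level,
            tuple(sorted({owner[p] for bp in pairs for p in bp})),
            tuple(sorted(pairs)) if imp.kind != "decoy" else (),
        )
        for (imp, pairs) in raw_records
    ]
    return Fixture(spec, structure, sections, records)


def _verify_perfect(fix: Fixture, params: NNParameterSet) -> bool:
    """Perfect 2-cluster implants must be the unique DP optimum."""
    by_index = {s.index: s for s in fix.sections}
    for rec in fix.implants:
        if rec.kind != "2cluster" or rec.level != "perfect":
            continue
        a, b = rec.section_indices[0], rec.section_indices[-1]
        s1, s2 = by_index[a], by_index[b]
        res = section_pair_mfe(fix.structure.sequence, s1, s2, params)
        if len(res.structures) != 1:
            return False
        got = set(res.structures[0].global_pairs(s1, s2))
        if got != set(rec.pairs):
            return False
    return True


def generate_structure(spec: FixtureSpec, params: NNParameterSet | None = None) -> Fixture:
    """Build a fixture; deterministic in ``spec.seed``.

    When ``params`` is given, candidates are regenerated until every perfect
    2-cluster implant is the unique MFE structure of its section pair
    (raising :class:`GenerationError` after ``max_attempts`` failures).
    """
    rng = np.random.default_rng(spec.seed)
    last = None
    for _ in range(spec.max_attempts):
        fix = _build_candidate(spec, rng)
        if params is None or _verify_perfect(fix, params):
            return fix
        last = fix
    raise GenerationError(
        f"no candidate with unique implant optima in {spec.max_attempts} attempts "
        f"(seed {spec.seed})") from None


def generate_corpus(
    spec: FixtureSpec, n: int, params: NNParameterSet | None = None
) -> list[Fixture]:
    """n independent fixtures with per-molecule seeds spec.seed + i."""
    return [generate_structure(replace(spec, seed=spec.seed + i), params)
            for i in range(n)]


def sample_gains(spec: GainSampleSpec) -> np.ndarray:
    """MFE gains under the independent-pairing model: (geometric number of
    consecutive pairing successes at continuation probability p0) x energy."""
    rng = np.random.default_rng(spec.seed)
    n_pairs = rng.geometric(1.0 - spec.p0, size=spec.n) - 1
    return n_pairs * spec.per_pair_energy


def write_fixture(fix: Fixture, name: str = "fixture") -> tuple[str, str]:
    """Serialize a fixture as (dot-bracket text, ground-truth TSV sidecar)."""
    db = write_dotbracket(fix.structure, header=f">{name} seed={fix.spec.seed}")
    lines = [f"# seed={fix.spec.seed}", "kind\tlevel\tsections\tpairs"]
    for rec in fix.implants:
        pair_txt = ",".join(f"{p.pos5}-{p.pos3}" for p in rec.pairs)
        sec_txt = ",".join(map(str, rec.section_indices))
        lines.append(f"{rec.kind}\t{rec.level}\t{sec_txt}\t{pair_txt}")
    return db, "\n".join(lines) + "\n"


# --- exhaustive oracles --------------------------------------------------

ORACLE_MAX_LEN = 10


def _enumerate_matchings(allowed: list[list[bool]]) -> Iterator[tuple[tuple[int, int], ...]]:
    """Every antiparallel non-crossing pairing: i strictly increasing,
    j strictly decreasing, including the empty pairing."""
    l1 = len(allowed)

    def rec(i_min: int, j_max: int) -> Iterator[tuple[tuple[int, int], ...]]:
        yield ()
        for i in range(i_min, l1):
            for j in range(j_max + 1):
                if allowed[i][j]:
                    for rest in rec(i + 1, j - 1):
                        yield ((i, j),) + rest

    l2 = len(allowed[0]) if l1 else 0
    return rec(0, l2 - 1)


def _oracle_score(
    pairs: Sequence[tuple[int, int]], b1: str, b2: str, params: NNParameterSet
) -> float:
    """Definitional score: loop term between each consecutive pair of the
    duplex, innermost pair free."""
    e = 0.0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        outer = pair_type(b1[i1], b2[j1])
        inner = pair_type(b1[i2], b2[j2])
        d1, d2 = i2 - i1, j1 - j2
        if d1 == 1 and d2 == 1:
            e += stacking_energy(params, outer, inner)
        elif d1 == 1:
            e += bulge_energy(params, d2 - 1, outer, inner)
        elif d2 == 1:
            e += bulge_energy(params, d1 - 1, outer, inner)
        else:
            e += interior_energy(params, d1 - 1, d2 - 1, outer, inner,
                                 b1[i1 + 1] + b2[j1 - 1], b1[i2 - 1] + b2[j2 + 1])
    return e


@dataclass
class OracleResult:
    mfe: float
    structures: list[tuple[tuple[int, int], ...]]  # all non-empty argmin pairings


def oracle_duplex_mfe(
    seq: str,
    sec1: Section,
    sec2: Section,
    params: NNParameterSet,
    mask: Sequence[int] = (),
    tol: float = 1e-9,
) -> OracleResult:
    """Exhaustive-enumeration MFE over all antiparallel non-crossing canonical
    pairings of two small sections (guarded to lengths <= 10)."""
    if len(sec1) > ORACLE_MAX_LEN or len(sec2) > ORACLE_MAX_LEN:
        raise ValueError(f"oracle refuses sections longer than {ORACLE_MAX_LEN} nt")
    mask = frozenset(mask)
    b1 = seq[sec1.start:sec1.end]
    b2 = seq[sec2.start:sec2.end]
    allowed = [
        [
            pair_type(b1[i], b2[j]).pairable
            and sec1.start + i not in mask
            and sec2.start + j not in mask
            for j in range(len(b2))
        ]
        for i in range(len(b1))
    ]
    mfe = 0.0
    scored: list[tuple[float, tuple[tuple[int, int], ...]]] = []
    for pairs in _enumerate_matchings(allowed):
        if not pairs:
            continue
        e = _oracle_score(pairs, b1, b2, params)
        scored.append((e, pairs))
        mfe = min(mfe, e)
    structures = sorted(p for e, p in scored if abs(e - mfe) <= tol)
    return OracleResult(mfe, structures)


def oracle_triplex_mfe(
    seq: str,
    s1: Section,
    s2: Section,
    s3: Section,
    params: NNParameterSet,
    w: float,
    tol: float = 1e-9,
) -> tuple[float, list[tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]]]:
    """Brute-force joint minimum of E(former) + w*E(latter) over all pairs of
    compatible duplexes (no section2 base reused).  Sections must be small."""
    if max(len(s1), len(s2), len(s3)) > 6:
        raise ValueError("joint oracle refuses sections longer than 6 nt")
    b1 = seq[s1.start:s1.end]
    b2 = seq[s2.start:s2.end]
    b3 = seq[s3.start:s3.end]

    def options(ba: str, bb: str) -> list[tuple[float, tuple[tuple[int, int], ...]]]:
        allowed = [[pair_type(x, y).pairable for y in bb] for x in ba]
        out = []
        for pairs in _enumerate_matchings(allowed):
            e = _oracle_score(pairs, ba, bb, params) if pairs else 0.0
            if e <= 0.0 + tol:  # positive-energy duplexes never beat staying apart
                out.append((e, pairs))
        return out

    formers = options(b1, b2)   # (i in s1, j in s2)
    latters = options(b2, b3)   # (i in s2, j in s3)
    best = None
    argmins: list[tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]] = []
    for ef, fp in formers:
        fused = {j for _, j in fp}
        for el, lp in latters:
            if fused & {i for i, _ in lp}:
                continue
            obj = ef + w * el
            if best is None or obj < best - tol:
                best = obj
                argmins = [(fp, lp)]
            elif abs(obj - best) <= tol:
                argmins.append((fp, lp))
    return best, sorted(argmins)
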