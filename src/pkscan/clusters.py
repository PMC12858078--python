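"""Section graphs, pseudoknot clusters, and 2-/3-cluster structure prediction.

Two sections are *connected* when at least one pseudoknot base pair joins a
base in each; the connected components of that relation are *N-clusters*.
2-clusters (pseudoknot order 1, e.g. H/K-type) are predicted directly from
the section-pair MFE structure.  For 3-clusters (order 2) the sections are
ordered 5'→3' as s1, s2, s3; in the type-1 (chain) topology the s1–s2 duplex
is the *former* pair and s2–s3 the *latter*, and the prediction minimizes

    E(former) + w * E(latter),      0 < w <= 1

subject to no base of s2 serving both duplexes.  w = 1 is the equal-weighting
strategy; "sequential" instead fixes the former duplex at its own MFE and
then optimizes the latter over the remaining s2 bases, mimicking
co-transcriptional (5'-first) folding.  The default w = 0.8 favours the
former pair, which forms earlier during transcription.

The weighted search enumerates split points of s2: each candidate assigns a
contiguous prefix of s2 to one duplex and the suffix to the other (both
assignments tried), running the masked DP on each side.  Because loop
penalties make interleaved allocations energetically dominated, this matches
exhaustive joint enumeration on small instances (checked against the
brute-force oracle in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .duplex import (
    DEFAULT_CAP,
    DuplexStructure,
    SectionPairResult,
    section_pair_mfe,
    section_pair_mfe_masked,
)
from .structures import BasePair, PseudoknottedStructure, Section, identify_sections
from .thermo import NNParameterSet

__all__ = [
    "SectionGraph",
    "Cluster",
    "TriplexPrediction",
    "UnsupportedTopologyError",
    "build_section_graph",
    "find_clusters",
    "order_former_latter",
    "predict_2cluster",
    "predict_3cluster",
]


class UnsupportedTopologyError(ValueError):
    """Requested prediction is not defined for this cluster topology."""


@dataclass(frozen=True)
class SectionGraph:
    sections: tuple[Section, ...]
    edges: frozenset[tuple[int, int]]  # (section index, section index), i < j


@dataclass(frozen=True)
class Cluster:
    """Connected component of sections under pseudoknot edges."""

    sections: tuple[Section, ...]  # ordered by 5' start
    edges: frozenset[tuple[int, int]]
    topology: str  # 2cluster | type1 | type2 | other | unsupported

    @property
    def size(self) -> int:
        return len(self.sections)

    @property
    def order(self) -> int:
        """Pseudoknot order: decompositions needed to reach a nested set
        (1 for 2-clusters, 2 for 3-clusters)."""
        return self.size - 1


@dataclass
class TriplexPrediction:
    former: DuplexStructure
    latter: DuplexStructure
    former_pairs: list[BasePair]  # global coordinates
    latter_pairs: list[BasePair]
    w: float
    objective: float  # E(former) + w * E(latter)
    strategy: str

    def __post_init__(self):
        f2 = {p.pos3 for p in self.former_pairs}
        l2 = {p.pos5 for p in self.latter_pairs}
        if f2 & l2:
            raise ValueError(f"section2 bases reused across former/latter: {f2 & l2}")


def build_section_graph(
    structure: PseudoknottedStructure, sections: Iterable[Section] | None = None
) -> SectionGraph:
    """One edge per section pair joined by >= 1 reference pseudoknot pair."""
    sections = tuple(sections if sections is not None else identify_sections(structure))
    owner: dict[int, int] = {}
    for s in sections:
        for pos in s.positions:
            owner[pos] = s.index
    edges = set()
    for p in structure.pseudoknot_pairs:
        if p.pos5 not in owner or p.pos3 not in owner:
            raise ValueError(
                f"pseudoknot pair {p} has an endpoint outside every section")
        a, b = owner[p.pos5], owner[p.pos3]
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return SectionGraph(sections, frozenset(edges))


def _classify3(ranks: dict[int, int], edges: set[tuple[int, int]]) -> str:
    e = {tuple(sorted((ranks[a], ranks[b]))) for a, b in edges}
    if e == {(0, 1), (1, 2)}:
        return "type1"  # chain through the middle section
    if len(e) == 2:
        return "type2"
    return "other"


def find_clusters(graph: SectionGraph) -> list[Cluster]:
    """Connected components with >= 2 sections, topology-labelled."""
    g = nx.Graph()
    g.add_edges_from(graph.edges)
    by_index = {s.index: s for s in graph.sections}
    clusters = []
    for comp in nx.connected_components(g):
        members = tuple(sorted((by_index[i] for i in comp), key=lambda s: s.start))
        edges = {e for e in graph.edges if e[0] in comp and e[1] in comp}
        if len(members) == 2:
            topology = "2cluster"
        elif len(members) == 3:
            ranks = {s.index: r for r, s in enumerate(members)}
            topology = _classify3(ranks, edges)
        else:
            topology = "unsupported"
        clusters.append(Cluster(members, frozenset(edges), topology))
    clusters.sort(key=lambda c: c.sections[0].start)
    return clusters


def order_former_latter(cluster: Cluster) -> tuple[tuple[Section, Section], tuple[Section, Section]]:
    """5'→3' former/latter split of a type-1 3-cluster."""
    if cluster.topology != "type1":
        raise UnsupportedTopologyError(
            f"former/latter split requires a type-1 3-cluster, got {cluster.topology}")
    s1, s2, s3 = cluster.sections
    return (s1, s2), (s2, s3)


def predict_2cluster(
    seq: str,
    sec1: Section,
    sec2: Section,
    params: NNParameterSet,
    *,
    cap: int = DEFAULT_CAP,
) -> SectionPairResult:
    """MFE duplex prediction for a section pair (the 2-cluster rule)."""
    return section_pair_mfe(seq, sec1, sec2, params, cap=cap)


def _first_structure(result: SectionPairResult) -> DuplexStructure:
    if result.structures:
        return result.structures[0]
    return DuplexStructure((), 0.0)


def predict_3cluster(
    seq: str,
    cluster: Cluster,
    params: NNParameterSet,
    *,
    w: float = 0.8,
    strategy: str = "weighted",
    cap: int = DEFAULT_CAP,
) -> TriplexPrediction:
    """Joint former/latter duplex prediction for a type-1 3-cluster.

    Strategies: "weighted" minimizes E(former) + w*E(latter); "equal" is
    weighted with w = 1; "sequential" fixes the former duplex at its own MFE
    first, then fills the latter from the unused section2 bases.
    """
    if not 0 < w <= 1:
        raise ValueError("weight w must satisfy 0 < w <= 1")
    (s1, s2), (_, s3) = order_former_latter(cluster)

    if strategy == "equal":
        w = 1.0
        strategy_used = "equal"
        mode = "weighted"
    elif strategy in ("weighted", "sequential"):
        strategy_used = strategy
        mode = strategy
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    if mode == "sequential":
        former_res = section_pair_mfe(seq, s1, s2, params, cap=cap)
        former = _first_structure(former_res)
        used = {s2.start + j for _, j in former.pairs}
        latter_res = section_pair_mfe_masked(seq, s2, s3, params, used, cap=cap)
        latter = _first_structure(latter_res)
        obj = former.energy + w * latter.energy
        return TriplexPrediction(
            former, latter,
            former.global_pairs(s1, s2), latter.global_pairs(s2, s3),
            w, obj, strategy_used)

    # weighted: enumerate contiguous splits of section2, both side-assignments
    l2 = len(s2)
    best: tuple[float, int, int] | None = None
    best_pair: tuple[DuplexStructure, DuplexStructure] | None = None
    for assignment in (0, 1):  # 0: former gets the prefix, 1: former gets the suffix
        for k in range(l2 + 1):
            prefix = set(range(s2.start, s2.start + k))
            suffix = set(range(s2.start + k, s2.end))
            former_mask, latter_mask = (suffix, prefix) if assignment == 0 else (prefix, suffix)
            fr = section_pair_mfe_masked(seq, s1, s2, params, former_mask, cap=cap)
            lr = section_pair_mfe_masked(seq, s2, s3, params, latter_mask, cap=cap)
            obj = fr.mfe + w * lr.mfe
            key = (obj, assignment, k)
            if best is None or key < best:
                best = key
                best_pair = (_first_structure(fr), _first_structure(lr))
    former, latter = best_pair
    return TriplexPrediction(
        former, latter,
        former.global_pairs(s1, s2), latter.global_pairs(s2, s3),
        w, best[0], strategy_used)
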