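"""Penalty-ordered graph-expanding search for primer set combinations (PSCs).

The candidate PSs form a graph: one node per PS (grouped by template, each
carrying its design penalty) and an edge wherever the scoring matrix marks two
PSs compatible.  A PSC is a clique holding exactly one PS per template whose
amplicons additionally keep a minimum electrophoretic band spacing (MinBS) on
the configured gel.  Finding such cliques is NP-complete in general, so the
search is greedy with backtracking: templates are expanded most-constrained
first, and within a template candidates are tried in ascending penalty, so the
first solution found is the locally optimal greedy PSC.  The search then keeps
running past the first solution (bounded by a node-admission budget), collects
further complete cliques, and reports the best ``k`` by total penalty.  There
is no randomness anywhere; ties break lexicographically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .design import PrimerSet
from .gel import GelModel, min_band_spacing
from .interaction import CompatibilityMatrix

__all__ = [
    "CompatibilityGraph",
    "PSC",
    "SearchFailure",
    "expand_graph",
    "enumerate_top_pscs",
    "validate_psc",
]


class SearchFailure(Exception):
    """No PSC covers all templates; names the first uncoverable template."""

    def __init__(self, template_id: str, message: str = ""):
        self.template_id = template_id
        super().__init__(message or f"no primer set of template {template_id!r} "
                                    f"can join any valid combination")


@dataclass
class CompatibilityGraph:
    """Candidate PSs grouped by template + the compatibility edge relation."""

    ps_by_template: Dict[str, List[PrimerSet]]
    matrix: CompatibilityMatrix

    @classmethod
    def from_matrix(cls, matrix: CompatibilityMatrix) -> "CompatibilityGraph":
        groups: Dict[str, List[PrimerSet]] = {}
        for ps in matrix.ps_list:
            groups.setdefault(ps.template_id, []).append(ps)
        for tid in groups:
            groups[tid].sort(key=lambda ps: (ps.penalty, ps.rank))
        return cls(groups, matrix)

    @property
    def templates(self) -> List[str]:
        return list(self.ps_by_template)

    def expansion_order(self) -> List[str]:
        """Most-constrained template first (fewest candidates), then input order."""
        tids = list(self.ps_by_template)
        return sorted(tids, key=lambda t: (len(self.ps_by_template[t]), tids.index(t)))

    def connected(self, a: PrimerSet, b: PrimerSet) -> bool:
        return self.matrix.compatible(a, b)


@dataclass(frozen=True)
class PSC:
    """A primer set combination: one mutually compatible PS per template."""

    members: Tuple[PrimerSet, ...]
    total_penalty: float
    min_band_spacing: float

    @property
    def covered_templates(self) -> Tuple[str, ...]:
        return tuple(ps.template_id for ps in self.members)

    @property
    def amplicon_sizes(self) -> Tuple[int, ...]:
        return tuple(ps.amplicon_size for ps in self.members)

    def member_key(self) -> Tuple[str, ...]:
        return tuple(sorted(ps.id() for ps in self.members))


def _make_psc(members: Sequence[PrimerSet], gel: GelModel) -> PSC:
    ordered = tuple(sorted(members, key=lambda ps: ps.template_id))
    return PSC(
        members=ordered,
        total_penalty=sum(ps.penalty for ps in ordered),
        min_band_spacing=min_band_spacing([ps.amplicon_size for ps in ordered], gel),
    )


def _search(
    graph: CompatibilityGraph,
    minbs: float,
    gel: GelModel,
    node_budget: int,
    collect_limit: int,
) -> Tuple[List[Tuple[PrimerSet, ...]], int]:
    """Backtracking clique enumeration in greedy (penalty-ascending) order.

    Returns (solutions in discovery order, deepest level reached).  Stops once
    the admission budget or the collection limit is exhausted.
    """
    order = graph.expansion_order()
    for tid in order:
        if not graph.ps_by_template[tid]:
            raise SearchFailure(tid, f"template {tid!r} has zero candidate primer sets")
    pos_cache: Dict[int, float] = {}

    def pos(size: int) -> float:
        if size not in pos_cache:
            pos_cache[size] = gel.predict(size)
        return pos_cache[size]

    solutions: List[Tuple[PrimerSet, ...]] = []
    admissions = 0
    deepest = 0
    members: List[PrimerSet] = []

    def dfs(level: int) -> bool:
        """Returns True when the search should stop entirely."""
        nonlocal admissions, deepest
        deepest = max(deepest, level)
        if level == len(order):
            solutions.append(tuple(members))
            return len(solutions) >= collect_limit
        for cand in graph.ps_by_template[order[level]]:
            if not all(graph.connected(cand, m) for m in members):
                continue
            p_new = pos(cand.amplicon_size)
            if any(abs(p_new - pos(m.amplicon_size)) < minbs for m in members):
                continue
            admissions += 1
            members.append(cand)
            stop = dfs(level + 1)
            members.pop()
            if stop or admissions >= node_budget:
                return True
        return False

    dfs(0)
    return solutions, deepest


def expand_graph(
    graph: CompatibilityGraph,
    minbs: float = 3.0,
    gel: Optional[GelModel] = None,
    node_budget: int = 100_000,
) -> PSC:
    """Greedy clique expansion: the first full-coverage PSC in greedy order.

    Grows the clique one template at a time, always trying the lowest-penalty
    untried candidate; a node is admitted only if it is connected to every
    current member and keeps MinBS satisfied; dead ends backtrack to the
    next-lowest-penalty alternative.  Raises :class:`SearchFailure` naming the
    first uncoverable template when no PSC exists within the budget.
    """
    gel = gel or GelModel.default()
    solutions, deepest = _search(graph, minbs, gel, node_budget, collect_limit=1)
    if not solutions:
        order = graph.expansion_order()
        raise SearchFailure(order[min(deepest, len(order) - 1)])
    return _make_psc(solutions[0], gel)


def enumerate_top_pscs(
    graph: CompatibilityGraph,
    minbs: float = 3.0,
    gel: Optional[GelModel] = None,
    k: int = 15,
    node_budget: int = 100_000,
) -> List[PSC]:
    """Up to ``k`` distinct valid PSCs, ascending total penalty.

    Continues the backtracking search past the first solution, deduplicates by
    member-set identity, and sorts by (total penalty, member ranks, amplicon
    sizes).  Because candidates are pre-selected per template, the result is
    locally, not globally, optimal.
    """
    gel = gel or GelModel.default()
    collect_limit = max(200, 20 * k)
    solutions, _ = _search(graph, minbs, gel, node_budget, collect_limit)
    seen = set()
    pscs: List[PSC] = []
    for sol in solutions:
        psc = _make_psc(sol, gel)
        key = psc.member_key()
        if key in seen:
            continue
        seen.add(key)
        pscs.append(psc)
    pscs.sort(key=lambda p: (
        p.total_penalty,
        tuple(ps.rank for ps in p.members),
        p.amplicon_sizes,
    ))
    return pscs[:k]


def validate_psc(
    psc: PSC,
    matrix: CompatibilityMatrix,
    minbs: float = 3.0,
    gel: Optional[GelModel] = None,
) -> Tuple[bool, List[str]]:
    """Independent re-check of a PSC: clique, one PS per template, MinBS.

    Returns (ok, reasons); reasons enumerate every violated pair or spacing.
    """
    gel = gel or GelModel.default()
    reasons: List[str] = []
    tids = [ps.template_id for ps in psc.members]
    if len(set(tids)) != len(tids):
        dupes = sorted({t for t in tids if tids.count(t) > 1})
        reasons.append(f"duplicate templates: {','.join(dupes)}")
    for i in range(len(psc.members)):
        for j in range(i + 1, len(psc.members)):
            a, b = psc.members[i], psc.members[j]
            if a.template_id != b.template_id and not matrix.compatible(a, b):
                reasons.append(f"incompatible pair: {a.id()} x {b.id()} "
                               f"({matrix.reason(matrix.index_of(a), matrix.index_of(b))})")
    spacing = min_band_spacing([ps.amplicon_size for ps in psc.members], gel)
    if spacing < minbs:
        reasons.append(f"MinBS violated: {spacing:.2f} mm < {minbs:.2f} mm")
    return (not reasons, reasons)
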