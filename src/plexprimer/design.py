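"""Candidate primer-set generation per template.

For every template the designer enumerates every (start, length, strand)
window inside the allowed region, filters on the default multiplex design
constraints — melting temperature 57-63 degC, size 18-27 bp, GC 45-55%,
3'-pentamer stability magnitude <= 9.0 kcal/mol, self-complementarity <= 8.0
and 3' self-complementarity <= 3.0 — pairs surviving forward/reverse primers
under the product-size (100-500 bp) and Tm-difference (< 3 degC) constraints,
and returns the ``candidates_per_template`` (default five) lowest-penalty
primer sets, ordered ascending by penalty.  The penalty is a weighted sum of
deviations from the constraint optima, so a smaller penalty means a better
primer set; weights ship as an overridable :class:`PenaltyWeights`.

Enumeration is exhaustive over windows (no heuristics), so on small templates
the output is checkable against a brute-force scan.  A fast vectorised
prescreen (prefix-sum GC and Tm with a safety margin) trims the window set;
every emitted primer's properties are recomputed with the scalar
:mod:`plexprimer.thermo` routines, which are authoritative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import thermo
from .thermo import NNParameterTable, ReactionConditions, validate_dna, revcomp

__all__ = [
    "DesignConstraints",
    "PenaltyWeights",
    "Primer",
    "PrimerSet",
    "gc_content",
    "self_complementarity",
    "enumerate_candidates",
    "primer_penalty",
    "pair_penalty",
    "design_primer_sets",
]

logger = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PenaltyWeights:
    """Per-unit weights of the primer penalty terms (lower penalty = better).

    Units: ``tm`` per degC of Tm deviation from the optimum, ``size`` per bp of
    length deviation, ``gc`` per GC percentage point, ``self_comp`` per
    self-complementarity score unit (applied to both the global and the 3'
    score), ``end_stability`` per kcal/mol of 3'-pentamer dG magnitude
    (0 by default: end stability acts as a hard filter only).
    """

    tm: float = 1.0
    size: float = 1.0
    gc: float = 0.5
    self_comp: float = 0.25
    end_stability: float = 0.0


@dataclass(frozen=True)
class DesignConstraints:
    """Design constraints and optima for multiplex candidate primers.

    Intervals are inclusive.  Optima default to range midpoints (Tm 60 degC,
    size 22 bp, GC 50%); the penalty measures deviation from them.
    """

    tm_range: Tuple[float, float] = (57.0, 63.0)
    size_range: Tuple[int, int] = (18, 27)
    gc_range: Tuple[float, float] = (45.0, 55.0)
    max_end_stability: float = 9.0
    max_self_complementarity: float = 8.0
    max_3prime_self_complementarity: float = 3.0
    max_tm_difference: float = 3.0
    product_size_range: Tuple[int, int] = (100, 500)
    candidates_per_template: int = 5
    max_candidates_per_strand: int = 200
    weights: PenaltyWeights = field(default_factory=PenaltyWeights)

    def __post_init__(self) -> None:
        for name in ("tm_range", "size_range", "gc_range", "product_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {lo} > {hi}")
        if self.candidates_per_template < 1:
            raise ValueError("candidates_per_template must be >= 1")

    @property
    def tm_opt(self) -> float:
        return 0.5 * (self.tm_range[0] + self.tm_range[1])

    @property
    def size_opt(self) -> int:
        return (self.size_range[0] + self.size_range[1]) // 2

    @property
    def gc_opt(self) -> float:
        return 0.5 * (self.gc_range[0] + self.gc_range[1])


@dataclass(frozen=True)
class Primer:
    """An oriented oligo with template coordinates and cached properties.

    ``start`` is the 0-based plus-strand offset of the primer's 5' end: the
    leftmost footprint base for a forward primer, the rightmost for a reverse
    primer (whose sequence is the reverse complement of the footprint).
    """

    sequence: str
    template_id: str
    strand: str  # "+" forward, "-" reverse
    start: int
    tm: float
    gc: float
    end_dg: float
    self_any: float
    self_3p: float
    penalty: float

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def footprint(self) -> Tuple[int, int]:
        """0-based half-open plus-strand interval covered by the primer."""
        if self.strand == "+":
            return (self.start, self.start + self.length)
        return (self.start - self.length + 1, self.start + 1)

    @property
    def three_prime_position(self) -> int:
        """Plus-strand coordinate of the 3'-terminal base."""
        return self.start + self.length - 1 if self.strand == "+" else self.start - self.length + 1

    def id(self) -> str:
        return f"{self.template_id}{self.strand}{self.start}L{self.length}"

    def matches_template(self, template: str) -> bool:
        lo, hi = self.footprint
        sub = template[lo:hi].upper()
        return sub == self.sequence if self.strand == "+" else revcomp(sub) == self.sequence


@dataclass(frozen=True)
class PrimerSet:
    """A forward + reverse primer pair amplifying one template region.

    ``amplicon_size`` is measured 5'-end to 5'-end inclusive; ``rank`` is the
    0-based index within the template's penalty-ordered candidate list.
    """

    forward: Primer
    reverse: Primer
    amplicon_size: int
    penalty: float
    rank: int = -1

    def __post_init__(self) -> None:
        if self.forward.template_id != self.reverse.template_id:
            raise ValueError("forward and reverse primers come from different templates")
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")

    @property
    def template_id(self) -> str:
        return self.forward.template_id

    def id(self) -> str:
        return f"{self.template_id}.r{self.rank}"


def gc_content(seq: str) -> float:
    """GC percentage of an ACGT string: 100 * (#G + #C) / length."""
    seq = validate_dna(seq, min_length=1)
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


def _self_comp_offset_scores(seq: str) -> List[Tuple[int, int]]:
    """(offset, score) of the ungapped self-annealing alignment at every offset.

    Offset k pairs position i of the oligo with position L-1-i+k of the same
    oligo read 3'->5'; each Watson-Crick complementary pair scores +1, each
    mismatch -1, summed over the overlap.
    """
    L = len(seq)
    comp = thermo.COMPLEMENT
    out = []
    for k in range(-(L - 1), L):
        lo = max(0, k)
        hi = min(L - 1, L - 1 + k)
        score = 0
        for i in range(lo, hi + 1):
            score += 1 if comp[seq[i]] == seq[L - 1 - i + k] else -1
        out.append((k, score))
    return out


def self_complementarity(seq: str) -> Tuple[float, float]:
    """(global, 3'-anchored) self-complementarity alignment scores.

    Ungapped alignment of the oligo against itself in annealing orientation,
    +1 per complementary pair and -1 per mismatch, maximised over all offsets
    (floored at 0).  The 3' score restricts the maximum to offsets whose
    overlap includes the 3'-terminal base, so it can never exceed the global
    score.
    """
    seq = validate_dna(seq, min_length=8)
    scores = _self_comp_offset_scores(seq)
    glob = max(s for _, s in scores)
    three = max(s for k, s in scores if k >= 0)
    return (float(max(glob, 0)), float(max(three, 0)))


def primer_penalty(
    tm: float,
    length: int,
    gc: float,
    self_any: float,
    self_3p: float,
    end_dg: float,
    constraints: DesignConstraints,
) -> float:
    """Weighted sum of deviations from the configured optima for one primer."""
    w = constraints.weights
    return (
        w.tm * abs(tm - constraints.tm_opt)
        + w.size * abs(length - constraints.size_opt)
        + w.gc * abs(gc - constraints.gc_opt)
        + w.self_comp * (self_any + self_3p)
        + w.end_stability * abs(end_dg)
    )


def pair_penalty(fwd: Primer, rev: Primer, constraints: DesignConstraints) -> float:
    """Penalty of a primer pair: the sum of both primers' deviation penalties.

    Pairs whose Tm difference exceeds the cap are rejected outright rather
    than scored.
    """
    if abs(fwd.tm - rev.tm) > constraints.max_tm_difference:
        raise ValueError(
            f"Tm difference {abs(fwd.tm - rev.tm):.2f} degC exceeds cap "
            f"{constraints.max_tm_difference} degC; pair rejected"
        )
    return fwd.penalty + rev.penalty


def _passes_filters(
    tm: float, length: int, gc: float, self_any: float, self_3p: float, end_dg: float,
    c: DesignConstraints,
) -> bool:
    return (
        c.size_range[0] <= length <= c.size_range[1]
        and c.tm_range[0] <= tm <= c.tm_range[1]
        and c.gc_range[0] <= gc <= c.gc_range[1]
        and abs(end_dg) <= c.max_end_stability
        and self_any <= c.max_self_complementarity
        and self_3p <= c.max_3prime_self_complementarity
    )


def enumerate_candidates(
    template: str,
    template_id: str = "T",
    region: Optional[Tuple[int, int]] = None,
    constraints: Optional[DesignConstraints] = None,
    cond: Optional[ReactionConditions] = None,
    table: Optional[NNParameterTable] = None,
) -> List[Primer]:
    """All primers on both strands passing every individual filter.

    ``region`` is a 0-based half-open plus-strand interval the whole primer
    footprint must lie in (default: the whole template).  Windows containing
    non-ACGT template bases are skipped.  Output order is deterministic:
    by strand (+ then -), then footprint start, then length.
    """
    c = constraints or DesignConstraints()
    cond = cond or ReactionConditions()
    table = table or NNParameterTable.default()
    template = template.upper()
    n = len(template)
    if region is None:
        region = (0, n)
    lo, hi = region
    if not (0 <= lo < hi <= n):
        raise ValueError(f"region {region} outside template of length {n}")
    if hi - lo < c.size_range[0]:
        raise ValueError(
            f"region {region} shorter than minimum primer size {c.size_range[0]}"
        )

    codes = _CODE[np.frombuffer(template.encode(), dtype=np.uint8)].astype(np.int64)
    bad = (codes < 0).astype(np.int64)
    safe = np.where(codes < 0, 0, codes)
    # prefix sums over bases, GC flags and stack dH/dS
    gc_flag = ((safe == 1) | (safe == 2)).astype(np.int64) & (1 - bad)
    p_bad = np.concatenate([[0], np.cumsum(bad)])
    p_gc = np.concatenate([[0], np.cumsum(gc_flag)])
    dh_tab = np.zeros((4, 4))
    ds_tab = np.zeros((4, 4))
    for a_i, a in enumerate("ACGT"):
        for b_i, b in enumerate("ACGT"):
            dh_tab[a_i, b_i], ds_tab[a_i, b_i], _ = table.stack(a + b)
    stack_dh = np.zeros(max(n - 1, 0))
    stack_ds = np.zeros(max(n - 1, 0))
    if n >= 2:
        stack_dh = dh_tab[safe[:-1], safe[1:]]
        stack_ds = ds_tab[safe[:-1], safe[1:]]
    p_dh = np.concatenate([[0.0], np.cumsum(stack_dh)])
    p_ds = np.concatenate([[0.0], np.cumsum(stack_ds)])
    init_dh = np.where((safe == 0) | (safe == 3), table.init_at[0], table.init_gc[0])
    init_ds = np.where((safe == 0) | (safe == 3), table.init_at[1], table.init_gc[1])

    salt = np.log(cond.sodium_equivalent)
    ct_term = thermo.GAS_CONSTANT * np.log(cond.primer_concentration / 4.0)
    tm_margin = 1.5  # degC prescreen slack (covers palindrome x=1 shift); survivors recomputed exactly
    gc_margin = 1e-9

    out: List[Primer] = []
    memo_sc: dict = {}
    for L in range(c.size_range[0], c.size_range[1] + 1):
        if hi - lo < L:
            continue
        starts = np.arange(lo, hi - L + 1)
        if starts.size == 0:
            continue
        valid = (p_bad[starts + L] - p_bad[starts]) == 0
        gc_pct = 100.0 * (p_gc[starts + L] - p_gc[starts]) / L
        dh = (p_dh[starts + L - 1] - p_dh[starts]) + init_dh[starts] + init_dh[starts + L - 1]
        ds = (p_ds[starts + L - 1] - p_ds[starts]) + init_ds[starts] + init_ds[starts + L - 1]
        ds_eff = ds + 0.368 * (L - 1) * salt
        with np.errstate(divide="ignore", invalid="ignore"):
            tm_vec = 1000.0 * dh / (ds_eff + ct_term) - 273.15
        keep = (
            valid
            & (gc_pct >= c.gc_range[0] - gc_margin)
            & (gc_pct <= c.gc_range[1] + gc_margin)
            & (tm_vec >= c.tm_range[0] - tm_margin)
            & (tm_vec <= c.tm_range[1] + tm_margin)
        )
        for s in starts[keep]:
            window = template[s : s + L]
            props = memo_sc.get(window)
            if props is None:
                tm = thermo.primer_tm(window, cond, table)
                gcp = gc_content(window)
                scores = _self_comp_offset_scores(window)
                glob = float(max(0, max(sc for _, sc in scores)))
                three_fwd = float(max(0, max(sc for k, sc in scores if k >= 0)))
                three_rev = float(max(0, max(sc for k, sc in scores if k <= 0)))
                end_fwd = thermo.perfect_duplex_dg(window[-5:], table)
                end_rev = thermo.perfect_duplex_dg(revcomp(window[:5]), table)
                props = (tm, gcp, glob, three_fwd, three_rev, end_fwd, end_rev)
                memo_sc[window] = props
            tm, gcp, glob, three_fwd, three_rev, end_fwd, end_rev = props
            if _passes_filters(tm, L, gcp, glob, three_fwd, end_fwd, c):
                pen = primer_penalty(tm, L, gcp, glob, three_fwd, end_fwd, c)
                out.append(
                    Primer(window, template_id, "+", int(s), tm, gcp, end_fwd,
                           glob, three_fwd, pen)
                )
            if _passes_filters(tm, L, gcp, glob, three_rev, end_rev, c):
                # reverse primer over the same footprint: sequence is the
                # reverse complement, Tm/GC/global self-score are identical by
                # stack symmetry; 3' self-score and 3' pentamer differ.
                pen = primer_penalty(tm, L, gcp, glob, three_rev, end_rev, c)
                out.append(
                    Primer(revcomp(window), template_id, "-", int(s + L - 1), tm,
                           gcp, end_rev, glob, three_rev, pen)
                )
    out.sort(key=lambda p: (p.strand, p.footprint[0], p.length))
    return out


def design_primer_sets(
    template: str,
    template_id: str = "T",
    region: Optional[Tuple[int, int]] = None,
    constraints: Optional[DesignConstraints] = None,
    cond: Optional[ReactionConditions] = None,
    table: Optional[NNParameterTable] = None,
) -> List[PrimerSet]:
    """The lowest-penalty feasible primer sets for one template, ascending.

    Pairs every forward against every reverse candidate (after capping each
    strand at the ``max_candidates_per_strand`` best single-primer penalties),
    keeps pairs with non-overlapping footprints, product size inside
    ``product_size_range`` and Tm difference within the cap, and returns up to
    ``candidates_per_template`` distinct sets sorted ascending by penalty with
    ties broken by (amplicon size, forward start, forward sequence).
    """
    c = constraints or DesignConstraints()
    cands = enumerate_candidates(template, template_id, region, c, cond, table)
    fwd = sorted((p for p in cands if p.strand == "+"),
                 key=lambda p: (p.penalty, p.start, p.length))[: c.max_candidates_per_strand]
    rev = sorted((p for p in cands if p.strand == "-"),
                 key=lambda p: (p.penalty, p.start, p.length))[: c.max_candidates_per_strand]
    if not fwd or not rev:
        logger.info("template %s: no feasible %s primers survive the filters",
                    template_id, "forward" if not fwd else "reverse")
        return []

    pairs = []
    for f in fwd:
        f3 = f.start + f.length - 1
        for r in rev:
            size = r.start - f.start + 1
            if not (c.product_size_range[0] <= size <= c.product_size_range[1]):
                continue
            if r.start - r.length + 1 <= f3:  # overlapping footprints
                continue
            if abs(f.tm - r.tm) > c.max_tm_difference:
                continue
            pairs.append((f.penalty + r.penalty, size, f, r))
    if not pairs:
        logger.info("template %s: no feasible primer pair under product/Tm constraints",
                    template_id)
        return []
    pairs.sort(key=lambda t: (t[0], t[1], t[2].start, t[2].sequence, t[3].start))
    sets = []
    for rank, (pen, size, f, r) in enumerate(pairs[: c.candidates_per_template]):
        sets.append(PrimerSet(f, r, size, pen, rank))
    return sets
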