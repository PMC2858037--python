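"""Pairwise primer-set vetting: dimers, cross-specificity, scoring matrix.

Two candidate primer sets (PSs) may share a multiplex tube only if their four
primers neither dimerize nor co-amplify anything unintended from the
background database.  Both checks are thermodynamic:

* **Dimer check** — the minimum nearest-neighbor duplex dG37 over every
  ungapped relative offset of the two oligos in annealing orientation; at or
  below the cutoff (default -7 kcal/mol) the pair is a dimer.  Only contiguous
  Watson-Crick runs contribute (no bulges or loops).

* **Specificity check** — a primer *binds* the database wherever its
  3'-terminal seed (default 9 nt) matches exactly and the full ungapped
  extension is stable (dG37 <= -9 kcal/mol by default).  Six primer pairs are
  examined for two PSs ``i`` and ``j``: each PS's own pair (PP1, PP2) must
  yield exactly its intended amplicon, and the four cross pairings
  (PP3: Fi x Fj, PP4: Ri x Rj, PP5: Fi x Rj, PP6: Ri x Fj) must yield no
  amplicon at all up to the maximum amplifiable size (default 2000 bp).

The results populate a symmetric 0/1 compatibility (scoring) matrix over all
candidate PSs: 1 means no dimer and no nonspecific amplicon between the two
PSs; cells joining two PSs of the same template are structurally excluded
(never co-selectable) rather than scored.  A PS whose own pair fails step one
is disqualified globally: every cross cell involving it is 0.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .design import Primer, PrimerSet
from .thermo import (
    COMPLEMENT,
    DuplexAlignment,
    NNParameterTable,
    duplex_dg,
    revcomp,
    validate_dna,
)

__all__ = [
    "InteractionSettings",
    "BindingSite",
    "PredictedAmplicon",
    "Reason",
    "KmerIndex",
    "build_index",
    "dimer_dg",
    "is_dimer",
    "find_binding_sites",
    "predict_amplicons",
    "ps_is_specific",
    "cross_compatible",
    "CompatibilityMatrix",
    "build_scoring_matrix",
    "sites_to_bed",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionSettings:
    """Thresholds of the dimer and specificity engines.

    seed_length : exact-match 3'-anchor length for binding-site search (nt).
    min_binding_dg : a site counts only if its full-extension dG37 is at or
        below this (kcal/mol); aligned with the 3'-stability criterion.
    max_amplicon : largest nonspecific product considered amplifiable (bp).
    dimer_cutoff : duplex dG37 at or below which two oligos are a dimer
        (kcal/mol); initiation terms are included in the duplex dG.
    """

    seed_length: int = 9
    min_binding_dg: float = -9.0
    max_amplicon: int = 2000
    dimer_cutoff: float = -7.0

    def __post_init__(self) -> None:
        if self.seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        if self.max_amplicon < 1:
            raise ValueError("max_amplicon must be >= 1")


class Reason(NamedTuple):
    """Diagnostic tag for a compatibility decision."""

    tag: str  # compatible | dimer | nonspecific_amplicon | same_template
    detail: str = ""

    def __str__(self) -> str:
        return f"{self.tag}({self.detail})" if self.detail else self.tag


COMPATIBLE = Reason("compatible")


@dataclass(frozen=True)
class BindingSite:
    """A stable primer binding location on a database sequence.

    ``strand`` is the strand the primer mimics: a plus-strand site means the
    primer reads like the plus strand (extends rightward); a minus-strand site
    extends leftward.  ``three_prime_position`` / ``five_prime_position`` are
    0-based plus-strand coordinates of the primer's terminal bases.
    """

    primer_id: str
    db_id: str
    strand: str  # "+" or "-"
    three_prime_position: int
    five_prime_position: int
    binding_dg: float
    seed_length: int
    primer_length: int

    @property
    def footprint(self) -> Tuple[int, int]:
        lo = min(self.three_prime_position, self.five_prime_position)
        return (lo, lo + self.primer_length)


@dataclass(frozen=True)
class PredictedAmplicon:
    """A potential PCR product: a plus-strand site upstream of a minus-strand site."""

    db_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    size: int
    pair_label: str = ""

    def __post_init__(self) -> None:
        if self.forward_site.strand != "+" or self.reverse_site.strand != "-":
            raise ValueError("amplicon requires a plus-strand and a minus-strand site")
        if self.size < 1:
            raise ValueError("amplicon size must be >= 1")


class KmerIndex:
    """Exact k-mer positions over both strands of a background database.

    Plus-strand words are indexed directly; a minus-strand query for word ``w``
    is answered by looking up ``revcomp(w)`` on the plus strand, so both
    strands resolve in O(1) expected time from a single dictionary.
    """

    def __init__(self, records: Mapping[str, str], k: int):
        if not records:
            raise ValueError("background database is empty")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.records: Dict[str, str] = {rid: seq.upper() for rid, seq in records.items()}
        self._words: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for rid, seq in self.records.items():
            for i in range(len(seq) - k + 1):
                word = seq[i : i + k]
                if all(b in COMPLEMENT for b in word):
                    self._words[word].append((rid, i))

    def plus_positions(self, word: str) -> List[Tuple[str, int]]:
        """(record_id, start) of plus-strand occurrences of ``word``."""
        return list(self._words.get(word.upper(), ()))

    def minus_positions(self, word: str) -> List[Tuple[str, int]]:
        """(record_id, start) of plus-strand starts whose minus strand reads ``word``."""
        return list(self._words.get(revcomp(word), ()))

    def n_plus_words(self, record_id: str) -> int:
        seq = self.records[record_id]
        return max(len(seq) - self.k + 1, 0)


def build_index(records: Mapping[str, str], seed_length: int = 9) -> KmerIndex:
    """Index every seed-length word of the background database on both strands."""
    return KmerIndex(records, seed_length)


def _alignment_offsets(l1: int, l2: int) -> range:
    """Every ungapped offset with at least one overlapping column."""
    return range(-(l2 - 1), l1)


def dimer_dg(p1: str, p2: str, table: Optional[NNParameterTable] = None) -> float:
    """Most stable (minimum) duplex dG37 over all ungapped offsets of two oligos.

    Symmetric in its arguments; two oligos with no complementary dinucleotide
    anywhere score 0 (no offset can beat the empty duplex).
    """
    table = table or NNParameterTable.default()
    p1 = validate_dna(p1, min_length=8, context="oligo 1")
    p2 = validate_dna(p2, min_length=8, context="oligo 2")
    best = 0.0
    for offset in _alignment_offsets(len(p1), len(p2)):
        dg = duplex_dg(DuplexAlignment.from_offset(p1, p2, offset), table)
        if dg < best:
            best = dg
    return best


def is_dimer(
    p1: str,
    p2: str,
    cutoff: float = -7.0,
    table: Optional[NNParameterTable] = None,
) -> bool:
    """True iff the pair's minimum duplex dG37 is at or below ``cutoff`` kcal/mol."""
    return dimer_dg(p1, p2, table) <= cutoff


def _site_dg(primer_like_5to3: str, db_region: str, table: NNParameterTable) -> float:
    """Duplex dG37 of a primer laid 5'->3' along a same-length plus-strand region.

    Columns where the primer base equals the database base are paired (the
    primer anneals to the complementary strand); runs of matches stack.
    """
    bottom = "".join(COMPLEMENT[b] for b in db_region)
    return duplex_dg(DuplexAlignment(top=primer_like_5to3, bottom=bottom, offset=0), table)


def find_binding_sites(
    primer: Primer | str,
    index: KmerIndex,
    settings: Optional[InteractionSettings] = None,
    table: Optional[NNParameterTable] = None,
    primer_id: Optional[str] = None,
) -> List[BindingSite]:
    """All stable binding sites of a primer over both strands of the database.

    A site requires an exact 3'-terminal seed match with the whole primer
    footprint inside the record, and full-extension dG37 at or below
    ``settings.min_binding_dg``.  Results are sorted (record, strand, 3' end).
    """
    settings = settings or InteractionSettings()
    table = table or NNParameterTable.default()
    if isinstance(primer, Primer):
        seq = primer.sequence
        pid = primer_id or primer.id()
    else:
        seq = validate_dna(primer, min_length=settings.seed_length, context="primer")
        pid = primer_id or seq
    k = settings.seed_length
    if len(seq) < k:
        raise ValueError(f"primer shorter than seed length {k}")
    if index.k != k:
        raise ValueError(f"index built with k={index.k}, settings ask {k}")
    seed = seq[-k:]
    L = len(seq)
    rc = revcomp(seq)
    sites: List[BindingSite] = []
    for rid, s in index.plus_positions(seed):
        t = s + k - 1  # 3'-end plus coordinate
        if t - L + 1 < 0:
            continue
        region = index.records[rid][t - L + 1 : t + 1]
        dg = _site_dg(seq, region, table)
        if dg <= settings.min_binding_dg:
            sites.append(BindingSite(pid, rid, "+", t, t - L + 1, dg, k, L))
    for rid, u in index.minus_positions(seed):
        if u + L > len(index.records[rid]):
            continue
        region = index.records[rid][u : u + L]
        dg = _site_dg(rc, region, table)
        if dg <= settings.min_binding_dg:
            sites.append(BindingSite(pid, rid, "-", u, u + L - 1, dg, k, L))
    sites.sort(key=lambda b: (b.db_id, b.strand, b.three_prime_position))
    return sites


def predict_amplicons(
    sites_f: Sequence[BindingSite],
    sites_r: Sequence[BindingSite],
    max_size: int,
    pair_label: str = "",
) -> List[PredictedAmplicon]:
    """All correctly oriented (plus upstream of minus) site pairs on one record.

    Size is measured 5'-end to 5'-end inclusive and capped at ``max_size``.
    """
    out = []
    for f in sites_f:
        if f.strand != "+":
            continue
        for r in sites_r:
            if r.strand != "-" or r.db_id != f.db_id:
                continue
            if f.three_prime_position >= r.three_prime_position:
                continue
            size = r.five_prime_position - f.five_prime_position + 1
            if 1 <= size <= max_size:
                out.append(PredictedAmplicon(f.db_id, f, r, size, pair_label))
    out.sort(key=lambda a: (a.db_id, a.forward_site.five_prime_position,
                            a.reverse_site.five_prime_position))
    return out


def _pair_amplicons(
    sites_a: Sequence[BindingSite],
    sites_b: Sequence[BindingSite],
    max_size: int,
    label: str,
) -> List[PredictedAmplicon]:
    """Products a primer pair can make: plus sites of one with minus sites of the other."""
    amps = predict_amplicons([s for s in sites_a if s.strand == "+"],
                             [s for s in sites_b if s.strand == "-"], max_size, label)
    if sites_a is not sites_b:
        amps += predict_amplicons([s for s in sites_b if s.strand == "+"],
                                  [s for s in sites_a if s.strand == "-"], max_size, label)
    amps.sort(key=lambda a: (a.db_id, a.forward_site.five_prime_position,
                             a.reverse_site.five_prime_position))
    return amps


def ps_is_specific(
    ps: PrimerSet,
    index: KmerIndex,
    settings: Optional[InteractionSettings] = None,
    table: Optional[NNParameterTable] = None,
    _site_cache: Optional[Dict[str, List[BindingSite]]] = None,
) -> Tuple[bool, str]:
    """Step one: the PS's own pair yields exactly its intended amplicon.

    Returns (ok, detail).  The intended amplicon is the one on the PS's own
    template record at the designed coordinates; its absence is flagged as a
    template/database mismatch, which is distinct from nonspecificity.
    """
    settings = settings or InteractionSettings()
    table = table or NNParameterTable.default()

    def sites(p: Primer) -> List[BindingSite]:
        if _site_cache is not None and p.id() in _site_cache:
            return _site_cache[p.id()]
        s = find_binding_sites(p, index, settings, table)
        if _site_cache is not None:
            _site_cache[p.id()] = s
        return s

    amps = _pair_amplicons(sites(ps.forward), sites(ps.reverse),
                           settings.max_amplicon, "PP1")
    intended = [
        a for a in amps
        if a.db_id == ps.template_id
        and a.forward_site.five_prime_position == ps.forward.start
        and a.reverse_site.five_prime_position == ps.reverse.start
        and a.size == ps.amplicon_size
    ]
    if not intended:
        return False, "template_missing_from_database"
    if len(amps) > len(intended) or len(intended) > 1:
        return False, f"{len(amps)} amplicons (expected 1)"
    return True, "specific"


_PP_CROSS = (("PP3", "f", "f"), ("PP4", "r", "r"), ("PP5", "f", "r"), ("PP6", "r", "f"))


def cross_compatible(
    ps_i: PrimerSet,
    ps_j: PrimerSet,
    index: KmerIndex,
    settings: Optional[InteractionSettings] = None,
    table: Optional[NNParameterTable] = None,
    _site_cache: Optional[Dict[str, List[BindingSite]]] = None,
    _dimer_cache: Optional[Dict[Tuple[str, str], float]] = None,
    _step_one: Optional[Dict[str, Tuple[bool, str]]] = None,
) -> Tuple[bool, Reason]:
    """Step two: may two PSs from different templates share a tube?

    Checks, in order: each PS's own-pair specificity (PP1/PP2), every
    unordered pairing of the four primers (including each with itself) for
    dimers, then the four cross pairs PP3-PP6 for nonspecific amplicons.  The
    reason names the first failing check.
    """
    settings = settings or InteractionSettings()
    table = table or NNParameterTable.default()
    if ps_i.template_id == ps_j.template_id:
        raise ValueError("cross_compatible requires PSs from different templates")
    site_cache = _site_cache if _site_cache is not None else {}

    def step_one(ps: PrimerSet, label: str) -> Optional[Reason]:
        if _step_one is not None and ps.id() in _step_one:
            ok, detail = _step_one[ps.id()]
        else:
            ok, detail = ps_is_specific(ps, index, settings, table, site_cache)
            if _step_one is not None:
                _step_one[ps.id()] = (ok, detail)
        if not ok:
            return Reason("nonspecific_amplicon", f"{label}:{detail}")
        return None

    for ps, label in ((ps_i, "PP1"), (ps_j, "PP2")):
        bad = step_one(ps, label)
        if bad:
            return False, bad

    primers = [("TiPf", ps_i.forward), ("TiPr", ps_i.reverse),
               ("TjPf", ps_j.forward), ("TjPr", ps_j.reverse)]
    for (name_a, pa), (name_b, pb) in itertools.combinations_with_replacement(primers, 2):
        key = tuple(sorted((pa.sequence, pb.sequence)))
        if _dimer_cache is not None and key in _dimer_cache:
            dg = _dimer_cache[key]
        else:
            dg = dimer_dg(pa.sequence, pb.sequence, table)
            if _dimer_cache is not None:
                _dimer_cache[key] = dg
        if dg <= settings.dimer_cutoff:
            return False, Reason("dimer", f"{name_a}x{name_b}:{dg:.2f}")

    def sites(p: Primer) -> List[BindingSite]:
        if p.id() not in site_cache:
            site_cache[p.id()] = find_binding_sites(p, index, settings, table)
        return site_cache[p.id()]

    by_role = {"f": {"i": ps_i.forward, "j": ps_j.forward},
               "r": {"i": ps_i.reverse, "j": ps_j.reverse}}
    for label, role_i, role_j in _PP_CROSS:
        amps = _pair_amplicons(sites(by_role[role_i]["i"]), sites(by_role[role_j]["j"]),
                               settings.max_amplicon, label)
        if amps:
            a = amps[0]
            return False, Reason(
                "nonspecific_amplicon",
                f"{label}:{a.db_id}:{a.size}bp",
            )
    return True, COMPATIBLE


@dataclass
class CompatibilityMatrix:
    """Symmetric 0/1 scoring matrix over all candidate PSs with diagnostics.

    ``values[i, j] == 1`` iff the two PSs may co-occur in a PSC.  Cells joining
    PSs of the same template carry the ``same_template`` tag and are never
    co-selectable regardless of value.
    """

    ps_list: List[PrimerSet]
    values: np.ndarray
    reasons: List[List[Reason]]

    @property
    def ids(self) -> List[str]:
        return [ps.id() for ps in self.ps_list]

    def index_of(self, ps: PrimerSet) -> int:
        return self.ids.index(ps.id())

    def value(self, i: int, j: int) -> int:
        return int(self.values[i, j])

    def reason(self, i: int, j: int) -> Reason:
        return self.reasons[i][j]

    def compatible(self, a: PrimerSet, b: PrimerSet) -> bool:
        i, j = self.index_of(a), self.index_of(b)
        return self.values[i, j] == 1 and self.reasons[i][j].tag != "same_template"

    def to_tsv(self) -> Tuple[str, str]:
        """(values_tsv, reasons_tsv) with row/column PS ids."""
        ids = self.ids
        head = "ps_id\t" + "\t".join(ids)
        vrows = [head]
        rrows = [head]
        for i, rid in enumerate(ids):
            vals = ["-" if self.reasons[i][j].tag == "same_template" else str(int(self.values[i, j]))
                    for j in range(len(ids))]
            vrows.append(rid + "\t" + "\t".join(vals))
            rrows.append(rid + "\t" + "\t".join(str(self.reasons[i][j]) for j in range(len(ids))))
        return "\n".join(vrows) + "\n", "\n".join(rrows) + "\n"


def build_scoring_matrix(
    all_ps: Sequence[PrimerSet],
    index: KmerIndex,
    settings: Optional[InteractionSettings] = None,
    table: Optional[NNParameterTable] = None,
) -> CompatibilityMatrix:
    """Vet every cross-template PS pair once and cache the results.

    O(N^2) cells; binding sites and dimer free energies are computed once per
    primer / primer pair and shared across cells.
    """
    settings = settings or InteractionSettings()
    table = table or NNParameterTable.default()
    n = len(all_ps)
    templates = {ps.template_id for ps in all_ps}
    if len(templates) < 2:
        raise ValueError("scoring matrix needs candidate PSs from >= 2 templates")
    values = np.zeros((n, n), dtype=np.int8)
    reasons: List[List[Reason]] = [[Reason("same_template")] * n for _ in range(n)]
    site_cache: Dict[str, List[BindingSite]] = {}
    dimer_cache: Dict[Tuple[str, str], float] = {}
    step_one: Dict[str, Tuple[bool, str]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if all_ps[i].template_id == all_ps[j].template_id:
                continue
            ok, reason = cross_compatible(
                all_ps[i], all_ps[j], index, settings, table,
                _site_cache=site_cache, _dimer_cache=dimer_cache, _step_one=step_one,
            )
            values[i, j] = values[j, i] = 1 if ok else 0
            reasons[i][j] = reasons[j][i] = reason
    for ps_id, (ok, detail) in step_one.items():
        if not ok:
            logger.info("PS %s disqualified at step one: %s", ps_id, detail)
    return CompatibilityMatrix(list(all_ps), values, reasons)


def sites_to_bed(sites: Iterable[BindingSite]) -> str:
    """BED6 (0-based half-open) lines for binding sites; score = 10*|dG| capped at 1000."""
    lines = []
    for s in sorted(sites, key=lambda b: (b.db_id, b.footprint[0], b.strand, b.primer_id)):
        lo, hi = s.footprint
        score = min(1000, int(round(abs(s.binding_dg) * 10)))
        lines.append(f"{s.db_id}\t{lo}\t{hi}\t{s.primer_id}\t{score}\t{s.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
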