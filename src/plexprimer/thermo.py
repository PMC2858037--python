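"""Nearest-neighbor DNA duplex thermodynamics.

The duplex stability model is the unified Watson-Crick nearest-neighbor (NN)
parameter set: each adjacent base-pair stack contributes a tabulated
(``dH``, ``dS``) increment, duplex initiation contributes a per-terminal-pair
term keyed on whether the terminal pair is A:T or G:C, and self-complementary
duplexes carry an entropic symmetry correction.  Free energies are reported at
37 degC (``dG37 = dH - 310.15 * dS / 1000`` with dH in kcal/mol and dS in
cal/(mol K)).

Melting temperature follows the two-state formula

    Tm = 1000 * dH / (dS + R * ln(C_T / x)) - 273.15

with ``R = 1.987 cal/(mol K)``, total strand concentration ``C_T`` and
``x = 4`` for non-self-complementary oligos (``x = 1`` for self-complementary
ones, which also receive the symmetry correction).  Salt is handled by the
sodium-equivalent entropy correction ``dS += 0.368 * (N - 1) * ln([Na+]eq)``
over the ``N - 1`` phosphate stacks, where the divalent contribution uses the
von Ahsen approximation ``[Na+]eq = [mono] + 120 * sqrt([Mg2+] - [dNTP])``
(concentrations in mM inside the square root).

Only perfect Watson-Crick stacks contribute: mismatches, bulges and dangling
ends carry no parameters here and simply interrupt a stack run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Mapping, Tuple

__all__ = [
    "COMPLEMENT",
    "revcomp",
    "validate_dna",
    "is_self_complementary",
    "NNParameterTable",
    "ReactionConditions",
    "DuplexAlignment",
    "duplex_dg",
    "perfect_duplex_dg",
    "primer_tm",
    "end_stability_dg",
]

GAS_CONSTANT = 1.987  # cal / (mol K)
T37 = 310.15  # K

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def validate_dna(seq: str, *, min_length: int = 1, context: str = "sequence") -> str:
    """Return ``seq`` uppercased, or raise ``ValueError`` naming the first bad base.

    IUPAC ambiguity codes are rejected, not expanded: degenerate-primer design
    is out of scope and every downstream model assumes a concrete base.
    """
    if not isinstance(seq, str):
        raise ValueError(f"{context} must be a string, got {type(seq).__name__}")
    up = seq.upper()
    for i, base in enumerate(up):
        if base not in COMPLEMENT:
            raise ValueError(f"{context} contains non-ACGT base {base!r} at position {i}")
    if len(up) < min_length:
        raise ValueError(f"{context} too short: length {len(up)} < {min_length}")
    return up


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string (5'->3' in, 5'->3' out)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def is_self_complementary(seq: str) -> bool:
    """True iff the oligo equals its own reverse complement (requires even length)."""
    seq = seq.upper()
    return len(seq) % 2 == 0 and seq == revcomp(seq)


@dataclass(frozen=True)
class NNParameterTable:
    """Unified NN parameter table: 16 stacks, two initiation terms, symmetry term.

    ``stacks`` maps the top-strand dinucleotide read 5'->3' (the bottom strand
    is its Watson-Crick complement) to ``(dH, dS, dG37)``.  ``init_at`` /
    ``init_gc`` are the per-terminal-base-pair initiation terms; ``symmetry``
    is the self-complementary duplex correction.
    """

    stacks: Mapping[str, Tuple[float, float, float]]
    init_at: Tuple[float, float, float]
    init_gc: Tuple[float, float, float]
    symmetry: Tuple[float, float, float]

    def __post_init__(self) -> None:
        missing = [a + b for a in "ACGT" for b in "ACGT" if a + b not in self.stacks]
        if missing:
            raise ValueError(f"NN table missing stacks: {missing}")
        for name, (dh, ds, dg) in list(self.stacks.items()) + [
            ("INIT_AT", self.init_at),
            ("INIT_GC", self.init_gc),
            ("SYMMETRY", self.symmetry),
        ]:
            if abs(dg - (dh - T37 * ds / 1000.0)) > 0.01:
                raise ValueError(f"NN entry {name}: dG37 inconsistent with dH/dS")

    def stack(self, dinuc: str) -> Tuple[float, float, float]:
        return self.stacks[dinuc]

    def init_for(self, base: str) -> Tuple[float, float, float]:
        """Initiation term for a duplex terminating in base pair ``base``:complement."""
        return self.init_at if base in "AT" else self.init_gc

    @classmethod
    def from_tsv(cls, path) -> "NNParameterTable":
        """Load (stack, dH, dS, dG37) rows; dG37 is recomputed exactly from
        dH/dS so the working value carries full precision (the stored column
        is validated as a checksum to 0.01 kcal/mol)."""
        stacks: Dict[str, Tuple[float, float, float]] = {}
        special: Dict[str, Tuple[float, float, float]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, dh_s, ds_s, dg_s = line.split("\t")
                dh, ds = float(dh_s), float(ds_s)
                dg = dh - T37 * ds / 1000.0
                if abs(dg - float(dg_s)) > 0.01:
                    raise ValueError(f"NN entry {name}: stored dG37 inconsistent")
                entry = (dh, ds, dg)
                if name in ("INIT_AT", "INIT_GC", "SYMMETRY"):
                    special[name] = entry
                else:
                    stacks[name] = entry
        return cls(
            stacks=stacks,
            init_at=special["INIT_AT"],
            init_gc=special["INIT_GC"],
            symmetry=special["SYMMETRY"],
        )

    @classmethod
    def default(cls) -> "NNParameterTable":
        return _default_table()


@lru_cache(maxsize=1)
def _default_table() -> NNParameterTable:
    with resources.as_file(
        resources.files("plexprimer.data").joinpath("nn_unified.tsv")
    ) as path:
        return NNParameterTable.from_tsv(path)


@dataclass(frozen=True)
class ReactionConditions:
    """PCR annealing-reaction conditions feeding the Tm calculation.

    primer_concentration : total oligo concentration C_T, molar (default 50 nM).
    monovalent : monovalent cation concentration, molar (default 50 mM).
    divalent / dntp : Mg2+ and total dNTP, molar; the free-Mg2+ excess enters the
        sodium-equivalent via the von Ahsen square-root term.  Set divalent to 0
        for a pure monovalent correction.
    """

    primer_concentration: float = 50e-9
    monovalent: float = 50e-3
    divalent: float = 1.5e-3
    dntp: float = 0.6e-3

    def __post_init__(self) -> None:
        if self.primer_concentration <= 0 or self.monovalent <= 0:
            raise ValueError("primer and monovalent concentrations must be > 0")
        if self.divalent < 0 or self.dntp < 0:
            raise ValueError("divalent/dNTP concentrations must be >= 0")

    @property
    def sodium_equivalent(self) -> float:
        """Effective monovalent concentration (molar) including divalent excess."""
        mono_mm = self.monovalent * 1e3
        free_div_mm = max(self.divalent - self.dntp, 0.0) * 1e3
        return (mono_mm + 120.0 * math.sqrt(free_div_mm)) * 1e-3


@dataclass(frozen=True)
class DuplexAlignment:
    """An ungapped alignment of two oligos in annealing orientation.

    ``top`` is written 5'->3'; ``bottom`` is written 3'->5' left-to-right, so
    column ``i`` of the top strand pairs with ``bottom[i - offset]``.  A column
    is *matched* when the two bases are Watson-Crick complementary; consecutive
    matched columns form the stacks that contribute free energy.
    """

    top: str
    bottom: str  # 3'->5' left-to-right
    offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "top", validate_dna(self.top, context="top strand"))
        object.__setattr__(self, "bottom", validate_dna(self.bottom, context="bottom strand"))

    @classmethod
    def from_offset(cls, p1: str, p2: str, offset: int) -> "DuplexAlignment":
        """Align ``p1`` (5'->3') against ``p2`` (5'->3') shifted by ``offset``.

        ``p2`` is flipped into 3'->5' orientation; ``offset`` is the column of
        ``p1`` under which ``p2``'s 3'-terminal base sits.
        """
        return cls(top=p1, bottom=p2[::-1].upper(), offset=offset)

    def matched_columns(self) -> List[int]:
        cols = []
        for i in range(len(self.top)):
            j = i - self.offset
            if 0 <= j < len(self.bottom) and COMPLEMENT[self.top[i]] == self.bottom[j]:
                cols.append(i)
        return cols

    def matched_stacks(self) -> List[str]:
        """Top-strand dinucleotides over consecutive matched columns."""
        cols = self.matched_columns()
        return [
            self.top[c : c + 2]
            for k, c in enumerate(cols[:-1])
            if cols[k + 1] == c + 1
        ]

    @property
    def is_self_duplex(self) -> bool:
        """Both strands are the same molecule (bottom read 5'->3' equals top)."""
        return self.top == self.bottom[::-1]


def duplex_dg(alignment: DuplexAlignment, table: NNParameterTable | None = None) -> float:
    """dG37 (kcal/mol) of an ungapped duplex alignment.

    Sum of stack dG37 over consecutive complementary columns, plus initiation
    terms for the first and last matched pair of the alignment, plus the
    symmetry correction when the two strands are the same molecule.  An
    alignment with no matched column returns 0.  More negative = more stable.
    """
    table = table or NNParameterTable.default()
    cols = alignment.matched_columns()
    if not cols:
        return 0.0
    dg = 0.0
    for k, c in enumerate(cols[:-1]):
        if cols[k + 1] == c + 1:
            dg += table.stack(alignment.top[c : c + 2])[2]
    dg += table.init_for(alignment.top[cols[0]])[2]
    dg += table.init_for(alignment.top[cols[-1]])[2]
    if alignment.is_self_duplex:
        dg += table.symmetry[2]
    return dg


def perfect_duplex_dg(seq: str, table: NNParameterTable | None = None) -> float:
    """dG37 of the fully base-paired duplex of ``seq`` with its complement."""
    table = table or NNParameterTable.default()
    seq = validate_dna(seq, min_length=2)
    dg = sum(table.stack(seq[i : i + 2])[2] for i in range(len(seq) - 1))
    dg += table.init_for(seq[0])[2] + table.init_for(seq[-1])[2]
    if is_self_complementary(seq):
        dg += table.symmetry[2]
    return dg


def _duplex_dh_ds(seq: str, table: NNParameterTable) -> Tuple[float, float]:
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        sdh, sds, _ = table.stack(seq[i : i + 2])
        dh += sdh
        ds += sds
    for terminal in (seq[0], seq[-1]):
        tdh, tds, _ = table.init_for(terminal)
        dh += tdh
        ds += tds
    if is_self_complementary(seq):
        dh += table.symmetry[0]
        ds += table.symmetry[1]
    return dh, ds


def primer_tm(
    seq: str,
    cond: ReactionConditions | None = None,
    table: NNParameterTable | None = None,
) -> float:
    """Two-state NN melting temperature (degC) of a primer against its perfect complement."""
    cond = cond or ReactionConditions()
    table = table or NNParameterTable.default()
    seq = validate_dna(seq, min_length=8, context="primer")
    dh, ds = _duplex_dh_ds(seq, table)
    ds += 0.368 * (len(seq) - 1) * math.log(cond.sodium_equivalent)
    x = 1.0 if is_self_complementary(seq) else 4.0
    return 1000.0 * dh / (ds + GAS_CONSTANT * math.log(cond.primer_concentration / x)) - 273.15


def end_stability_dg(seq: str, table: NNParameterTable | None = None) -> float:
    """dG37 of the perfectly matched duplex of the final five 3' residues.

    This is the 3'-end stability used by the candidate filter: a very stable
    3' pentamer promotes extension from mis-primed sites, so designs cap its
    magnitude (default cap 9.0 kcal/mol).
    """
    seq = validate_dna(seq, min_length=5, context="primer")
    return perfect_duplex_dg(seq[-5:], table)
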