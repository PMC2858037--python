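"""Synthetic template/background generation for testing the whole pipeline.

Real multiplex panels come from genomes; these fixtures emulate their
*structure* while making every expected outcome checkable from a manifest:

* **Zoned templates** — a forward primer zone, an AT-rich spacer that admits
  no primers (GC and Tm filters fail there), and a reverse primer zone.  The
  spacer length sets the amplicon size, so a multi-template fixture has
  well-separated gel bands by construction.
* **Purine bias** — with ``purine_bias > 0.5`` the forward zone is A/G-rich
  and the reverse zone C/T-rich on the plus strand, so *every* primer the
  designer can pick is purine-rich.  Purine-rich oligos cannot form long
  Watson-Crick runs with each other, which suppresses primer dimers without
  filtering; GC content stays near 50% because G and C appear at equal rates.
* **Screening** — each accepted template must yield the full candidate count
  and every candidate primer's 3' seed must occur exactly once in its own
  template; ``ensure_clean`` additionally enforces cross-template seed
  disjointness and a dimer-free candidate pool, so a zero-decoy clean fixture
  produces an all-ones cross-template scoring matrix by construction.
* **Planted decoys** — a background padding record receives copies of the 3'
  dozen bases of two chosen primers at amplifiable spacing, creating exactly
  the cross-amplification (e.g. a PP5 product) the manifest declares.
* **Planted dimer anchors** — an 8-base 3'-complementary anchor (below the
  9 nt specificity seed, so the dimer channel stays decoupled from the
  binding-site channel) written into a partner template's reverse zone; the
  manifest records the engineered dimerizing primer pair.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .design import DesignConstraints, Primer, PrimerSet, design_primer_sets
from .interaction import InteractionSettings, dimer_dg
from .thermo import ReactionConditions, perfect_duplex_dg, revcomp

__all__ = [
    "FixtureError",
    "FixtureSpec",
    "Fixture",
    "random_dna",
    "biased_dna",
    "random_template",
    "generate_fixture",
    "write_fixture",
]

_BASES = np.array(list("ACGT"))


class FixtureError(RuntimeError):
    """The fixture spec is contradictory or could not be satisfied."""


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random sequence with expected GC fraction ``gc`` (A/T and G/C symmetric)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def biased_dna(rng: np.random.Generator, length: int, probs: Sequence[float]) -> str:
    """Random sequence with explicit per-base probabilities (A, C, G, T)."""
    return "".join(rng.choice(_BASES, size=length, p=list(probs)))


def _count_occurrences(haystack: str, word: str) -> int:
    """Overlapping occurrences of ``word`` on the plus strand of ``haystack``."""
    n = 0
    start = 0
    while True:
        i = haystack.find(word, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def _both_strand_count(seq: str, word: str) -> int:
    return _count_occurrences(seq, word) + _count_occurrences(seq, revcomp(word))


def _candidate_primers(sets: Sequence[PrimerSet]) -> List[Primer]:
    seen = {}
    for ps in sets:
        for p in (ps.forward, ps.reverse):
            seen.setdefault(p.sequence, p)
    return list(seen.values())


def random_template(
    seed_or_rng,
    length: int = 600,
    gc: float = 0.5,
    constraints: Optional[DesignConstraints] = None,
    cond: Optional[ReactionConditions] = None,
    max_tries: int = 60,
) -> str:
    """A uniform random template guaranteed to admit the full candidate count.

    Resamples (bounded) until ``design_primer_sets`` returns
    ``candidates_per_template`` sets, so downstream tests can rely on the
    default candidate pool being full.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    c = constraints or DesignConstraints()
    for _ in range(max_tries):
        t = random_dna(rng, length, gc)
        if len(design_primer_sets(t, "T", None, c, cond)) == c.candidates_per_template:
            return t
    raise FixtureError(
        f"no {length} bp template with {c.candidates_per_template} feasible primer "
        f"sets found in {max_tries} tries; constraints may be contradictory"
    )


@dataclass
class FixtureSpec:
    """Parameters of a synthetic multiplex design study.

    ``amplicon_targets`` (bp, one per template) default to an even spread over
    110-480 bp so that gel bands are separable; ``purine_bias`` is the A+G
    fraction of the forward primer zone (and C+T fraction of the reverse
    zone); ``ensure_clean`` turns on cross-template seed and dimer screening.
    """

    n_templates: int = 5
    amplicon_targets: Optional[Sequence[int]] = None
    amplicon_tolerance: int = 15
    zone_length: int = 45
    spacer_gc: float = 0.25
    purine_bias: float = 0.5
    n_decoys: int = 0
    n_dimer_plants: int = 0
    background_pad: int = 4000
    decoy_gap: int = 260
    anchor_length: int = 12
    seed: int = 0
    ensure_clean: bool = False
    max_template_tries: int = 80
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    conditions: ReactionConditions = field(default_factory=ReactionConditions)
    interaction: InteractionSettings = field(default_factory=InteractionSettings)

    def targets(self) -> List[int]:
        if self.amplicon_targets is not None:
            t = list(self.amplicon_targets)
            if len(t) != self.n_templates:
                raise FixtureError("amplicon_targets length must equal n_templates")
            return t
        if self.n_templates == 1:
            return [300]
        # geometric spacing matched to the log-size gel law: with every
        # realized amplicon within +-amplicon_tolerance of its target, a 1.28
        # ratio between consecutive windows keeps > 3 mm band spacing on the
        # default 1% agarose model across the whole 100-500 bp product range
        out = [self.constraints.product_size_range[0]]
        for _ in range(self.n_templates - 1):
            out.append(int(round(1.28 * (out[-1] + self.amplicon_tolerance)
                                 + self.amplicon_tolerance)))
        return out

    def validate(self) -> None:
        if self.n_templates < 1:
            raise FixtureError("need at least one template")
        pmin, pmax = self.constraints.product_size_range
        for t in self.targets():
            if not (pmin <= t <= pmax - self.amplicon_tolerance):
                raise FixtureError(
                    f"amplicon target {t} bp (+- {self.amplicon_tolerance}) does not "
                    f"fit the product size range {pmin}-{pmax}; fewer templates or "
                    f"explicit targets needed"
                )
        if self.zone_length < self.constraints.size_range[0]:
            raise FixtureError("primer zone shorter than the minimum primer size")
        if not (0.0 < self.spacer_gc < 0.45):
            raise FixtureError("spacer_gc must stay below the primer GC window")
        if self.n_decoys > 0:
            # consecutive decoys must sit farther apart than the maximum
            # amplifiable size, or their planted sites combine into products
            # the manifest does not declare
            spacing = self.interaction.max_amplicon + 200
            need = 400 + self.n_decoys * (self.decoy_gap + 2 * self.anchor_length + spacing)
            if self.background_pad < need:
                raise FixtureError(
                    f"background_pad {self.background_pad} too small for "
                    f"{self.n_decoys} decoys (need >= {need})"
                )


@dataclass
class Fixture:
    """Generated templates, background database, manifest and candidate pool."""

    spec: FixtureSpec
    templates: Dict[str, str]
    background: Dict[str, str]
    candidate_sets: Dict[str, List[PrimerSet]]
    manifest: Dict

    @property
    def template_ids(self) -> List[str]:
        return list(self.templates)


def _zoned_template(rng: np.random.Generator, spec: FixtureSpec, target: int) -> str:
    q = spec.purine_bias
    fwd_probs = (q / 2, (1 - q) / 2, q / 2, (1 - q) / 2)  # A,C,G,T: purine-rich
    rev_probs = ((1 - q) / 2, q / 2, (1 - q) / 2, q / 2)  # pyrimidine-rich
    # primer 5' ends sit anywhere in their 45 bp zones, so realized amplicons
    # span roughly [spacer + 35, spacer + 90]; centering that range on the
    # target keeps candidates inside the +-tolerance window
    spacer_len = max(target - 62, 12)
    zone_a = biased_dna(rng, spec.zone_length, fwd_probs)
    spacer = random_dna(rng, spacer_len, spec.spacer_gc)
    zone_b = biased_dna(rng, spec.zone_length, rev_probs)
    return zone_a + spacer + zone_b


def _template_acceptable(
    tid: str,
    template: str,
    sets: List[PrimerSet],
    spec: FixtureSpec,
    accepted: Dict[str, str],
    accepted_primers: List[Primer],
    target: Optional[int] = None,
) -> bool:
    c = spec.constraints
    k = spec.interaction.seed_length
    if len(sets) < c.candidates_per_template:
        return False
    if target is not None and any(
        abs(ps.amplicon_size - target) > spec.amplicon_tolerance for ps in sets
    ):
        return False
    primers = _candidate_primers(sets)
    # every candidate 3' seed anchors exactly one site in its own template
    for p in primers:
        if _both_strand_count(template, p.sequence[-k:]) != 1:
            return False
    if not spec.ensure_clean:
        return True
    for p in primers:
        seed = p.sequence[-k:]
        for other in accepted.values():
            if _both_strand_count(other, seed) != 0:
                return False
    for q in accepted_primers:
        if _both_strand_count(template, q.sequence[-k:]) != 0:
            return False
    cutoff = spec.interaction.dimer_cutoff
    for ps in sets:
        f, r = ps.forward.sequence, ps.reverse.sequence
        if (dimer_dg(f, f) <= cutoff or dimer_dg(f, r) <= cutoff
                or dimer_dg(r, r) <= cutoff):
            return False
    for p in primers:
        for q in accepted_primers:
            if dimer_dg(p.sequence, q.sequence) <= cutoff:
                return False
    return True


def _plant_dimer_anchor(
    rng: np.random.Generator,
    spec: FixtureSpec,
    templates: Dict[str, str],
    candidate_sets: Dict[str, List[PrimerSet]],
    donor_tid: str,
    host_tid: str,
) -> Dict:
    """Write an 8-base 3'-complement anchor of a donor primer into the host's reverse zone.

    Returns the manifest entry.  The engineered partner is the reverse primer
    whose 3' end sits on the anchor; the designer may or may not select it,
    but the dimer classifier must flag the engineered pair.
    """
    donors = sorted(
        _candidate_primers(candidate_sets[donor_tid]),
        key=lambda p: perfect_duplex_dg(p.sequence[-8:]),
    )
    donor = donors[0]
    anchor = donor.sequence[-8:]
    if perfect_duplex_dg(anchor) > spec.interaction.dimer_cutoff - 0.3:
        raise FixtureError(
            f"no donor primer of {donor_tid} has a 3' octamer stable enough "
            f"({perfect_duplex_dg(anchor):.2f} kcal/mol) to plant a dimer anchor"
        )
    host = templates[host_tid]
    zone_b_start = len(host) - spec.zone_length
    k = spec.interaction.seed_length
    for s in range(zone_b_start + 4, len(host) - 8 - 4):
        planted = host[:s] + anchor + host[s + 8:]
        sets = design_primer_sets(planted, host_tid, None, spec.constraints, spec.conditions)
        if len(sets) < spec.constraints.candidates_per_template:
            continue
        ok = True
        for p in _candidate_primers(sets):
            seed = p.sequence[-k:]
            if _both_strand_count(planted, seed) != 1:
                ok = False
                break
            for tid, other in templates.items():
                if tid != host_tid and _both_strand_count(other, seed) != 0:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        templates[host_tid] = planted
        candidate_sets[host_tid] = sets
        partner_len = 20
        window_start = s
        partner = revcomp(planted[window_start : window_start + partner_len])
        return {
            "template": host_tid,
            "start": s,
            "end": s + 8,
            "anchor": anchor,
            "donor_template": donor_tid,
            "donor_primer": donor.sequence,
            "engineered_primer": partner,
            "expected_dimer_dg": round(dimer_dg(donor.sequence, partner), 4),
        }
    raise FixtureError(f"could not plant a dimer anchor into {host_tid}")


def _screened_pad_chunk(
    rng: np.random.Generator,
    length: int,
    forbidden: set,
    k: int,
    prev_tail: str,
    gc: float = 0.45,
    max_tries: int = 50,
) -> str:
    """A padding chunk none of whose k-mers (incl. the junction) is a primer seed."""
    for _ in range(max_tries):
        chunk = random_dna(rng, length, gc)
        joined = prev_tail + chunk
        if any(joined[i : i + k] in forbidden for i in range(len(joined) - k + 1)):
            continue
        return chunk
    raise FixtureError("could not sample a padding chunk avoiding every primer seed")


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a complete, manifest-documented synthetic design study."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    targets = spec.targets()

    templates: Dict[str, str] = {}
    candidate_sets: Dict[str, List[PrimerSet]] = {}
    accepted_primers: List[Primer] = []
    for i, target in enumerate(targets):
        tid = f"T{i + 1}"
        for _ in range(spec.max_template_tries):
            t = _zoned_template(rng, spec, target)
            sets = design_primer_sets(t, tid, None, spec.constraints, spec.conditions)
            if _template_acceptable(tid, t, sets, spec, templates, accepted_primers,
                                    target=target):
                templates[tid] = t
                candidate_sets[tid] = sets
                accepted_primers.extend(_candidate_primers(sets))
                break
        else:
            raise FixtureError(
                f"template {tid} (target {target} bp): no acceptable template in "
                f"{spec.max_template_tries} tries"
            )

    dimer_entries: List[Dict] = []
    for d in range(spec.n_dimer_plants):
        donor = f"T{(d % spec.n_templates) + 1}"
        host = f"T{((d + 1) % spec.n_templates) + 1}"
        if donor == host:
            raise FixtureError("dimer plants need at least two templates")
        dimer_entries.append(
            _plant_dimer_anchor(rng, spec, templates, candidate_sets, donor, host)
        )

    k = spec.interaction.seed_length
    seeds = set()
    for sets in candidate_sets.values():
        for p in _candidate_primers(sets):
            seeds.add(p.sequence[-k:])
            seeds.add(revcomp(p.sequence[-k:]))

    background: Dict[str, str] = dict(templates)
    decoy_entries: List[Dict] = []
    if spec.background_pad > 0:
        chunks: List[str] = []
        remaining = spec.background_pad
        while remaining > 0:
            size = min(500, remaining)
            tail = chunks[-1][-(k - 1):] if chunks else ""
            chunks.append(_screened_pad_chunk(rng, size, seeds, k, tail))
            remaining -= size
        pad = "".join(chunks)
        pos = 400
        a_len = spec.anchor_length
        tids = list(templates)
        for d in range(spec.n_decoys):
            ti = tids[d % len(tids)]
            tj = tids[(d + 1) % len(tids)]
            if ti == tj:
                raise FixtureError("decoys need at least two templates")
            ps_a = candidate_sets[ti][0]
            ps_b = candidate_sets[tj][0]
            fwd_anchor = ps_a.forward.sequence[-a_len:]
            rev_anchor = revcomp(ps_b.reverse.sequence[-a_len:])
            for _ in range(50):
                filler = random_dna(rng, spec.decoy_gap, 0.3)
                if not any(filler[x : x + k] in seeds for x in range(len(filler) - k + 1)):
                    break
            else:
                raise FixtureError("could not sample a decoy filler avoiding primer seeds")
            segment = fwd_anchor + filler + rev_anchor
            end = pos + len(segment)
            if end + 400 > len(pad):
                raise FixtureError("background_pad exhausted while planting decoys")
            pad = pad[:pos] + segment + pad[end:]
            expected_size = (
                spec.decoy_gap + ps_a.forward.length + ps_b.reverse.length
            )
            decoy_entries.append({
                "record": "BG1",
                "start": pos,
                "end": end,
                "pp": "PP5",
                "template_i": ti,
                "template_j": tj,
                "rank_i": 0,
                "rank_j": 0,
                "forward_primer": ps_a.forward.sequence,
                "reverse_primer": ps_b.reverse.sequence,
                "expected_size": expected_size,
            })
            pos = end + spec.interaction.max_amplicon + 200
        background["BG1"] = pad

    manifest = {
        "seed": spec.seed,
        "n_templates": spec.n_templates,
        "purine_bias": spec.purine_bias,
        "ensure_clean": spec.ensure_clean,
        "seed_length": k,
        "templates": [
            {
                "id": tid,
                "length": len(seq),
                "target_amplicon": targets[i],
                "n_candidate_sets": len(candidate_sets[tid]),
            }
            for i, (tid, seq) in enumerate(templates.items())
        ],
        "background_records": {rid: len(seq) for rid, seq in background.items()},
        "decoys": decoy_entries,
        "dimer_plants": dimer_entries,
    }
    return Fixture(spec, templates, background, candidate_sets, manifest)


def _write_fasta(records: Dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fixture(fixture: Fixture, outdir) -> Dict[str, Path]:
    """Write templates.fa, background.fa, regions.tsv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "templates": outdir / "templates.fa",
        "background": outdir / "background.fa",
        "regions": outdir / "regions.tsv",
        "manifest": outdir / "manifest.json",
    }
    _write_fasta(fixture.templates, paths["templates"])
    _write_fasta(fixture.background, paths["background"])
    with open(paths["regions"], "w") as fh:
        fh.write("# record_id\tstart\tend (1-based inclusive)\n")
        for tid, seq in fixture.templates.items():
            fh.write(f"{tid}\t1\t{len(seq)}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(fixture.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
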