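"""End-to-end orchestration: FASTA in, vetted PSC report out.

Stages run strictly in order — candidate design per template, dimer +
specificity vetting into the scoring matrix, graph-expanding PSC search, gel
modelling — and the pipeline itself uses no randomness, so identical inputs
reproduce byte-identical machine-readable outputs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml
from Bio import SeqIO

from .design import (
    DesignConstraints,
    Primer,
    PrimerSet,
    design_primer_sets,
    gc_content,
    primer_penalty,
    self_complementarity,
)
from .gel import GelModel
from .interaction import (
    CompatibilityMatrix,
    InteractionSettings,
    KmerIndex,
    build_index,
    build_scoring_matrix,
)
from .search import PSC, CompatibilityGraph, SearchFailure, enumerate_top_pscs
from .thermo import NNParameterTable, ReactionConditions, end_stability_dg, primer_tm, revcomp

__all__ = [
    "RunConfig",
    "RunResult",
    "read_fasta",
    "read_regions",
    "run",
    "run_files",
    "panel_to_primer_sets",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of one design run (file paths + all thresholds)."""

    templates_path: str
    background_path: str
    outdir: str
    regions_path: Optional[str] = None
    minbs: float = 3.0
    report_k: int = 15
    node_budget: int = 100_000
    render_png: bool = True
    abort_on_empty_template: bool = False
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    conditions: ReactionConditions = field(default_factory=ReactionConditions)
    interaction: InteractionSettings = field(default_factory=InteractionSettings)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a config mapping from YAML; keyword overrides win over the file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key, klass in (
            ("constraints", DesignConstraints),
            ("conditions", ReactionConditions),
            ("interaction", InteractionSettings),
        ):
            if isinstance(raw.get(key), dict):
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in raw[key].items()}
                raw[key] = klass(**sub)
        return cls(**raw)


@dataclass
class RunResult:
    """Everything a report needs: inputs, intermediates and the ranked PSCs."""

    templates: Dict[str, str]
    background: Dict[str, str]
    candidate_sets: Dict[str, List[PrimerSet]]
    matrix: Optional[CompatibilityMatrix]
    index: Optional[KmerIndex]
    pscs: List[PSC]
    gel: GelModel
    minbs: float
    settings: InteractionSettings
    attrition: Dict[str, Dict]
    diagnostics: List[str]

    @property
    def all_ps(self) -> List[PrimerSet]:
        return [ps for sets in self.candidate_sets.values() for ps in sets]


def read_fasta(path) -> Dict[str, str]:
    """Ordered id -> uppercase sequence; record id is the first token; duplicates error."""
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in records:
            raise ValueError(f"duplicate FASTA record id {rid!r} in {path}")
        records[rid] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_regions(path) -> Dict[str, Tuple[int, int]]:
    """record_id -> 0-based half-open allowed primer region (file is 1-based inclusive)."""
    regions: Dict[str, Tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected record_id<TAB>start<TAB>end")
            rid, start, end = parts
            s, e = int(start), int(end)
            if s < 1 or e < s:
                raise ValueError(f"{path}:{lineno}: bad 1-based interval {s}-{e}")
            regions[rid] = (s - 1, e)
    return regions


def run(
    templates: Dict[str, str],
    background: Dict[str, str],
    regions: Optional[Dict[str, Tuple[int, int]]] = None,
    constraints: Optional[DesignConstraints] = None,
    conditions: Optional[ReactionConditions] = None,
    settings: Optional[InteractionSettings] = None,
    minbs: float = 3.0,
    report_k: int = 15,
    node_budget: int = 100_000,
    gel: Optional[GelModel] = None,
    abort_on_empty_template: bool = False,
) -> RunResult:
    """Run design -> vetting -> matrix -> search -> gel on in-memory records."""
    constraints = constraints or DesignConstraints()
    conditions = conditions or ReactionConditions()
    settings = settings or InteractionSettings()
    gel = gel or GelModel.default()
    if not templates:
        raise ValueError("empty template set")
    diagnostics: List[str] = []
    attrition: Dict[str, Dict] = {}

    candidate_sets: Dict[str, List[PrimerSet]] = {}
    for tid, seq in templates.items():
        region = (regions or {}).get(tid)
        sets = design_primer_sets(seq, tid, region, constraints, conditions)
        attrition[tid] = {"candidate_sets": len(sets)}
        logger.info("template %s: %d candidate primer sets", tid, len(sets))
        if not sets:
            msg = f"template {tid}: no feasible primer set under the design constraints"
            diagnostics.append(msg)
            if abort_on_empty_template:
                raise RuntimeError(msg)
            continue
        candidate_sets[tid] = sets

    all_ps = [ps for sets in candidate_sets.values() for ps in sets]
    if len(candidate_sets) < 2:
        diagnostics.append("fewer than two templates with candidates; nothing to combine")
        return RunResult(templates, background, candidate_sets, None, None, [],
                         gel, minbs, settings, attrition, diagnostics)

    index = build_index(background, settings.seed_length)
    matrix = build_scoring_matrix(all_ps, index, settings)
    reason_counts = Counter(
        matrix.reasons[i][j].tag
        for i in range(len(all_ps))
        for j in range(i + 1, len(all_ps))
        if all_ps[i].template_id != all_ps[j].template_id and matrix.values[i, j] == 0
    )
    for tag, n in sorted(reason_counts.items()):
        diagnostics.append(f"matrix: {n} cross-template pairs blocked by {tag}")
        logger.info("matrix: %d pairs blocked by %s", n, tag)

    graph = CompatibilityGraph.from_matrix(matrix)
    try:
        pscs = enumerate_top_pscs(graph, minbs, gel, k=report_k, node_budget=node_budget)
    except SearchFailure as exc:
        pscs = []
        diagnostics.append(f"search: {exc}")
    if not pscs:
        diagnostics.append("no valid PSC found (see matrix reasons above)")
    return RunResult(templates, background, candidate_sets, matrix, index, pscs,
                     gel, minbs, settings, attrition, diagnostics)


def run_files(config: RunConfig) -> Tuple[RunResult, Dict[str, Path]]:
    """File-based entry point: read inputs, run the pipeline, write the report bundle."""
    from .report import write_report

    templates = read_fasta(config.templates_path)
    background = read_fasta(config.background_path)
    regions = read_regions(config.regions_path) if config.regions_path else None
    result = run(
        templates, background, regions,
        constraints=config.constraints, conditions=config.conditions,
        settings=config.interaction, minbs=config.minbs,
        report_k=config.report_k, node_budget=config.node_budget,
        abort_on_empty_template=config.abort_on_empty_template,
    )
    paths = write_report(result, config.outdir, render_png=config.render_png)
    return result, paths


def _locate(primer_seq: str, template: str, tid: str) -> Primer:
    """Locate a panel primer on its template and rebuild its cached properties."""
    fwd_pos = template.find(primer_seq)
    rc = revcomp(primer_seq)
    rev_pos = template.find(rc)
    if fwd_pos >= 0:
        strand, start = "+", fwd_pos
    elif rev_pos >= 0:
        strand, start = "-", rev_pos + len(primer_seq) - 1
    else:
        raise ValueError(f"primer {primer_seq} not found on template {tid!r}")
    tm = primer_tm(primer_seq)
    gc = gc_content(primer_seq)
    end_dg = end_stability_dg(primer_seq)
    s_any, s_3p = self_complementarity(primer_seq)
    c = DesignConstraints()
    pen = primer_penalty(tm, len(primer_seq), gc, s_any, s_3p, end_dg, c)
    return Primer(primer_seq, tid, strand, start, tm, gc, end_dg, s_any, s_3p, pen)


def panel_to_primer_sets(
    panel: Sequence[Tuple[str, str, str]],
    templates: Dict[str, str],
) -> List[PrimerSet]:
    """Rebuild PrimerSets from an existing panel of (template_id, fwd, rev) rows.

    Used by the ``check`` verb to vet primers designed elsewhere: each primer
    is located on its template (forward on the plus strand, reverse as a
    reverse complement) and its thermodynamic properties recomputed.
    """
    sets = []
    for rank, (tid, fwd_seq, rev_seq) in enumerate(panel):
        if tid not in templates:
            raise ValueError(f"panel references unknown template {tid!r}")
        fwd = _locate(fwd_seq.upper(), templates[tid], tid)
        rev = _locate(rev_seq.upper(), templates[tid], tid)
        if fwd.strand != "+" or rev.strand != "-":
            raise ValueError(
                f"panel pair for {tid!r}: expected forward on + and reverse on - strand"
            )
        size = rev.start - fwd.start + 1
        sets.append(PrimerSet(fwd, rev, size, fwd.penalty + rev.penalty, rank=0))
    return sets
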