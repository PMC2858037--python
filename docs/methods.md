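# Methods

## Duplex thermodynamics

Duplex stability uses the unified Watson–Crick nearest-neighbor (NN)
parameter set (ΔH° in kcal/mol, ΔS° in cal/(mol·K) per dinucleotide stack,
initiation terms keyed on the terminal A:T or G:C pair, and an entropic
symmetry correction for self-complementary duplexes), shipped as the
versioned resource `data/nn_unified.tsv`. The working ΔG°₃₇ is recomputed
exactly as ΔH° − 310.15·ΔS°/1000 at load time; the file's ΔG column is a
checksum validated to 0.01 kcal/mol. Only perfect Watson–Crick stacks carry
parameters: mismatches, bulges, dangling ends and hairpin folding are out of
scope and simply interrupt a stack run.

The duplex ΔG°₃₇ of an ungapped alignment is the sum of stack terms over
consecutive complementary columns, plus initiation at the first and the last
matched pair of the whole alignment, plus the symmetry term when the two
strands are the same molecule. Consequently two disjoint complementary runs
in one alignment together pay exactly one pair of terminal initiations; this
convention is frozen by the oracle-equivalence tests. An alignment with no
complementary column scores 0.

Melting temperature is two-state:
Tm = 1000·ΔH° / (ΔS° + R·ln(C_T/x)) − 273.15, R = 1.987 cal/(mol·K),
x = 4 for non-self-complementary oligos and 1 (plus the symmetry ΔS°) for
self-complementary ones. Salt enters through the entropy correction
ΔS° += 0.368·(N−1)·ln[Na⁺]eq over the N−1 stacks, with
[Na⁺]eq = [monovalent] + 120·√([Mg²⁺] − [dNTP]) (mM inside the root).

Default reaction conditions: C_T = 50 nM, 50 mM monovalent, 1.5 mM Mg²⁺,
0.6 mM dNTP. The divalent terms are on by default deliberately: with a pure
50 mM monovalent correction, 18–27-mers at 45–55 % GC melt mostly at
52–56 °C and the default 57–63 °C acceptance window would be nearly empty;
the chosen defaults are the classic singleplex-design conditions under which
that window is meaningful. Setting `divalent=0` recovers a pure monovalent
model. All ΔG-based cutoffs (−7, −9, 9.0 kcal/mol) are interpreted at 37 °C
and include initiation terms.

## Candidate design

Enumeration is exhaustive over (start, length, strand) windows — no
heuristics — so on small templates the candidate set is verifiable against a
brute-force scan. A vectorised prefix-sum prescreen (GC exactly; Tm with a
1.5 °C safety margin that covers the palindrome x=1 shift) trims windows;
every survivor's properties are recomputed with the scalar thermodynamic
routines, which are authoritative. Filters: length 18–27 bp, Tm 57–63 °C, GC
45–55 % (the stricter of the two conventional GC windows; both are
configurable), |ΔG°₃₇| of the 3′ pentamer ≤ 9.0 kcal/mol, self-complementarity
≤ 8.0 and 3′ self-complementarity ≤ 3.0.

Self-complementarity is an ungapped alignment of the oligo against itself in
annealing orientation, +1 per complementary pair and −1 per mismatch,
maximised over all offsets and floored at 0; the 3′ score restricts the
maximum to offsets whose overlap includes the 3′-terminal base. This scores
in units where the historical 8.0/3.0 caps are meaningful.

The single-primer penalty is a weighted sum of deviations from the optima
(range midpoints: Tm 60 °C, size 22 bp, GC 50 %): 1.0/°C, 1.0/bp, 0.5/GC-%,
0.25 per self-complementarity unit (both scores), 0 per kcal/mol of 3′-end
stability (a hard filter only). Weights only need to induce a stable
ranking; they are exposed in `PenaltyWeights`. A pair's penalty is the sum of
its two primers' penalties; pairs with ΔTm > 3 °C are rejected rather than
scored. Pairing requires non-overlapping footprints and a 100–500 bp product
measured 5′-end to 5′-end inclusive. Ties break lexicographically by
(amplicon size, forward start, forward sequence) so output is deterministic.
Before pairing, each strand is capped at its best 200 candidates by
single-primer penalty to bound the quadratic step (configurable).

Coordinates are 0-based half-open internally; the regions side file and
human-readable reports are 1-based inclusive. Non-ACGT bases are rejected in
primers and simply void the enclosing window in templates; degenerate-primer
design is explicitly out of scope.

## Dimer and specificity screening

`dimer_dg` minimises duplex ΔG°₃₇ over every ungapped relative offset of two
oligos in annealing orientation (no bulges or loops); a pair is a dimer at or
below −7 kcal/mol. The cutoff includes initiation terms, since the duplex ΔG
convention does.

A binding site requires an exact 3′-terminal seed match (9 nt default, via a
both-strand k-mer hash of the background) with the whole primer footprint
inside the record, and full-extension ΔG°₃₇ ≤ −9 kcal/mol (aligned with the
3′-stability criterion). Amplicons are plus-strand sites upstream of
minus-strand sites on one record, size 5′-to-5′ inclusive, capped at 2000 bp
(beyond that a nonspecific product is considered unamplifiable). The 2000 bp
cap, seed length and binding threshold are all configurable; there is no
mismatch tolerance in the seed and no gapped alignment, so sensitivity is
governed by the seed length. No external alignment tool is involved; the
k-mer + thermodynamics path is the single specificity engine.

Two PSs may share a tube iff: both pass step one (their own pair yields
exactly the intended amplicon — an absent intended amplicon is flagged as a
template/database mismatch, distinct from nonspecificity), none of the ten
unordered pairings of their four primers (including self-pairs) is a dimer,
and none of the four cross pairs PP3–PP6 yields any amplicon. Checks run in
that order and the reported reason names the first failure. A PS failing
step one is disqualified globally (every cross cell involving it is 0) and
logged. Same-template cells are structurally excluded from selection rather
than scored 0, so cell diagnostics stay meaningful. The O(N²) matrix is
computed once with per-primer site caching and per-pair dimer caching.

## PSC search

Candidate PSs form a graph (node = PS with its penalty; edge = matrix value
1). The search grows a clique one template at a time — templates ordered
most-constrained first (fewest candidates, then input order), candidates in
ascending penalty — admitting a node only if it connects to every member and
keeps MinBS satisfied, backtracking chronologically on dead ends. The first
solution is the greedy PSC; the search then continues past it (bounded by a
node-admission budget, default 10⁵, since the underlying problem is
NP-complete), deduplicates solutions by member set, sorts by total penalty
with (member ranks, amplicon sizes) tie-break, and reports the best 15 by
default. Because candidates are pre-selected per template, results are
locally — not globally — optimal; tests therefore assert validity and
greedy consistency, and on exhaustively enumerable instances the greedy-first
solution is additionally confirmed against the global optimum. An
independent validator re-checks every emitted PSC (clique, one PS per
template, MinBS); failure to cover a template raises an explicit error
naming the first uncoverable template.

## Gel model

Migration distance follows the log-size law distance = a − b·ln(size + c),
fitted by least squares to a shipped 1 % agarose calibration ladder
(100 bp–3 kb, 60 mm lane); the fitted parameters are stored as the versioned
resource `data/gel_model_1pct.tsv` and the refit is exercised in tests.
Distances are clamped to the lane and sizes outside the calibrated range
raise an extrapolation warning. Other gel recipes are supported by fitting a
user ladder with `GelModel.fit`. MinBS is the minimum pairwise distance
difference among a combination's amplicons (+∞ for a single band); the
default acceptance threshold is 3 mm — a visually separable spacing on a
60 mm lane — and is configurable, as no canonical value exists. The text
gel rendering is byte-stable for golden-file testing; the PNG is a
convenience view.

## Synthetic fixtures: what they emulate and what they do not

The generator builds zoned templates — a forward primer zone, an AT-rich
spacer that fails the GC/Tm filters, a reverse primer zone — so each
template's amplicon size is controlled by its spacer. Default targets are
geometrically spaced (ratio 1.28 from 100 bp) because gel distance is
logarithmic in size: with every candidate amplicon screened to ±15 bp of its
target, every combination clears the 3 mm MinBS by construction. With
`purine_bias` (default 0.8 in clean mode) the forward zone is A/G-rich and
the reverse zone C/T-rich, so all designable primers are purine-rich and
cannot form long Watson–Crick runs with one another — the dominant dimer
channel is suppressed structurally, not by filtering, while GC stays near
50 % because G and C appear at equal rates. Clean mode additionally screens
accepted templates so that every candidate's 3′ seed occurs exactly once in
its own template and nowhere in the others, and that the designed candidate
pool is dimer-free; a clean zero-decoy fixture therefore produces an all-ones
cross-template matrix by construction. Decoys are planted by copying the 3′
dozen bases of two chosen primers into a padding record at amplifiable
spacing (consecutive decoys sit farther apart than the 2000 bp amplicon cap
so they cannot combine into undeclared products); dimer-prone material is
planted as an 8-base 3′-complementary anchor — deliberately below the 9 nt
seed so the dimer and specificity channels stay decoupled — and the manifest
records the engineered dimerizing pair. Everything derives from one integer
seed and is bit-reproducible; the pipeline itself uses no randomness.

These fixtures emulate the structure of a real design problem (multiple
targets, a large background, decoy binding sites, dimer-prone oligos) but
not real genomic sequence statistics: no repeats, no homopolymer tracts, no
compositional skew beyond the engineered zones, and backgrounds of tens of
kilobases rather than gigabases. Passing tests therefore demonstrate
correctness of the algorithms under controlled conditions, not recall on a
real transcriptome; on real data the same engines simply see more seeds and
more sites.

## Numerical and design choices

- Amplicon size is measured 5′ end to 5′ end inclusive everywhere.
- Float-formatted outputs are fixed to 4 decimals; JSON/TSV iteration orders
  are sorted, making machine-readable outputs byte-stable.
- The NN oracle-equivalence tests pin the implementation to 1e-6 of the
  stated conventions; a cross-check against an independent NN implementation
  (Biopython's melting-temperature module, same unified table, with the
  strand-excess concentration expressed as C_T/4) agrees to 1e-6 °C.
- Problem sizes in tests and the acceptance script (600 bp templates, ~20 kb
  decoy backgrounds, 3–5-plex panels, 3-candidate hand instances) are chosen
  so every brute-force oracle remains exhaustively enumerable.
- Known limitations: no hairpin/secondary-structure energies, no mismatch or
  gapped binding-site model, no multi-tube partitioning when no single-tube
  PSC exists, and single-calibration gel (1 %) unless a user ladder is
  supplied.
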