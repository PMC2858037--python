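# plexprimer

Multiplex PCR amplifies several target regions in one tube, one primer set
(PS: a forward + a reverse primer) per target. Designing the primers is much
harder than for singleplex PCR: every primer must avoid dimerizing with every
other primer, none of the ~2k oligos may co-amplify anything unintended from
the genomic or transcript background, and the amplicons must land far enough
apart on an agarose gel to be told apart by eye. `plexprimer` is a toolkit
for molecular biologists and pipeline authors that designs, vets and ranks
**primer set combinations** (PSC: one PS per template, all mutually
compatible) for such assays.

## Method

1. **Candidate design.** For each template, every primer window on both
   strands is enumerated and filtered on the multiplex defaults: Tm 57–63 °C,
   length 18–27 bp, GC 45–55 %, 3′-pentamer stability |ΔG°₃₇| ≤ 9.0 kcal/mol,
   self-complementarity ≤ 8.0 and 3′ self-complementarity ≤ 3.0. Surviving
   forward/reverse pairs with product size 100–500 bp and ΔTm < 3 °C are
   scored by a penalty (weighted deviations from the optima; smaller is
   better) and the best five PSs per template are kept.
2. **Thermodynamics.** ΔG°₃₇ and Tm come from the unified Watson–Crick
   nearest-neighbor model: ΔG°₃₇ = ΔH° − 310.15·ΔS°/1000 summed over stacks
   plus initiation and symmetry terms, and
   Tm = 1000·ΔH° / (ΔS° + R·ln(C_T/x)) − 273.15 with the sodium-equivalent
   entropy salt correction.
3. **Dimer check.** For any two oligos the minimum duplex ΔG°₃₇ over all
   ungapped annealing offsets is computed; at or below **−7 kcal/mol** the
   pair is a dimer.
4. **Two-step specificity.** A primer binds the background database wherever
   its 3′-terminal 9-mer seed matches exactly and the full ungapped extension
   is stable (ΔG°₃₇ ≤ −9 kcal/mol). For two PSs *i*, *j* six primer pairs are
   screened: each PS's own pair (PP1, PP2) must produce exactly its intended
   amplicon, and the four cross pairings (PP3: FᵢFⱼ, PP4: RᵢRⱼ, PP5: FᵢRⱼ,
   PP6: RᵢFⱼ) must produce no product ≤ 2000 bp.
5. **Scoring matrix and graph search.** The results fill a symmetric 0/1
   compatibility matrix over all candidate PSs (1 = no dimer, no nonspecific
   amplicon). On the graph it induces — node = PS, edge = compatible — a
   greedy, penalty-ordered clique expansion with backtracking assembles PSCs,
   subject to **MinBS**: the minimum pairwise difference in predicted gel
   migration (distance = a − b·ln(size + c), calibrated on a 1 % agarose
   ladder) must clear 3 mm. The best 15 PSCs by total penalty are reported,
   with a text and PNG virtual electrophotogram.

## Worked example

Generate a synthetic two-target study and design a panel:

```sh
plexprimer fixture --out fx -k 2 --seed 3 --pad 800
plexprimer design --templates fx/templates.fa --background fx/background.fa --out out
```

The run prints `15 PSC(s) written to out/report.txt`; the report begins:

```
## PSC 1  (total penalty 2.9901, MinBS 5.68 mm)
  T1 [cand 0]  amplicon 105 bp  penalty 1.6238
    F 5'-AGTACGGTAGGAGAGTGAACGA-3'  Tm 60.03 C  GC 50.0%  len 22
    R 5'-GCACAGAAGAAGGAAGAAAGCG-3'  Tm 60.10 C  GC 50.0%  len 22
  T2 [cand 0]  amplicon 161 bp  penalty 1.3663
    F 5'-AGGGAGGAGAAGAAGGGAAGAA-3'  Tm 59.89 C  GC 50.0%  len 22
    R 5'-CGGGAAAGAAGGGGAAGTTGTT-3'  Tm 60.75 C  GC 50.0%  len 22
    pairwise checks: all member pairs compatible (no dimer, no nonspecific amplicon)
```

Read: the top-ranked combination pairs each template's lowest-penalty PS
(`cand 0`), the two amplicons (105 and 161 bp) migrate 5.68 mm apart on the
modeled 1 % gel (> the 3 mm MinBS threshold), all four primers sit on the Tm
optimum of 60 °C at 50 % GC, and all pairwise dimer/cross-amplification
checks passed. `out/` also holds machine-readable twins (`pscs.json`,
`pscs.tsv`), the compatibility matrix with per-cell reasons (`matrix.tsv`,
`matrix_reasons.tsv`), primer binding sites (`binding_sites.bed`) and the
virtual gel (`virtual_gel.txt`/`.png`). `plexprimer check` vets an existing
primer panel the same way, and `plexprimer gel --sizes 120,260,410` renders a
gel for arbitrary fragment sizes.

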