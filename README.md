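# arctail

Analysis pipeline for characterizing the C-terminal tail of the neuronal
protein **Arc/Arg3.1** — a ~396-residue immediate-early gene product central
to synaptic plasticity and memory. Arc's capsid domain (N-lobe + C-lobe,
~residues 206–364) is structurally ordered, while its C-terminal tail is
divergent and intrinsically disordered. `arctail` packages the four
computational analyses that establish this, for anyone who wants to run them
on Arc orthologs, on the deposited NMR chemical-shift tables, or on related
proteins:

1. **Ortholog conservation** — align an ortholog family, flag every
   non-unanimous alignment column, and compute the *variation rate* of a
   region: the fraction of variant columns among its reference positions
   (rat numbering). The tail (351–396) is far more variable than the rest
   of the protein or the N-lobe (207–277).
2. **PEST degradation signal** — scan for stretches rich in P, E, S, T (and
   D) between positively charged flanks, scored with the classical
   PEST-FIND statistic

   `score = 0.55 · DEPST − 0.5 · HI`

   where `DEPST` is the corrected mass-percent of D/E/P/S/T in the region
   and `HI` a mass-weighted, non-negatively rescaled Kyte–Doolittle
   hydropathy index; scores ≥ +5 mark *potential* degradation signals.
3. **ΔCα secondary chemical shifts** — `ΔCα(i) = Cα_obs(i) − Cα_rc(type i)`
   against a random-coil reference table; sustained positive runs mark
   α-helix, sustained negative runs β-strand, small/discrete values random
   coil. Segmenting the C-lobe + tail construct (residues 280–396) yields
   five helices and a terminal coil segment whose start residue is the
   disordered-tail boundary (D357).
4. **Chemical shift perturbation (CSP)** — between two constructs sharing a
   residue range, `CSP(i) = √(ΔH(i)² + ΔN(i)²/5)` over backbone amides;
   residues above mean + 2·SD are flagged. Perturbations confined to the
   inter-domain junctions (282–285, 362–363) indicate minimal interaction
   between the capsid domain and the tail.

Input formats: FASTA (plain or aligned) and NMR-STAR v3.x assigned
chemical-shift loops (BMRB depositions). A fully seeded synthetic-data
module generates stand-in inputs with the same statistical structure —
ortholog families with region-specific substitution rates, shift tables
with planted helix/coil patterns, construct pairs with planted junction
perturbations, PEST-compliant implants — so the entire pipeline runs and
is testable offline.

## Worked example

```sh
cat > config.yaml <<EOF
conservation: {synthetic: true}
pest:         {synthetic: true}
chemshift:    {synthetic: true}
csp:          {synthetic: true}
EOF
arctail report --config config.yaml --seed 11 --out-dir out
```

prints (and writes `out/report.json`, `out/report.txt`):

```
arctail 0.1.0 (seed 11)

[conservation]
  c_terminal_tail       21/46  variant columns  rate 45.6%
  rest_of_protein       41/350 variant columns  rate 11.7%
  n_lobe                 5/71  variant columns  rate 7.0%

[pest]
  SYN_ARC: 12-24 score -20.21 (poor)
  SYN_ARC: 187-203 score -9.80 (poor)
  SYN_ARC: 205-228 score -11.87 (poor)
  SYN_ARC: 230-249 score -9.94 (poor)
  SYN_ARC: 291-319 score -13.01 (poor)
  SYN_ARC: 351-392 score +15.70 (potential)

[chemshift]
  helices: 5  strands: 0
  tail start: D357
```

Reading it: in this one simulated nine-member family, 21 of the 46
C-terminal-tail columns are not unanimous (45.6% — single-family draws
scatter around the planted 39.1%), against 11.7% elsewhere and 7.0% in the
N-lobe. The only *potential* PEST region spans 351–392 with score +15.70.
The ΔCα segmentation finds five helices, no strand, and a terminal coil
segment starting at D357; the CSP comparisons flag only the junction
residues 282–285 and 362–363.

Each stage is also a subcommand (`conserve`, `pest`, `cs-delta`,
`cs-segment`, `csp`, `simulate`) and a plain library call — see
`docs/methods.md` for the model details and defaults.

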