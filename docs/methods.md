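# Methods

This note documents the models behind each `arctail` stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Coordinates and data model

All residue numbering is 1-based in full-length rat Arc coordinates
(1–396). Subdomain constructs (280–396, 208–396, 280–363) keep full-length
numbering: the NMR-STAR reader takes residue numbers from the author
sequence-code column (`Auth_seq_ID`), which is where BMRB depositions of
subdomain constructs carry full-length numbering, falling back to
`Seq_ID`/`Comp_index_ID` when author codes are absent; the column actually
used is recorded on the returned table (`numbering_source`) so a
construct-locally numbered deposition is visible and can be remapped by the
caller. Construct-local numbering is never exposed downstream.

Tables are written with 4-decimal floats; TSV output round-trips to
identical values at that precision.

## Conservation and the variation rate

A family is either compared positionally (all sequences equal length — the
common case for mammalian Arc orthologs) or globally aligned with MAFFT
(`--auto`), with the engine recorded in the family metadata. A column is
**variant** iff the members are not unanimous: any gap, any `'X'`, or more
than one residue symbol makes it variant. This all-or-nothing definition is
the one consistent with the region arithmetic — a 46-column tail at rate
0.391 implies exactly 18 variant columns, 350 columns at 0.123 imply 43,
and 71 N-lobe columns at 0.070 imply 5 — which the test suite verifies by
direct construction. The majority residue breaks ties in favour of the
reference residue, then alphabetically, so the profile is deterministic.

The **variation rate** of a region is (variant columns)/(region length).
"Rest of the protein" is the complement of the tail, positions 1–350.
The statistic is permutation-invariant in the members and additive in
variant counts over disjoint regions; both are property-tested.

`disorder_index` is deliberately simple plumbing: for a sliding window
(default 21, odd, truncated at termini) it computes the distance of
(mean absolute net charge, mean normalised Kyte–Doolittle hydropathy) from
the charge/hydropathy order–disorder boundary line,
`d = (<R> + 1.151)/2.785 − <H>`, positive = disorder-like. It exists as a
built-in cross-check only and is not a substitute for dedicated disorder
predictors, which are out of scope.

## PEST scan

Candidates are maximal stretches strictly between positively charged
residues (K, R, H) or the termini, length ≥ `min_window` (default 10), and
must contain ≥1 P, ≥1 of {D, E} and ≥1 of {S, T}; content failures are
reported as `invalid` rather than silently dropped. Scoring:

* `DEPST` = 100 × (mass of D/E/P/S/T residues − correction) / (total
  region mass), with the correction subtracting one equivalent each of
  (D|E), P and (S|T); the pair equivalents are taken as the pair's mean
  residue mass. Standard average residue masses (Da, residue = amino acid
  − water) are tabulated in `pest.AVERAGE_RESIDUE_MASS` and pinned by the
  frozen-oracle test.
* `HI` = mass-weighted mean of `ltkdhi = 10·KD + 45`, the Kyte–Doolittle
  scale rescaled to [0, 90] (Ile → 90, Arg → 0).
* `score = 0.55·DEPST − 0.5·HI`; `potential` at score ≥ +5.0 (default),
  otherwise `poor`.

These conventions follow the classical PEST-FIND formulation as
popularised by EMBOSS `epestfind`; where that tool leaves details
ambiguous (the exact equivalent-mass convention, integer vs float
`ltkdhi`), the choices above are fixed, documented, and pinned by a frozen
independent hand computation on a 14-mer (`EPESTDSSAQPTAE` between K
flanks: DEPST 59.2004 mass-%, HI 26.7366, score +19.1919). The score
identity is re-verified from the stored fields of every emitted region.

## ΔCα secondary shifts and segmentation

The random-coil Cα reference is a Wishart-style peptide table shipped as
`WISHART_RANDOM_COIL_CA` (provenance-labelled, swappable via
`RandomCoilReference`); no sequence-neighbour correction is applied — the
comparison is a plain per-residue subtraction. Changing the reference table
shifts every ΔCα by per-type constants, so the segmentation thresholds and
the table choice interact; this is why the table is explicit.

Classification: helix if ΔCα > `pos_thresh`, strand if < `neg_thresh`,
else coil. Defaults ±0.05 ppm. **This band is roughly an order of
magnitude smaller than the ±0.5–0.7 ppm customary for Cα secondary
shifts**; it is usable only on data whose coil values genuinely sit inside
it. Both readings (±0.05 and ±0.5) are exercised by the tests and reported
by the acceptance script; with the shipped generator defaults both give
identical segmentations.

"Continuous" is operationalised as `min_run = 4` consecutive same-class
residues (one helical turn); shorter helix/strand runs are relabelled coil.
Unobserved residues (prolines, the first two residues of a construct,
unassigned positions) are missing data: they inherit the state of their
flanking classified neighbours when those agree and become coil otherwise,
so a data gap never splits an otherwise continuous segment. With
`min_run = 1` and thresholds at 0 the segmentation reduces exactly to the
sign pattern of the profile (property-tested). The disordered-tail start is
the first residue of the final coil segment when — and only when — the
construct ends in coil; a construct ending in helix returns a "no terminal
tail" result rather than raising.

Recovery study (also run by the acceptance script): 200 replicate tables
of the 280–396 construct, planted five-helix pattern of magnitude
+2.5 ppm, uniform Gaussian noise σ = 0.3 ppm on every residue,
classification at ±0.5 ppm / `min_run` 4. Mean per-residue state accuracy
is ≈ 98% and the mean absolute tail-start error ≲ 0.3 residues. The
±0.5 ppm reading is used for this study because the noise was planted at
6× the ±0.05 band — inside that band per-residue classification carries no
information and only the run-length filter would be doing the work.

## CSP

`CSP = √(ΔH² + ΔN²/5)` with the nitrogen divisor fixed at 5 (≈ 1/√5
weighting). Pairing requires both H and N in both tables at the same
residue number; type mismatches and incomplete amides are excluded *and
reported*, never silently dropped. The profile is symmetric in its inputs,
absolutely homogeneous of degree 1, and satisfies
`CSP² = ΔH² + ΔN²/5` exactly — all property-tested over random pairs.

"Major" perturbation has no universal cutoff; the default rule flags
CSP > mean + 2·SD over the profile (population SD), with an absolute-cutoff
rule available, and the rule plus effective threshold echoed in every
output. A degenerate all-equal profile yields an empty set with a warning.
Junction residues are flagged, not excluded: their perturbation is the
informative signal that the removed domain touches only its immediate
neighbourhood.

## Synthetic data: what it emulates, what it does not

Every generator takes a mandatory seed (one `numpy` generator per call, no
global state), returns machine-readable truth alongside the data, and is
byte-deterministic. Defaults define the simulated study conditions:

* **Families** — nine members, 396 columns, gapless; per-column variant
  probability 0.391 in the tail (351–396), 0.070 in the N-lobe (207–277)
  and 0.1365 elsewhere in 1–350, the unique value making the 1–350 average
  0.123 given the N-lobe rate. A variant column mutates one random
  non-reference member to a uniformly drawn different residue — an
  alphabet-agnostic substitution model sufficient for rate recovery, *not*
  a phylogenetic model: no tree, no rate heterogeneity among members, no
  indels, no back-substitution structure.
* **Shift tables** — construct 280–396, five helices (281–289, 293–304,
  308–319, 323–337, 342–356) matching a five-helix C-lobe bundle, coil
  from 357. Helix ΔCα +2.5 ± 0.3 ppm; coil ΔCα uniform within the
  ±0.05 ppm insignificance band, plus occasional (p = 0.05) isolated
  "discrete" outliers of 0.1–0.5 ppm that are never placed flush against a
  planted helix — an outlier touching a helix is indistinguishable from
  helix extension under any threshold rule, so it would not be "discrete".
  The first two construct residues and all prolines are omitted, as in
  real assignments. Not emulated: residue-type-dependent shift
  dispersions, neighbour effects, chemical exchange, assignment errors.
* **CSP pairs** — amide noise σ_H = 0.01 ppm, σ_N = 0.05 ppm (spectral
  reproducibility scale); junction offsets (ΔH, ΔN) = (0.15, 0.6) ppm,
  typical of contact-site perturbations and large enough that the flagged
  set is a property of the planted structure rather than of the seed.
* **PEST implant** — a mixed D/E/P/S/T-plus-small-neutral template cycled
  over 351–392 between lysine flanks at 350/393; the synthetic Arc-like
  backbone is otherwise uniform-random with an aspartate forced at 357.

Consequently, passing tests demonstrate that the *methods* recover planted
truth under realistic noise and reproduce the arithmetic of the region
statistics exactly; they do not certify performance on real depositions,
where numbering conventions, missing data patterns and shift dispersions
are messier. The readers for those real formats are tested on hand-written
fixtures, and `fetch_cached` can pull real accessions when a network is
available.

## Problem sizes and runtime

Defaults used by the test suite and `scripts/acceptance.py`: 300 replicate
families for the rate estimates (standard error ≈ 0.4 percentage points on
the tail rate), 500 for the binomial-calibration check, 200 replicates for
the segmentation recovery study, single seeded instances for the
segmentation/PEST/CSP endpoint checks. The full suite runs in a few
seconds on one CPU; the acceptance script in about one second.

## Known limitations

* The conservation stage treats all ortholog sets as star-shaped samples;
  no phylogenetic weighting (a non-goal).
* PEST scoring constants beyond the published 0.55/−0.5 weights follow one
  documented reading of the PEST-FIND conventions; other implementations
  may differ by a few score units on the same region.
* The ΔCα stage uses Cα only; CB/CO/HA-based indices and chemical-shift
  order parameters are out of scope.
* The mean + 2·SD CSP rule is sensitive to the fraction of perturbed
  residues (they inflate their own threshold); for profiles where many
  residues are perturbed, use the absolute-cutoff rule.
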