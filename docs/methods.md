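# Methods

This note documents the models implemented in pistolkit, their assumptions,
the defaults that matter, and the choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and alphabets

All public coordinates are 1-based inclusive, in either `transcript` or
`cds` frame; the internal 0-based representation is confined to
`Region.to_slice()` and audited by a round-trip test.  Sequences are held
as RNA; DNA input is normalised (T→U) with the source alphabet recorded so
FASTA output can restore it.  IUPAC ambiguity codes are rejected by default
or, on request, masked to N; masked positions can neither pair in the
folding model nor be reported as cleavage sites.

A published site list rarely states whether positions index the G or the U
of the GU dinucleotide, or which frame they count in.
`scanner.calibrate_convention` resolves this empirically: it returns every
(frame, anchor) convention under which all listed positions land on GU.
For the bundled synthetic target the G-indexed CDS-frame convention holds,
and that is the toolkit's default convention everywhere (`position` = index
of the G).

## Accessibility model

The scanner ranks GU sites by how unpaired they are in the thermodynamic
ensemble of a local window.  The ensemble is computed with a
McCaskill-style inside–outside partition function over *nested* secondary
structures with Watson–Crick and GU wobble pairs and a deliberately simple
energy model:

- per-pair formation free energies: GC −3.0, AU −2.0, GU −1.0 kcal/mol;
- minimum hairpin loop of 3 unpaired bases; loops otherwise free;
- temperature 37 °C (RT ≈ 0.616 kcal/mol), all exposed in `EnergyModel`.

The inside recursion is `Z(i,j) = Z(i+1,j) + Σ_k w(i,k)·Z(i+1,k−1)·Z(k+1,j)`
with `w = exp(−ΔG/RT)`; pair probabilities come from the matching outside
recursion (an inside–outside pass over the interval grammar, O(n³) with
vectorised inner sums).  All arithmetic is carried in log space, so results
stay finite for windows of several hundred nucleotides — verified in the
tests on a GC-rich 300-mer.

Why this model rather than a full nearest-neighbour engine: the scanning
decision only needs a *ranking* of sites by unpaired probability, and a
per-pair model is exactly checkable against exhaustive Boltzmann
enumeration.  The test suite enumerates every structure for sequences up to
14 nt and requires agreement of Z, P(i,j) and q(i) to 1e-9 relative.  The
model deliberately omits stacking context, loop penalties, dangles and
pseudoknots; it is not a substitute for a Turner-model engine when absolute
free energies matter.

Folding windows default to 120 nt centred on the site (clipped at ends):
local structure governs arm hybridisation, and window size is exposed in
`ScanConfig`.  The site score is a weighted mean of unpaired probabilities
over the GU dinucleotide and the two arm footprints (equal weights by
default, normalised so a fully unpaired window scores 1).  Ranking is a
stable sort, score descending, position ascending on ties — the toolkit
exposes a ranking, not an accessibility cutoff.

## Construct assembly

A scaffold file declares the catalytic core, the P2 stem and pseudoknot
pair lists, conserved positions, and its own numbering for the two
catalytic positions.  The bundled default (`data/scaffold_synthetic.txt`)
is a synthetic pistol-like core — it has the architecture (P2 hairpin,
complementary pseudoknot, catalytic G/C) but is not a natural or
crystal-structure sequence; users supply their own file for real
constructs.  With the default 8-nt P1 arm the catalytic positions fall at
construct positions 40 and 41.

Arms are exact reverse complements of the substrate flanks: the P3 arm
binds the `p3_len` nucleotides ending at the G, the P1 arm the `p1_len`
nucleotides starting at the U, so the GU sits at the junction of the two
intermolecular duplexes and the assembled ribozyme reads
`p1_arm + core + p3_arm` (5′→3′, antiparallel to the substrate).  "P3
length" counts intermolecular pairs only, not closing pairs.  Only the P3
length is screened by `arm_length_series` (P1 fixed by the scaffold),
mirroring how such libraries are optimised.  The M5 control mutates G→U
and C→A at the catalytic positions and nothing else, so it binds but
cannot cleave; `simulate_cleavage` returns an explicit no-cleavage outcome
for it.

The scissile bond is placed 3′ of the G by default (`cut_offset`
configurable), which reproduces the reference geometry of a 46-nt substrate
cut into 29 + 17 nt fragments when the G is the 29th base of the window.
Products are annotated with the pistol chemistry (2′,3′-cyclic phosphate /
5′-hydroxyl).

## Off-target screen

The arms' joint binding footprint (revcomp(P3 arm) + revcomp(P1 arm), GU at
the junction) is searched against a transcriptome with an ungapped
seed-and-extend scan: an exact 12-nt seed centred on the GU junction, then
full-footprint extension tolerating ≤2 mismatches.  A hit also reports
whether the matched segment itself carries GU at the junction — without it
the segment can be bound but not cleaved.  The scan is cross-checked
against an exhaustive sliding-window oracle in the tests; with seed =
footprint and 0 mismatches it reduces to exact string search.  This is a
guide-design-style complementarity screen, not a local aligner: no gaps,
no scoring matrix.

## Kinetics

Fraction cleaved from gel bands is `P/(P+S)` on raw intensities; with
`normalize_by_length` intensities are first divided by fragment length
(mass-proportional stains) and the product amount is the mean over product
bands, since one cleavage event yields one of each fragment.  Fractions are
scale-free: multiplying all intensities in a lane by a constant changes
nothing downstream.

Time courses are fitted to F(t) = F∞·(1 − e^(−k_obs·t)) by bounded
derivative-based least squares with an analytic Jacobian, deterministic
data-derived initialisation (F∞ from the response maximum; k from a
through-origin log-linear regression of the pre-plateau points), tolerances
1e-10 and ≤500 iterations — reproducibility over cleverness; identical
inputs give bit-identical parameters.  F∞ is fitted by default because
gels rarely reach 100% cleavage; `plateau_mode="fixed_1"` pins it, and the
mode used is echoed in every output.  Standard errors come from the
Jacobian at the optimum.  Units are minutes and min⁻¹ throughout.

Metal-condition comparisons are pairwise k_obs ratios per shared
concentration, satisfying ratio(a,b)·ratio(b,a) = 1.

Dose-response tables (nM vs percent inhibition) are fitted with a
four-parameter log-logistic model, R(c) = bottom + (top − bottom)/(1 +
(IC50/c)^hill), on log-concentration with deterministic initialisation
(extremes for top/bottom, interpolated half-response for IC50, hill = 1).
A 4PL rather than 3PL was chosen because neither asymptote is safely
assumed at 0/100 in knockdown assays; fits whose IC50 falls outside the
tested span are flagged `extrapolated`.

## Synthetic data: what it emulates, and what it does not

The generators are seeded pure functions producing: random-background
transcripts with GU dinucleotides planted at stated positions (optionally
excluding all others), decoy transcriptomes with footprints planted at
chosen mismatch counts, first-order time courses, length-proportional gel
lanes, and 4PL dose-response tables.  Defaults are the study conditions the
toolkit is exercised against: GU sites at positions 359/388/427/473 of a
CDS-length target; k_obs = 0.1056 min⁻¹ with plateau 0.85; a 46-nt
substrate cut into 29 + 17; the published Mn²⁺/Mg²⁺ rate pairs
(0.1165/0.0539 min⁻¹ at 0.5 mm, 0.0154/0.0009 min⁻¹ at 15.6 µm); and
IC50 = 137.4 nM (hill 1, top 85%, bottom 5%).

Measurement noise is additive Gaussian, clipped to the valid range, with
each reported value the mean of three replicates (per-replicate sd 0.02 on
fractions, 3 percentage points on responses) — matching how triplicate
densitometry and qPCR assays are actually reported.  The kinetic sampling
grid is 13 points over 0–120 min, denser early (0, 1, 2, 5, 10, … 120)
where the exponential changes fastest, as a kineticist would sample; the
dose series is a 9-point half-log dilution series (1–10⁴ nM) bracketing
both asymptotes, as an IC50 assay is designed.

What passing tests show — and don't.  With triplicates at these noise
levels the Cramér–Rao bound puts the best achievable relative sd of k̂_obs
near 2.4%, so recovery is asserted on the median over 100 seeds (<2%) and
on a reference seed (<5%), not on every seed; the IC50 spread is larger
(top/bottom–IC50 correlation) and is asserted as a <10% median.  The
generators emulate measurement noise only: no pipetting drift, no lane
smearing, no partial re-folding of substrate, no cellular heterogeneity.
Recovery under this noise model demonstrates estimator correctness, not
performance on real gels.

## Problem sizes

The default test and acceptance runs use an 870-nt synthetic target,
80–120-nt folding windows, transcriptomes of 8–20 decoys of 0.5–1 kb, and
100-seed fit studies; exhaustive structure enumeration is run to 14 nt.
These sizes exercise every code path at full fidelity while keeping the
whole suite in the seconds range.

## Known limitations

- The energy model ranks accessibility; it does not predict structures
  quantitatively, and the most-probable-pair dot-bracket is a
  representative, not an MFE structure.
- The off-target scan is ungapped and anchored to a junction-centred seed;
  a bulged or shifted complementarity outside that geometry is not found.
- Kinetics cover single-turnover first-order fits only: no
  Michaelis–Menten/multiple-turnover analysis and no binding models of the
  k_obs-vs-metal-concentration curves.
- Target folding ignores pseudoknots (the scaffold's own pseudoknot is
  annotation, not energetics).
- The bundled scaffold is synthetic; results on it validate the machinery,
  not any particular natural pistol sequence.
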