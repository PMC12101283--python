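# Methods

This note documents the models behind `puredisplay`, the defaults and why
they were chosen, what the synthetic fixtures do and do not emulate, and
the package's known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Library definition

A library scheme is the pair (framework, CDR randomization rules).

The framework is a column-wise consensus of an alignment of synthetic
nanobody library scaffolds: per column the most frequent non-gap residue,
ties broken alphabetically so the consensus is deterministic; columns that
are gaps in a strict majority of rows are dropped. A column containing
only gaps raises an error (it carries no residue signal and indicates a
corrupt alignment), except in the degenerate single-row case where gaps
are simply removed. The consensus is split into FR1–FR4 at fixed segment
lengths (25/17/38/11 residues, typical VHH proportions).

CDR schemes fix a boundary position to its modal residue exactly when
that residue's frequency strictly exceeds a threshold — 30% for the
CDR1/CDR2 boundaries, 50% for CDR3 — and randomize every other position
over the 19 amino acids excluding cysteine (unpaired thiols cross-link).
The default layout is CDR1 length 10 with G, M, G fixed at positions 1,
2, 10; CDR2 length 10 with A, I, T, Y at 1, 2, 9, 10; CDR3 length 12 with
A, Y at 1, 12. The phrase "first and last two" with three named residues
for CDR1 admits two readings; we default to {1, 2, 10} (three fixed,
seven randomized) and expose the candidate set as a parameter so
{1, 2, 9, 10} is one argument away. With 7+6+10 = 23 randomized
positions the theoretical diversity is 19²³ (≈ 2.6 × 10²⁹), computed as
an exact big integer; the diversity of any physically synthesized library
(~10¹¹–10¹²) is set by the number of molecules, not by this bound.

Reverse translation uses the most frequent codon per amino acid in highly
expressed *E. coli* genes, one codon per residue. This mirrors
codon-controlled (trimer-phosphoramidite) synthesis, which avoids rare
codons; it also means sampled DNA is deterministic given the protein.

## Synthesis-error model and QC

Errors are independent per nucleotide: deletion with probability `d`,
substitution with probability `s` (default 0 — deletions dominate
observed failures). QC classifies a sequenced clone as

* `in_frame`: length divisible by 3 and no internal stop codon;
* `full_length`: the translated product has exactly the designed length
  (an in-frame 3-nt deletion is in frame but short);
* `framework_match`: all framework and fixed-CDR residues equal the
  design (evaluated once full length).

A clone passes iff all three hold. Under pure deletions any deletion
either shifts the frame or (if a multiple of 3) shortens the product, so
the pass probability of a length-L clone is (1−d)^L; compensating
combinations that restore both length and design are ignored, which is
exact at realistic rates. This identity calibrates `d` from an observed
pass fraction — for a 2/3 pass rate on the 369-nt default design,
d = 1 − (2/3)^(1/369) ≈ 1.1 × 10⁻³ per base. The pass fraction carries
an exact Clopper–Pearson interval because colony-sequencing samples are
small (tens of clones), where normal approximations are poor.

## Spacer scoring

Structured, GC-rich spacer mRNA stalls the PURE ribosome (the
reconstituted system has no helicases). As a cheap structure proxy we
compute the maximum number of nested base pairs by the Nussinov dynamic
program: Watson–Crick pairs plus GU wobble (the scored molecule is mRNA),
with at least 3 unpaired bases inside every hairpin loop — the standard
steric convention. Density is pairs/(length/2), so 1.0 would be a perfect
hairpin. Ranking sorts ascending by (pairing density, overall GC):
structure first, GC as tie-breaker, stable for ties.

Two caveats are deliberate. The score is combinatorial, not
thermodynamic: it bounds how much pairing is *possible* rather than
predicting the minimum-free-energy structure, and it systematically
scores random sequences well above their thermodynamically stable
pairing. And with wobble enabled the score is not symmetric under reverse
complement (G·U maps to C·A, which cannot pair); the symmetry property
holds, and is tested, for Watson–Crick-only scoring.

## Coverage and PCR arithmetic

Display efficiency is eluted/input molecules. The coverage rule
`input = diversity × complexes_per_member / efficiency` (rounded up)
reproduces the planning arithmetic for full-library display: at 4%
efficiency and 10¹¹ diversity, 10¹³ input molecules give each member an
expected four functional complexes, and the probability a member displays
at all is 1 − e⁻⁴ ≈ 0.98 under the Poisson representation of binomial
thinning. PCR quantification assumes perfect doubling by default
(template = product/2^cycles); sub-exponential efficiency is exposed as a
per-cycle factor in (1, 2]. Detection cycles is the smallest c with
template × factor^c ≥ a gel-visibility threshold (default 10 ng).

## Biopanning simulator

Each round chains per-clone binomial thinning steps: functional-complex
formation at `display_efficiency × (1 − incubation_release)`; optional
pre-incubation depletion removing streptavidin-motif complexes before the
target is seen; class- and surface-dependent capture; per-wash retention;
elution; Poisson amplification (mean 50, the approximate per-template
yield of T7 transcription; a factor of exactly 1 skips the step).
Affinity is abstracted into class-level capture/retention probabilities —
the study characterizes binder *classes* (target binders, HPQ/M
streptavidin-pocket binders, surface stickers, nonbinders), not kinetic
constants, so modelling Kd would add parameters with nothing to calibrate
them against.

Counts are conserved exactly within every round:
`functional = flow_through + Σwash + eluted + discarded`. The
`discarded` term is non-zero only under biotin elution, which recovers
complexes held via the displaceable target or the streptavidin biotin
pocket and leaves surface stickers (and nonspecifically stuck complexes)
on the support; under EDTA elution `discarded ≡ 0` and the three-term
form holds. Switching the surface to Ni-NTA drops streptavidin-motif
capture to baseline — the rescue strategy against HPQ/M enrichment.

The deterministic expectation mode replaces every sampling step by its
mean and is the analytic twin used in tests: for a two-type system it
reproduces the closed form p₀s^r / (p₀s^r + (1−p₀)b^r) exactly, and
sampler means converge to it. Expectation mode also runs safely at full
experimental scale (10¹³ molecules), where fractional expected counts are
meaningful; the stochastic path needs integer counts.

Amplification-induced variants (e.g. non-proofreading Taq errors) can be
modelled as a per-molecule Bernoulli event that founds a new clone record
inheriting its parent's class but not the spike flag; off by default.

## Scenario presets and calibration

The shipped presets encode the two campaign schedules: `egfp_campaign`
(four rounds on streptavidin surfaces, EDTA elution, wash stringency
rising in the final round) and `hfabp4_campaign` (adds an HPQ/M
background class, pre-incubation depletion from round 2, Ni-NTA surface
in round 3 — where EDTA elution is used, since biotin competition is
meaningless without streptavidin — and biotin elution elsewhere).

Per-class capture and retention values are calibrated fixtures: the study
reports class behaviour and endpoint numbers, not per-round
probabilities. They were chosen once, in expectation mode, so that the
full-scale spike-in campaign (spike:library = 10²:10¹³, efficiency 4%)
reaches a spike fraction of ≈ 0.096 after four rounds, matching the
observed "roughly 10%" enrichment timescale; they were not tuned further.

Two population scales are provided. `full` uses 10¹³ molecules with a
100-copy spike (ratio 10⁻¹¹), intended for expectation mode. `bench` uses
10⁷ molecules with a 100-copy spike so stochastic campaigns run in
milliseconds; the spike count is kept at 100 rather than scaled down
because the scientifically load-bearing condition is that the spike forms
about four functional complexes (100 × 4%) — a proportionally scaled
spike would form 10⁻⁴ and every stochastic run would lose it to
extinction, which is noise, not selection. The spike:background *ratio*
at bench scale is therefore 10⁻⁵, not 10⁻¹¹.

## What the fixtures do and do not emulate

Synthetic frameworks are random sequences with seeded point variation,
not the published scaffold alignments (those exist only as figures); they
exercise the consensus logic, not nanobody biology. CDR tables place the
designed modal residues above their thresholds by construction, so
scheme-derivation tests verify the thresholding rule, not field
frequencies. Spacers are composition-matched random sequences — the
"M13 pIII-like" one (GC 0.70) built as a near-perfect hairpin, the
"TolA-like" one (GC 0.56) shuffled — so the comparison tests the scoring
and ranking machinery, not the actual phage/TolA sequences. ELISA plates
contain an exact constructed number of above-threshold ratios.
Consequently, passing tests demonstrate correctness of the rules and
statistics, not that real libraries or spacers would produce these
numbers.

## Numerical choices

* Consensus and modal-residue ties: alphabetical, for determinism.
* `required_input` rounds the quotient to 12 significant digits before
  the ceiling so exact cases (4 × 10¹¹ / 0.04) are not bumped by float
  representation error.
* Detection cycles computed in closed form with a boundary correction
  loop against float error.
* Molecule counts: int64 in the sampler, float64 in expectation mode;
  diversity as an arbitrary-precision integer.
* All randomness flows through `numpy.random.Generator`; every generator
  is seeded and every fixture is byte-identical for a given seed.

## Limitations

No thermodynamic folding, pseudoknots, or codon-resolution ribosome
kinetics; the link between spacer structure and display efficiency is
exposed as a user-set efficiency per spacer (4% vs ~20% in the studied
pair), not derived from the pairing score. No qPCR standard-curve
fitting. Wet-lab observables downstream of selection (affinities, melting
temperatures, expression yields) are out of scope.
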