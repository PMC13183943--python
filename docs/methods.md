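# Methods

This note documents the models, parameter choices, and numerical
conventions behind `climkit`, and what its synthetic fixtures do and do
not establish about real data.

## Amplicon design

The sequenced molecule is fixed:

```
adapter5 · NNNNNN · TAG · reporter (240 nt) · GGT · NNNNNN · adapter3
          hexamer   bc5                       bc7   hexamer
```

The 258-nt insert (hexamers + anchors + reporter) is read by a 150-bp
pair whose mates overlap by 2·150 − 258 = 42 bp. Within the reporter,
codons at 0-based nucleotide offsets 96–216 carry the NNK saturation
scan and map one-to-one onto protein residues 38–77 of the Cd CliM
reporter (38–76 of wild-type CliM plus the engineered Lys77); the
flanking reporter sequence (a GFP/linker tail 5′, a FLAG tag 3′) is
constant. The full sequence is frozen in `design.py` and every
coordinate map (residue ↔ reporter codon ↔ insert nucleotide) derives
from it. Residue numbers are 1-based protein coordinates; reporter
codon indices are 0-based.

## Read processing

Mates are quality-filtered independently and a pair survives only if
both mates pass. The three per-read rules mirror common FASTQ
preprocessors: fail if > 30 % of bases are below Phred 20, or if the
mean Phred score (arithmetic mean of scores, not of error
probabilities) is below 25. All thresholds are configurable
(`QualityPolicy`).

Merging considers every ungapped 3′ overlap ≥ `min_overlap` (default
10 nt). Overlaps whose mismatch fraction exceeds `max_mismatch_frac`
(default 0.25) are not candidates; among candidates the overlap with
the most matching bases wins, ties preferring the longer overlap (the
expected 42-nt overlap is the longest plausible for this design).
Restricting the candidate set by the mismatch constraint *before*
maximizing matches is essential: a long spurious overlap matches ~25 %
of its bases by chance, which can exceed the absolute match count of a
shorter perfect overlap. At mismatching overlap positions the
higher-quality base is kept (ties keep the forward base) and the
consensus quality is the higher of the two. No adapter trimming is
performed: reads start at the insert ends by construction, and
read-through is impossible for a 258-nt insert with 150-bp reads.

The production path is vectorized over dense (n, 150) uint8 matrices;
the scalar `merge_pair`/`quality_filter` functions define the
semantics and the tests assert exact agreement between the two paths.

## Variant calling

A merged read is parsed only if it is exactly 258 nt (any other length
is presumed to carry an indel and discarded with reason `indel`) and
carries TAG/GGT exactly at their fixed positions (`anchor` otherwise).
The reporter is compared codon-wise to wild type: zero mismatched
codons → wild type; exactly one mismatched codon at a mutable position
→ a single-codon variant keyed by (residue, codon); one mismatch
outside the window → `offsite`; more than one → `multi`. Codons are
translated with the standard genetic code, stops labeled `*`. Observed
codons are *not* masked to the NNK pattern — sequencing errors produce
non-NNK codons, which are counted but flagged (`non_nnk`) so callers
can drop them. Hexamer content is ignored entirely (the library design
uses them as spacers, not unique molecular identifiers, and no
deduplication is performed). Bookkeeping is exact: wild type + variant
counts + discards = parsed reads.

Indel-tolerant (alignment-based) calling is out of scope; the fixed
amplicon makes length a reliable indel proxy.

## Fitness model

RPM normalizes within a sample over wild type plus all single-codon
variants (discards excluded), so Σ RPM = 10⁶ by construction. The
growth rate of a variant converts its frequency change into absolute
doublings per hour via the culture's CFU fold-change; it is undefined
(no pseudocounts) when the variant has zero reads at either timepoint.
Relative fitness divides the +Spc rate by the −Spc rate within the
same replicate; a non-positive −Spc reference rate leaves the ratio
undefined rather than sign-flipped, since a non-growing reference
makes the ratio uninterpretable.

Synonymous codons are summed per (residue, amino acid) *before* RPM and
growth-rate computation by default (`by_aa=True`), since fitness acts
at the protein level; per-codon scoring is available. The ≥ 8-read
support filter is applied to the t0 count of each condition within each
replicate, and a variant failing it in any contributing sample is
masked (NaN) in the heatmap, never zeroed. The heatmap is 21 rows
(20 amino acids + stop) × 40 columns (residues 38–77).

## Toeprint model

Reverse transcription halts a fixed distance downstream of a stalled
ribosome's P-site, so fragment length is linear in the stall codon with
slope −3 nt/codon. Absolute offsets are construct- and primer-specific,
so the model is anchored by one user-supplied calibration pair rather
than a hard-coded offset. Peak assignment matches each observed length
to the candidate codon predicted within a tolerance (default 1 nt, the
typical capillary sizing jitter), ties breaking toward the smaller
codon number. Consecutive-codon peaks spaced 2 nt apart (as reported
for the Ck CliM homolog) cannot both satisfy an exact 3-nt model; under
tolerance 0 the second peak is left unassigned rather than force-fit,
and only the jitter tolerance absorbs it. Raw electropherogram
processing and size-standard calibration are out of scope.

## Synthetic screen

The generator emulates the selection experiment: molecules carry one
NNK codon drawn uniformly over (40 positions × 32 NNK codons), draws
hitting the wild-type codon folding into the wild-type class, plus a
10 % un-mutagenized wild-type fraction. Each (residue, amino acid)
class has a planted relative fitness *r*; its +Spc growth rate is
*r*·g₀ and every class grows at g₀ without selection — the definition
of relative fitness as a ratio of growth rates, used generatively.
Frequencies at t1 are f·2^(g·h) renormalized; sequencing is a
multinomial draw at the stated depth, hexamers are uniform per
molecule, and substitution errors are applied per base with the Phred
string fixed at the quality matching the error rate (Q30 at 0.1 %,
uncorrelated with the actual error positions — the simplest model
consistent with the encoding). Metadata CFU values are derived
deterministically from the planted truth (CFU_t1 = CFU_t0 · Σ f·2^(g·h),
the bulk fold-change), so fitness-recovery tests isolate the counting
pipeline. All randomness flows from one seed; identical inputs give
byte-identical gzip FASTQ output (mtime pinned).

Defaults are the study conditions: 2 biological replicates, ± Spc,
2×10⁵ read pairs per sample, 0.1 % per-base error, g₀ = 2 doublings/h
and 2 h of growth — exponential-phase values typical of *B. subtilis*
in rich medium; the sequencing depth is a free parameter chosen once at
the scale used for the recovery analyses. Deliberately not modeled:
PCR jackpots, index hopping, plating error, quality-correlated errors,
indels, and chimeras. Passing recovery tests therefore demonstrates
correctness of the counting and fitness arithmetic under clean
assumptions, not robustness to those artifacts.

## Geometry

**Overlap volume.** Two bodies are unions of spheres (atoms dressed
with Bondi van-der-Waals radii, overridable per element; 1.70 Å
fallback). Uniform points are sampled over the axis-aligned bounding
box of whichever set has the smaller padded box (pad = that set's
largest radius — the intersection is contained in either body's box,
so the smaller is the tighter, lower-variance choice); the hit
fraction times the box volume estimates the intersection, with the
binomial standard error reported. The estimator is validated against
the closed-form two-sphere lens volume π(4r + d)(2r − d)²/12 and
converges as 1/√n; default 10⁶ samples, explicit seed required for
reproducibility.

**Sidechain truncation.** Ala keeps N/CA/C/O/CB (+OXT), Gly keeps the
backbone only; no rebuilding or minimization, matching the in-silico
mutation used to ask whether a smaller residue relieves a clash. By
sphere removal, truncation can only shrink any overlap volume.

**Superposition.** Standard Kabsch: SVD of the covariance of centered
paired coordinates with a determinant correction against reflections.
Requires ≥ 3 non-collinear pairs. The paired atom selection is always
explicit (e.g. rRNA phosphate atoms); no automatic chain mapping.

**Hydrogen-bond census.** A permissive geometric criterion — carbonyl
O(i) within 3.5 Å of amide N(i+4), no explicit hydrogens or angle term —
counting bonds that *can* form in a helical conformation. Pairs with
missing atoms are skipped with a warning, not errors.

**Helix fixture.** Backbones are built by natural-extension (NeRF)
placement from ideal bond lengths/angles; the default dihedrals
(φ = −62°, ψ = −45°) are tuned so the resulting helix hits the
canonical 1.5 Å/residue rise, ~100°/residue turn, and ~3 Å (i, i+4)
O···N distances under this bond geometry.

## Functional mode analysis

The functional mode is the unit-norm linear combination of
mean-centered ensemble coordinates maximizing covariance with the
observable — the first partial-least-squares latent direction,
w ∝ Xᶜᵀyᶜ, fit on training frames only (by default the first half of
the replica labels, emulating replica-wise train/validation splits of
simulation data). Pearson correlations between the projection and the
observable are reported for both splits. A single covariance mode is
not a least-squares regressor: when coordinates are sample-correlated,
even a noiseless linear observable yields validation correlation
below 1. Exact-recovery tests therefore use fixtures whose training
coordinates are centered and orthonormal, for which w equals the
planted mode identically; realistic correlated fixtures are tested
against recovery thresholds and a permutation null instead. Input
frames are assumed already superposed (rigid-body motion removed), as
the `superpose` routine provides.

## Problem sizes

The recovery analyses run at 2×10⁵ read pairs per sample (1.6×10⁶
pairs per screen), 10⁶ Monte-Carlo samples for volume oracles, and
ensembles of a few hundred frames — scales chosen so every quantity's
sampling error is far below the effect being measured while the whole
suite remains desk-runnable in minutes.

## Known limitations

- No indel-tolerant variant calling; reads with indels are discarded,
  which under-counts variants on error profiles richer than
  substitutions.
- The merge consensus resolves quality ties toward the forward read;
  with realistic asymmetric quality profiles this is immaterial, but
  it is a convention, not an inference.
- The overlap-volume estimator assumes the two bodies are already in a
  common frame; alignment quality is the caller's responsibility.
- Structure-dependent analyses (deposited ribosome models, aligned
  release factors) require coordinate files the user supplies; the
  package ships only synthetic fixtures.
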