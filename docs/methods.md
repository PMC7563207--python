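# Methods

## Problem and model

A stable-isotope tracer experiment acquires two sample arms on the same
LC-MS platform: unlabeled controls, from which molecules are identified
(MS2-based, by external software — those identifications are *inputs*
here), and isotopically labeled samples, in which each identified
molecule spreads over a ladder of mass isotopomers. Because the heavy
isotopomers of a molecule differ only in neutron count, they (i) co-elute
with the unlabeled molecule and (ii) sit at exactly predictable m/z:

    mz(M+n) = mz(M+0) + n · 1.0033548378 / z

The pipeline therefore needs no feature identification in the labeled
samples at all: it expands each reference ion into theoretical rungs and
asks, per rung, whether a labeled-sample MS1 feature sits close enough in
(m/z, RT).

### Candidate expansion

Ladder caps are 10 labels for polar metabolites and 40 for intact lipids,
reflecting typical carbon counts of each class; when the elemental
formula is known the cap tightens to the carbon count, since a molecule
cannot carry more ¹³C than carbon atoms. M+0 is expanded as a candidate
too, although it is not a "labeled" isotopomer: the labeling-ratio
denominator needs the ¹²C intensity *from the same labeled run*, so the
unlabeled rung must be located there as well.

### Matching and scoring

Candidates and features are compared with hard pre-gates followed by a
continuous score:

* gates: |Δm/z| ≤ 10 ppm of the theoretical m/z, |ΔRT| ≤ 30 s of the
  *reference* RT (both configurable);
* score: `1 − sqrt((Δm/z·β)² + ΔRT²)` with β = 0.1, Δm/z in Th and ΔRT in
  seconds; accepted iff ≥ 0.61. Among gated features the best score wins;
  ties break toward higher intensity, then smaller |Δm/z|, then input
  order (fully deterministic).

The two-layer design is deliberate. With β = 0.1 the m/z term contributes
at most ~10⁻³ to the distance for any plausible high-resolution
deviation, so the score is dominated by ΔRT and cannot by itself reject a
co-eluting ion tens of ppm away. The ppm gate carries that burden; the
score then discriminates on co-elution quality. The 0.61 cutoff
corresponds to a pure-RT deviation of 0.39 s — appropriate for the
sub-second RT reproducibility of a modern UHPLC-Orbitrap platform. For
chromatography with coarser reproducibility, `rt_unit="minutes"` rescales
the RT axis of the score so the same cutoff spans ±23.4 s.

The score is written with a Euclidean (root) combination of the two
terms; a `score_form="sum_of_squares"` flag preserves the rootless
alternative for comparison. ΔRT is always computed against the reference
RT, not between features, because co-elution with the unlabeled molecule
is the physical anchor.

One hit per candidate per sample is emitted, but a single feature may
serve several candidates: overlapping envelopes of different molecules
genuinely share m/z space, so forbidding reuse would silently drop true
assignments. Reused features are flagged (`feature_shared`) for audit.

Grades bin the score for human triage: A ≥ 0.95, B ≥ 0.85, C ≥ 0.70,
else D. The bins are this package's own convention.

### Quantification

Per molecule and sample: labeling ratio = Σ heavy / (Σ heavy + M+0), and
the normalized isotopomer distribution over all matched rungs. When heavy
rungs matched but M+0 did not, the ratio is reported as 1.0 with an
`m0_missing` flag instead of dropping the molecule — fully labeled pools
can extinguish the unlabeled peak, and silence would bias exactly the
most-labeled molecules. Lipid aggregates are unweighted means across the
lipids of a class (or carrying a chain); a lipid contributes once per
*distinct* chain token it carries. `compare_conditions` provides a plain
log2 ratio and difference between conditions; no statistical test is
attached because none is part of the method.

**No natural-abundance correction is performed anywhere.** Raw M+1/M+2
intensities contain ≈ 1.07% per carbon of natural ¹³C signal; reported
ratios are raw labeled fractions, not tracer enrichments. Downstream flux
modeling that requires corrected MIDs must apply its own correction.

## Peak picking

MS1 feature detection is a deliberately simple re-specification of an
EIC-based picker: centroids of consecutive scans within a 4 ppm window
join one trace, traces break at RT gaps > 300 s; within a trace, a
local-maximum run of ≥ 3 points is a peak if its apex clears 3× the trace
noise (median of non-peak points, floored at 1) and 2× the local
baseline, with apex intensity retained in [10⁴, 10⁷]. Feature m/z is the
intensity-weighted mean over the run; feature RT is the apex scan time
(always a literal input centroid). Density-based clustering knobs of
legacy pickers without an analogue here are accepted in configuration for
provenance and ignored with a logged notice. Peak picking is an upstream,
replaceable stage: pre-picked feature CSVs (sample_id, polarity, mz,
rt_s, intensity) are a first-class input that bypasses it entirely.
Whether feature intensity is apex or integrated area is configurable
(default apex).

mzML is read by a minimal internal MS1 reader (64/32-bit, zlib or raw
base64) and mzXML via pyteomics; files must be polarity-annotated, and
profile-mode scans are centroided naively (local maxima) with a warning.

## Chemistry conventions

Atomic monoisotopic masses are hard-coded (IUPAC most-abundant-isotope
values, 7 decimals); no external lookup happens at run time, and the
table is cross-checked against an independent mass model in the tests.
Adduct deltas are neutral-fragment atomic sums with the electron mass
ignored — an error below 0.001 Th at z = 1, invisible at the 2-decimal
precision at which ion coordinates are reported. This convention
reproduces the canonical formate-lipid coordinates (778.56 / 804.58).
Formulas use Hill notation without parentheses or isotope prefixes;
whitespace is tolerated. ¹⁵N tracing would only change the spacing
constant and can be configured via a custom adduct/spacing, but is
untested.

## Synthetic data

The simulator emulates the two-arm design: the unlabeled export contains
each molecule's M+0 ion (formula + adduct) at its nominal RT; each
labeled sample contains one feature per envelope component at the
theoretical rung m/z perturbed by Gaussian m/z jitter (default sd
1.5 ppm), Gaussian RT jitter (default sd 0.14 s), and lognormal intensity
noise (default CV 0.1), plus uniform (m/z, RT) decoys and optional
interferers at a fixed Th offset from a host molecule — the co-eluting
lipid overlap scenario. The jitter defaults model the mass accuracy and
retention reproducibility of a high-resolution Orbitrap with tight UHPLC;
the RT sd of 0.14 s is the platform-level reproducibility the default
score cutoff presumes, and it is the package's reference condition for
the recovery tests. Randomness comes from one seeded generator with
per-sample substreams keyed by a stable hash of the sample id, so adding
a sample never perturbs existing ones.

What the simulator does *not* emulate: chromatographic peak shapes beyond
Gaussians, natural-abundance envelopes (an intentionally omitted
correction, see above), cross-sample RT drift, ionization suppression,
and correlated noise between isotopomers of one molecule. Passing
recovery tests therefore demonstrate the correctness of the search and
quantification logic under the stated noise model — not performance on
real chromatograms, where RT reproducibility and interference density
must be assessed per platform.

Evaluation counts a hit as true only if its (molecule, n) was planted
*and* the matched feature is the planted one — matching a decoy at the
right annotation is still a false positive. Zero hits report precision
1.0 with an explicit flag.

## Numerical and design choices

* Problem sizes in the test suite (e.g. 100 random search instances of
  200 candidates × 2000 features; 20 seeds × 50 molecules for recovery)
  were chosen to exercise the algorithms well beyond the sizes at which
  implementation shortcuts would surface, while keeping the suite quick
  to run routinely.
* The windowed search is verified against an exhaustive brute-force
  oracle sharing only the mathematical definition (gates, score, tie
  rules), not the code path.
* Score comparisons use plain floating-point ≥ against the cutoff; a
  feature landing exactly on the theoretical boundary may fall either way
  at the last ulp, which is immaterial for continuous data.
* Reference pooling deduplicates on (name, adduct, polarity) and takes
  median m/z and RT across occurrences — robust to one outlier run among
  several unlabeled runs; ref_ids are reassigned stably (polarity, then
  m/z) so pooling is idempotent and order-insensitive.
* Result CSVs keep a fixed column block (mz1 … Grades) with sample and
  reference ids around it; manifests exclude wall-clock data so reruns
  are byte-identical.
* Degenerate inputs: empty feature lists yield header-only results with a
  warning (not an error); an all-zero intensity group makes the
  distribution undefined (error) while the ratio reports 0 with a flag;
  molecules with no hits produce no summary record rather than zeros.

## Known limitations

No cross-sample RT alignment, no FDR statistic on real data (decoy-based
evaluation exists only for simulations), no isotope fine structure, no
natural-abundance correction, and no flux-network modeling: the output
(per-molecule labeling ratios and isotopomer distributions) is intended
as input to such downstream analyses.
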