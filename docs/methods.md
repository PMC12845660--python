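# Methods

This note records the models, conventions and design choices behind
`fluorscreen`, in the order the pipeline applies them.

## Mass arithmetic and Kendrick analytics

Monoisotopic masses are sums of most-abundant-isotope atomic masses taken
from the NIST table shipped with pyteomics (C 12 exactly, H 1.0078250,
F 18.9984032, O 15.9949146, S 31.9720707, …). All ions are singly charged
deprotonated species; the charge-carrier convention is fixed as
m([M−H]⁻) = M − 1.007276 Da (proton mass). Fragment anion m/z values in
the built-in diagnostic database include the electron mass.

The Kendrick mass for base unit B is KM = m · nominal(B)/exact(B) with
nominal masses 50 (CF₂) and 14 (CH₂); the Kendrick mass defect is
KMD = round(KM) − KM. The sign convention is arbitrary in the literature;
this one makes CF₂ homologs share an identical KMD, which the test suite
verifies to 10⁻⁶ Da under k-fold CF₂ insertion.

**Homologous-series detection** first clusters features whose KMDs agree
within 0.002 Da (transitive closure), then links members whose pairwise
mass differences are integer multiples (1–10) of the exact base-unit mass
within 5 ppm of the larger mass, and emits connected components with ≥ 2
members. The multiplicity cap of 10 bounds the search and covers the
C4–C14 span of the target list. The implementation (union-find) is tested
against an independent O(n³) boolean-closure oracle.

One genuine subtlety: 6:2 FTS and ADONA differ by 49.99903 Da — within
5 ppm of one CF₂ unit at m/z ≈ 428 — although they are not formula
homologs. Any KMD detector must group them, so the synthetic generator's
ground truth defines series as what is mathematically present in the
noise-free planted ion masses at the screening tolerances (with a small
allowance, 3 SD of the cross-feature m/z noise, for borderline spacings
that the many sample copies will almost surely link). Recovery is
evaluated at the compound level: which compound families form series, and
that no decoy or background feature ever joins one.

**Formula enumeration** is an exhaustive bounded depth-first search over
element counts with mass pruning (the lightest element is solved in closed
form), at ±5 ppm by default. The plausibility filters — RDBE ≥ 0,
F ≤ 2C+1, and H+F ≤ 2C+2 for acyclic C/H/F/O species — are this package's
own approximations biased toward PFAS-like compositions, configurable and
disclosed as such; they reconstruct no proprietary rule set. Equivalence
with an unpruned brute force is tested on small mass windows.

## Screening

Cross-sample grouping uses transitive closure on |ΔRT| ≤ 0.2 min and
|Δm/z| ≤ 5 ppm; group consensus m/z is the intensity-weighted mean.
Tolerance-based grouping deliberately stands in for vendor-style adaptive
chromatographic alignment, which is out of scope. Blank matching reuses
the same tolerances. The blank rule is read as: maximum sample area at
most 5× the matched blank's maximum area ⇒ background (the boundary ratio
of exactly 5 is removed).

The isotope-pattern score is a declared surrogate for vendor-internal
similarity scoring, keeping the published operating points (threshold
≥ 80, intensity tolerance ±30 %): the theoretical envelope is computed by
per-element polynomial convolution of isotope abundances aggregated by
nominal shift (mass offsets abundance-averaged within each bin, so S/Cl
M+2 spacings are honored); peaks match within 10 ppm; relative-intensity
deviations within the tolerance count as zero, larger ones cap at 1, and
a missing expected peak above 5 % relative abundance scores a full
deviation; score = 100 · (1 − mean deviation).

Confidence levels follow the standard annotation framework: L1 requires an
authentic-standard RT match (±0.1 min) plus accurate mass plus MS2
evidence; L2 accurate mass plus a curated-library MS2 match; L3 an
assigned formula plus diagnostic/in-silico fragment evidence; L4 formula
only; L5 accurate mass only. The decision table is exhaustively checked
against an independently coded 32-case oracle, and monotonicity (more
evidence never worsens the level) is property-tested. Only L1–L3 are
retained for interpretation. In the pipeline, the isotope gate on formula
assignment applies when an MS1 envelope is available for the feature;
otherwise the ±5 ppm formula fit stands alone. MS2 matching uses 10 ppm
(fragment spectra are acquired at lower resolving power than full scan).
When several suspects match one group, all candidates are kept and ranked
by |ppm error| then isotope score; quantification uses the best.

## Quantification

RRFs are fitted as the least-squares slope through the origin of
(A_native/A_labeled) against (C_native/C_labeled). Surrogate assignment
for compounds without standards minimizes |ΔRT|, breaking ties by shared
subclass and then by nearest neutral mass; the choice is deterministic
and tested against brute-force lexicographic minimization. QC boundaries
are literal: S/N exactly 3 fails, ion-ratio uncertainty exactly 30 %
fails, |ΔRT| exactly 0.1 min passes; the RT gate applies only to
standard-confirmed targets, since suspect-screening compounds have no
reference RT. The synthetic feature tables carry no qualifier-ion data,
so the pipeline passes 0 for the ion-ratio uncertainty; the gate itself
is fully unit-tested. The MQL extrapolates each accepted record to the
concentration that would produce S/N = 10, assuming S/N proportional to
concentration — an explicit, documented assumption — and takes the
minimum. Blank correction subtracts the procedural-blank concentration
floored at zero, so concentrations are never negative.

## Compliance screening

Per-sample sums are lower-bound: `not_detected` and `below_mql` records
contribute zero. PFOA equivalents multiply each concentration by its
relative potency factor; the shipped RPF table is the published
relative-potency placeholder set (PFOA 1, PFNA 10, PFOS 2, …) and is a
user-editable input, not a claim about any particular survey. Compounds
without an RPF are excluded with a warning. Exceedance comparisons are
strict (a value exactly at a standard does not exceed it): 4.4 ng/L for
ΣPFOAeq, 0.65 ng/L and 36000 ng/L for PFOS. River summaries average over
samples, not settlements; the sample standard deviation uses ddof = 1 and
single-sample water bodies report sd = 0 with a flag. Values are kept at
full precision and rounded only at presentation (3 significant figures).
An `include_ssa` switch extends ΣPFOAeq from the targets-only tier to all
compounds with RPFs, mirroring two-tier reporting.

## Risk prioritization

The 18 hazard attributes are grouped 3/2/3/10: three Biowin biodegradation
probabilities (persistence; reflected before normalization, since lower
biodegradability means more hazard), log BCF and log Kow
(bioaccumulation), three acute aquatic potencies as −log₁₀(mg/L)
(ecotoxicity), and ten human-health endpoints including oral rat LD₅₀ as
−log₁₀. The human-endpoint count of ten is what makes the printed group
weights (1/9, 1/6, 1/18, 1/60 per attribute) sum to exactly 1 — verified
in rational arithmetic — and is obtained by splitting skin/eye
irritation-or-corrosion into separate skin and eye endpoints; this is an
inference, recorded as such. Attribute direction alignment is explicit
configuration. Min–max normalization maps a constant attribute to all
zeros (degenerate rule), so pipelines never emit NaN; the same rule
applies to a degenerate exposure range. ToxPi is the plain weighted sum
of normalized attributes; no slice-level rescaling is applied.

Exposure is DF × magnitude with DF a fraction in [0, 1] (the subsequent
min–max renormalization makes the percent-vs-fraction choice inert) and
magnitude = (cᵢ − c_min)/(c_max − c_min) over the per-compound maxima.
RI = ToxPi × normalized exposure; categories use half-open intervals with
boundaries belonging to the lower category (RI = 0.1 is medium). RI is
monotone in every attribute, DF and cᵢ, and invariant under rescaling all
concentrations — both property-tested. Hazard inputs are QSAR-model
outputs; running QSAR predictors is out of scope.

## Paired statistics

Differences are downstream − upstream per settlement with non-detects as
zero. The Wilcoxon signed-rank statistic is W⁺ (sum of positive-difference
midranks); zero differences are dropped classically (Pratt handling is
available by flag). For n ≤ 25 the two-sided p is exact:
p = min(1, 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))) under the full 2ⁿ sign-assignment
null, evaluated by convolving the generating function over doubled
midranks — identical to explicit enumeration, which serves as the test
oracle at n ≤ 12 (and scipy's exact mode cross-checks tie-free cases).
Above n = 25 a normal approximation with tie-corrected variance
(Σr²/4) is used, without continuity correction. Shapiro–Wilk is computed
via scipy's implementation of the published coefficient approximation,
with the n = 3 closed form as an independent oracle. FDR adjustment is
Benjamini–Hochberg step-up (the specific FDR procedure is this package's
choice), delegated to statsmodels and verified against a hand-rolled
oracle. Tests are two-sided, and all 12 settlements are pooled across
rivers.

## Synthetic study

The generator emulates a 24-sample survey: 12 settlements (6 on a large
river, 3 on a canal, 1 each on three further rivers), each with one
upstream (odd site number) and one downstream (even) sample, plus 2
procedural blanks. The default roster holds 10 targets (C4–C9 PFCAs,
three PFSAs, a fluorotelomer sulfonate) and 10 suspect-screening
compounds (ultra-short-chain acids, an ether acid, two H-substituted
acids, four fluorinated pesticides). Mean concentrations sit at the
low-ng/L levels typical of moderately impacted rivers, with detection
probabilities from 16.7 % to 100 % and one dominant compound (a TFA
analogue, mean 513 ng/L ≥ 100× the median of the rest, 100 % detection).
PFNA's default mean (0.3 ng/L) is set so that, at its relative potency of
10, it contributes the plurality of the PFOA-equivalent sum — the
characteristic situation in which potency weighting, not raw
concentration, drives exceedances.

Concentration noise is lognormal with a 30 % CV (positive, right-skewed;
inter-site variance is a generator parameter, not a claim about any
survey), with unit-mean multipliers so compound means are preserved.
A `downstream_effect` multiplier defaults to 1.0 — the null of no
settlement effect, under which the statistics stage should find nothing
after FDR; this is verified over 500 simulated studies (pooled
significant fraction within 0.05 + 3 binomial SE). m/z errors are
N(0, 1 ppm) relative; feature areas follow the isotope-dilution response
model area = RRF_true · (C/C_IS) · A_IS so the quantification stage can
invert them, with suspect-screening compounds assigned the RRF of their
correct surrogate so that correct assignment is unbiased by construction.
S/N is proportional to concentration (50 per ng/L, anchoring the MQL at
0.2 ng/L). Fifty non-fluorinated decoys carry hydrocarbon-like positive
mass defects and are placed outside every planted compound's CF₂ Kendrick
band and each other's; five background signals appear in all samples and
blanks at sample/blank ratios between 2 and 4.5. MS2 spectra contain
class-typical fragments (decarboxylation and perfluoroalkyl anions for
carboxylates, SO₃⁻/FSO₃⁻ for sulfonates, non-diagnostic aromatic ions for
pesticides); MS1 isotope envelopes are emitted per PFAS feature. Ground
truth records every planted concentration, feature label, series
membership, RRF and hazard rank, and all generators are deterministic
given (design, seed).

What the generator does not emulate: chromatographic peak shapes, raw
profile spectra, vendor file formats, matrix effects and recovery losses,
qualifier-ion ratios, spatial (per-river) concentration structure, and
real spectral-library scoring. Passing recovery tests therefore
demonstrates the correctness of the screening/quantification logic under
the stated noise model, not field performance on real extracts.

## Problem sizes and numerics

The test suite and the acceptance script run the full 24-sample pipeline
(under a second), 200-seed Monte-Carlo recovery for calibration and
semi-quantification, 200 random datasets for the exact-Wilcoxon oracle,
and 500 null studies for type-I calibration — sizes chosen so the whole
battery completes in well under a minute while keeping binomial standard
errors small enough for 3-SE bounds to be meaningful. Tolerances in tests
are exact (1e-12) wherever the arithmetic is deterministic, 10⁻⁶ Da for
mass-defect identities, and the stated statistical bounds elsewhere.
ToxPi and normalized exposure are clipped against float summation drift
(≤ 2⁻⁵²) before the strict [0, 1] domain check of the risk index.
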