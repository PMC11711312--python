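# Methods

This note records the models implemented in `folliclemap`, the defaults and
conventions chosen where the design was genuinely open, and what the
synthetic study conditions do and do not establish about real data.

## Coordinate frame and vertical territories

All coordinates are in µm, right-handed. The follicle frame
(`FollicleFrame`) puts the vibrissal shaft midpoint at ringwulst level at the
x–y origin and the entry of the deep vibrissal nerve at z = 0; angles around
the shaft are counterclockwise degrees in [0, 360) with 0° = rostral and
90° = dorsal (so the caudal half-circle is 90–270°). Terminal height is
z above the nerve entrance.

Vertical ending territories are offsets from the ringwulst level
(`VerticalBands`): ring-sinus level = [+100, +300] µm (afferents surpass the
ringwulst by 100–300 µm), ringwulst level = the open ±100 µm window, and
cavernous-sinus level = [−300, −100] µm. Band edges are configurable; the
closed/open conventions above make every height belong to at most one band.

## Morphometric features

- **Terminal angle** uses the full-circle two-argument arctangent of the
  vector from the shaft centre to the terminal midpoint. A plain
  arctan-of-slope is ambiguous up to 180°; quadrant disambiguation is
  required because angular statistics run over the full circle. The angle is
  undefined (an error) when the terminal coincides with the centre.
- **Fiber caliber**: fiber area is the median over skeleton nodes of π·r²;
  fiber diameter is twice the median node radius.
- **Ranvier internode length** is the median of successive differences of
  the annotated Ranvier arc positions; with fewer than two positions it is
  reported absent (NaN), never zero.
- **Branch count** is the number of terminal tips minus one (equivalently
  Σ(children−1) over branch points). The *multibranch* flag defaults to
  branch count > 2; scoring schemes that use > 3 are supported via the
  threshold argument (both conventions appear in the literature for this
  preparation; neither is silently preferred).
- **Conduction velocity**: myelinated v = 6·d (m/s per µm of diameter);
  unmyelinated v = 0.32·ln(d) + 2.8 m/s, a logarithmic fit to classical
  C-fiber measurements. The log base of such fits is often unstated; natural
  log is used here (the default of the fitting tooling that produced the
  coefficients) and the formula is floored at 0.1 m/s for sub-threshold
  diameters so velocity stays positive and monotone where active.

## Exclusion and rule-based typing

Axons lost during segmentation inside an axon arm are excluded from
classification (trajectories curve inside arms, so their terminal territory
is unknown); axons that left their arm or ended near the root sheath are
kept. Fragments that cannot be connected to a ground-cable — an axon path
starting ≥100 µm below the ringwulst, below which no branching occurs — may
be branches of another axon and are excluded from axon-based analyses. The
exclusion log records the rule that fired per axon.

Typing is a pure rule table: ring-sinus terminal + root-sheath entrance →
Merkel; ring-sinus terminal + glassy-membrane terminal → lanceolate;
ringwulst terminal + glassy-membrane terminal → club-like; cavernous
terminal + shaft-ward trajectory → Ruffini-like; anything else →
Unclassified. Within the ring-sinus band the root-sheath entrance dominates
(Merkel over lanceolate), mirroring the dominating-characteristics reading
of the raster scores. Composition percentages are rounded half away from
zero, which reproduces the printed census values (5/32/63% from counts
14/90/174; 35% club-like and 17% Ruffini-like from 52 and 25 of 149). Note
that exact quotients are reported alongside: 51/149 = 34.2% and
21/149 = 14.1% do not round to the sometimes-quoted 35%/13%.

## Population statistics

- **Exact two-sided binomial test** (p₀ = 0.5): minimum-likelihood
  definition — the p-value sums pmf(m) over all outcomes with
  pmf(m) ≤ pmf(k)·(1+10⁻⁷); the relative tolerance guards floating-point
  ties. Verified against exact integer enumeration.
- **Polarization scan**: for each cut θ on a 20° grid, the half-open
  semicircle [θ, θ+180) is tested against Binomial(n, ½), per axon class and
  pooled. Half-open membership puts every angle on exactly one side;
  antipodal cuts give identical partitions and p-values.
- **Crossing index**: for every unordered axon pair, the signed circular
  difference (in (−180°, 180°]) of their angular positions at the reference
  level (100 µm below the ringwulst) and at their terminals; a sign change
  counts one crossing for both axons, tallied intra- or inter-arm. Exact 0°
  or 180° differences are order ties, not crossings — "sign change" is
  undefined on a circle without this tie-break. An axon in no crossing has
  index 0 rather than 0/0.
- **Gradient analysis**: ordinary least squares of velocity (and of fiber
  area) on terminal height via `scipy.stats.linregress`, reporting r, r² and
  the t-distribution p; both r and r² are reported because published
  accounts of such fits sometimes quote inconsistent pairs. Diameters are
  split at 850 µm terminal height with per-group medians.
- **Group tests**: Kruskal–Wallis with tie correction (scipy), then Dunn's
  post-hoc z on mean ranks with the pooled-rank variance including the tie
  term, two-sided normal p, Bonferroni over all pairs (6 for four types).
  Implemented in-package because no installed library provides Dunn's test;
  checked against hand rank arithmetic.

## Unsupervised subtype analysis

- **Gower dissimilarity**: equal-weight mean of per-variable terms —
  range-normalised absolute difference for continuous variables (0 when the
  range is 0), symmetric matching for binary flags (presence and absence
  equally informative: the flags are two-sided descriptors, not rare
  attributes). The axonal variable set is terminal height, fiber diameter,
  median internode length and branch count plus the ringwulst-apposition and
  root-sheath-entry flags; the morphological set is the binary score sheet.
  Implemented in-package (no installed Gower library).
- **FAMD**: continuous columns standardised (population SD); each binary
  variable contributes both indicator columns scaled by 1/√(category
  proportion) and centered; SVD of the combined matrix. Row coordinates are
  U·S, so with all-continuous input FAMD reduces exactly to PCA of the
  standardised matrix (this identity is a test). Constant continuous columns
  are an error; single-category binaries are dropped with a warning. FAMD is
  used for visualization; clustering runs on Gower distances directly.
- **Ward clustering**: `scipy.cluster.hierarchy.linkage(method="ward")` on
  the condensed Gower matrix — the Lance–Williams recurrence in the Ward.D2
  convention. This treats Gower distances as if Euclidean, a documented
  approximation (Gower space is not Euclidean in general). scipy's
  nearest-neighbor-chain agglomeration provides the deterministic tie-break.
  Club-like subtypes are found by cutting the dendrogram built within the
  morphologically identified club cluster at k = 2, then compared variable
  by variable with two-sided two-sample t-tests.

## Nerve linearization models

The linearly-unwrapped model projects nerve entry positions onto the
principal axis (orthogonal least squares — chosen over y-on-x regression so
the axis is equivariant under rigid motions of the section) and correlates
projections with terminal angles unwrapped at an explicit cut (default 0°, a
`--scan-cut` mode evaluates all 20° cuts and flags its output as
selection-biased). The radially-condensed model reads each afferent's polar
angle about the fitted nerve centre and unwraps it at the same cut. The
centre is an algebraic (Kåsa) circle fit with centroid fallback for
collinear inputs: with angularly polarized coverage the centroid sits well
off a ring's centre and warps the polar readout by tens of degrees, which
caps the radial model's r below what a genuinely radial layout warrants.
Scores are Pearson r (not circular correlation), matching the linear
regression readout the analysis is defined by. The linear model's score is
invariant under rigid motions of the cross-section; the radial model's score
is translation invariant but its angular unwrap is anchored to the section's
anatomical axes, so a rotation must co-rotate the cut to leave the score
unchanged.

## Synthetic study conditions

`SyntheticConfig` defaults define the emulated follicle: 51/21/52/25
Merkel/lanceolate/club/Ruffini myelinated deep afferents (the classified
census), 58 unmyelinated and 14 superficial axons; ringwulst at 900 µm above
the nerve entrance so the type territories straddle the 850 µm diameter
split (Ruffini-like and unmyelinated below, the rest above). Terminal angles
are von Mises with µ = 135° (dorso-caudal) and κ = 1 — von Mises being the
canonical circular analogue of a Gaussian bias; κ = 0 gives uniform angles.
Fiber area follows area = −10 + 0.04·height µm² plus Gaussian noise
(SD 3 µm²), floored at 0.2 µm², giving myelinated diameters ≈4–7 µm;
unmyelinated areas are drawn log-normally around 0.8 µm² (such fibers are
thin regardless of height). Internode lengths scale with diameter
(≈100·d µm, SD 30) except for club-like afferents, whose two planted
subtypes differ in fiber area (offsets ±7.5 µm² around the gradient law,
mean-zero at the default 0.5 mixing so the population gradient is unbiased)
and internode length (means 350 vs 650 µm, SD 40). Club-like afferents are
generated unbranched — their endings are flat, precisely aligned terminals;
branching is a lanceolate trait — which matters because a spurious 0/1
branch variable would otherwise dominate the range-normalised Gower metric.
Six axon arms partition the circle into contiguous 60° sectors; each axon's
reference-level angle is its terminal angle plus 5° Gaussian jitter, so
crossings are predominantly intra-arm. Skeletons are ≥10-node piecewise
linear polylines from the nerve entrance to the terminal with node radius
encoding fiber radius, consistent by construction with the feature table
(verified by test).

Nerve layouts: *linear* places entry x monotonically in the terminal angle
unwrapped at the configured cut (1 µm per 3.6°) with Gaussian y jitter;
*radial* places afferents on a 50 µm ring at their terminal angle, with
jitter applied to the unwrapped coordinate and clipped at the cut — the cut
runs through the innervation gap, so no axon straddles it; circular jitter
across the cut would create ±360° outliers that are artifacts of the
unwrapped representation, not of the layout. *shuffled* permutes the linear
positions.

Determinism: every afferent draws from its own substream
(`SeedSequence([seed, index])`), and the layout embedding from a reserved
substream, so identical configurations are byte-identical after
serialization.

Reported simulation sizes (20 seeds for recovery rates and clustering, 100
seeds for power-style rates, n = 174 for gradient and layout analyses, 1000
angles for the polarization scan) are the package's chosen problem sizes for
the property checks.

## What the synthetic conditions do not show

The generator emulates the *statistical* structure the analyses assume, not
follicle biology: skeletons are smooth polylines without tortuosity, myelin
geometry or reconstruction noise; flags are set exactly per the rule table,
so classification accuracy on synthetic data is 100% by construction and
says nothing about rater agreement on images; the caliber gradient is
affine by design; and the nerve layouts are idealized. Passing tests
establish that the estimators recover planted structure at realistic sizes
and noise levels — not that real follicles have that structure. Real-data
statistics (e.g. a measured gradient r or the published linearization
r = 0.9 vs 0.27 ordering) require the reconstructions themselves, which are
deliberately not bundled.

## Known limitations

- Ward on Gower distances is an approximation (see above); dendrogram
  heights have no strict variance interpretation.
- The exact binomial's tie tolerance (10⁻⁷ relative) can differ from other
  implementations at extreme n where pmf values collide in floating point.
- The crossing index compares each axon pair at exactly two levels; axons
  that cross an even number of times between the levels are not counted.
- `--scan-cut` model selection is selection-biased by construction and is
  labelled as such in its output.
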