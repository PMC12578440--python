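# Methods

## Interaction screen

**Contact definition.**  An interface residue pair is two amino acids
on different chains whose minimum heavy-atom Euclidean distance is
within the contact cutoff.  The default cutoff is 4.0 Å and the
comparison is inclusive (≤); the comparator is configurable because
"within 4 Å" is sometimes used strictly.  Hydrogens, waters and
hetero-compounds are removed on read, so the criterion operates on
heavy atoms of amino-acid residues only — predicted models carry no
hydrogens, and this makes the result identical across PDB and mmCIF
inputs.  Candidate pairs come from a KD-tree ball search with a small
numeric margin; the boundary decision is always made on exact
distances, so a pair at exactly 4.000 Å is classified identically to a
brute-force scan.

**Confidence filter.**  Per-residue pLDDT is read from the
temperature-factor column (all atoms of a residue carry the same value
in the AlphaFold convention; when they differ the mean is used and a
warning recorded).  A contacting residue is excluded when its pLDDT is
*strictly below* 50, so a residue at exactly 50.0 is retained.  The
filter applies to the residues of both partners independently: a
contact whose residues straddle the threshold contributes only the
passing residue.

**Model selection.**  Prediction runs sample several models (five by
default, recorded as run metadata); interfaces are computed on the
rank-1 model.  When ranks are absent, the model with the highest mean
pLDDT is used, ties broken by first occurrence.

**Bidirectional consensus.**  Input order can change a server's
prediction, so the screen refuses to run on a single order.  A pair is
"interacting" in one order when at least
`min_interface_residues_per_chain` (default 1) residues survive on
*each* chain, and consensus-positive only when both orders interact
(logical AND).  The union interface pools the surviving residues of
both orders per subunit.  The positivity threshold is a configuration
knob because there is no canonical count; 1 is the most permissive
choice, and the AND over orders is what provides specificity.

**Ranking.**  Consensus-positive pairs are ordered by total
union-interface residue count, tie-broken by mean pLDDT of the union
residues, then lexicographically — an explicit, reproducible surrogate
for "top pairs", recorded in every report.

**Fragment handling.**  A subunit too long for a prediction server's
input limit can be screened as overlapping fragments.  Fragment
interfaces are mapped to full-length positions via declared offsets and
deduplicated by full-length position; a residue identity conflict in an
overlap indicates a wrong offset and raises.

## Steric feasibility

A pairwise model only contains two subunits, but in vivo each lives in
an assembled complex.  An interface residue is useful only if it is
still solvent-exposed there; otherwise engaging it would require
partial disassembly or a conformational change.  Because no operational
definition of "sterically feasible" is standard, this package defines
it as **relative solvent accessibility ≥ 0.25** (side-chain plus
backbone heavy atoms) with a 1.4 Å water probe — both configurable and
stamped into every report.

Accessible surface area uses rolling-probe sphere-point sampling
(Shrake–Rupley with a Fibonacci point distribution, ≥ 960 points per
atom, element van-der-Waals radii) as implemented in biotite; per-residue
ASA is divided by the theoretical maximal ASA of that amino-acid type in
an extended Gly-X-Gly tripeptide (Tien et al. 2013, PLOS ONE 8:e80635)
and clamped to [0, 1].  With fixed sample points, deleting atoms can
only unblock points, so accessibility is exactly monotone under chain
deletion; rotation invariance holds to sampling tolerance (tested at
0.5 percentage points of the feasibility percentage).

Mapping from a pairwise model onto complex chains uses global pairwise
alignment (match +1, mismatch −1, gap open −5, extend −1, Biopython's
PairwiseAligner).  An alignment identity below 90 % raises — the wrong
subunit was probably supplied — unless cross-species mapping is
requested (a complex may carry an orthologue's sequence), in which case
it warns.  Complexes may hold several copies of a subunit; a residue is
feasible if accessible on **at least one copy**, since one partner can
dock on one face of a filament.  Unmapped residues are reported
separately and excluded from the percentage's denominator, never
silently dropped.  Percentages are reported both pooled and per
subunit.

## FRAP

Processing order: bleach validation → correction → normalization →
smoothing → fitting.

* *Bleach validation*: depth = first post-bleach / mean pre-bleach
  intensity after background subtraction; a proper experiment bleaches
  to below 50 %.
* *Correction*: corrected(t) = (bleached − background) · R(0)/R(t),
  where R(t) is the background-subtracted unbleached reference cell and
  R(0) its pre-bleach mean.  A multiplicative per-frame acquisition
  loss cancels exactly; because R(0) is a pre-bleach average, a
  constant scale factor can survive, which the subsequent normalization
  removes (the correction-inversion test therefore compares normalized
  traces, at 1e-9).
* *Normalization*: pre-bleach mean → 100 %, first post-bleach frame →
  0 %.  The whole pipeline is invariant under scaling all raw
  intensities by any positive constant.
* *Smoothing*: centered 3-point rolling average over post-bleach frames
  only, full windows only (output shortened, each value timestamped at
  the central frame).  Pre-bleach frames are not smoothed — the fit
  never sees them.
* *Fit*: bounded least squares (scipy, trust-region reflective) of
  y = m₁ + m₂·exp(−m₃·x) with m₃ ∈ (1e-6, 1e3) 1/s, time zero at the
  first post-bleach frame.  Initialization m₁ = last value,
  m₂ = first − last, m₃ = 3/span; on poor convergence the fit restarts
  from five log-spaced m₃ values.  Deterministic and seedless.
  t½ = ln 2 / m₃ by construction, so t½·m₃ = ln 2 holds to machine
  precision for every fit.

## Image quantification

ROI intensity: per-pixel cytoplasmic background is estimated from the
annulus between an enclosing ROI2 (≈ twice the area of ROI1; a ratio
outside [1.5, 2.5] warns) and the signal ROI1:
corrected = sum₁ − (sum₂ − sum₁)/(area₂ − area₁) · area₁.  The value is
invariant under adding any constant to the image.

Line scans sample one point per pixel of line length and average
`width` (default 3, odd required) nearest-pixel samples perpendicular
to the line; bilinear interpolation is available behind a flag but
nearest-pixel is the default to match integer-pixel source tooling.
Alignment modes shift profiles so the computed center sits at 0:
reference-channel global peak, own brightest pixel, midpoint of the two
highest strict local maxima separated by ≥ 3 samples (raises on
unimodal profiles), or an externally supplied center.  Peak ties break
to the lowest index.  The long-axis colocalization profile applies one
1.5 µm × 3.5 µm rectangle at the identical position to both channels
and averages over the short-axis extent at each long-axis pixel.
Coordinates are 0-based (row, col) pixels internally; reported
positions are µm relative to the alignment center.

## Reporter activities

Two ONPG normalizations: specific activity
OD₄₂₀ × 1.7 / (0.0045 × protein(mg/ml) × extract volume(ml) × time(min))
in nmol/min/mg, and culture-density units
1000 × OD₄₂₀ / (T(min) × V(ml) × OD₅₉₅).  Both are linear in OD₄₂₀ and
inversely proportional to elapsed time (property-tested).  Replicate
aggregation is a plain mean ± sample SD helper; ANOVA/post-hoc testing
is out of scope.

## Synthetic data

Generators emulate only what the pipeline measures.

* **Pair models** are bead-and-stick pseudo-proteins (Cα plus one
  pseudo side-chain atom per residue, 5 Å backbone spacing, 2 Å minimum
  separation).  Planted contacts relocate the partner residue to an
  exact distance, so the expected contact list, distances, and
  post-filter interfaces are known a priori; the generator refuses
  geometrically infeasible specs.  pLDDTs are planted to two decimals —
  the temperature-factor column's file precision — so files round-trip
  exactly.  The default panel reproduces the study design: 4 × 8 = 32
  combinations, six bidirectional interfaces, and negatives split among
  no-contact, low-confidence and single-order mechanisms.
* **Complexes** are rows of single-atom residues (12 Å spacing, chains
  30 Å apart); burial is enforced by a 150-point occluding shell at
  5 Å radius hosted on the *next* chain, so deleting that neighbour
  un-buries the residue — the octamer→hexamer exposure effect.  Buried
  residues score exactly 0 and exposed residues > 0.5; default complex
  sequences use small/medium amino-acid types so a fully exposed
  single-atom residue clears 0.5 of its reference area.
* **FRAP traces** forward-simulate the fit equation on the percent
  scale, invert the normalization around the planted bleach depth,
  apply per-frame acquisition decay and additive Gaussian noise
  (fraction of the bleach dynamic range, on the bleached channel), at
  the study's settings: 5 pre-bleach frames, 150 @ 0.33 s or
  70 @ 10 s, depth < 0.5 enforced.
* **Images** plant rim (two membrane-proximal Gaussian peaks), disk
  (signal across the whole division plane) or rim+center geometry over
  uniform cytoplasm, with recorded peak positions and signal sums.

What the generators do *not* emulate: real protein geometry and
packing, PAE error structure, disordered regions, optics (PSF, photon
noise statistics), or cell-to-cell variability.  Passing tests
demonstrate that the algorithms implement their stated definitions
exactly and recover planted truth under realistic noise — not that the
specific feasibility percentages or interaction calls of any real
subunit pair would be reproduced, which requires the original predicted
models.

## Problem sizes and numerical choices

The test suite and the acceptance script run the contact oracle on 100
random structures of 20–80 residues per chain, the screen on the full
32-pair panel, feasibility on octamer-scale complexes (8 chains × 10
residues plus burial shells), deletion monotonicity on 20 random
complexes, and FRAP recovery on 100 noisy traces per setting — sizes at
which every check completes in seconds while exercising the same code
paths as full-scale data.  Known limitations: accessibility depends
mildly on the sphere-point count (< 0.02 per residue when doubling from
960); the exponential fit assumes a single kinetic component; line
scans use nearest-pixel sampling, so sub-pixel peak positions are
quantized to the pixel grid.
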