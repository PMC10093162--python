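# Methods

## Problem and data model

A MALDI-MSI acquisition of a trypsin-digested tissue section produces one
peptide-range mass spectrum per pixel of a 2-D grid (here m/z 600–3200,
nominal 100 µm spacing). In combined hepato-cholangiocarcinoma the section
contains two molecular phenotypes — hepatocellular (HCC-like) and
cholangiocellular (iCCA-like) — in contiguous spatial domains, with fibrotic
sub-domains and occasionally small foci of one phenotype hidden inside the
other. The package's data model is: `MSIDataset` (0-based pixel grid,
x-right/y-down, one `Spectrum` per pixel; imzML's 1-based convention is
converted at the I/O boundary), `PeakTable` (pixels × aligned m/z bins),
`SegmentationTree`, `PCAResult`, `TrypticPeptide`, `IonImage`. Negative raw
intensities are clipped to zero at load (TIC normalization assumes
non-negativity); sequences are restricted to the 20 standard residues
because peptide masses must be exact.

## Preprocessing

**Baseline.** The "convolution" family of MALDI baselines is implemented as
a grey-scale morphological opening — moving minimum then moving maximum over
a window of 2·`half_width`+1 bins (default half_width 50) — smoothed by a
moving average of the same width. A pure opening reproduces any monotone or
slowly varying trend exactly while removing every peak narrower than the
window, so planted ramps leave residuals < 2 intensity units in the window
interior and peak apexes are preserved within 5%. A moving-minimum followed
directly by the moving average (without the dilation step) would bias the
baseline low by roughly slope × half_width and was rejected for that reason.

**TIC normalization.** Uniform rescaling of each non-blank pixel to a common
total ion current (default target 100). All-zero pixels (off-tissue matrix
blanks) are flagged and excluded from clustering and PCA rather than
normalized — scaling is undefined on them.

**Peak picking** (profile mode only): local maxima at least `snr` (default
5) times the robust noise level 1.4826 × MAD of the non-zero intensities.

**Alignment.** Proprietary vendor alignment is replaced by gap-based
tolerance clustering: all per-pixel centroids are pooled, sorted, and split
into bins wherever the gap between consecutive m/z values exceeds the
tolerance (default 0.3 Da, appropriate for reflectron-TOF peptide data).
Bin centers are intensity-weighted means. The rule is permutation-invariant
over pixels, and raising the tolerance can only merge bins.

## Segmentation

Recursive bisecting k-means (k = 2 per split; scikit-learn k-means++ with
10 restarts, seeded deterministically per node from the caller's seed)
on the unit-variance-scaled peak table, mirroring the hierarchical
arborescence of commercial MSI segmentation. "Weak denoising" is one 3×3
median (majority) pass on the binary label image after each split, with
off-grid and off-node neighbours ignored and exact ties keeping the
original label; it suppresses isolated misassignments the way spatial
denoising presets do. Recursion stops at the requested depth, below 10
pixels per node (smaller nodes chase noise at phantom scale), or when a
node's rows are identical (no variance to reduce — single leaf, warned).

Clusters of a tree cut are named by majority vote against a region
annotation (ties broken toward the lower region code and logged), or by an
explicit user mapping. Quantification folds fibrosis/focus sub-labels into
their parent component and reports counts and percentages, rounded half-up
to one decimal; the half-up convention and the population-SD choice in the
cohort report are the ones that reproduce the published-style tables
digit-for-digit.

## PCA

Columns centered and unit-variance scaled (zero-variance columns dropped
with a warning), covariance eigendecomposed with `eigh`, components ordered
by decreasing eigenvalue. Sign convention: each loading column's
largest-magnitude element is positive, making results reproducible across
linear-algebra backends. Scores of the first component rendered on the grid
give the phenotype-separating component image; loading extremes list the k
most positive/negative loadings with their bin m/z. Independent tests check
the decomposition against a brute-force SVD to 1e-8. PCA defaults to all
pixels jointly; per-case analysis is just PCA of a per-case table.

## In silico digestion and uniqueness

Trypsin rule: cleave C-terminal to K or R unless the next residue is P.
`digest` enumerates all peptides with up to `max_missed` (default 1) missed
cleavages with 1-based positions; zero-missed peptides concatenate to the
parent sequence. [M+H]⁺ masses use the standard monoisotopic and average
residue tables with H₂O = 18.010565 Da and proton = 1.007276 Da; cysteine
is unmodified (the tissue protocol has no alkylation step); monoisotopic
masses drive matching (reflectron TOF). Peptides are observable only within
the closed acquisition window [600, 3200] Da. Uniqueness collapses I to L
(isobaric, indistinguishable by MS) and requires the peptide to occur in
exactly one proteome record. Marker-peptide selection ranks unique
in-window peptides by fewest missed cleavages, then descending mass (the
sparser end of the spectrum), and returns the top n = 2 — returning fewer
with a warning when fewer exist, never fabricating.

## Virtual IHC

Each selected peptide is matched to the nearest aligned bin within a
tolerance (default 0.3 Da; ties toward the lower m/z bin, logged). Its ion
image sums intensities over bins in the window per pixel; off-tissue pixels
are missing. Overlap with an annotated region uses Otsu binarization by
default (parameter-free, standard for bimodal intensity fields) and reports
Dice and IoU (Dice = 2·IoU/(1+IoU) is asserted on every row). Pixels
positive outside the region are counted and reported, never interpreted —
they are the candidate areas a conventional stain may have missed.

## Phantom generator

The phantom defines the study conditions for all recovery tests. Default
layout, 60×60 grid: a 4-column off-tissue margin; an HCC field; a
25-pixel-radius iCCA lobe with an internal fibrosis ring (radii 20–23); a
3-column fibrosis band in the HCC field; three hidden iCCA foci of diameter
3 (3×3 blocks) in the HCC field and one HCC focus at the lobe center;
optionally a small MVI embolus carrying both phenotype signatures.

Signatures: 50 background species (m/z drawn in the window with ≥ 1 Da
spacing, means uniform 20–80) shared identically by all tissue regions, so
clustering must use the multivariate marker structure; 10 marker species —
the [M+H]⁺ masses of the two proteome-unique tryptic peptides of each of
five synthetic marker proteins (two HCC-like, two iCCA-like, one shared),
planted at mean 100 in their own phenotype's regions. Fibrosis sub-domains
carry 0.8 × the parent signature plus three stromal species at mean 40:
fibrotic stroma retains most of the parent tumor signal with a modest
overlay, which is also what makes fibrosis fold into its parent component
at the first split, reproducing the observed arborescence (phenotypes
first, fibrosis below). Noise: per-pixel log-normal TIC factor (σ = 0.3,
making TIC normalization consequential), additive Gaussian peak noise
(σ = 5, i.e. SNR ≈ 20 on a marker peak), m/z jitter (σ = 0.05 Da, well
inside the 0.3 Da alignment tolerance given the ≥ 1 Da species spacing).
Everything is deterministic given the seed.

What the phantom does *not* emulate: isotope patterns, matrix-cluster
chemical noise, mass-dependent resolution and calibration drift,
biological within-phenotype gradients, and co-registration error between
serial sections. Passing recovery tests therefore demonstrates the
correctness and robustness of the algorithms under the stated noise model,
not performance on real tissue.

**Hidden-focus recall** is a detection criterion: a planted focus counts as
recovered when at least half of its pixels land in the leaf of its own
phenotype. Pixel-exact recovery of a 3×3 focus is structurally impossible
under a 3×3 median filter (its corners are always smoothed away, leaving
the 5-pixel plus shape), and detection — flagging the focus for
histological re-review — is the operationally relevant event. For 5×5 foci,
where the filter preserves 21 of 25 pixels, pixel-level recall ≥ 80% is
asserted directly.

The weak-denoising guarantee is likewise scoped to what a median filter
provides: on label images whose true regions are ≥ 3×3 contiguous and whose
labels contain salt-and-pepper errors, one 3×3 median pass never lowers
agreement with the true partition. On an error-free labeling the pass can
only erode convex corners, so "never decreases accuracy" holds relative to
noisy labels, not degenerate perfect ones.

## Problem sizes and determinism

Recovery suites use 20 phantom seeds at the default 60×60 grid (3360
on-tissue pixels, 63 aligned bins) — large enough for stable ARI/Dice
statistics, small enough that the full suite runs in tens of seconds on one
CPU. Oracle suites use 500 random sequences (digestion) and 1000 random
splits (mass additivity). All randomness flows through explicit integer
seeds; identical seed and input give byte-identical label maps and CSV
outputs.

## Known limitations

- The Mascot step is export-and-filter only: the package writes an MGF peak
  list and applies the strict score > 56 threshold to an externally
  produced identification table; no scoring is implemented.
- Alignment is single-pass gap clustering; no recalibration against
  internal standards and no isotope deconvolution.
- Only [M+H]⁺ is matched; Na⁺/K⁺ adducts and PTMs are out of scope.
- Marker proteins shipped with the phantom are synthetic stand-ins
  (seeded random sequences); the digestion pipeline itself runs on any
  FASTA, including real UniProt records.
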