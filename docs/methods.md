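# Methods

`crypticnes` re-implements, as a tested pipeline, the in-silico analyses
behind the identification of a cryptic nuclear export signal (NES) in
human SOD1, together with the quantification procedures used to measure
its consequences in cells and in *C. elegans*. This note documents the
models, the defaults, and the deliberate design choices.

## NES consensus scanning

A leucine-rich NES is modelled as an anchor/spacer pattern: an ordered
set of hydrophobic anchor residues (Φ) with per-gap bounds on the number
of intervening residues (X). Two classes ship with the package:

- **`pki`** (default): Φ⁰-X₂-Φ¹-X₃-Φ²-X₂₋₃-Φ³-X-Φ⁴ — the spacing of the
  protein kinase inhibitor NES, i.e. gap ranges (2,2), (3,3), (2,3),
  (1,1). Match spans are 10–15 residues.
- **`relaxed`**: five Φ anchors with uniform X₁₋₃ spacers. This is the
  package's candidate-discovery class: the generic leucine-rich spacing
  used to nominate NES-like regions when the functional spacing is not
  known in advance.

The anchor alphabet defaults to {L, I, V, F, M}. Trp is deliberately
excluded: with this alphabet the P1 construct (residues 24–55 of mature
SOD1) contains exactly eight hydrophobic candidate residues (V29, V31,
I35, L38, L42, F45, V47, F50), which is the count the mutational screen
enumerated; including W32 would break that correspondence. The alphabet
is configurable per class.

Scanning is exhaustive: every start position and every admissible choice
of each variable gap is enumerated (no greedy shortest-match bias), so
distinct anchor placements over the same span are all reported. Matches
are merged into regions by transitive span overlap for region-level
reporting. The scanner is validated by exact set-equality against a
brute-force oracle that tests every 5-tuple of anchor-eligible positions
directly, over 1,000 random sequences.

On the mature human SOD1 sequence the strict `pki` class yields exactly
one match — anchors I35, L38, L42, F45, V47, span 35–47, inside the
experimentally confirmed P1 peptide. The `relaxed` class yields two
disjoint candidate regions (29–50 and 94–106). The original candidate
nomination procedure was not published in enough detail to reconstruct
its exact pattern; the `relaxed` class is this package's documented
reconstruction of a two-candidate discovery scan, and the second region
should be interpreted the way the original P2 was — a candidate that
failed functional validation.

Numbering is mature-protein numbering (initiator Met removed), 1-based,
inclusive spans. This is the convention under which SOD1 mutant names
(A4V, G85R, G93A) and the 33–51 peptide are self-consistent. Sequences
carry an explicit `numbering_offset` so excised peptides keep parental
numbering; FASTA description lines carry it as `offset=<n>`.

Mutations are applied with a wild-type residue check: applying L42Q to a
sequence whose residue 42 is not Leu is an error, which catches
off-by-one numbering mistakes instead of silently mutating the wrong
site.

## Anchor conservation

Given an ortholog alignment, each anchor's column (mapped through the
reference row's gaps) is checked against the anchor alphabet: the anchor
is conserved iff every ortholog residue in that column is a valid
anchor. Gap characters count as non-conserving. This reproduces the
observation that the Φ² anchor of the SOD1 consensus (Leu42 in human) is
not conserved — mouse carries Gln at that column — whereas anchors
substituted among {L, I, V, F, M} still count as conserved.

## Solvent accessibility and burial

SASA is computed by the Shrake–Rupley method with a deterministic
golden-spiral point set (default 960 points, configurable down to 60):
each atom's expanded sphere (van der Waals radius + probe) carries the
quasi-uniform lattice, and its SASA is the sphere area times the
fraction of points outside all other atoms' expanded spheres. Using a
fixed lattice instead of random sampling makes results reproducible
without a seed; translation invariance is exact and rotation invariance
holds to within the quadrature error (<2% at 960 points).

Defaults: probe 1.4 Å (water); vdW radii C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å. HETATM records (waters, the Cu/Zn ions) and hydrogens are
excluded by default — the analysis is of the protein surface — with
flags to include them. Alternate locations keep the highest-occupancy
conformer. Burial is assessed on the isolated selected chain (a monomer
of the SOD1 dimer); computing in the dimer can only increase burial, so
monomer analysis is the conservative choice for calling an anchor
buried.

Relative solvent accessibility (RSA) divides the residue's summed atomic
SASA by the theoretical Gly-X-Gly extended-tripeptide maximum (Tien et
al. 2013 values, shipped as a swappable table). A residue is **exposed**
iff RSA ≥ 0.20 (a common convention; boundary inclusive), otherwise
**buried**. The 0.20 default and the inclusive tie rule are explicit
because the original analysis classified exposure by visual inspection
of a rendered surface, which does not define a numeric criterion.

Accuracy is validated against closed forms (isolated sphere exactly;
two-sphere spherical-cap overlap within 2%) and against an independent
Shrake–Rupley implementation (biotite) within 5% per residue on a
synthetic peptide trace.

## Cryptic calling

A consensus match is called **cryptic** when ≥ 4 of its 5 anchors are
buried, **surface** when ≤ 1 is buried, and **ambiguous** otherwise.
The cryptic cutoff is anchored to the canonical positive case: the SOD1
consensus has four buried anchors and a single exposed one (Leu42), and
is export-competent only when misfolding exposes the rest. Both cutoffs
are configurable and are echoed in the report's `#config:` header line;
reports are deterministically ordered so identical inputs give
byte-identical output.

## N/T fluorescence quantification

Per-cell nuclear (N) and total (T) fluorescence are **integrated
(summed)** background-subtracted intensities, not means — under uniform
intensity the ratio then equals the nuclear area fraction, which is the
natural noise-free check. Background is the median intensity outside all
cell masks; pixels negative after subtraction are clamped to zero, so
0 ≤ N/T ≤ 1.

Segmentation thresholds each channel at the background median plus five
robust standard deviations (1.4826·MAD), falling back to Otsu for
noise-free images, then labels connected components, fills holes (a
nucleus dimmer than threshold must not punch a hole in its cell), and
discards border-touching cells. The background+5σ rule is used instead
of plain Otsu because a two-compartment cell is a three-class image
(background, cytoplasm, nucleus) and Otsu's single split can land
between cytoplasm and a much brighter nucleus. Nuclei are assigned to
the cell containing their centroid, and the nuclear mask is intersected
with the cell mask.

The original measurements were manual (ImageJ) on unpublished raw
images, so this module's contract is **ground-truth recovery on
generated images** — mean measured ratio within 0.05 of the true
nuclear fraction at SNR ≥ 10 over 30 cells — not replication of the
published curves, whose per-cell values were never deposited. For the
same reason the published time-course p-values are not acceptance
quantities.

Time courses are normalized per group to the group's own t = 0 mean
ratio (set to 1 exactly, SEM scaled by the same factor), which is how
the published trajectories were presented.

## Phenotype statistics

- **Bagging rate**: 100 × bagged/total, exact rational arithmetic before
  the final float. From the printed counts, 33/47 → 70.2% and 7/41 →
  17.1%, matching the reported "about 70%" and "about 17%".
- **Survival**: animals were followed until all died, so there is no
  censoring and Kaplan–Meier machinery is deliberately omitted. S(d) is
  the exact fraction with death day > d; mean survival is the arithmetic
  mean of death days.
- **Relative IP efficiency**: per-sample IP/WCL band-density ratio as
  fold over a reference sample (reference ≡ 1); scale-invariant per
  blot.
- **Group comparisons**: paired or unpaired two-tailed Student's t
  (pooled variance when unpaired), delegating to scipy with one added
  convention: two zero-variance samples with equal means give t = 0,
  p = 1. Validated against the textbook formulas to 1e-10.

## Synthetic data

Generators cover every input class with machine-readable truth, all
byte-deterministic under a fixed seed:

- **Peptides**: background residues drawn with anchor letters
  down-weighted to frequency 0.02 each (low accidental match rate while
  staying sequence-like); planted motifs sample gap choices uniformly
  from the class ranges, with spacers drawn from non-anchor letters so
  the planted tuple is a valid match by construction.
- **Toy structures**: isolated atom and two-atom pair (closed-form SASA
  truth), a cage with a fully enclosed central atom (truth 0), and a
  CA-trace helix (no analytic truth; used for cross-implementation
  comparison).
- **Cell images**: non-overlapping disk cells with inner nuclear disks,
  placed by rejection sampling; each cell's nuclear intensity is solved
  from pixel-counted areas so the noise-free N/T equals the configured
  fraction exactly. Noise is Poisson shot noise at a configured photon
  budget plus Gaussian read noise — the standard microscopy model.
  Disk geometry is chosen over realistic morphology because the
  contract is ratio recovery, not segmentation difficulty; passing
  tests therefore demonstrate measurement correctness, not robustness
  to real cell shapes, debris, or uneven illumination.
- **Phenotype tables**: the four transgenic lines (WT, L42Q, G85R,
  G85R/L42Q) with the study's cohort sizes (n = 20 bends, n = 50
  survival, bagging denominators 46/45/41/47, n = 12 egg counts).
  Bends are rounded normal draws (means 95/95/60/35, the double mutant
  lowest, as the published ordering requires; exact means were shown
  graphically only and are this package's realistic choice). Death days
  are geometric — the discrete memoryless lifetime — with the double
  mutant's per-day hazard 0.415 chosen so that 80% die by day 3, the
  one printed survival figure; other hazards (1/12, 1/12, 1/8) give the
  published ordering. Bagging probabilities equal the printed count
  ratios; hatched eggs are Poisson truncated at ≥ 1 with means 2.4
  (G85R) and 4.2 (G85R/L42Q), the printed per-mother averages.

## Numerical and degenerate-input choices

- Scanner output ordering: span start, then anchor tuple — total and
  deterministic.
- Quadrature: 960 points keeps the two-sphere worst case under 0.3%
  error; error at 60 points is ~3%, and the suite asserts it shrinks
  with the point count.
- Exposure tie at RSA = threshold counts as exposed.
- Empty inputs: scanning a motif longer than the sequence returns an
  empty list; an image with no component above threshold returns an
  empty segmentation with a warning; empty statistical inputs are
  errors.
- T = 0 cells are skipped with a warning rather than producing NaN.

## Known limitations

- The burial analysis of the actual SOD1 crystal structure (2c9v) needs
  the deposited coordinates, which are not redistributed with the
  package; the corresponding end-to-end test runs only when
  `external/2c9v.pdb` is supplied. The SASA engine itself is validated
  on analytic and cross-implementation oracles.
- The `relaxed` discovery class is a reconstruction; the second
  candidate region it nominates has no claim to function.
- No probabilistic NES scoring, no NLS scanning, no mmCIF input, no
  CRM1 binding energetics, and no modelling of the misfolding process
  itself.
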