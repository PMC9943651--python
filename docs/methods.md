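# Methods

## Binding model

The titration model describes a labelled oligonucleotide probe (total
concentration R, μM) binding a protein (total P, μM) 1:1 with dissociation
constant K_D, while a fraction NS of the protein is held in a nonspecific
complex that does not compete with specific binding.  The coupled
constraints

    R = R_free + x
    P(1 − NS) = P_free + x
    P_free · R_free = K_D · x

reduce to a quadratic in the specific complex x, solved at the physical
root x = 2P′R / (b + √(b² − 4P′R)) with P′ = P(1 − NS) and b = P′ + R + K_D.
This form avoids the catastrophic cancellation of the textbook
(b − √(b² − 4P′R))/2 expression when P′R ≪ b².  The observed anisotropy is

    A = A₀ + ΔA (x + NS·P) / R

i.e. the nonspecific complex is assumed to change the probe's anisotropy
with the same amplitude as the specific one.  Two properties of this model
are worth keeping in mind:

* The NS term grows linearly in P with no saturation.  At the top of the
  standard titration range (120 μM protein, 0.05 μM probe) the term
  NS·P/R is 2400·NS, so even NS ≈ 0.01 contributes substantially to the
  signal there.  The model is implemented exactly as stated; no saturation
  correction is applied.
* With NS free, A₀, ΔA, K_D and NS are jointly identifiable only because the
  NS term has a distinct (linear) concentration dependence; a titration that
  does not reach well past K_D will not separate them, which the AIC
  comparison below handles by preferring NS = 0.

### Parameters and defaults

| parameter | units | default (simulation) | meaning |
|---|---|---|---|
| K_D | μM | — | dissociation constant of the specific complex |
| A₀ | – | 0.10 | anisotropy baseline of the free probe |
| ΔA | – | 0.15 | anisotropy change at full saturation |
| NS | – | 0.02 | nonspecifically sequestered protein fraction |
| probe | μM | 0.05 | labelled oligonucleotide concentration (50 nM) |
| protein grid | μM | 12 points, log-spaced 0.1–120 | standard assay range |
| replicates | – | 3 | independent series fitted globally |
| noise SD | – | 0.003 (2% of ΔA) | additive homoscedastic Gaussian |

A₀ and ΔA are typical plate-reader anisotropy values for a Cy3-labelled
oligonucleotide; the noise level corresponds to a well-run triplicate
experiment where residual scatter is a few percent of the binding amplitude.

### Fitting

`fit_global` stacks all replicates of one condition and minimizes the summed
squared residuals over shared (K_D, A₀, ΔA) and, optionally, NS, using
bounded trust-region least squares.  Starting values: A₀ = min(A),
ΔA = range(A), K_D = protein concentration nearest the half-range
anisotropy, NS = 0.01; four additional multistart perturbations (K_D jittered
on the log scale) guard against local minima, and the best minimum wins.
Standard errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹ at the
optimum.  The fit is reported `converged=False` when the optimizer fails
*or* when |ΔA| < 2·SE(ΔA) — an amplitude indistinguishable from zero means
K_D is unidentifiable, and the flag prevents a spurious tight K_D from being
read off a flat series.

### Model selection and outliers

NS > 0 is tested against NS = 0 with the least-squares AIC,
n·ln(RSS/n) + 2k, where k counts the free model parameters plus one for the
noise scale.  Lower AIC wins; exact ties go to the simpler NS = 0 model.
Both fits must use the identical point set.

Outliers are flagged in a single pass: residuals from a converged
preliminary fit are studentized against a robust scale (1.4826 × median
absolute deviation) with the Gauss–Newton leverage correction, and points
with |t| > 3 are removed before one refit.  The robust scale matters: an RMS
scale is itself inflated by contamination, which caps the flaggable fraction
near 10% and masks gross misfit.  With the MAD scale, if more than 20% of
points exceed the threshold the routine refuses to flag and raises instead —
that situation is model misfit, not outliers.  The rule is deliberately
single-pass and deterministic.

## Stereochemistry calls

### Chirality from coordinates

Each internucleotide phosphorothioate is a stereocenter at phosphorus with
substituents S, O3′, O5′ and the remaining non-bridging oxygen.  The package
uses the priority order S > O3′ > O5′ > O(non-bridging) (the field's
convention for Rp/Sp labels: the ester oxygens are ranked by their carbon
substituents, O3′ above O5′) and assigns the label from the sign of the
triple product (a−d)·((b−d)×(c−d)) over the priority-ordered substituent
positions.  The sign→label mapping (negative → R) was calibrated once
against an independent CIP implementation on randomized tetrahedral centers,
including mirrored ones, and frozen as a module constant; the test suite
re-verifies it against that oracle.  Centers whose substituent tetrahedron
has |volume| < 0.1 Å³ are rejected as geometrically degenerate rather than
labelled.

### Map evidence

Anomalous difference maps are interrogated at the two candidate non-bridging
sites of each linkage.  The peak statistic is the maximum of the trilinearly
interpolated value at the site and of the voxel values within a 1.0 Å
radius, divided by the map σ — a maximum rather than an integral, because
the question is whether a peak is present at a contourable level, not its
total scattering weight.  Defaults, all config-exposed:

* contour threshold 3.5σ (the level at which such maps are typically
  displayed and judged);
* ratio margin 1.5 — one site must beat the other by this factor to be
  called alone; two above-threshold peaks within the margin are "mixed"
  (the situation refined crystallographically as two 0.5-occupancy
  conformers);
* B-factor cutoff 60 Å² on the phosphate-group mean — above it the density
  is considered too disordered for any call and the linkage is forced to
  indeterminate with `reliable=False`;
* search radius 1.0 Å, comfortably below half the ~2.8 Å separation of the
  two candidate sites, so the two peak measurements cannot bleed into each
  other.

Linkages are numbered 5′→3′ starting at 1.  The "evenly distributed"
criterion in the underlying experimental practice is qualitative; the ratio
margin is this package's declared quantitative substitute.

## Contacts and superposition

Contacts use Bondi van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80 Å) with a pair in contact when d ≤ r_a + r_b + 0.5 Å.  Pairs of
polar-capable atoms (N, O, S) within 3.5 Å are classified polar; otherwise
a pair with at least one C or S is a hydrophobic van der Waals contact.
Altloc groups contribute only their highest-occupancy conformer unless
requested otherwise.  Pocket summaries rank protein residues by hydrophobic
contacts to PS sulfur atoms.  Water bridges are reported when a water oxygen
lies within the polar cutoff of polar atoms in both selections.

Superposition pairs Cα atoms by global sequence alignment (identity scoring,
affine gaps, only identical aligned residues paired), then applies the
Kabsch closed-form rotation (SVD with determinant correction) and up to five
rejection cycles dropping pairs that deviate more than 2× the current RMSD.
This emulates the iterative-pruning behaviour of common alignment tools,
whose exact settings vary; reproduction of published RMSD/atom-count figures
is therefore expected within ±0.1 Å and ±10 atoms, not exactly.

## Synthetic data

The generators exist so the full pipeline can be exercised hermetically.

`build_ps_strand` places phosphate groups on an idealized helix (rise
3.4 Å, twist 36°, radius 9.4 Å) with chemically correct phosphate geometry
(P–O ester 1.60 Å, P–O non-bridging 1.48 Å, P–S 1.95 Å, tetrahedral
angles).  Bases and sugars are not built: no downstream computation reads
them.  OP1/OP2 atoms mark the two candidate sites; sulfur occupancy rides on
"SP" atoms — one full-occupancy atom for a programmed Rp or Sp linkage, two
0.5-occupancy altloc conformers for "mixed".  B-factors follow the
per-linkage profile (default 30 Å²).

`render_anomalous_map` writes values directly on the σ scale (grid σ ≡ 1 by
construction): a Gaussian blob of the stated σ-height at each sulfur,
weighted by occupancy, plus optional voxel noise.  This convention is
deliberate: with zero noise the ratio peak/std(voxels) is independent of
blob amplitude, so "a blob of height h σ" is only well-defined against a
fixed σ reference.  When maps are written to CCP4 the σ is stored in the
header RMS word and restored on read.  Defaults: blob σ-width 0.9 Å
(matching the peak sharpness of a ~2 Å anomalous dataset), voxel size
0.5 Å, blob height 10σ for a full-occupancy sulfur — high enough that a
0.5-occupancy conformer (5σ) still clears the 3.5σ contour, as in a
well-measured long-wavelength dataset.

What the synthetic data do **not** emulate: real duplex conformation, sugar
pucker, base pairing and mismatches, crystal packing, solvent structure,
Fourier series termination ripples, anisotropic disorder, and correlated map
noise.  Passing round-trip tests therefore demonstrates the correctness of
the geometry, peak-measurement and decision logic — not robustness to every
pathology of experimental maps.  Likewise the titration generator's
additive homoscedastic Gaussian noise reflects the equal-weighting
assumption of the analysis, not instrument-specific error structure.

## Problem sizes

The default test and acceptance runs use: 50 seeded repetitions of the
triplicate 12-point titration design for parameter recovery (median fitted
K_D reported); 50 simulated experiments per AIC selection rate; 50 random
strands (6–15 nt) for the noiseless stereo round trip and 20 seeded strands
at 0.5σ voxel noise for the noisy one; 10⁴ random draws for the
quadratic-root oracle comparison.  These sizes give stable medians and rates
(binomial SE on a 90% rate at n=50 is ~4%) while keeping a full run in tens
of seconds.

## Known limitations

* The NS term's unbounded linear growth makes fits with NS free sensitive to
  the top-concentration points; the AIC guard prefers NS = 0 when the data
  do not demand otherwise.
* Chirality assignment requires both candidate sites; linkages missing OP
  atoms are skipped with a warning rather than reconstructed from one site.
* The sequence-alignment pairing in `match_calpha` assumes near-identical
  sequences (identity scoring); remote homologs would need a substitution
  matrix.
* Deposited-structure reproductions (superposition RMSDs, pocket contacts on
  archived entries) require network access to fetch coordinates and are
  exercised only in the two tests that do so.
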