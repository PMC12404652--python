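# Methods

This note records the models, conventions and parameter choices behind
`endopheno`, and what its validation does and does not demonstrate.

## Signal-accumulation metric

The per-cell statistic is `max(I) / median(I)` over all pixels of the
cell ROI in the tagged channel, with the nucleus included and no
background subtraction. The raw-pixel convention is deliberate: the
metric is a within-ROI shape statistic, and any flat-field or offset
correction would change scores (an additive offset pushes scores toward
1; this is tested as a documented behavior, not a bug). Consequences:

- the score is ≥ 1 (the maximum of a set is never below its median) and
  exactly 1 only for a homogeneous ROI;
- it is invariant under multiplicative intensity rescaling (exposure,
  gain, detector units), so scores are comparable across acquisitions up
  to additive background differences;
- the median of an even-sized pixel set uses midpoint interpolation
  (NumPy convention), fixed so results are bit-reproducible and checked
  against a sort-based oracle.

A cell with zero median cannot be scored; it is reported with NaN and a
warning rather than silently dropped.

Signal-to-noise filtering is defined as the ratio of a cell's median to
the median of a designated non-expressing cell in the same field, with a
default cutoff of 3. Both the formula and the cutoff are implementation
conventions (configurable), chosen as the simplest ratio that uses the
non-expressing reference; they are not claims about any particular
instrument.

## Phenotype classifier

The classifier is a deterministic surrogate for blinded human scoring.
Pipeline per cell: threshold at `k × median` (default k = 3), remove
components below `min_structure_area` (default 4 px²), compute the
fraction of total cell intensity inside the surviving puncta, then count
structures after dilating by `merge_radius` (default 2 px, disk) with
8-connected labeling.

Decision rule: `cytoplasmic` if the punctate signal fraction is below
`localized_fraction_cutoff` (default 0.5; a tie counts as localized);
otherwise `clustered` if the structure count is ≤ `cluster_max` (= 3,
the one constant fixed by the scoring convention this mirrors) and
`distributed` above it. The pre-count dilation emulates a human grouping
of touching vesicle clumps; counting is verified against a brute-force
flood-fill oracle (including a naive Euclidean dilation) on random
masks. Because the threshold is median-relative, calls are invariant
under multiplicative intensity scaling.

All parameters except `cluster_max` are defaults, not claims; how "dim
cytoplasmic signal" maps to a numeric cutoff is genuinely
underdetermined, and 0.5 was chosen as the least-informative split.

A blinding utility (`blind_ids`) produces a seeded permutation key of
cell identifiers, reproducing the rename-to-random-numbers workflow and
enabling scorer-agreement experiments.

## Replicate statistics (SuperPlots)

Cells within a biological replicate are correlated, so inference uses
only the per-(construct, replicate) arithmetic means; adding or removing
cells that leave a replicate mean unchanged cannot change any test
result (tested). Designs:

- paired two-tailed t-test on replicate means;
- repeated-measures one-way ANOVA with Dunnett many-to-one comparisons
  against a reference construct. The error term is the subject×treatment
  interaction mean square with (k−1)(n−1) degrees of freedom; adjusted
  p-values are two-sided tail probabilities of the equicorrelated
  (ρ = 1/2) multivariate-t distribution, computed by deterministic
  quadrature (Gauss–Hermite over the shared normal factor, adaptive
  quadrature over the chi-distributed scale). Agreement with published
  multivariate-t values is tested to |Δp| ≤ 1e-3, and the two-group case
  collapses to the paired t-test (tested to 1e-6);
- repeated-measures ANOVA with Tukey all-pairs adjustment via the
  studentized range distribution;
- unpaired one-way ANOVA Dunnett via `scipy.stats.dunnett`.

Zero variance of paired differences raises an explicit degenerate-result
error instead of returning a meaningless p. Significance bands use
inclusive cutoffs at 0.05/0.01/0.001/0.0001 (`*` to `****`, `ns` above
0.05). Type-I error of the paired t at α = 0.05 is verified at
0.05 ± 0.02 over 5,000 simulated three-replicate null experiments.

Fold-changes are reported as the ratio of means of replicate means
(reference = 1 by construction); because the convention is ambiguous in
general use, the mean of per-replicate ratios is computed alongside for
complete paired designs. Normality testing is out of scope: with three
to six replicates per group it has essentially no power.

## Flow-cytometry trafficking assay

Three conditions measure surface receptor by geometric mean of the
surface-label intensity among expressing cells: `Total` (antagonist
only), `Internalized` (agonist only), `Recycled` (agonist then
antagonist). Estimators:

    internalization = 1 − Internalized/Total
    recycling       = (Recycled − Internalized)/(Total − Internalized)

`Total = Internalized` makes recycling undefined and raises an error
naming the degeneracy. Estimates outside [0, 1] (possible with noise)
are returned with an out-of-range flag rather than clipped.

Expression gating keeps events whose GFP intensity strictly exceeds the
99th percentile (linear interpolation) of a non-expressing control
population; 99 is the conventional control-based gate and is
configurable. Geometric means exclude nonpositive values with a logged
count — adding an offset instead would bias the geometric mean.
Scatter-based cell/singlet gating is out of scope; event tables are
expected pre-gated (the simulator emits them that way) and are CSV
rather than FCS binary.

## Sequence features

Coordinates are 1-based inclusive throughout, matching construct
nomenclature (`2198t` keeps 1..2198; `t347` keeps 348..end). Disorder
consensus is the element-wise mean of binary per-residue calls across M
structure models, so values lie on {0, 1/M, …, 1} and hit 1 (or 0) only
on unanimity. Alanine scanning replaces consecutive non-overlapping
triplets anchored at the region start with `AAA`, skipping (and logging)
a 1–2 residue remainder; windows already reading `AAA` are emitted and
flagged. Phospho-capable counting tallies S/T/Y and reports the percent
rounded to the nearest integer alongside the raw fraction. The
conservation profile is the per-column modal-residue fraction among
non-gap sequences — a deliberate surrogate, not a reimplementation of
any particular alignment viewer's score.

The package bundles only toy sequences plus `O75165_SYNTHETIC`, a
synthetic full-length stand-in (2,243 residues) whose C-terminal 45-mer
carries two YLT motifs at full-length positions 2206 and 2215 and
exactly 13 S/T/Y residues (29%), with tyrosine-free filler upstream. It
exists so the worked arithmetic can run without any download; analyses
of the real protein should be run on a user-supplied UniProt FASTA,
which drops into the same functions unchanged.

## Synthetic scene generator

The generator defines the conditions under which the pipeline is
validated. Cells are random ellipses (semi-axes 16–22 px) placed without
overlap, fully inside the field, with bounded retries (failure raises a
placement error). Each expressing cell draws a total GFP amount from a
log-normal (μ = 10, σ = 0.8 on the log scale, ≈10-fold spread) emulating
transient-transfection heterogeneity; a fraction φ goes into `n_puncta`
(default 6) Gaussian spots (σ = 1 px, truncated at 3σ and renormalised
to unit mass so intensity is conserved to discretization), the remainder
is spread uniformly over the cell. Distributed arrangements enforce a
minimum spot separation (12 px, relaxed only when a cell is too full) so
spots render as distinct structures; clustered arrangements draw cluster
centers in a perinuclear band and jitter member spots within ~1 px so
each group stays contiguous. A constant per-cell pedestal
(`cytoplasm_baseline`, default 2) represents autofluorescence and is
what makes non-expressing reference cells measurable for SNR; the
intensity-conservation guarantee is therefore stated net of the
pedestal. Noise is Poisson on the rendered intensities followed by
additive Gaussian read noise (σ = 2) and clipping at zero — the standard
camera model. Membrane outline, nucleus fill and a marker channel
(each punctum included with probability 0.9) complete the field.
Rendering uses 32-bit floats; TIFF export scales to 16 bits with the
scale recorded in a JSON sidecar.

The flow simulator draws per-event surface intensities as log-normal
multiplicative noise around the exact condition geometric means implied
by the specified true internalization and recycling fractions, with
non-expressing events pinned at the untreated level — so an estimator
that fails to gate is biased, which is the failure mode gating guards
against. With cv = 0 the construction is exact and recovery is to
machine precision.

Sizes used in the shipped tests and acceptance checks (6–30 cells per
field, fields of 192–640 px, 10,000 flow events, 20 seeds, 5,000 null
experiments) were chosen as the smallest scales at which the recovery
and calibration checks are statistically meaningful.

What the generator does **not** emulate: 3D optics and defocus, a real
point-spread function, spatially varying illumination, cell crowding and
overlap, vesicle motion, autofluorescence texture, or realistic endosome
size/number distributions (spot count and size are free parameters, not
biological claims). Passing recovery tests therefore demonstrates the
estimators' correctness under the stated statistical structure, not
performance on any particular microscope's data.

## Numerical conventions and degenerate inputs

- Pixel coordinates are 0-based (row, col); line scans address pixel
  centers and interpolate bilinearly, min-max normalizing each channel
  along the scan (constant channel → all zeros by convention).
- Strict inequalities: puncta threshold (`> k·median`) and expression
  gate (`> percentile`); inclusive: SNR cutoff (`≥`), localized-fraction
  cutoff (`≥`), significance bands (`≤`).
- Errors are raised (not silently absorbed) for: zero-median regions in
  classification, empty replicate groups, zero-variance paired
  differences, no positive values for a geometric mean, out-of-range
  sequence edits, zero-length line scans, and unplaceable scenes.

## Known limitations

- The classifier's agreement with human scorers is untestable here;
  only its agreement with simulated ground truth and its internal
  determinism are demonstrated.
- The repeated-measures Dunnett assumes the equicorrelation structure
  implied by a balanced complete design; unbalanced paired designs are
  rejected rather than approximated.
- Geometric-mean summaries assume roughly log-normal intensity
  distributions; heavy contamination by debris events (no scatter
  gating) would bias them.
- The conservation profile ignores residue similarity (no substitution
  matrix); it identifies strictly conserved columns only.
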