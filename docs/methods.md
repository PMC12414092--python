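# Methods

## Library enumeration

The residue-class scheme is an ordered partition of the 20 standard amino
acids into six physicochemical classes (acidic, basic,
hydrophobic/aliphatic, aromatic, polar-uncharged, unique). A motif seeds a
library in which every position may carry any residue of the class of the
motif residue at that position, *including the original residue* — the
library size is therefore the plain product of per-position class sizes
(3600 for the 8-mer `GEPDTYWQ`), and the motif is always a member.

Enumeration order is our own deterministic convention: positions vary
rightmost-fastest and class members are taken in scheme order. The web
generator this mirrors does not document its ordering, so library indices
(`PCS1…PCSn`) are reproducible within `pepfunnel` but not comparable to any
external numbering. Ambiguity codes (B, Z, X) and the rare residues (U, O)
are rejected rather than mapped: the scheme is defined only over the 20
standard codes.

## Descriptors

* **Mass**: Expasy average (default) and monoisotopic residue masses plus
  one water (18.01528 / 18.01056 Da). Summation is done in integer 10⁻⁵ Da
  units, so sequences whose residue multisets have equal summed table masses
  (e.g. a D+Q vs E+N swap) come out bit-identical. Published masses from the
  screening web server reproduce to within 0.25 Da; the server's mass table
  is unpublished, so exact agreement is not expected.
* **Net charge**: the integer side-chain convention, (#K + #R) − (#D + #E);
  histidine and termini contribute 0. This is the convention under which
  every member of the `GEPDTYWQ` library carries exactly −2 (the motif's two
  acidic-class positions are conserved as acidic, and no position admits a
  basic residue).
* **Isoelectric point**: root of the Henderson–Hasselbalch net-charge curve
  over pH 0–14, found by Brent bisection to 10⁻⁴ pH. The charge curve is
  strictly decreasing, so the root is unique. Packaged pKa set: EMBOSS
  (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
  Y 10.1); the set is selectable by name.
* **Hydrophobicity / amphipathicity**: mean of the Eisenberg consensus
  scale, and the helical hydrophobic moment μH = |Σₖ hₖ(cos kδ, sin kδ)|/N
  at δ = 100°. μH is linear (homogeneous of degree one) in the scale values,
  not shift-invariant — a deliberate property, tested as such. The screening
  server's hydrophobicity and amphipathicity scales are unidentified (all 16
  published hits share the amphipathicity value 0.16, which no documented
  scale reproduces), so the published columns are treated as *inputs* to the
  funnel, never as targets for these descriptors.

## Toxicity model

A support-vector machine over amino-acid composition (AAC, 20 fractions),
dipeptide composition (DPC, 400 overlapping fractions) or their
concatenation (default). Labels: decision value > 0 ⇒ Toxin; more positive
means higher confidence of toxicity. The screening predicate is a separate
band — retain score > −0.30 *and* label Non-Toxin — because the published
funnel keeps Non-Toxin peptides with scores in (−0.30, 0). Why the band
excludes *more*-negative (safer-scoring) peptides is not explained in the
source protocol; it is implemented as configured.

The published training corpus is not redistributable, so the packaged
benchmark is synthetic: toxins over-sample C, K and R five-fold relative to
uniform *and* place those residues as one contiguous run at a random offset.
The clustering is a permutation — invisible to AAC, visible to DPC — so
composition-only and AAC+DPC models have genuinely different ceilings, as
they do on real toxin data where local order (e.g. clustered cysteines of
disulfide-rich toxins) matters. This is a caricature for validation, not a
biological model: passing tests show the learner recovers a planted rule of
this shape, not that it predicts real toxicity. Benchmark conditions:
500/500 training peptides of length 15, an equal-size held-out draw, linear
kernel, C = 1.

## Aggregation profiling

Per-residue a4v values from the in-vivo AGGRESCAN scale (packaged, swappable).
The hot-spot window average (HWA) is a centred moving average, window 5 for
short sequences (< 75 residues, the original method's rule), truncated at the
termini rather than padded so the HWA is defined at every position. Hot
spots are maximal runs of ≥ 5 residues with HWA > −0.02; prolines split runs
by default (β-breaker behaviour). The funnel statistic is
Na4vSS = 100·a4vSS/N = 100·mean(a4v); exclusion is *strict* (Na4vSS < −57),
so a candidate exactly on −57 survives — the shipped hit table contains
exactly such a boundary case. The original method's end-effect corrections
are not reconstructible from the protocol source, so published Na4vSS values
are calibration references, not recomputation targets. Area-based statistics
(HSA/THSA etc.) are not part of the funnel and are left to the profile
consumer.

## The screening funnel

Stages are pure predicates (field, comparator, threshold, optional
exact-match side conditions); the report records per-stage input/retained
counts and id sets, and the final set equals the intersection of all
non-informational predicates regardless of order. Default cascade and
thresholds, following the published narrative: toxicity band (> −0.30,
Non-Toxin) → amphipathicity (retain ≤ 0.30) → hydrophobicity (retain
≥ −0.20) → molecular weight (≤ 900 Da, *informational only* — the narrative
kept every candidate at this step although masses exceed the stated bound)
→ aggregation (Na4vSS ≥ −57).

Two documented text-vs-data conflicts are surfaced rather than absorbed:
the amphipathicity threshold is stated as "> 0.30" yet every surviving hit
prints 0.16 (default retains ≤ 0.30; the opposite direction is one stage
definition away), and 9 of the 16 published hits print hydrophobicity below
the stated −0.20 cutoff (the default cascade excludes them; the test suite
asserts exactly this discrepancy). The published intermediate counts
(3600 → 172 → 88 → 19 → 16) depend on the web servers' score columns for
all 3600 candidates, which are not machine-readable here; the funnel
therefore consumes score CSVs and ships the 16-row hit table as a fixture.

## MM/GBSA bookkeeping

Identities: E_gas = E_int + E_vdw + E_ele; G_sol = G_GB + G_SA;
G_SA = γ·SASA with γ = 0.0072 kcal/mol/Å² (1.4 Å probe);
ΔG_bind = E_gas + G_sol − TΔS. TΔS defaults to absent (0): the shipped
energy table reports no entropy term, and normal-mode entropy is out of
scope. E_int is taken as 0 when a table omits it. The audit re-derives every
identity whose operands are present and flags discrepancies beyond 0.05
kcal/mol (two-decimal rounding of each operand). On the shipped table the
reference-inhibitor row fails both the gas-sum and the total-binding
identity by ~0.3 kcal/mol — a genuine internal inconsistency of the
published numbers whose origin (components vs total) cannot be resolved —
and the top-hit row's gas sum is off by 0.09, consistent with a small
unreported E_int or rounding. One standard error in that table (248.63 ±
114) is stored verbatim; it is almost certainly a typeset artifact of 1.14.
The endpoint form ΔG_bind = G_complex − G_receptor − G_ligand is supported
as an alternative constructor via per-term differences and agrees with the
component form on consistent inputs by construction.

Per-residue decomposition entries are ranked ascending (most favourable
first), stable on ties. The shipped decomposition fixture stores three
printed energies against the first three of four listed residue names, as
the source sentence is ambiguous (noted in the file header).

## Trajectory metrics

* **Superposition**: Kabsch SVD with the determinant correction, always a
  proper rotation; requires ≥ 3 non-collinear atoms. Cross-checked in tests
  against an independent solver.
* **Alignment convention**: per-frame metrics are computed after aligning
  the selection to the time-averaged structure (mean recomputed once after a
  first alignment pass). Functions accept `prealigned=True` for ensembles
  without rigid-body drift; note that alignment absorbs up to 6 of the 3N
  displacement degrees of freedom, slightly deflating fluctuation estimates
  for small selections.
* **RMSF**: per-atom root-mean-square deviation from the time mean, averaged
  per residue. For isotropic per-axis noise σ the expected value is √3·σ.
* **Radius of gyration**: uniform weights by default (mass weighting
  optional), as the weighting convention in the source protocol is unstated.
* **SASA**: an in-package Shrake–Rupley implementation — golden-spiral test
  points (default 960) on each solvent-expanded sphere, neighbour culling
  via a k-d tree, probe 1.4 Å, Bondi-style van-der-Waals radii. Validated
  against the analytic isolated-sphere area 4π(r + 1.4)²; doubling the point
  count moves results by < 0.5 %. Atoms with exactly identical coordinates
  are treated as fully buried duplicates with a warning.
* **DCCM**: normalised covariance of displacement vectors; symmetric,
  unit diagonal, entries clipped to [−1, 1]; zero-variance atoms (up to
  float rounding) get zero off-diagonal entries with a warning.
* **PCA**: economy SVD of the centred frame × 3N coordinate matrix —
  eigenvalues descending, orthonormal modes, centred projections, and the
  trace identity (Σλ = total variance) holds to 10⁻⁶.

Published trajectory-derived magnitudes (mean RMSD ≈ 1.6 Å, RoG ≈ 25 Å,
SASA ≈ 24,000 Å²) come from 300-ns explicit-solvent MD of the full protein
and are expected magnitudes only; nothing here re-runs MD. Validation is by
parameter recovery on the synthetic generator: known σ profiles recovered
within 5 % at 2000 frames, planted correlation blocks recovered at |C| > 0.9,
a planted single mode captures > 90 % of PCA variance.

## Synthetic generators

Pure functions of (parameters, seed), NumPy `default_rng`, no global state.
The trajectory generator superimposes isotropic Gaussian per-atom noise and
shared-mode blocks (per-frame scalar driver × fixed unit direction) on an
idealised C-α helix, and returns the exact ground-truth RMSF
√(3σ² + Σ amplitude²) alongside the ensemble. The energy generator draws
components in realistic ranges (E_vdw −80…−20, E_ele ±300, G_GB ±300,
G_SA −10…−1 kcal/mol) with consistent sums, and can inject a defect of
stated magnitude into one stored value for audit testing. What the
generators do *not* emulate: real force-field correlations, solvent
structure, sequence-dependent geometry, or the composition of real toxin
databases — green tests demonstrate correctness of the computations, not
fidelity to laboratory data.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: the
full 3600-member library (enumeration is O(library size) and takes
milliseconds), 500/500-peptide toxicity benchmarks, trajectories of up to
2000 frames × 30 atoms, and SASA systems of a few atoms at ≤ 1920 quadrature
points. These sizes give the statistical properties being tested (e.g. 5 %
RMSF recovery needs ~2000 frames) without requiring simulation
infrastructure.

## Known limitations

* Scores from the unpublished web-server models (SVM toxicity values,
  hydrophobicity/amphipathicity columns, Na4vSS end-corrections, folding
  energies, docking scores) cannot be regenerated; the funnel treats them as
  external inputs and the shipped 16-row table is a fixture, so the
  published intermediate funnel counts are config-dependent outputs, not
  assertions.
* The packaged toxicity model is trained on synthetic data; its scores are
  not comparable to the published column's scale.
* No MD, docking, folding or secondary-structure assignment; binary
  trajectory formats are out of scope (multi-model PDB only).
* The integer charge convention ignores histidine protonation and termini;
  use the pI machinery for pH-dependent charge.
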