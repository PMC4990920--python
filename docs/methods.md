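# Methods

## Model and conventions

The central object is a discrete-state, discrete-time Markov state model: a
row-stochastic transition matrix `T` estimated at a lag time τ, whose row i
is the distribution over successors of state i.  The master equation
`dp/dt = K p` with `T = exp(τK)` has the spectral solution

```
p(t) = Σ_n (r_n · p(0)) μ_n^(t/τ) l_n
```

with `μ_n` the eigenvalues of `T`, `l_n`/`r_n` its biorthonormal left/right
eigenvectors (`l_m · r_n = δ_mn`), and implied timescales
`τ_n = −τ / ln μ_n`.  The stationary mode has `μ_0 = 1`, `l_0 = π`,
`r_0 = 1`, and an infinite timescale.  Note the column-stochastic convention
(`T[j,i]` = probability of i→j), common in master-equation notation, is the
transpose of ours; there the population modes are the *right* eigenvectors.
Conversion happens only at the I/O boundary.

Sign convention for non-stationary modes: each right eigenvector is flipped
so its entry sum is ≥ 0; when that sum vanishes within tolerance (it is
exactly zero for left eigenvectors, since `l_n · r_0 = 0`), the first
nonzero entry is made positive.  This makes eigenmode amplitudes
reproducible across platforms and lets population flux be read consistently
off the sign structure.

For reversible matrices the spectrum is computed through the symmetric
similarity transform `D^{1/2} T D^{−1/2}` (`D = diag π`), which guarantees a
real spectrum and orthogonal modes; the stationary distribution comes from
the estimator itself (reversible MLE) or from a minimum-norm linear solve of
`π(T − I) = 0, Σπ = 1` (which picks the uniform blend for degenerate chains
such as the identity).  Non-reversible matrices go through a general
eigensolver; complex pairs are flagged and their real parts retained, never
silently truncated.

### Estimators

* **Counting.**  Sliding-window counting (every pair `(t, t+τ)`) is the
  default: it uses all data and is consistent with likelihood estimation at
  short lags.  Strided counting is available for independence checks.
  Counts are trimmed to the largest strongly connected component (most
  states, ties by total counts) and the dropped states are always reported.
* **Reversible MLE.**  The likelihood `Π T_ij^{C_ij}` is maximized under
  detailed balance by the standard fixed-point iteration on a symmetric
  auxiliary matrix, `x_ij ← (C_ij + C_ji)/(C_i/x_i + C_j/x_j)`,
  `T_ij = x_ij/x_i`.  Detailed balance holds exactly at every iterate;
  convergence is declared when the largest relative change of `x` drops
  below 1e−10 (default), capped at 1e6 sweeps.  On symmetric counts the
  initial iterate is already the fixed point, so the estimate equals plain
  row normalization to machine precision.
* **tICA.**  Mean-free, *symmetrized* covariance estimators pooled over
  trajectories with each transition pair weighted equally (matching the
  count weighting downstream); the symmetrization forces a real spectrum
  and is standard practice for reversible dynamics.  The default ridge
  `ε = 1e−10 · tr C(0) / d` keeps the generalized eigenproblem well posed
  when features have zero variance (frozen coordinates) while perturbing
  the spectrum negligibly; with `ε = 0` a singular `C(0)` raises an error
  naming the dead features.  Default lag: one snapshot.
* **Clustering.**  k-centers is a deterministic farthest-point traversal
  (first center = frame 0 by default, ties to the lowest frame index),
  giving bit-reproducible pipelines and a cover radius within a factor two
  of optimal.  k-means runs Lloyd iterations from the k-centers solution;
  an emptied cluster is re-seeded at the farthest point.  The metric is
  plain Euclidean distance in tICA space, with no eigenvalue re-weighting.
* **GMRQ.**  `trace[(AᵀSA)⁻¹(AᵀCA)]` with `A` the first m training
  eigenvectors on the state basis, `S` the diagonal test visit frequencies
  and `C` the symmetrized test transition frequencies.  Folds split whole
  trajectories, never frames, preserving temporal correlation.  Default
  m = 3 (stationary plus two slow modes).  A training state unvisited in
  the test fold makes the overlap singular; a 1e−10 pseudocount ridge is
  applied with a warning rather than dropping the fold.
* **BACE.**  The merge criterion is the leading log-likelihood-ratio term
  of the Bayes factor between "two states" and "one merged state",
  `ln BF(i,j) = Σ_k C_ik ln(p_ik/q_k) + C_jk ln(p_jk/q_k)` with `q` the
  count-weighted merged row.  Only pairs with at least one observed
  transition are candidates (kinetically disconnected states never merge);
  ties break to the lowest index pair, making the merge sequence
  deterministic.  Counts re-aggregate exactly after each merge.

### Contact enrichment

Frames are partitioned into quadrants about the *medians* of (tIC1, tIC2)
(robust to sign/offset conventions; a zero-centered option exists; boundary
frames go to the lower quadrant index).  Contacts default to heavy-atom
minimum distance < 4.5 Å (Cα alternative: 8.0 Å).  Enrichment of a contact
in a region is the smoothed odds ratio

```
BF = [f_r/(1−f_r)] / [f_a/(1−f_a)],   f = (k + α)/(n + 2α),  α = 1
```

kept behind a single function so the smoothing can be swapped.  The
complement identity `BF(contact) · BF(no contact) = 1` holds exactly.  Note
that with zero observed contacts the smoothed ratio is `(n_a+α)/(n_r+α)`,
i.e. unity only when the region spans all frames — a deliberate property of
the smoothing, not a bug.

### Torsion accounting for rigidified peptides

Helical peptide ligands are rigidified for docking by an artificial bond
between the terminal alpha-carbons (the backbone N-to-C variant is
available), closing a macrocycle through the entire backbone; docking
engines treat closed cycles as rigid, so the backbone becomes a single
anchor while sidechains stay searchable.  Ring perception is graph
theoretic (a bond is in a ring iff it is not a bridge).

Two tallies are kept, as one rule table in `docking/torsions.py`:

* **perceived** — flexible bonds found by a docking engine's perception on a
  fully flexible ligand: single, acyclic, heavy-heavy bonds with ≥ 2 atoms
  riding on each side.  Methyl/ammonium rotors count; a lone hydroxyl
  hydrogen does not.
* **grown** — torsions actually sampled by anchor-and-grow around a rigid
  anchor: bonds moving ≥ 1 heavy atom or a polar hydrogen; pure-carbon
  methyl rotors are frozen and the conjugated tyrosine hydroxyl is rigid.

When no convention is forced, a cyclized (anchored) ligand is tallied with
`grown` and a linear one with `perceived` — the quantity an engine reports
in each setup.  This two-mode accounting is a calibration: the two printed
tallies for the p53 fragment (66 linear, 29 rigidified) cannot both be
produced by any single bond-counting rule, because the macrocycle only
absorbs 32 rotatable backbone bonds.  Under this convention the regression
values are: linear ETFSDLWKLLPE (charged termini) = 66; cyclized = 29;
cyclized TSFAEYWALLSP = 21.  Within either fixed convention, cyclization
never increases the count and the decrease equals exactly the number of
previously rotatable bonds absorbed into the macrocycle (a tested
invariant).

Residue templates are heavy-atom graphs with per-atom hydrogen counts at
physiological protonation (charged termini by default, Asp/Glu/Lys charged,
His neutral).  Anchor reporting lists rigid segments of ≥ 5 atoms after
cutting all grown-rotatable bonds; no conformer search is performed.

### Docking statistics

A (ligand, receptor) cell is a *success* when the best-scoring pose is
within 2.0 Å (default) of the crystal pose, a *scoring failure* when a
sampled pose is but the best-scoring one is not, and a *sampling failure*
otherwise; the classes partition all cells.  Pose RMSD follows the docking
convention: computed in the receptor frame with no superposition, with
optional name-based atom correspondence.  For enrichment, receptors are
ranked per ligand by best pose score (ties by receptor id) and TPR(N) is
the fraction of ligands with a success in their top N; it is non-decreasing
and reaches the ligand success fraction at N = n_receptors.  Funnel tables
export (score, rmsd) pairs with a per-ligand Spearman correlation.

## Synthetic data: what it emulates, and what it does not

The chain generator emulates the statistical shape of a distributed
short-trajectory simulation campaign: many trajectories with truncated
exponential lengths (resampled above the cap, floored at 2 frames; defaults
mean 500 / max 5000 frames for desk-scale runs, and the mean-67 / max-945
shape of the emulated campaign is a parameter choice away), round-robin
starts over an initial-conformation pool (default pool of 24 in the spec
type, 4 for the planted chain), and latent slow two-state structure under
diffuse high-dimensional emissions.

The planted chain is a symmetric doubly-stochastic 4×4 matrix with exact
spectrum {1, 0.95, 0.5, 0.3}, constructed by spectral synthesis over a
Helmert basis; its slow mode separates state 0 from a fast-mixing triplet,
so τ₁ = −1/ln 0.95 ≈ 19.50 steps with a τ₁/τ₂ gap of ln 0.5 / ln 0.95 ≈
13.5.  Emissions are state means drawn once from a seeded standard normal
in 10-D plus isotropic Gaussian noise, default σ = 0.25.  With unit-scale
means the typical inter-mean distance is ≈ 4.5, so σ = 0.25 puts the
fixture firmly in the decodable regime: state labels are recoverable from
features, and pipeline tests probe estimator recovery rather than
boundary-microstate misassignment.  (At σ ≈ 0.5 the basins overlap enough
in the 2-D projection that discretization recrossings, not estimation
error, dominate the apparent τ₁ — a real phenomenon, but a different
experiment.)  Randomness uses one global seed expanded through a
splitmix64 counter, so adding trajectories never reshuffles existing ones.

What the generator does *not* emulate: non-Markovian memory within states,
state-dependent emission anisotropy, slow drift, or anything resembling
actual molecular geometry.  Passing recovery tests therefore demonstrates
correctness of the estimators under the model's own assumptions — not that
a particular molecular system is two-state.

The double-well sampler integrates overdamped Langevin dynamics
(Euler–Maruyama, kT = 1) on
`U(x,y) = h((x/a)² − 1)² + ½(y/w)²`, `a = separation/2`, with
fluctuation–dissipation-consistent noise; long runs reproduce Boltzmann
occupancies (a tested oracle), and divergence (|x| > 10·separation) raises
an integration-instability error rather than returning garbage.

## Numerical choices

* Tolerances: row-stochasticity 1e−12 on generators, 1e−10 on estimator
  outputs; detailed balance residual 1e−10; biorthonormality 1e−8;
  reversible-MLE convergence 1e−10 relative.
* Tie-breaks are always "lowest index": k-centers farthest-point ties,
  nearest-center assignment ties, BACE merge ties, quadrant boundaries,
  enrichment score ties (receptor id).
* Degenerate inputs: identity transition matrices get the uniform
  stationary blend; single-frame quadrant input is valid; empty clusters
  re-seed at the farthest point.
* Implied timescales are ∞ for μ ≥ 1 − 1e−12 and undefined (NaN) for
  μ ≤ 0.

## Problem sizes

Default test and pipeline sizes are desk scale by design: 200 trajectories
with mean length 500 frames (~10⁵ frames), 50 microstates, lags 1–20.
These sizes give sampling errors of a few percent on the planted slow
timescale, small against the 15% recovery tolerance used in the tests.

## Known limitations

* The "2304 pairwise distances" of the emulated study cannot be
  reconstructed as C(n,2) for any integer n nor as a lid × site product;
  both an all-pairs and a cross (lid × site) rule are provided and the rule
  used is recorded in output headers rather than pretending to resolve the
  discrepancy.
* No rate-matrix (K) estimation: K is defined only implicitly through
  `T = exp(τK)` and matrix logarithms of estimated matrices are
  ill-conditioned; the package never computes K.  No transition-path
  theory, committors, or PCCA+.
* The BACE Bayes factor is the leading likelihood-ratio term, not the full
  marginal-likelihood expression; for well-separated blocks they order
  merges identically.
* DSSP letters are consumed, never computed; no chemical-shift prediction;
  the docking engine itself (grids, minimizer, conformer search) is out of
  scope — only its outputs are evaluated.
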