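# lidmsm

Markov state models (MSMs) of a receptor whose intrinsically disordered
N-terminal "lid" competes with a peptide ligand for its binding cleft — and
the evaluation statistics for docking ligand libraries against the receptor
conformations such a model produces.

The package is for structural/computational biologists who want a tested,
desk-scale implementation of the full modelling chain:

1. **Featurization** — pairwise C&alpha; distances over the lid segment plus
   binding-site residues selected by proximity to a bound ligand; DSSP
   letter strings reduced to helix/sheet fractions.
2. **tICA** — time-lagged independent component analysis,
   `C(τ) v = λ (C(0) + εI) v`, with symmetrized, mean-free covariance
   estimators pooled over trajectories.
3. **Clustering** — deterministic farthest-point k-centers (default) or
   Lloyd k-means in the projected space.
4. **MSM estimation** — transition counting at a lag τ, ergodic trimming,
   multinomial or reversible (detailed-balance constrained) maximum
   likelihood, and the spectral solution of the master equation

   p(t) = Σₙ (rₙ·p(0)) μₙ^{t/τ} lₙ,  with implied timescales
   τₙ = −τ / ln μₙ.

5. **Model selection** — generalized matrix Rayleigh quotient (GMRQ)
   cross-validation with trajectory-level folds.
6. **Coarse-graining** — BACE-style Bayesian agglomerative lumping of
   microstates by the smallest log Bayes factor between outgoing transition
   distributions.
7. **Contact enrichment** — smoothed odds-ratio Bayes factors for residue
   contacts inside quadrants of the (tIC1, tIC2) landscape.
8. **Docking evaluation** — peptide rigidification via an artificial bond
   between terminal alpha-carbons, rotatable-torsion accounting,
   pose-RMSD, the success / scoring-failure / sampling-failure taxonomy,
   cross-docking outcome matrices, funnel tables and top-N true-positive
   enrichment curves.

A synthetic-data module generates trajectory ensembles with planted ground
truth (a 4-state reversible chain with eigenvalues {1, 0.95, 0.5, 0.3} and
Gaussian feature emissions, exponential trajectory lengths, a 2-D
double-well Langevin sampler), so every stage has a parameter-recovery test
with no external dataset.

## Worked example

Recover the planted slow timescale through the full pipeline:

```python
import numpy as np
from lidmsm.synthetic import default_chain_spec, sample_lengths, simulate_chain
from lidmsm.tica import TICA
from lidmsm.cluster import KCenters
from lidmsm.msm import implied_timescale_curves

spec = default_chain_spec(seed=1, n_trajectories=200)
_, features = simulate_chain(spec, sample_lengths(spec))
tica = TICA(lag=1).fit(features)
proj = [tica.transform(f, n_components=2) for f in features]
clusterer = KCenters(k=50).fit(np.vstack(proj))
labels = [clusterer.predict(p) for p in proj]
print(implied_timescale_curves(labels, [1, 2, 5, 10, 20], n_timescales=2)
      .round(3).to_string(index=False))
```

```
 lag  lag_time  tau_1  tau_2  gap_ratio
   1       1.0 18.721  1.432     13.075
   2       2.0 18.816  1.427     13.185
   5       5.0 19.037  1.531     12.436
  10      10.0 18.958  2.813      6.738
  20      20.0 18.798  6.029      3.118
```

The slowest implied timescale is flat in the lag (18.7–19.0 steps against a
planted value of −1/ln 0.95 ≈ 19.50, within 4%), and the large τ₁/τ₂ gap at
short lags is the fingerprint of effective two-state kinetics: here, the
planted slow exchange between state 0 and the fast-mixing triplet {1, 2, 3}.
τ₂ drifts upward at lags beyond its own relaxation time (μ₂²⁰ is smaller
than the counting noise), which is why the gap is read off at short lags.

Torsion accounting for a rigidified helical peptide, from the command line:

```sh
$ lidmsm dockeval torsions --sequence ETFSDLWKLLPE --cyclized
sequence: ETFSDLWKLLPE
convention: grown
total: 29
  backbone_phi: 1
  backbone_psi: 1
  backbone_omega: 0
  sidechain_heavy: 24
  polar_hydrogen_rotors: 3
  terminal_rotors: 0
```

The same peptide in linear form has 66 perceived flexible bonds; cyclization
absorbs the backbone into one rigid anchor and leaves only the sidechain
torsions plus the two dangling terminal bonds.

The same chain is scriptable end to end: `lidmsm run --out rundir --seed 1`
writes labels, counts, spectra, an implied-timescale table and a summary
manifest; `lidmsm simulate | tica | cluster | msm | timescales | bace |
enrich | dockeval` expose the individual stages on plain-text files.

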