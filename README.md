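# edgentropy

Sample-entropy analysis of time-varying functional connectivity (TVFC) and
variance-component brain–behavior modelling, built for resting-state fMRI
studies that relate the *timescales* of connectivity fluctuations to
cognitive performance — for example in early-psychosis cohorts scored on a
standard cognition battery.

## The science in brief

Every pair of brain parcels defines an edge whose sliding-window
correlation is itself a timeseries. The sample entropy of that series —
edge sample entropy (ESE) —

```
SampEn(x; m, eps) = -ln( U^{m+1} / U^m ),    r = eps * sigma_x
```

measures how *irregular* the edge's connectivity fluctuations are: low ESE
means self-similar, slowly evolving coupling (long integration
timescales), high ESE means erratic coupling. With the standard m = 2 and
eps = 0.20, each subject yields one ESE value per edge (6670 edges for a
116-parcel atlas).

High- and low-entropy network templates (HEN/LEN) are the edges with the
largest and smallest group-mean ESE in a reference (control) group at a
chosen density. Masking patients' ESE vectors with a template and
correlating them across patients gives a similarity matrix `R`, which
enters a multivariate variance-component model of the behavioral table
`Y` (N subjects × P measures):

```
Y = XB + C + E,   Vec(C) ~ N(0, Sigma_c ⊗ R),   Vec(E) ~ N(0, Sigma_e ⊗ I)
```

Covariates `X` are removed by projection onto the orthogonal complement of
their column space; `Sigma_c`, `Sigma_e` are estimated in closed form by
moment matching with the kernel moments τ = Tr(R)/N, κ = Tr(R²)/N and
ν = N(κ − τ²). The headline quantity is the variance explained

```
M = Tr(Sigma_c) / (Tr(Sigma_c) + Tr(Sigma_e)),
```

with per-measure fractions from the matrix diagonals, a one-sided Wald
test and a permutation test (rows and columns of R permuted jointly), and
bias-corrected bootstrap / jackknife confidence intervals for HEN-vs-LEN
contrasts. Downstream analyses cover edgewise (rank-one-kernel) variance
estimates aggregated into 8 system blocks and tested against edge-shuffle
and degree/strength-preserving rewire nulls, normalized degree-centrality
and its HEN−LEN "Node-Entropy" summary, and correlation of Node-Entropy
with cortical annotation maps under variogram-matched spatial surrogates.

Because real imaging data of this kind are access-restricted, the package
ships a first-class synthetic-data generator whose planted ground truth
(regular/irregular edge sets, behavioral variance fractions, map
smoothness) is recoverable by every pipeline stage.

## Worked example

```python
import numpy as np
from edgentropy import synth
from edgentropy.entropy import edge_entropy
from edgentropy.templates import (group_mean_entropy, proportional_threshold,
                                  build_similarity)
from edgentropy.tvfc import preprocess_timeseries, sliding_window_correlation
from edgentropy.varcomp import VarianceComponentModel, quantile_normalize

cfg = synth.SyntheticConfig(n_controls=20, n_patients=40, n_parcels=30,
                            n_frames=410, seed=7)
plan = synth.make_plan(cfg.n_parcels, n_regular_pairs=6,
                       n_irregular_nodes=3, seed=cfg.seed)
subjects = synth.generate_parcel_timeseries(cfg, plan)

entropy = {"control": [], "patient": []}
for ts in subjects:
    ed = sliding_window_correlation(preprocess_timeseries(ts))
    entropy[ts.group].append(edge_entropy(ed).values)

mean_ese = group_mean_entropy(np.array(entropy["control"]))
len_mask = proportional_threshold(mean_ese, 0.06, "LEN")
print(f"LEN template: {len(len_mask)} edges at density {len_mask.density}")

patients = np.array(entropy["patient"])
R = build_similarity(patients, len_mask)
X = synth.generate_covariates(cfg.n_patients, seed=8).to_numpy()
Y = synth.generate_behavior(
    synth.spec_for_fraction(0.4, 7, R, n_covariates=5), X, seed=9)

fit = VarianceComponentModel(n_perm=999, random_state=0).fit(
    quantile_normalize(Y).to_numpy(), R, X)
print(f"variance explained M = {fit.m_overall_:.2f} "
      f"(SE {fit.se_overall_:.2f})")
print(f"p-Wald = {fit.p_wald_:.4f}, p-Perm = {fit.p_perm_:.4f}")
print("per-measure fractions:", np.round(fit.m_per_measure_, 2))
```

prints

```
LEN template: 26 edges at density 0.06
variance explained M = 0.38 (SE 0.16)
p-Wald = 0.0000, p-Perm = 0.0010
per-measure fractions: [0.12 0.64 0.61 0.45 0.4  0.22 0.17]
```

Behavior was planted at an overall fraction of 0.40 through the LEN-masked
similarity matrix: the model recovers M = 0.38, both tests reject the null
(the permutation p is at its resolution floor for 999 permutations), and
the per-measure fractions scatter around the planted value as expected for
a 40-patient draw.

The same flow is available from a shell:

```bash
edgentropy simulate --out data/sim --seed 1
edgentropy all --data data/sim --out results/run1 --seed 1
edgentropy controls --data data/sim --out results/ctl --mode shuffled-edges
```

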