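# mseplsc

EEG complexity and brain–behavior correlation analysis for three-group
(ASD / ADHD / control) cognitive-task studies: multiscale sample-entropy
feature extraction from 14-channel EEG, behavior and seed partial-least-
squares correlation (PLSC) with permutation inference, and graph-theoretic
summaries of the resulting functional connectivity. A synthetic-cohort
generator with a planted brain–behavior correlation makes every stage
testable end to end without access to clinical recordings.

Intended users: researchers analyzing multichannel EEG complexity against
behavioral/demographic measures in grouped designs, and anyone who needs a
tested, reproducible reference implementation of the MSE → PLSC →
connectivity chain.

## The methods in brief

**Multiscale entropy.** For each channel, sample entropy
SampEn(m, r) = −ln(A/B) — the negative log conditional probability that two
length-m templates within Chebyshev tolerance r remain within tolerance at
length m+1 — is computed on coarse-grained versions of the signal
(non-overlapping window means of width τ = 1..20), with m = 2 and
r = 0.15·sd. The analysis feature per subject and channel is the mean over
scales.

**Behavior PLSC.** The subjects × channels feature block X and the
subjects × 3 behavior block Y (age, mean emotional state, confidence) are
centered and scaled to unit column sum of squares within each group; the
stacked per-group correlation matrix R (9 × 14) is decomposed by SVD,
R = U Δ Vᵀ. V weights channels ("brain saliences"), U weights
group-by-measure combinations; brain scores are L_X = Z_X V and behavior
scores L_Y,n = Z_Y,n U_n per group. The global association — the inertia
I = Σ δ_l — is tested by permuting the rows of X (default 10,000
permutations, within-group scope).

**Seed PLSC and graphs.** Channels F3/F4 are removed from X and used as the
second block, yielding a 6 × 12 stacked correlation map of seed-to-channel
connectivity per group. The channels × (group, seed) map is condensed to a
weighted undirected graph (row-wise Pearson correlations), thresholded
(absolute |w| ≥ 0.20 by default), and summarized by node degree, strength,
edge density and betweenness centrality on 1/|w| distances.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
import numpy as np
from mseplsc import (MSEParams, SimulationConfig, behavior_matrix,
                     behavior_plsc, permutation_test, seed_plsc,
                     simulate_cohort)
from mseplsc.pipeline import _features_from_dataset

# a reduced cohort: 10 subjects/group, 4,000 samples, scales 1..5,
# behavior planted on channel FC6 with low noise
loading = np.zeros(14); loading[10] = 1.0
cfg = SimulationConfig(group_sizes=(10, 10, 10), n_samples=4_000,
                       mse_params=MSEParams(tau_max=5),
                       behavior_loading=loading, behavior_noise_sd=0.1,
                       rng_seed=7)
ds = simulate_cohort(cfg)
feats = _features_from_dataset(ds, "valid")
Y = behavior_matrix(ds.behavior, "valid", list(feats.data.index))

res = behavior_plsc(feats, Y)
d = res.decomposition
print("rank", d.rank)
print("LV1 explains %.1f%%" % d.explained_variance[0])
print("top |V| channel:", feats.channels[int(np.argmax(np.abs(d.V[:, 0])))])
perm = permutation_test(feats.values, Y.to_numpy(), res.design,
                        n_perm=199, seed=3)
print("permutation p = %.3f" % perm.p_value)
```

prints

```
rank 9
LV1 explains 47.0%
top |V| channel: FC6
permutation p = 0.030
```

The first latent variable carries the planted FC6–behavior association —
its brain salience peaks on the loaded channel — and the observed inertia
exceeds 194 of the 199 within-group row permutations of X, so the global
brain–behavior association is detected at p = 0.03 (the attainable floor
with 199 permutations is 1/200 = 0.005).

The same analysis runs from the shell:

```bash
mseplsc simulate --out data/ --seed 7 --group-sizes 10,10,10 \
    --n-samples 4000 --tau-max 5
mseplsc extract-mse --in data/ --condition valid --tau-max 5 \
    --out features.csv
mseplsc plsc --features features.csv --behavior data/behavior.csv \
    --condition valid --out plsc_valid/
mseplsc permtest --features features.csv --behavior data/behavior.csv \
    --condition valid --n-perm 10000 --seed 42 --out perm.json
mseplsc seed-plsc --features features.csv --condition valid --out seed_valid/
mseplsc graph --saliences seed_valid/R_seed.csv --threshold 0.20 --out graph/
mseplsc dfs                 # analytic mixed-design degrees of freedom
mseplsc run-all --out bundle/ --seed 42   # everything, both conditions
```

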