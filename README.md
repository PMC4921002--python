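# mdcall

Genotype calling for two-channel SNP-array intensity data, built for the
regime where standard per-SNP mixture models break down: **rare
variants**, whose minor genotype clusters hold a handful of points — or
none at all.

Each sample contributes a raw intensity pair *x = (r, g)* per SNP, one
channel per allele.  Within a SNP the pairs form up to three genotype
clusters (AA, AB, BB) along the contrast axis *y = (r − g)/(r + g)*.
`mdcall` routes every SNP to one of three calling models based on its
estimated minor-allele frequency (MAF) and per-cluster sample sizes
*n<sub>k</sub>*:

| group | condition | model |
|---|---|---|
| g1 | MAF ≥ 0.05 | three-component bivariate Gaussian mixture, fitted by EM |
| g2 | MAF < 0.05 and some cluster has b₁ ≤ n_k < b₂ (b₁=3, b₂=10) | Dirichlet-process Gaussian mixture (collapsed Gibbs) |
| g3 | otherwise | DP mixture on the target SNP stacked with a selected **reference SNP** |

The EM model (g1) is the classical mixture
*x<sub>i</sub> ~ Σ<sub>k</sub> π<sub>k</sub> N(μ<sub>k</sub>, Σ<sub>k</sub>)*
with responsibilities as per-call quality: the **Posterior Rate** (PR) of a
call is the posterior probability of its assigned cluster, the per-SNP
**APR** is the mean PR over assigned samples, and calls with PR < 0.85 are
withheld (NC).  The DP mixture (g2) infers the *number* of occupied
clusters from the data through the Chinese-restaurant-process conditional
with a conjugate Normal–Wishart component prior and a sampled
concentration α.  For extremely rare SNPs (g3) even the DP fails — the
rich-gets-richer property lets a big cluster swallow one or two stray
minor points — so a reference SNP with clean three-cluster structure is
selected (high MAF, balanced clusters, minimal Mahalanobis-type cluster
distance to the target) and its rows are stacked with the target's before
the DP fit, anchoring the missing clusters.

## Worked example

```python
import mdcall as md

specs = md.default_panel_specs(n_samples=150, n_common=14, n_low=3, n_rare=3)
dataset, truth = md.simulate_panel(specs, populations=["POP1", "POP2"], seed=99)
callset = md.run_md(dataset, md.MDConfig(seed=5))

print(md.call_rate(callset), md.accuracy(callset, md.truth_mapping(truth)))
```

Running `python examples/04_full_panel.py` (exactly the above plus
reporting) prints:

```
routing groups: {'g1': 14, 'g2': 3, 'g3': 3}
models used:    {'GMM': 14, 'DP-GMM': 3, 'DP-Ref': 3}
call rate: 99.83 %
accuracy vs simulator truth: 99.53 %
SNPs failing HWE per population: {'POP1': 1, 'POP2': 2}
```

The 14 common SNPs kept their EM calls, the three moderately rare SNPs
were refitted with the DP mixture, and the three extremely rare SNPs were
called with reference assistance; over 99 % of the 3 000 cells received a
genotype and over 99 % of those match the simulator's truth.  The other
`examples/` scripts walk through each model in isolation, printing the
recovered cluster parameters, consensus cluster counts and the
reference-vs-plain comparison for a two-point minor cluster.

A thin CLI wraps the same pipeline:

```sh
mdcall simulate --out-dir sim --seed 3
mdcall run --intensities sim/intensities.tsv --out-dir out --seed 4
mdcall eval --calls out/calls.tsv --truth sim/truth.tsv --populations sim/populations.tsv
```

Input is long-form TSV (`SNP  Sample  r  g  [Population]`); outputs are a
calls table (genotype, PR, model per cell) and a per-SNP summary (APR,
MAF, routing group, cluster sizes).

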