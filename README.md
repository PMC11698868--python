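# alphadiv

Alpha-diversity analysis for microbial count data: 19 within-sample
diversity metrics organized into four complementary categories, an
exactly-controlled synthetic ASV community generator, and a pipeline
for comparing how the metrics behave.

"Alpha diversity" is routinely reported as a single interchangeable
number, but its metrics answer different questions. `alphadiv` groups
them accordingly:

* **Richness** — how many taxa: observed features S, the unseen-species
  estimators Chao1 `S + F1²/(2F2)` and ACE (Chao–Lee, rare threshold
  k = 10), Fisher's log-series α (root of `S = α ln(1 + N/α)`),
  Margalef `(S−1)/ln N`, Menhinick `S/√N`, and Robbins `F1/(N+1)` —
  the probability that the next read is an unseen taxon.
* **Dominance** — how concentrated: Berger-Parker `n_max/N`, Simpson
  `1 − Σp_i²`, its complement (dominance) and inverse (ENSPIE), Gini
  (mean-absolute-difference form), McIntosh `(N−U)/(N−√N)`, Strong
  `max_i(b_i/N − i/S)`.
* **Information** — entropy blends: Shannon `−Σp_i log₂ p_i`,
  Brillouin `(ln N! − Σ ln n_i!)/N`, Heip `(e^H−1)/(S−1)`, Pielou
  `H/ln S`.
* **Phylogenetic** — Faith PD: the branch length of the tree spanned
  by the observed taxa.

Here S is the number of observed taxa, N the total reads, F1/F2 the
singleton/doubleton counts, p_i = n_i/N. Because several estimators
live entirely on the rare tail (F1, F2), the package keeps exact
control of singletons and doubletons in its synthetic communities —
every generated sample realizes its target S, F1 and F2 exactly, and
the top-two abundance ratio can be pinned (2x/10x/100x) to probe
dominance metrics directly.

## Worked example

```python
from alphadiv import GeneratorConfig, generate_dataset
from alphadiv.alpha_metrics import compute_alpha_stream, default_registry

cfg = GeneratorConfig(richness_levels=(50, 200), seed=42, distribution="poisson")
ds = generate_dataset(cfg, with_tree=True)           # 34 samples
mat = compute_alpha_stream(ds.iter_labeled(),
                           registry=default_registry(), tree=ds.tree)
print(mat.values.loc[["S050_F1000", "S200_F1060"],
      ["observed_features", "chao1", "robbins", "berger_parker",
       "shannon", "faith_pd"]].round(4))
```

```
            observed_features  chao1  robbins  berger_parker  shannon   faith_pd
S050_F1000               50.0   50.0   0.0000         0.0260   5.6292   484.6453
S200_F1060              200.0  275.0   0.0095         0.0109   6.9614  1450.4072
```

Sample `S050_F1000` has 50 taxa and no singletons, so Chao1 adds
nothing (50.0) and Robbins is 0: nothing suggests unseen taxa.
`S200_F1060` has 60 singletons and 24 doubletons, so Chao1 extrapolates
75 unseen taxa (275 = 200 + 60²/48) and Robbins reports a ~1% chance
that the next read is a new taxon. Berger-Parker falls with richness
(the top Poisson-abundance taxon holds a smaller share of reads) while
Shannon and Faith PD rise.

The same flow is scriptable end to end:

```bash
alphadiv run-all --distribution poisson --seed 42 --tree --out run/
# run/: table.tsv design.tsv tree.nwk alpha.tsv correlations/ \
#       regressions/ key_factors.tsv panel.tsv config.json run.log
```

`panel.tsv` is the recommended reporting panel — one metric per
category (observed_features + robbins, berger_parker, shannon,
faith_pd) — because within a category metrics are largely redundant,
while no single category captures the others.

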