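# coculture

Analysis pipeline for pairwise bacterial interspecies interactions measured
as endpoint cell densities of mono- and co-cultures across growth
environments of varying carbon-source diversity.

The question the package addresses: when two bacterial species share a
batch culture, does each partner facilitate, inhibit, or leave unaffected
the other's growth — and how does the answer change as the number of carbon
sources in the medium increases while the total carbon mass stays fixed?
It is aimed at microbial-ecology groups running co-culture screens
(fluorescent-labelled strains, defined minimal media, endpoint flow
cytometry) who need the full statistical chain from raw density tables to
community-level conclusions, plus a synthetic-data module so the whole chain
is testable without any experimental download.

## The statistics at the core

For species *i* co-cultured with *j* in environment *m*, with triplicate
endpoint densities `Y_m^{i,j}(r)` and mono-culture mean `Ȳ_m^i` (all
densities floored at the detection limit 4.57×10⁵ cells/ml):

* **Unidirectional calls.** The three ratios `Y_m^{i,j}(r) / Ȳ_m^i` are
  tested against 1 with a one-sample two-tailed t-test; after
  Benjamini–Hochberg correction across every test in the run (FDR 0.05) the
  direction is called facilitated (+), unaffected (0) or inhibited (−).
  The unordered pair of calls gives one of six interaction classes:
  mutualism (+,+), commensalism (+,0), exploitation (+,−), neutralism
  (0,0), amensalism (−,0), competition (−,−).
* **Effect size and interaction type.**
  `E_m^{i,j} = log2(Ȳ_m^{i,j} / Ȳ_m^i)`, and the interaction-type angle
  `θ_m^{i,j} = arctan((E_ij + E_ji) / |E_ij − E_ji|)` in degrees — the angle
  between the plotted point (min E, max E) and the line max = −min.
  θ ∈ [−90°, 90°]; +90° is equal mutual facilitation, −90° equal mutual
  inhibition.  Environment and pair averages (θ̄_m, θ̄^{i,j}) summarise the
  profile.
* **Mixing effects.** Growth on a mixture of n sources is compared against
  the average growth on its components via a constructed three-point
  pseudo-sample {m̄+s, m̄, m̄−s}, where m̄ averages the component mean log10
  yields and s² averages their unbiased log10 variances (Welch two-sample
  t-test, BH-corrected).
* **Grower stratification.** Per species, mono-culture mean log10 yields
  across environments are split into growers/non-growers by the exact
  two-cluster partition under Ward's minimum-variance criterion;
  interactions between two growers are tested for class enrichment with
  one-sided hypergeometric tests.
* **Community statistics.** Monte-Carlo chi-square heterogeneity of class
  counts, pairwise PERMANOVA of θ profiles over biochemical source
  categories, a rank-based species enrichment test, and the Spearman trend
  between carbon-source number and θ.
* **FBA by-products.** For stoichiometric models, flux balance analysis
  plus a >1% essentiality criterion identifies carbon-containing
  metabolites in essential nonzero-flux reactions — the minimal by-product
  pool available for cross-feeding.

The synthetic-data module supplies (a) planted-effect tables with known
ground truth and (b) a mechanistic batch consumer-resource simulator
(shared carbon pools, partial re-secretion of consumed carbon as a
cross-feedable by-product) that reproduces the qualitative
diversity→competition trend.

## Worked example

```python
from coculture.core import PipelineConfig
from coculture.pipeline import run_full_pipeline
from coculture.synthetic import default_resource_config, generate_resource_dataset

sim = default_resource_config(seed=1)
culture, envs = generate_resource_dataset(sim)        # 8 species, 32 environments
result = run_full_pipeline(culture, envs, PipelineConfig(seed=1))

print(result.grower_fractions)
print(result.trend)
```

prints

```
   n_sources    n  grower_fraction
0          0    8         0.000000
1          1  128         0.335938
2          2   64         0.531250
3          4   32         0.812500
4          8   16         0.937500
5         16    8         1.000000
           x          y       rho             p    n
0  n_sources  theta_deg -0.342572  2.629801e-25  868
```

Reading: in single-source media only a third of species–environment
combinations grow (the rest sit at the detection floor and can only be
cross-fed), while 16-source media support every species; across the 868
interactions in carbon-containing environments the interaction-type angle θ
falls significantly as source number rises (ρ = −0.34) — more diverse media
push pairs toward mutual inhibition, because every grower now contests the
same fixed 1.0 mg/ml carbon budget.

The same analyses are available from the shell:

```sh
coculture simulate --seed 1 --out-dir sim
coculture run-all --config config.yaml --seed 1 --out-dir report
```

where `config.yaml` points at the culture and environment tables and may
override any pipeline constant (detection floor, FDR, iteration counts).

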