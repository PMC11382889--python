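# valleypop

Fine-scale population structure and phenotypic divergence analysis for
diploid microsatellite data.

## The problem

When two subpopulations of a highly mobile species — for example blue tits
(*Cyanistes caeruleus*) breeding on the opposite slopes of a single wooded
valley — occupy ecologically different habitats, limited natal dispersal can
produce genetic differentiation at a surprisingly small spatial scale, and
spatially varying selection can drive quantitative traits apart faster than
genetic drift would.  Detecting this requires running several analyses on
the same multilocus genotype + trait + capture–mark–recapture dataset:

* **Marker screening and diversity** — per-locus allele counts, observed
  heterozygosity H_O, Nei's unbiased expected heterozygosity
  H_E = (2n/(2n−1))(1 − Σp_i²), an exact conditional Hardy–Weinberg test,
  and a Brookfield-style null-allele estimate r = (H_E − H_O)/(1 + H_E)
  used to discard unreliable loci.
* **Hierarchical AMOVA** — allelic variance partitioned among populations
  (σ²_a), among individuals within populations (σ²_b) and within
  individuals (σ²_c), with F_ST = σ²_a/σ²_T, F_IS = σ²_b/(σ²_b+σ²_c),
  F_IT = (σ²_a+σ²_b)/σ²_T so that (1−F_IT) = (1−F_IS)(1−F_ST), and
  permutation tests with a scheme per statistic.
* **Bayesian admixture clustering** — a Gibbs sampler over the classic
  admixture model (membership vectors q on the K-simplex, cluster allele
  frequencies, correlated-frequency prior with per-cluster drift F),
  evidence estimated as mean(lnL) − var(lnL)/2, and the number of clusters
  chosen by the ΔK criterion (second-order rate of change of ln P(X|K)
  across K, standardised by the between-replicate standard deviation),
  with label-switching resolved across replicates.
* **P_ST–F_ST comparison** — phenotypic differentiation
  P_ST = gσ²_B/(gσ²_B + 2h²σ²_W) evaluated over a grid of the additive
  proportion g and heritability h², classified against neutral F_ST
  (diversifying / indistinguishable / uniform selection).
* **Natal dispersal** — transition matrices between forests and slopes from
  ringing/recapture records.

A Balding–Nichols (F-model) generator produces synthetic datasets with a
known F_ST, F_IS and trait P_ST so that every estimator can be validated by
parameter recovery, and the whole pipeline runs end-to-end without any
external data.

## Worked example

```python
from valleypop.simulate import make_study_fixture
from valleypop.amova import run_amova_suite
from valleypop.pst import pst_sensitivity, trait_variance_components

# two subpopulations (78 + 93 birds), 24 microsatellite loci,
# F_ST = 0.016, F_IS = 0.19, clutch-size P_ST = 0.052
bundle, truth = make_study_fixture(seed=123)

res = run_amova_suite(bundle, strata=("all",), n_permutations=999, seed=1)["all"]
print(f"df = {res.df}")
print(f"F_ST = {res.f_st:.3f} (p = {res.p_values['F_ST']:.3f}), "
      f"F_IS = {res.f_is:.3f}")

meta = bundle.metadata.set_index("sample_id")
clutch = bundle.traits[bundle.traits["trait"] == "clutch_size"]
comp = trait_variance_components(
    clutch["value"].to_numpy(),
    meta.loc[clutch["sample_id"], "population"].to_numpy(),
    trait="clutch_size",
)
pst_res = pst_sensitivity(comp, f_st=res.f_st)
print(f"P_ST(1,1) = {pst_res.pst_null:.3f} -> {pst_res.classification}")
```

prints

```
df = (1, 169, 171, 341)
F_ST = 0.015 (p = 0.001), F_IS = 0.193
P_ST(1,1) = 0.017 -> diversifying
```

The degrees of freedom are the three-level AMOVA bookkeeping for 171
diploid individuals in 2 populations; the recovered F_ST (0.015) sits at
the generator's target of 0.016 within the sampling error of 24 loci; the
permutation p-value says no random relabelling of individuals reached the
observed F_ST; and the clutch-size P_ST exceeds F_ST — the signature of
diversifying selection on that trait (at a 171-bird sample size the P_ST
point estimate itself is noisy; the generator's target was 0.052).

The same pipeline is scriptable from the shell:

```bash
valleypop simulate --preset study --seed 123 -o data/
valleypop amova --genepop data/genotypes.gen --n-perm 9999 --seed 1
valleypop structure --genepop data/genotypes.gen --k-min 1 --k-max 5 --seed 1
valleypop run -c config.yaml          # full report (JSON + markdown)
```

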