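# mycoassembly

Community-assembly analysis for ectomycorrhizal (EM) fungal OTU tables — and
for any sample × OTU count data with a phylogeny and host/site metadata.

Root-associated fungal communities are shaped by a mixture of deterministic
processes (host filtering, soil and climate) and stochastic ones (dispersal
limitation, ecological drift). `mycoassembly` packages the standard toolkit
for quantifying that mixture:

- **Phylogenetic null models.** Within-sample mean nearest taxon distance
  (MNTD) and its standardized effect size, the nearest taxon index
  (NTI = −(MNTD_obs − μ_null)/σ_null); between-sample phylogenetic turnover
  (βMNTD, abundance-weighted) and its standardized effect size βNTI, with a
  taxa-label-shuffle null (999 shuffles by default). |βNTI| > 2 is read as
  deterministic assembly, |βNTI| ≤ 2 as stochastic.
- **Sloan neutral community model.** Occupancy of an OTU with mean relative
  abundance *p* in communities of *N* individuals is predicted as
  1 − B(d; Nmp, Nm(1−p)) with detection limit d = 1/N; the migration rate
  *m* is fitted by bounded least squares and R² measures fit quality, with
  Wilson 95% bands classifying OTUs as above/within/below the neutral
  expectation.
- **Host–fungus preference.** Standardized specialization d′ per fungal OTU
  and per plant (d′ = Σ p_ij ln(p_ij/q_j) / ln(total/A_i)), and a
  two-dimensional preference score per plant–fungus pair
  (2DP = (a_obs − μ_null)/σ_null) under fixed-marginal (Patefield)
  randomizations, with BH-FDR control and a 2DP > 1.6 strong-preference rule.
- **Distance-based statistics.** Seeded rarefaction, Hellinger transform,
  Bray–Curtis, cophenetic and great-circle distances, PCoA, PCNM spatial
  eigenvectors, one-factor PerMANOVA, PERMDISP, Mantel and partial Mantel
  tests, environmental vector fitting, Kruskal–Wallis with Conover post-hoc
  comparisons and a compact letters display, OTU accumulation curves and
  Venn-style OTU partitions.
- **Synthetic data.** Seeded generators emulating a 63-sample / 5-host /
  8-site / 1,900-km study design (depth 1,055, ~288 lognormally abundant
  OTUs), with tunable host-preference strength, clade-structured habitat
  filtering on a simulated phylogeny and exponential distance decay — so
  every stage is verifiable without any field data.

## Worked example

```python
from mycoassembly import simulate
from mycoassembly.neutral import fit_sloan
from mycoassembly.assembly import bnti

cfg = simulate.SimulationConfig(seed=42, n_samples=60, n_otus=300,
                                depth=1000, migration_rate=0.1)
table = simulate.gen_neutral_table(cfg)     # neutral communities, known m
print(fit_sloan(table).summary())
```

```
Sloan neutral community model
=============================
samples:            60
OTUs:               289
community size N:   1000
detection limit d:  0.001
migration rate m:   0.105398
R-squared:          0.9731
OTUs above band:    16
OTUs within band:   266  (wilson 95% CI)
OTUs below band:    7
m = 0.1054: a lower value of m suggests more limited dispersal in the turnover of the community.
```

The fitted migration rate (0.105) recovers the generating value (0.1): these
communities assemble neutrally, and most OTUs sit inside the 95% neutral
band. Feeding the same table and a random phylogeny to the βNTI machinery
gives the matching verdict — phylogenetic turnover indistinguishable from
the taxa-shuffle null for ~93% of sample pairs:

```python
tree = simulate.gen_tree(cfg.n_otus, seed=143)
summary = bnti(table, tree, n_null=999, seed=7).summary
# pairs: 1770  frac |bNTI|<=2: 0.928  >2: 0.062  <-2: 0.010
```

## Command line

```sh
mycoassembly simulate --seed 1 --out fixture/        # synthetic dataset
mycoassembly run-all --config config.yaml            # full analysis bundle
```

`run-all` executes rarefaction → diversity tests → host/spatial
eigenvectors → Bray–Curtis → PerMANOVA/PERMDISP/envfit/Mantel → NTI/βNTI →
neutral fit → single-site preference analysis, writing TSV tables plus a
versioned `report.json`; reruns with the same config are byte-identical.

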