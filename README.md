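# sogwas — ancestry-aware GWAS for two-group hybrid panels

`sogwas` detects QTLs in hybrid breeding panels built from two divergent
genetic groups (the Dent and Flint heterotic pools of North-European
maize are the motivating case) while keeping track of which group each
allele's local genetic background came from.  It is aimed at
quantitative geneticists analysing factorial (inter-group) or admixed
diallel hybrid panels who want to separate the effect of a SNP allele
from the effect of the ancestry surrounding it — the information that
reveals heterotic-group complementarity and background-specific gene
action, and that a conventional additive/dominance scan discards.

## The model

Each hybrid carries, at every marker, two gametes `(allele, origin)`
with allele ∈ {0, 1} and origin ∈ {D, F}.  Combining them gives four
SNP-Origin (SO) *alleles* — 0D, 1D, 0F, 1F — and ten unordered SO
*genotype* classes; an inter-group factorial realizes only the four
mixed-background classes (0D0F, 0D1F, 1D0F, 1D1F), an admixed diallel
all ten.  The Gso association model fits one effect β_c per observed SO
class on top of a polygenic mixed model,

    y = μ + β_c + A + D + I^aa + I^ad + I^dd + ε ,

with A ~ N(0, K_a σ²_a), D ~ N(0, K_d σ²_d) and epistatic terms on the
Hadamard-product kinships; the multi-environment layer adds environment
effects, AxE/DxE components and per-environment error variances.
Marker effects are then tested as Wald contrasts of the class effects:

* within-background additivity and dominance, e.g.
  `a_DD = (β_1D1D − β_0D0D)/2`, `d_DF = (β_0D1F + β_1D0F)/2 − (β_1D1F + β_0D0F)/2`;
* their means `a`, `d` and comparisons `s_a = a_DD − a_FF`,
  `t_a = a_DF − (a_DD + a_FF)/2` (and the dominance twins);
* origin effects `o_a`, `o_d` built from homozygous-SNP classes;
* `Δ_LD = β_0D1F − β_1D0F`, separating the two mixed-phase double
  heterozygotes;
* global tests `g` over all participating classes.

Kinships use the NOIA (natural and orthogonal interactions) codings, so
additive and dominance codings are orthogonal under the panel's
observed genotype frequencies.  Null-model variance components are
estimated once per chromosome by REML with leave-one-chromosome-out
(LOCO) kinships and recycled across markers with a per-marker variance
scale (P3D style).  The benchmark Gad model regresses on allele dosage
(α) and heterozygosity (δ) under the same covariance.  Discoveries are
BH-controlled per (contrast, panel, model, trait) family pooling all
environments, and significant markers are grouped into QTLs via
Hill–Weir LD-decay windows (r² threshold 0.1, windows initialized at
0.5 cM and grown in 0.1 cM steps) and merged across layers into
meta-QTLs within each effect family.

Because the real panels of this design are access-restricted, the
package ships a first-class simulator: Balding–Nichols founder pools,
an incomplete factorial of F1s, origin-tracked doubled-haploid lines
(Haldane recombination), a sparse diallel, and plot-level phenotypes
with background-specific QTLs, polygenic covariance, GxE and row/column
field effects — every downstream stage is testable against known truth.

## Worked example

```python
import numpy as np
import sogwas as sg
from sogwas.gwas import CONTRASTS

# synthetic admixed diallel: 2 chromosomes, 300 markers, 200 hybrids
gmap     = sg.simulate_map(300, n_chrom=2, seed=0)
founders = sg.simulate_founders(40, 40, 300, divergence=0.25, seed=1)
f1       = sg.simulate_factorial(founders, 80, seed=2)
dh       = sg.simulate_dh(f1, gmap, 120, seed=3)
panel    = sg.simulate_diallel(dh, 200, seed=4)

# one QTL acting only in the Dent/Dent background (a_DD = 1.2)
arch = sg.TrueArchitecture(qtls=[sg.QtlEffect(marker=65, a_dd=1.2)])
plots, truth = sg.simulate_phenotypes(panel, arch, sg.FieldLayout(14, 32),
                                      n_env=2, seed=5)

# field correction, then the variance partition for one environment
plots = sg.filter_density(plots)
corrected, fits = sg.correct_all(plots, "trait")
exp  = corrected[corrected["check"] == "experimental"]
data = exp.rename(columns={"trait": "value"})[["hybrid", "env", "value"]]
kin  = sg.panel_kinships(panel)
print(sg.variance_report(sg.fit_mono(data[data["env"] == "env1"],
                                     kin, panel.hybrids)))

# multi-environment SO-genotype scan with LOCO kinships
loco = sg.loco_kinships(panel, gmap)
res  = sg.run_gwas(panel, gmap, data, loco, model="gso",
                   layers=["MULTI"], contrasts=["a_DD", "s_a", "a"])
print(res.sort_values("p").head(3)[["marker", "contrast", "estimate",
                                    "se", "p", "q"]])
```

prints (abridged):

```
component  variance  pct_main_genetic
        a     0.766            86.803
        d     0.116            13.197
        ...
    error     0.962               NaN

marker contrast  estimate     se         p         q
m00065     a_DD     1.079 0.1997 6.498e-08 5.134e-06
m00136     a_DD    0.8768 0.2152 4.626e-05  0.001827
m00065        a    0.5607 0.1648  0.000669   0.01873
```

The variance partition attributes ~87% of the main genetic variance to
additivity.  The causal marker m00065 tops the scan: its
background-specific `a_DD` estimate (1.08) recovers the simulated
effect (1.2 in trait units, shrunk by LD with the tested marker), while
the background-averaged `a` is diluted to 0.56 — exactly the situation
in which a conventional dosage regression loses power.  Clustering the
significant markers by LD windows yields a QTL interval around m00065
(`chr1:[49.2, 50.2] cM`, contrasts `a+a_DD`).

The same pipeline is scriptable from the shell:

```bash
sogwas simulate --seed 7 --out run/
sogwas correct  --plots run/plots.csv --env env1 --out run/corrected.csv
sogwas varcomp  --genotypes run/genotypes.tsv --map run/map.tsv \
                --plots run/plots.csv --mode mono --env env1 --out run/vc.csv
sogwas gwas     --genotypes run/genotypes.tsv --map run/map.tsv \
                --plots run/plots.csv --model gso --out run/gwas.tsv
sogwas cluster  --genotypes run/genotypes.tsv --map run/map.tsv \
                --in run/gwas.tsv --out run/qtl.tsv
```

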