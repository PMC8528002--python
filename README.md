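# qpa — quantitative phenotypic assay toolkit for well-plate microalgae

`qpa` implements the computational side of a high-throughput quantitative
phenotypic assay (QPA) for microalgae grown in multi-well plates. From three
standard instruments — a plate reader (in vivo Chl-a fluorescence, ROS
assay), a flow cytometer (scatter and fluorescence per cell), and a PAM
fluorometer (rapid light curves) — it derives ten phenotypic traits per
culture well and analyses the resulting multivariate phenotypes as 2-D
"trait-scapes". It is aimed at phytoplankton ecologists, experimental
evolution labs and screening pipelines that phenotype many strains across
many growth environments.

## The ten traits

| trait | units | derivation |
|---|---|---|
| growth rate μ | d⁻¹ | steepest OLS slope of ln(RFU) vs time over 4 consecutive readings |
| cell size (ESD) | μm | (median FSC − b)/a from a bead calibration FSC = a·size + b |
| granularity | counts | median side scatter of the gated population |
| Chl-a per size | counts μm⁻¹ | median red fluorescence / median cell size |
| neutral lipids | counts cell⁻¹ | median green fluorescence, post-stain − pre-stain (BODIPY 505/515) |
| silicification | counts·d | PDMPO UV stain delta (stained − unstained at 24 h) / μ over the incubation |
| ROS | counts cell⁻¹ μm⁻¹ | (stained − blank RFU) / cells in aliquot / median size (H₂DCFDA) |
| α | dimensionless | initial slope of the P-I curve |
| ETRmax | rel. units | peak of the P-I curve |
| Ik | μmol m⁻² s⁻¹ | ETRmax / α, exactly |

Cells are gated from debris by minimum Chl-a (red) and forward-scatter
thresholds; medians use the lower-median convention. Rapid light curves are
converted to relative electron transport, ETR = Y·E·0.5, and fitted with the
exponential-saturation model with optional photoinhibition:

ETR(E) = Pₛ(1 − e^(−αE/Pₛ))·e^(−βE/Pₛ),  ETRmax = Pₛ[α/(α+β)][β/(α+β)]^(β/α) for β > 0.

Multivariate analysis: traits are z-scored, projected by PCA (the
trait-scape), group centroids compared by Euclidean distance and direction
(degrees from horizontal, atan2), between-scape geometry compared by
regressing pairwise centroid distances, and group separation tested with a
first-principles PERMANOVA (one-way, two-factor sequential with interaction,
and pairwise; free permutations, p = (#{F* ≥ F}+1)/(n_perm+1)).

Because raw instrument data for such assays are rarely deposited, the
package ships a first-class synthetic-data generator (`qpa.simulate`) that
emulates all four instrument streams with a recorded ground-truth manifest,
making every stage of the pipeline testable end to end.

## Worked example

```python
from qpa.simulate import SimulationConfig, default_strains, simulate_experiment
from qpa.traits import process_bundle
from qpa.traitscape import standardize, pca, centroids, shift_metric
from qpa.multivar import euclidean_distance_matrix, permanova
import numpy as np

strains = {k: v for k, v in list(default_strains().items())[:3]}
cfg = SimulationConfig(strains=strains, n_replicates=3, seed=42)
bundle = simulate_experiment(cfg, "experiment")   # writes the instrument files
table, excluded = process_bundle("experiment")    # derives all ten traits
print(table.data[["strain_id", "growth_rate", "size", "etrmax"]].round(3))

z = standardize(table)
scape = pca(z)
print("PC1+PC2 variance: %.1f%%" % scape.var_explained[:2].sum())
groups = table.data.strain_id.tolist()
cents = centroids(scape, groups)
m = shift_metric(cents["S1"], cents["S3"])
print(f"S1->S3 shift: distance {m.distance:.2f}, direction {m.direction_deg:.1f} deg")
res = permanova(euclidean_distance_matrix(np.asarray(z)), groups,
                n_permutations=999, seed=0)
print(f"PERMANOVA: pseudo-F {res.pseudo_f:.2f}, p = {res.p_value}")
```

Output:

```
  strain_id  growth_rate   size  etrmax
0        S1        0.906  4.013  71.634
1        S1        0.906  3.988  69.696
2        S1        0.917  3.985  67.151
3        S2        0.758  5.994  60.735
4        S2        0.761  6.021  61.520
5        S2        0.747  6.043  63.748
6        S3        0.623  7.956  56.391
7        S3        0.618  7.997  55.525
8        S3        0.603  7.963  57.858
PC1+PC2 variance: 98.9%
S1->S3 shift: distance 6.63, direction 1.0 deg
PERMANOVA: pseudo-F 21.77, p = 0.005
```

The derived growth rates and sizes sit within a few percent of the
generator's ground truth (S1: μ = 0.9 d⁻¹, 4 μm; S3: μ = 0.6 d⁻¹, 8 μm);
the three strains separate cleanly in the trait-scape (PERMANOVA p at the
permutation floor for 3×3 wells), and the S1→S3 centroid shift is almost
purely along PC1, the axis dominated by the size/growth trade-off.

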