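# embryoaxis

Analysis pipeline for single-cell studies of post-implantation human
embryos (5–11 days post-fertilisation, d.p.f.). It covers the
computational stages such a study needs end to end:

- **QC and lineage annotation** of 10x-style scRNA-seq count matrices:
  cells are removed when mitochondrial reads exceed 20% of total
  expression or fewer than 1000 genes are detected; embryos enter the
  analysis only when epiblast, hypoblast and trophoblast are all present.
  Lineages (epiblast, hypoblast, cyto-/syncytiotrophoblast) are called by
  marker-signature scoring and marker genes re-derived by one-vs-rest
  rank-sum tests with Benjamini–Hochberg correction.
- **Pluripotency-stage projection**: an L2-regularised multinomial
  logistic regression maps query cells (e.g. embryonic stem cell lines)
  onto reference stage clusters; per-group mean class probabilities are
  the quantitative matching scores.
- **Anterior-hypoblast signalling analysis**: Spearman co-expression of
  *CER1* with BMP/NODAL/WNT antagonists (*LEFTY1/2*, *HHEX*, *NOG*,
  *DKK1/4*, *SFRP1*, …), PCA + k-means sub-clustering of the hypoblast,
  and AUCell-style rank-based regulon activity scores.
- **3D angular-asymmetry analysis**: from segmented nucleus coordinates,
  a proximal–distal axis is fitted, every marker-positive hypoblast cell
  gets an angle in [0°, 180°] along the hypoblast hemisphere, and a
  label-permutation test decides whether the marker domain is biased
  toward one side — the signature of a putative anterior signalling
  centre.
- **Synthetic data generators** for all of the above, so every stage is
  testable without any sequencing or imaging data.

## The angular model

Each embryo defines a frame (c, **d**, **r**): c is the epiblast
centroid, **d** the unit vector from it to the hypoblast centroid
(proximal→distal), and **r** a lateral unit reference pointing toward the
side holding the majority of marker-positive cells. A cell at position p
has angle

&theta; = arccos( (p − c)·**r** / |p − c| ) ∈ [0°, 180°],

so 0° is the marker-majority side, 90° the distal pole, 180° the opposite
side. The localisation-bias test is deliberately reference-free: with
u<sub>i</sub> the unit azimuthal projections (components of p − c
orthogonal to **d**, normalised), the statistic is the mean resultant
length T = | mean over marker⁺ cells of u<sub>i</sub> |, and the null
distribution comes from permuting marker labels among the hypoblast
cells: p = (1 + #{T<sub>perm</sub> ≥ T<sub>obs</sub>}) / (n_perm + 1).
Choosing 0° from the data and then testing "mean ≠ 90°" would be
circular; permutation of labels avoids that.

## Worked example

Simulate a 9 d.p.f.-like cohort (restricted CER1 domain, concentrated to
one side) and quantify the asymmetry:

```python
from embryoaxis import (simulate_geometry_cohort, fit_axis, reference_direction,
                        angular_profile, align_profiles, marker_fraction)
from embryoaxis.experiment_stats import iqr_summary

cohort = simulate_geometry_cohort(9, n_embryos=6, seed=4)
profiles = []
for i, embryo in enumerate(cohort):
    axis = reference_direction(embryo, fit_axis(embryo))
    profiles.append(angular_profile(embryo, axis, n_perm=10_000, seed=i))
pooled, table = align_profiles(profiles)
print(table.round(4).to_string(index=False))
fr = [marker_fraction(g) for g in cohort]
s = iqr_summary(fr)
print(f"CER1+ fraction: median {100*s['median']:.0f}%, IQR {100*s['q25']:.0f}-{100*s['q75']:.0f}%")
```

```
embryo_id  n_marker_pos  mean_angle  bias_p  biased
    S9E01             5     66.5676  0.0874   False
    S9E02             8     63.2940  0.0028    True
    S9E03             9     64.9226  0.0001    True
    S9E04            10     75.7709  0.0368    True
    S9E05             7     55.9191  0.0026    True
    S9E06             9     68.1936  0.0003    True
CER1+ fraction: median 34%, IQR 29-36%
```

Mean angles sit well below the symmetric 90°, most embryos test as
biased (p ≤ 0.05), and roughly a third of the hypoblast is CER1⁺ — the
asymmetric, restricted-domain regime. Re-running with
`simulate_geometry_cohort(7, ...)` gives the 7 d.p.f.-like regime
instead: ~3/4 of hypoblast cells positive, mean angles near 90° and few
or no biased calls.

The same steps run from the shell:

```sh
embryoaxis simulate --out sim --seed 1
embryoaxis qc --counts sim --out qc
embryoaxis annotate --counts sim --out ann
embryoaxis axis --geometry sim/geometry_9dpf.csv --out axis9 --seed 1
```

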