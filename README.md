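# soilsom

Social-ecological patterning of soil heavy-metal risk: a reusable pipeline
for scoring point-sampled soil metals with the Hakanson potential
ecological risk index, aggregating risk to administrative units by ordinary
kriging and zonal means, discovering unit-level patterns with a batch
self-organizing map (SOM), clustering the SOM codebook with k-means
selected by the Davies-Bouldin index, and characterizing the resulting
clusters statistically.

It is written for environmental-health and landscape researchers who have
(a) a table of geolocated soil samples with concentrations of the eight
metals Cr, Ni, Zn, Hg, Cu, As, Cd and Pb, (b) administrative-unit polygons,
and (c) a unit-level table of socio-economic and biophysical covariates
(population density, livestock units, elevation, NDVI, road density, parent
material shares, ...), and who want to classify the units into
interpretable social-ecological risk patterns.

## The method

**Risk scoring.** For each metal *i*, the contamination factor is
C_r^i = C_sample^i / C_ref^i with C_ref a regulatory reference
concentration, the single-metal ecological risk is

    E_r^i = T_r^i × C_r^i

with the toxic-response factors T_r = {Hg: 40, Cd: 30, As: 10, Cu: 5,
Pb: 5, Ni: 5, Cr: 2, Zn: 1}, and the aggregate potential ecological risk
index is RI = Σ_i E_r^i. E_r grades use the conventional breaks 40 / 80 /
160 / 320 (low → very high). No RI grade scale is imposed.

**Spatial aggregation.** Per-metal C_r and RI are interpolated onto a
regular grid by ordinary kriging (spherical or exponential variogram fitted
by pair-count-weighted least squares; weights sum to 1) and averaged over
the grid-cell centers inside each unit polygon.

**Pattern discovery.** The units × 20 matrix (19 covariates + RI,
z-scored) trains a batch SOM on a hexagonal lattice. Map size is chosen by
scanning candidate lattice shapes and minimizing the quantization error QE
(mean case-to-BMU distance), ties broken by the topographic error TE
(fraction of cases whose first and second BMUs are not lattice neighbors).
The codebook is then clustered with k-means (greedy k-means++ seeding, 10
restarts); the number of clusters minimizes the Davies-Bouldin index, and
every unit inherits the cluster of its best matching unit.

**Characterization.** Per-cluster mean (SD) tables with one-way ANOVA and
compact-letter post-hoc groupings (Tukey HSD default, Duncan's multiple
range test optional), and per-cluster Spearman correlations of each
covariate with RI (exact permutation p for n ≤ 9, t approximation
otherwise), with an explicit marker for cells where a variable is constant.

Because no public dataset accompanies the method, the package ships a
synthetic scene generator that plants nine covariate/metal archetypes over
a tessellation of 253 towns with 1,018 samples, giving the pipeline a fully
specified, seed-reproducible testbed with known ground truth.

## Worked example

```python
from soilsom import (make_scene, score_samples, interpolate_to_towns,
                     assemble_feature_matrix, train, SOMConfig,
                     quantization_error, topographic_error,
                     select_k, project_labels)

scene = make_scene(seed=0)                      # 253 towns, 1,018 samples
scored = score_samples(scene.samples, scene.panel)
town_table, _ = interpolate_to_towns(scored, scene.samples, scene.towns,
                                     cell_size=0.02, fields=["ri"])
matrix = assemble_feature_matrix(scene.covariates, town_table["ri"])
model = train(matrix, SOMConfig(n_rows=12, n_cols=7, seed=0))
print(f"QE = {quantization_error(model, matrix):.3f}, "
      f"TE = {topographic_error(model, matrix):.4f}")
best, scan = select_k(model.codebook, range(2, 11), seed=0)
print(f"selected k = {best.k} (DBI = {best.dbi:.3f})")
towns = project_labels(model, best.labels, matrix)
```

prints

```
QE = 1.224, TE = 0.0435
selected k = 9 (DBI = 0.710)
```

QE is the mean distance (z-score units) from each town's 20-variable
profile to its best matching SOM unit; TE says 4.4% of towns have
non-adjacent first/second BMUs (good topology preservation). The
Davies-Bouldin scan bottoms out at k = 9 — the generator planted nine
archetypes, and the projected town labels recover them (adjusted Rand
index ≈ 0.99 for this seed). Town RI spans ≈ 211-628.

The same analysis runs from the shell:

```bash
soilsom simulate --seed 0 --out scene/
soilsom run-all --config config.yaml --seed 0
```

where `config.yaml` points at the scene files; artifacts (risk table,
kriged grids, map-quality scan, codebook, U-matrix, DBI scan, cluster
labels, summary/correlation tables, and a checksummed run manifest) land in
the configured output directory.

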