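# clonemorph

Quantitative profiling of clonal cell populations from instance-segmented
microscopy: single-cell morphology and cell-network topology across cell
densities in 2D, phenotype clustering of clonal lineages, and spheroid
invasion quantification in 3D.

## Who this is for

Labs that expand single-cell clones (e.g. from melanoma lines), image them
over a subculture cycle, and want to turn segmented label images into
comparable per-clone phenotype vectors — and to ask whether those 2D
phenotypes predict 3D invasive behavior in collagen-embedded spheroids.
Segmentation itself is pluggable: any instance segmenter that produces
integer label TIFFs works, and `segeval` scores it against annotated ground
truth via the binary error e_binary = |A_gt − A_pred|/A_gt and the object
count error e_object = |N_gt − N_pred|/N_gt.

## The model

**2D.** Each labeled cell contributes shape properties (area A, boundary
length P, circularity 4πA/P², aspect ratio of the inertia-equivalent
ellipse). Cells are nodes of an adjacency network G with an edge whenever
two cell boundaries come within 5 µm (strict, boundary-pixel centers).
From G we derive ⟨deg⟩, var(deg(v)), the degree entropy
H(x) = −Σᵢ P(xᵢ) ln P(xᵢ), the average colorability
⟨χ(G)⟩ = Σᵢ χ(cᵢ)/n over connected components cᵢ (chromatic numbers exact
by backtracking up to a configurable component size), component number,
component-mass entropy H(|C|), the largest-component mass fraction
|c₁|/|G|, and the box-counting fractal dimension of the cell foreground,
dim_box(S) = lim log N(ε)/log(1/ε), estimated as the log–log slope over a
grid of box sizes.

**Progressions.** Density (confluency — the covered area fraction), not
time, is the independent variable. Every property is tracked against
confluency over one subculture cycle and fitted with a degree-2 polynomial;
the fits evaluated at low/mid/high confluency anchors (0.15/0.40/0.70)
form the clone's growth-variable vector.

**Clustering.** Growth variables are z-scored and clones clustered by Ward
agglomerative hierarchical clustering: a first cut into 2 superclasses
(parental lines), then 3 subclasses within each.

**3D.** Fifteen z-slices spanning 75 µm from the middle of a spheroid
stack are max-projected and Otsu-binarized. The largest component is the
spheroid body (area, circularity, solidity); opening-residue components
attached to the body are protrusions, with length measured tip to spheroid
centroid; disconnected components are disseminated regions, with
centroid-to-centroid distances. Six metrics (n_p, avg_p, max_p, n_c,
avg_c, max_c) are min–max normalized across the clone panel and averaged
into invasion3D ∈ [0, 1]. Spearman correlation matrices and |r|-threshold
correlation graphs (0.8 for variable–variable, 0.3 for the invasion3D
star) relate the 2D and 3D phenotypes.

Every stage has a synthetic counterpart (`clonemorph.synthetic`) that
plants exact ground truth — polygon cells with known areas/centroids/gaps,
quadratic trends with Gaussian noise, spheroids with capsule arms and
planted blobs — so the whole pipeline is testable without external data.

## Worked example

```python
import numpy as np
from clonemorph.synthetic import SyntheticPopulationSpec, generate_population
from clonemorph import build_network, network_metrics, snapshot

spec = SyntheticPopulationSpec(n_cells=150, target_confluency=0.30,
                               image_shape=(384, 384), seed=7)
img, truth = generate_population(spec)
snap = snapshot(img)
net = build_network(img, adjacency_threshold=5.0)
m = network_metrics(net, foreground=img.foreground)
print(f"cells={img.n_cells} confluency={snap.confluency:.3f}")
print(f"edges={net.n_edges} planted={len(truth.adjacency)} "
      f"exact={ {tuple(sorted(e)) for e in net.graph.edges} == truth.adjacency }")
print(f"mean_degree={m.mean_degree:.3f} avg_colorability={m.avg_colorability:.3f} "
      f"fractal_dim={m.fractal_dimension:.3f}")
```

prints

```
cells=81 confluency=0.302
edges=12 planted=12 exact=True
mean_degree=0.296 avg_colorability=1.159 fractal_dim=1.644
```

81 cells cover 30% of the field; all 12 planted sub-5 µm adjacencies are
recovered exactly; the sparse network has mean degree ≈ 0.3 and mostly
trivial components (average colorability just above 1), and the cell
foreground fills space with dimension ≈ 1.64 — between a curve and a
filled plane, as expected at moderate density.

The same stages are exposed on the command line:

```bash
clonemorph synth population pop.tif --n-cells 100 --seed 1
clonemorph measure pop.tif --pixel-size 1.0
clonemorph network pop.tif --pixel-size 1.0 --threshold 5
clonemorph run manifest2d.csv out/ --manifest-3d manifest3d.csv
```

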