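# latgraph

Graph-signal interpolation of cardiac **local activation time (LAT)** on
triangulated surface meshes, with a perceptual map-difference metric.

During catheter ablation, an electroanatomic mapping system records sparse,
irregularly placed LAT observations (ms) on the patient's cardiac chamber
surface (a triangular mesh, mm). Producing an accurate activation map from
few observations shortens the procedure. `latgraph` interpolates the sparse
signal directly on the surface by treating it as a semi-supervised learning
problem on the mesh graph, and scores map quality the way a clinician reads
it — through colour.

## Method

Given the mesh graph with cotangent-weighted Laplacian **L** (non-positive
weights clamped to a small positive floor), labeled-vertex selector
**M**<sub>l</sub> (and **M**<sub>u</sub> = **I** − **M**<sub>l</sub>), and the
partially sampled signal **f**<sub>s</sub>, the interpolant minimises

&nbsp;&nbsp;‖**M**<sub>l</sub>(**f** − **f**<sub>s</sub>)‖² + α‖**M**<sub>u</sub>**f**‖² + β **f**ᵀ**L f**

whose closed form is the sparse SPD solve

&nbsp;&nbsp;**f**\* = (**M**<sub>l</sub> + α**M**<sub>u</sub> + β**L**)⁻¹ **f**<sub>s</sub>,&nbsp;&nbsp;α = 10⁻⁵, β = 10⁻².

Before solving, edges whose nearest-observation (quantized) LAT values jump
by ≥ 50 ms are pruned, so sharp "early-meets-late" discontinuities (e.g.
re-entrant circuits) are not smeared. With α = β = 1 the solution is
exactly the graph filter **U**(**I** + **Λ**)⁻¹**U**ᵀ**f**<sub>s</sub> in the
Laplacian eigenbasis; the package exposes that spectral path for diagnostics.

Map accuracy is reported as **Mean Delta-E (MDE)**: estimated and true LAT
values are mapped to viridis colours over a fixed display range
[s<sub>min</sub>, s<sub>max</sub>], converted to CIELAB (D65), and compared
with the CIEDE2000 colour-difference formula; MDE is the mean ΔE₀₀ over the
evaluated points. NMSE is kept as the conventional secondary metric. A
clinically shaped sub-sampling protocol (peak density halfway between the
earliest and the mean activation, slowly decaying, nowhere vanishing) draws
realistic training subsets, and a synthetic generator produces focal and
early-meets-late activation maps so the whole pipeline is testable without
clinical data.

## Worked example

```python
import latgraph as lg

spec = lg.SyntheticSpec(seed=3)              # 2562-vertex icosphere, focal map
mesh = lg.make_mesh(spec)
truth = lg.simulate_focal_lat(mesh, spec)    # per-vertex ground truth (ms)
obs = lg.sample_observations(mesh, truth, 300, seed=4)

result = lg.GraphLATInterpolation(mesh, obs).fit()
print(result.summary())
print(result.evaluate(truth))
```

```
Graph LAT Interpolation Results
==============================================
Vertices                                  2562
Faces                                     5120
Raw observations                           300
Snapped vertices                           293
Used observations                          293
Graph edges (full)                        7680
Edges removed (>= delta_lat)                 0
alpha (Tikhonov)                     1.000e-05
beta (Dirichlet)                     1.000e-02
delta_lat [ms]                            50.0
Solver residual (inf-norm)           1.421e-13
Fitted range [ms]               -139.7 .. -46.9
==============================================
{'mde': 2.895169916175678, 'nmse': 0.021780192126062647}
```

293 of the 300 jittered observations snap to distinct mesh vertices; the
smooth map triggers no edge pruning; the fit reconstructs all 2562 vertices
with a mean perceptual error of ≈ 2.9 ΔE₀₀ units (differences below ~2 are
barely perceptible) and NMSE ≈ 0.02.

The same pipeline is scriptable from the shell:

```bash
latgraph simulate --subdivisions 4 --noise-sd 3 --seed 1 --outdir map/
latgraph interpolate --mesh map/mesh.ply --samples map/observations.csv --out fit.csv
latgraph evaluate --truth map/ground_truth.csv --pred fit.csv
latgraph crossval --mesh map/mesh.ply --samples map/observations.csv \
    --m 100 --reps 50 --methods graph,gpr --seed 1 --out cv.json
```

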