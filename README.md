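# mpxcoloc

Per-node polarity scores and protein colocalization analysis for
Molecular Pixelation (MPX) single-cell surface-proteome graphs.

MPX encodes the spatial organization of antibody-tagged surface proteins
on one cell as a bipartite graph: A-pixels and B-pixels (DNA-tagged
spatial neighborhoods) are nodes, and each antibody–oligonucleotide
conjugate molecule is an edge labeled with its marker and a
unique-molecule count. `mpxcoloc` answers, per cell: *which markers are
spatially polarized, and which groups of markers occupy the same region
of the cell surface?*

## Method

Each cell's bipartite graph is projected onto its A-nodes (two A-pixels
adjacent iff they share a B-pixel), moving marker counts onto vertices.
For a marker with count vector *x* on the projected graph, every vertex
ℓ receives a **local assortativity** score: the global degree-weighted
assortativity of *x* reweighted by the personalized-PageRank
distribution *w(ℓ)* of a random walk restarting at ℓ,

    score(ℓ) = (1/σ_e²) · ( Σ_v w_v(ℓ) · x_v · x̄_{N(v)} − μ_e² )

where μ_e, σ_e² are the mean and variance of *x* over edge ends and
x̄_{N(v)} is the neighbor mean at *v*. Raw scores are unbounded, so they
are passed through the **adjustment** ϱ = h∘g∘f:

* *f* — divide positive scores by the sum of positives, negatives by the
  sum of absolute negatives (both sign blocks then total ±1);
* *g* — divide by the Euclidean norm (unit energy);
* *h* — signed logarithm, h(z) = sgn(z)·ln(|z|+1).

The result lies in [−ln 2, +ln 2] componentwise, with 0 meaning uniform
mixing, and is comparable across markers and cells. Two per-cell filters
zero out low-information markers first: total count below the *isotype
threshold* (the maximum total among isotype-control antibodies), or
presence on ≤ 10 vertices.

On top of the adjusted fields:

* **pairwise colocalization** of two markers = Spearman correlation of
  their adjusted fields over vertices (exactly 0 if either field is
  all-zero);
* **higher-order colocalization** of k ≥ 3 markers = multiple-site
  similarity C_T = (T/(T−1))·(1 − |∪A_i| / Σ|A_i|) of the vertex sets
  with ϱ > 0 (the Sørensen index at T = 2);
* **differential colocalization** between samples = difference of
  per-cell means with a two-sided Wilcoxon rank-sum p-value, binned
  into 0–3 dots at 0.01 / 0.001 / 0.0001.

A fully seeded synthetic generator produces MPX-like cells (A-pixels on
a sphere, locally attached B-pixels, Poisson marker counts) with
optional planted polarity caps, so every analysis path can be exercised
without external data.

## Worked example

```python
from mpxcoloc import (AssortativityConfig, SyntheticCellConfig,
                      higher_order_colocalization, largest_component,
                      pairwise_colocalization, project_to_anodes,
                      score_cell, simulate_cell)

cfg = SyntheticCellConfig(polarized_markers=("CD50", "CD162", "CD44"),
                          enrichment_fold=8.0, cap_fraction=0.2, seed=42)
cell = simulate_cell(cfg)
graph = largest_component(project_to_anodes(cell, cfg.panel))
fields = score_cell(graph, cfg.panel, AssortativityConfig())

rho = fields["CD50"].values
print(f"CD50 adjusted scores: min={rho.min():.3f} max={rho.max():.3f}")
print(f"coloc(CD50, CD162) = {pairwise_colocalization(fields['CD50'], fields['CD162']):.3f}")
print(f"coloc(CD50, CD45)  = {pairwise_colocalization(fields['CD50'], fields['CD45']):.3f}")
trio = higher_order_colocalization(fields, ("CD50", "CD162", "CD44"))
print(f"higher-order C_3(CD50, CD162, CD44) = {trio.score:.3f}")
```

prints

```
CD50 adjusted scores: min=-0.057 max=0.142
coloc(CD50, CD162) = 0.935
coloc(CD50, CD45)  = -0.399
higher-order C_3(CD50, CD162, CD44) = 0.980
```

The three markers planted on the same 20% polar cap score near-maximal
pairwise (0.94) and trio (0.98) colocalization, while CD50 against an
unpolarized marker (CD45) does not; all adjusted scores stay inside the
±ln 2 ≈ ±0.693 bound.

The same pipeline is available from the shell:

```sh
mpxcoloc simulate --out-dir run --n-cells 40 \
    --condition stimulated --condition control --fold 8 --fold 1 \
    --polarized CD50,CD162 --seed 1
mpxcoloc score --edges run/edges.csv --panel run/panel.csv --out run/scores.csv
mpxcoloc coloc --scores run/scores.csv --out run/coloc.csv --tuple CD50,CD162,CD44
mpxcoloc diff  --coloc run/coloc.csv --sample-sheet run/sample_sheet.csv \
    --contrast stimulated:control --out run/diff.csv
```

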