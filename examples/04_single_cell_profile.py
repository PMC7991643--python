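"""Single-cell multi-marker profiling with morphology features.

Simulates ~60 cells with two markers whose expression is independent of
phenotype, quantifies each ROI, and shows that PCA on
morphology+intensity separates the SS/RS/FC phenotypes (silhouette > 0)
while intensity alone does not.
"""

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from virtustain import cellprofile, simgen

rows, labels = [], []
seed = 0
while len(rows) < 60:
    scene = simgen.generate_scene(
        5, field_size=(360, 360), seed=seed, size_scale=0.9,
        markers=("CD105", "CD90"), expression_sd=0.4,
    )
    seed += 1
    images = {m: simgen.render_ground_truth(scene, m) for m in ("CD105", "CD90")}
    rois = [
        cellprofile.CellROI(c.cell_id, c.cell_polygon, c.nucleus_polygon,
                            phenotype_label=c.phenotype)
        for c in scene.cells
    ]
    _, table = cellprofile.build_cell_table(images, rois)
    rows.append(table)
    labels += [c.phenotype for c in scene.cells]

table = pd.concat(rows, ignore_index=True).iloc[: len(labels)]
labels = np.array(labels[: len(table)])

z, rel_spread, excluded = cellprofile.standardize_table(table)
print("relative spread (sd/mean %) per variable:")
print(rel_spread.round(1).to_string())

res_all = cellprofile.pca(z, 2)
sil_all = silhouette_score(res_all.scores, labels)
z_int, _, _ = cellprofile.standardize_table(
    table, columns=["mean_CD105", "mean_CD90"]
)
sil_int = silhouette_score(cellprofile.pca(z_int, 2).scores, labels)
print(f"\nPCA explained variance: {np.round(res_all.explained_variance_ratio, 3)}")
print(f"silhouette, morphology+intensity: {sil_all:.3f}  (> 0: phenotypes separate)")
print(f"silhouette, intensity only:       {sil_int:.3f}  (~ 0: no segregation)")
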