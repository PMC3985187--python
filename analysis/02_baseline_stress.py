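"""Solve the turgid jigsaw template and quantify the stress pattern.

Finding reproduced: maximal tensile stress concentrates in the
indenting neck regions and its direction bridges the indentations,
while lobes carry less stress.  Writes the stress field as VTK and a
neck-vs-lobe summary CSV under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import pavemech as pm
from pavemech.io import write_vtk

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

params = pm.JigsawParams(n_cells=12, domain_size=60.0, lobe_amplitude=2.0,
                         lobe_wavelength=8.0, seed=7)
cx, lm = pm.make_jigsaw_cells(params)
mat = pm.MaterialParams()  # 40 MPa matrix, 0.2 MPa turgor, 1 um wall
mesh = pm.add_anticlinal_beams(pm.mesh_surface(cx, target_h=2.0), mat)
loads = pm.apply_loads_and_bcs(mesh, mat)
disp = pm.solve_equilibrium(mesh, mat, loads, n_increments=3)
stress = pm.principal_stress(disp, mesh, mat)

write_vtk(OUT / "baseline_stress.vtk", mesh,
          cell_data={"sigma1": stress.sigma1, "sigma2": stress.sigma2,
                     "dir1": stress.dir1, "dir2": stress.dir2},
          point_data={"uz": disp.u[:, 2]})

cent = mesh.element_centroids()[:, :2]
areas = mesh.element_areas()
rows = []
for k in range(len(lm.points)):
    d = np.linalg.norm(cent - lm.points[k], axis=1)
    near_neck = (d < 2.5) & (mesh.cell_label == lm.neck_cell[k])
    near_lobe = (d < 2.5) & (mesh.cell_label == lm.lobe_cell[k])
    if not (near_neck.any() and near_lobe.any()):
        continue
    d1 = stress.dir1[near_neck][:, :2]
    d1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    rows.append({
        "landmark": k,
        "sigma1_neck": np.average(stress.sigma1[near_neck],
                                  weights=areas[near_neck]),
        "sigma1_lobe": np.average(stress.sigma1[near_lobe],
                                  weights=areas[near_lobe]),
        "median_cos_neck_axis": np.median(np.abs(d1 @ lm.normals[k])),
    })
df = pd.DataFrame(rows)
df.to_csv(OUT / "neck_lobe_stress.csv", index=False)

print(f"template solved: {mesh.n_elements} elements, "
      f"{disp.n_iter} Newton iterations")
print(f"mean sigma1 near necks:  {df.sigma1_neck.mean():.3f} MPa")
print(f"mean sigma1 near lobes:  {df.sigma1_lobe.mean():.3f} MPa")
print(f"median |cos(dir1, neck axis)|: "
      f"{df.median_cos_neck_axis.median():.3f}")
print("-> stress concentrates in necks and bridges the indentations"
      if df.sigma1_neck.mean() > df.sigma1_lobe.mean() else
      "-> WARNING: neck/lobe ordering not reproduced")
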