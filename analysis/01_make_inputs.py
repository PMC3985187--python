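"""Generate the synthetic inputs every later stage consumes.

Writes a lobed pavement-cell template, filament textures spanning the
nematic-order range, an AFM force-curve grid from a known two-phase
modulus map, and a Poisson severing-event table, all seeded, under
results/inputs/.
"""

import json
from pathlib import Path

import numpy as np
import tifffile

import pavemech as pm
from pavemech.io import save_polygons

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

# jigsaw template: 12 cells, 60 um, 2 um lobes every 8 um
params = pm.JigsawParams(n_cells=12, domain_size=60.0, lobe_amplitude=2.0,
                         lobe_wavelength=8.0, seed=7)
cx, lm = pm.make_jigsaw_cells(params)
save_polygons(OUT / "jigsaw_cells.json", cx.cells, params=vars(params))
np.savetxt(OUT / "jigsaw_neck_landmarks.csv",
           np.column_stack([lm.points, lm.normals, lm.neck_cell, lm.lobe_cell]),
           header="x,y,nx,ny,neck_cell,lobe_cell", delimiter=",", comments="")
print(f"jigsaw template: {cx.n_cells} cells, {len(lm.points)} neck/lobe "
      f"landmarks, total area {cx.cell_areas().sum():.0f} um^2")

# filament textures across the order-parameter range
for S in (0.0, 0.5, 1.0):
    spec = pm.FilamentImageSpec(width=256, height=256, n_filaments=500,
                                order_parameter_S=S, mean_angle=30.0, seed=11)
    img, angles = pm.make_filament_image(spec)
    tifffile.imwrite(OUT / f"filaments_S{S:.1f}.tif", img.astype(np.float32))
    s_emp = abs(np.mean(np.exp(2j * angles)))
    print(f"filament texture S={S}: empirical order parameter {s_emp:.3f}")

# AFM grid: 2 MPa background with 8 MPa stripes (fibrous reinforcement)
jj = np.arange(32)[None, :] * np.ones((32, 1))
mod = np.where((jj // 4) % 2 == 1, 8.0, 2.0)
spec = pm.CurveGridSpec(modulus_map=mod, model="hertz_cone", noise_sd=0.02,
                        seed=9)
tifffile.imwrite(OUT / "afm_true_modulus.tif", mod.astype(np.float32))
print(f"AFM grid: {mod.shape} curves, moduli {mod.min()}-{mod.max()} MPa")

# severing events at the mock-treatment scale
sev = pm.make_severing_series(pm.SeveringSimSpec(
    rate=1e-3, cell_areas=[500.0] * 16, duration=10.0, seed=3))
sev.to_csv(OUT / "severing_events.csv", index=False)
print(f"severing series: {len(sev)} events across 16 cells")

(OUT / "manifest.json").write_text(json.dumps({
    "jigsaw": vars(params), "filament_seeds": 11, "afm_seed": 9,
    "severing_seed": 3}, indent=1))
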