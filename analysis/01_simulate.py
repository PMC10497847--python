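"""Generate one example synthetic input of each kind and record ground truth.

Writes a rendered dendrite scene (TIFF + truth JSON), a behavioral session
CSV, and a protein intensity TSV under results/inputs/, and prints what was
planted in each.
"""

from pathlib import Path

import numpy as np

from spinepipe import io as spio
from spinepipe.synth import (
    Bout,
    ImageSceneConfig,
    ProteinTableConfig,
    TrajectoryConfig,
    arrange_spines_along_core,
    default_objects,
    generate_protein_table,
    generate_trajectory,
    render_scene,
    sample_spine_shapes,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20230731

# --- dendrite scene with a balanced five-class spine mixture -------------
path = np.array([[2.5, 17.9], [33.3, 17.9]])
specs = sample_spine_shapes({c: 1.0 for c in
                             ("stubby", "mushroom", "thin", "long_thin",
                              "filopodia")}, 8, seed=SEED)
arrange_spines_along_core(specs, path, margin=2.5, seed=SEED + 1)
scene = ImageSceneConfig(dendrite_path=path, spine_specs=specs,
                         image_shape=(512, 512), seed=SEED + 2)
image, truth = render_scene(scene)
spio.write_image(OUT / "scene.tif", image)
spio.write_ground_truth(OUT / "scene.truth.json", truth)
print(f"scene: {len(specs)} spines on a {truth.core_length:.1f} um core, "
      f"true ratios {np.round(truth.ratios, 2).tolist()}")

# --- behavioral session with a capped bout plan --------------------------
objs = default_objects()
cfg = TrajectoryConfig(objects=objs,
                       bouts=[Bout("A", 30.0, 12.0), Bout("B", 50.0, 12.0)],
                       position_noise_cm=0.05, seed=SEED)
traj, t_truth = generate_trajectory(cfg)
spio.write_trajectory(OUT / "session.csv", traj)
print(f"session: planned A=12 s then B=12 s -> truth under the 20-s cap: "
      f"{ {k: round(v, 2) for k, v in t_truth.per_object_s.items()} }, "
      f"latency {t_truth.latency_s:.1f} s")

# --- protein table with planted 1.5-fold effects in O-BAY ----------------
pcfg = ProteinTableConfig(n_proteins=1200, fraction_dap=0.1,
                          fold_range=(1.5, 1.5), affected_group="O-BAY",
                          missing_rate=0.1, seed=SEED)
table, p_truth = generate_protein_table(pcfg)
spio.write_protein_table(OUT / "proteins.tsv", table)
p_truth.to_csv(OUT / "proteins.truth.csv")
n_up = (p_truth["direction"] == "up").sum()
n_down = (p_truth["direction"] == "down").sum()
print(f"proteins: {pcfg.n_proteins} rows, planted {n_up} up / {n_down} down "
      f"at fold 1.5 in O-BAY, 10% missingness")
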