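"""File interchange: TIFF images, trajectory CSVs, protein TSVs, YAML configs.

Images travel as single-channel 16-bit TIFF with the pixel size recorded in
a JSON sidecar (``<stem>.meta.json``); ground truth as JSON (lengths/widths
in um) plus a label-mask TIFF; trajectories as plain CSV; protein tables as
tab-separated text with one raw-intensity column per sample and the
sample-to-group map as a separate CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .behavior import Trajectory
from .morpho import FluorescenceImage
from .proteome import ProteinTable
from .synth.scene import GroundTruth


def write_image(path, image: FluorescenceImage) -> None:
    path = Path(path)
    arr = np.clip(np.round(image.intensity), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, arr.astype(np.uint16))
    sidecar = path.with_suffix("").with_suffix(".meta.json")
    sidecar.write_text(json.dumps({"pixel_size_um": image.pixel_size}))


def read_image(path, pixel_size: float | None = None) -> FluorescenceImage:
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    if pixel_size is None:
        sidecar = path.with_suffix("").with_suffix(".meta.json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no pixel size given and no sidecar {sidecar.name} found"
            )
        pixel_size = float(json.loads(sidecar.read_text())["pixel_size_um"])
    return FluorescenceImage(intensity=arr, pixel_size=pixel_size)


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Ground truth as JSON plus a label-mask TIFF alongside."""
    path = Path(path)
    payload = {
        "lengths_um": truth.lengths.tolist(),
        "head_widths_um": truth.head_widths.tolist(),
        "ratios": truth.ratios.tolist(),
        "base_points_um": truth.base_points.tolist(),
        "tip_points_um": truth.tip_points.tolist(),
        "core_length_um": truth.core_length,
        "core_polyline_um": truth.core_polyline.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1))
    tifffile.imwrite(
        path.with_suffix("").with_suffix(".labels.tif"),
        truth.spine_labels.astype(np.uint16),
    )


def write_trajectory(path, traj: Trajectory) -> None:
    traj.data.to_csv(path, index=False, float_format="%.6g")


def write_protein_table(path, table: ProteinTable, groups_path=None) -> None:
    """Protein table as TSV; the sample-to-group map as a separate CSV."""
    path = Path(path)
    out = table.data.reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
    if groups_path is None:
        groups_path = path.with_suffix("").with_suffix(".groups.csv")
    pd.DataFrame(
        {"sample": list(table.groups), "group": list(table.groups.values())}
    ).to_csv(groups_path, index=False)


def read_protein_table(path, groups_path=None) -> ProteinTable:
    path = Path(path)
    if groups_path is None:
        groups_path = path.with_suffix("").with_suffix(".groups.csv")
    df = pd.read_csv(path, sep="\t", na_values=["NA"]).set_index("protein_id")
    gmap = pd.read_csv(groups_path)
    return ProteinTable(data=df, groups=dict(zip(gmap["sample"], gmap["group"])))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def dump_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
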