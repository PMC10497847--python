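"""End-to-end orchestration of a four-group synthetic study.

``run_study`` drives every stage on synthetic data: renders dendrite scenes
per group and measures spine morphology, simulates and scores behavioral
sessions, generates a protein table and runs the TPA differential-abundance
chain, then computes the group statistics (full and compartment-stratified
KS on shape ratios, t-tests, latency ratios, DAP tables, ratio matrix,
overlaps) and writes a versioned CSV/JSON report bundle plus a run log.

Determinism: one global seed deterministically derives one sub-seed per
stage (via numpy's SeedSequence spawning, reduced modulo 2**31), so a rerun
with the same config is bit-identical and single stages can be re-executed
independently. The run log carries timings and is excluded from report
checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import morpho, proteome, stats
from .synth import (
    ImageSceneConfig,
    ProteinTableConfig,
    TrajectoryConfig,
    arrange_spines_along_core,
    generate_protein_table,
    generate_trajectory,
    plan_cohort_bouts,
    sample_spine_shapes,
)

GROUPS = ["Y-CTR", "Y-BAY", "O-CTR", "O-BAY"]

#: comparison plan: treated-vs-control and old-vs-young contrasts
DEFAULT_COMPARISONS = [
    ("O-BAY", "O-CTR"),
    ("O-CTR", "Y-CTR"),
    ("O-BAY", "Y-CTR"),
    ("Y-BAY", "Y-CTR"),
]

#: class mixtures per group: old groups enriched in mature (stubby/mushroom)
#: shapes, young groups thinner and more filopodia-like; the treated old
#: group shifts its immature compartment toward filopodia
DEFAULT_MIXTURES = {
    "Y-CTR": {"stubby": 0.15, "mushroom": 0.25, "thin": 0.30, "long_thin": 0.20, "filopodia": 0.10},
    "Y-BAY": {"stubby": 0.25, "mushroom": 0.35, "thin": 0.25, "long_thin": 0.10, "filopodia": 0.05},
    "O-CTR": {"stubby": 0.30, "mushroom": 0.35, "thin": 0.20, "long_thin": 0.10, "filopodia": 0.05},
    "O-BAY": {"stubby": 0.30, "mushroom": 0.35, "thin": 0.10, "long_thin": 0.10, "filopodia": 0.15},
}

#: behavioral program per group and day: novelty bias of the bout plan and
#: mean latency (s) to the first bout; improved groups shorten their latency
#: at Day 14, impaired groups lengthen it
DEFAULT_BEHAVIOR_PROGRAM = {
    "Y-CTR": {"day0": (0.60, 30.0), "day14": (0.60, 15.0)},
    "Y-BAY": {"day0": (0.60, 30.0), "day14": (0.60, 45.0)},
    "O-CTR": {"day0": (0.50, 30.0), "day14": (0.50, 45.0)},
    "O-BAY": {"day0": (0.50, 30.0), "day14": (0.60, 15.0)},
}


@dataclass
class MorphologySettings:
    n_scenes: int = 2
    spines_per_scene: int = 8
    image_px: int = 512
    pixel_size: float = 0.07
    dendrite_radius: float = 0.5
    psf_sigma: float = 0.1
    photon_scale: float = 500.0
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    mixtures: dict = field(default_factory=lambda: {g: dict(m) for g, m in DEFAULT_MIXTURES.items()})


@dataclass
class BehaviorSettings:
    n_animals: int = 9
    n_bouts: int = 10
    mean_bout_s: float = 4.0
    sample_rate: float = 25.0
    session_s: float = 600.0
    position_noise_cm: float = 0.05
    program: dict = field(default_factory=lambda: {g: dict(p) for g, p in DEFAULT_BEHAVIOR_PROGRAM.items()})


@dataclass
class StatsSettings:
    stratify_threshold: float = 2.0
    fc_threshold: float = 1.2
    alpha: float = 0.05


@dataclass
class StudyConfig:
    seed: int = 0
    groups: list[str] = field(default_factory=lambda: list(GROUPS))
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_COMPARISONS]
    )
    morphology: MorphologySettings = field(default_factory=MorphologySettings)
    behavior: BehaviorSettings = field(default_factory=BehaviorSettings)
    proteins: ProteinTableConfig = field(default_factory=ProteinTableConfig)
    stats: StatsSettings = field(default_factory=StatsSettings)

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group names must be unique")
        for a, b in self.comparisons:
            if a not in self.groups or b not in self.groups:
                raise ValueError(f"comparison ({a}, {b}) references unknown group")

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        kwargs: dict = {}
        for key in ("seed", "groups"):
            if key in raw:
                kwargs[key] = raw[key]
        if "comparisons" in raw:
            kwargs["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        if "morphology" in raw:
            kwargs["morphology"] = MorphologySettings(**raw["morphology"])
        if "behavior" in raw:
            kwargs["behavior"] = BehaviorSettings(**raw["behavior"])
        if "proteins" in raw:
            p = dict(raw["proteins"])
            if "groups" in p:
                p["groups"] = [tuple(g) for g in p["groups"]]
            if "fold_range" in p:
                p["fold_range"] = tuple(p["fold_range"])
            kwargs["proteins"] = ProteinTableConfig(**p)
        if "stats" in raw:
            kwargs["stats"] = StatsSettings(**raw["stats"])
        return cls(**kwargs)


STAGES = ["morphology", "behavior", "proteome"]


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Per-stage sub-seeds spawned deterministically from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


@dataclass
class StudyReport:
    out_dir: Path
    values: dict
    files: list[str]
    checksums: dict[str, str]


def _straight_path(image_px: int, pixel_size: float) -> np.ndarray:
    extent = image_px * pixel_size
    margin = 2.5
    y = extent / 2.0
    return np.array([[margin, y], [extent - margin, y]])


def run_morphology_stage(
    config: StudyConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render and measure every group's scenes.

    Returns (per-spine measurements, per-scene density table).
    """
    m = config.morphology
    rows = []
    scene_rows = []
    for gi, group in enumerate(config.groups):
        mixture = m.mixtures[group]
        for si in range(m.n_scenes):
            scene_seed = seed + 1000 * gi + si
            path = _straight_path(m.image_px, m.pixel_size)
            specs = sample_spine_shapes(mixture, m.spines_per_scene, seed=scene_seed)
            arrange_spines_along_core(specs, path, margin=2.0, seed=scene_seed + 1)
            scene = ImageSceneConfig(
                dendrite_path=path,
                spine_specs=specs,
                pixel_size=m.pixel_size,
                image_shape=(m.image_px, m.image_px),
                dendrite_radius=m.dendrite_radius,
                psf_sigma=m.psf_sigma,
                photon_scale=m.photon_scale,
                background_level=m.background_level,
                read_noise_sd=m.read_noise_sd,
                seed=scene_seed + 2,
            )
            image, truth = morpho_render(scene)
            background = morpho.estimate_background(image)
            n_measured = 0
            for roi in morpho.rois_from_labels(
                truth.spine_labels, truth.base_points, m.pixel_size
            ):
                try:
                    meas = morpho.measure_spine(image, roi, background=background)
                except ValueError:
                    continue
                n_measured += 1
                rows.append(
                    {
                        "group": group,
                        "scene": si,
                        "roi_id": roi.region_id,
                        "length_um": meas.length,
                        "head_width_um": meas.head_width,
                        "ratio": meas.ratio,
                        "class": meas.class_label,
                        "true_length_um": truth.lengths[roi.region_id - 1],
                        "true_head_width_um": truth.head_widths[roi.region_id - 1],
                        "true_ratio": truth.ratios[roi.region_id - 1],
                    }
                )
            scene_rows.append(
                {
                    "group": group,
                    "scene": si,
                    "spine_count": len(specs),
                    "dendrite_um": truth.core_length,
                    "density_per_um": morpho.compute_linear_density(
                        len(specs), truth.core_length
                    ),
                    "measured": n_measured,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(scene_rows)


def morpho_render(scene: ImageSceneConfig):
    # local import point kept separate for monkeypatch-friendly testing
    from .synth import render_scene

    return render_scene(scene)


def run_spine_stats(
    config: StudyConfig, spines: pd.DataFrame, scenes: pd.DataFrame
) -> pd.DataFrame:
    """Full + stratified KS on ratios and density t-tests per comparison."""
    thr = config.stats.stratify_threshold
    rows = []
    for a, b in config.comparisons:
        ra = spines.loc[spines["group"] == a, "ratio"].to_numpy()
        rb = spines.loc[spines["group"] == b, "ratio"].to_numpy()
        label = f"{a} vs {b}"
        if ra.size and rb.size:
            full = stats.ks_two_sample(ra, rb)
            rows.append(_ks_row(label, "full", full))
            for side in ("below", "above"):
                try:
                    strat = stats.stratified_ks(ra, rb, threshold=thr, side=side)
                except ValueError:
                    continue
                rows.append(_ks_row(label, side, strat))
        da = scenes.loc[scenes["group"] == a, "density_per_um"].to_numpy()
        db = scenes.loc[scenes["group"] == b, "density_per_um"].to_numpy()
        if da.size >= 2 and db.size >= 2:
            try:
                tt = stats.t_test_two_sample(da, db)
                rows.append(
                    {
                        "comparison": label,
                        "stratum": "density",
                        "D": np.nan,
                        "ks": tt.t,
                        "p_raw": tt.p,
                        "p_reported": tt.p,
                        "n1": da.size,
                        "n2": db.size,
                    }
                )
            except ZeroDivisionError:
                pass
    return pd.DataFrame(rows)


def _ks_row(comparison: str, stratum: str, res: stats.KsResult) -> dict:
    return {
        "comparison": comparison,
        "stratum": stratum,
        "D": res.D,
        "ks": res.ks_scaled,
        "p_raw": res.p_raw,
        "p_reported": res.p,
        "n1": res.n1,
        "n2": res.n2,
    }


def run_behavior_stage(config: StudyConfig, seed: int) -> pd.DataFrame:
    """Simulate and score each animal's Day-0 and Day-14 sessions."""
    b = config.behavior
    objects = _behavior_objects()
    params = bhv.ScoringParams(session_s=b.session_s)
    rows = []
    rng = np.random.default_rng(seed)
    for group in config.groups:
        prog = b.program[group]
        for animal in range(b.n_animals):
            for day in ("day0", "day14"):
                bias, latency_mean = prog[day]
                lat = float(rng.lognormal(np.log(latency_mean), 0.2))
                bout_seed = int(rng.integers(0, 2**31))
                bouts = plan_cohort_bouts(
                    objects,
                    novel_label="B",
                    novel_bias=bias,
                    n_bouts=b.n_bouts,
                    mean_bout_s=b.mean_bout_s,
                    latency_s=lat,
                    session_s=b.session_s,
                    seed=bout_seed,
                )
                traj_cfg = TrajectoryConfig(
                    objects=objects,
                    bouts=bouts,
                    session_s=b.session_s,
                    sample_rate=b.sample_rate,
                    position_noise_cm=b.position_noise_cm,
                    seed=bout_seed + 1,
                )
                traj, _truth = generate_trajectory(traj_cfg, params)
                summary = bhv.score_exploration(traj, objects, params)
                novel = familiar = np.nan
                if not summary.excluded:
                    novel, familiar = bhv.object_preference(summary, "B")
                rows.append(
                    {
                        "group": group,
                        "animal": animal,
                        "day": day,
                        "novel_s": novel,
                        "familiar_s": familiar,
                        "latency_s": summary.latency_s,
                        "total_s": summary.total_s,
                        "excluded": summary.excluded,
                    }
                )
    return pd.DataFrame(rows)


def _behavior_objects():
    from .synth import default_objects

    return default_objects()


def run_behavior_stats(config: StudyConfig, scores: pd.DataFrame) -> pd.DataFrame:
    """Novel-vs-familiar t-tests per group/day and latency-ratio summaries."""
    rows = []
    for group in config.groups:
        for day in ("day0", "day14"):
            sel = scores[
                (scores["group"] == group)
                & (scores["day"] == day)
                & (~scores["excluded"])
            ]
            if len(sel) >= 2:
                try:
                    tt = stats.t_test_two_sample(
                        sel["novel_s"].to_numpy(), sel["familiar_s"].to_numpy()
                    )
                    rows.append(
                        {
                            "group": group,
                            "metric": f"novel_vs_familiar_{day}",
                            "value": tt.t,
                            "p": tt.p,
                            "n": len(sel),
                        }
                    )
                except ZeroDivisionError:
                    pass
        merged = scores[scores["group"] == group].pivot_table(
            index="animal", columns="day", values="latency_s"
        )
        ratios = [
            bhv.latency_ratio(r["day14"], r["day0"])
            for _, r in merged.iterrows()
            if np.isfinite(r.get("day0", np.nan))
            and np.isfinite(r.get("day14", np.nan))
            and r["day0"] > 0
        ]
        if ratios:
            rows.append(
                {
                    "group": group,
                    "metric": "latency_ratio_day14_day0_median",
                    "value": float(np.median(ratios)),
                    "p": np.nan,
                    "n": len(ratios),
                }
            )
    return pd.DataFrame(rows)


def run_proteome_stage(config: StudyConfig, seed: int):
    """Generate a table, run filters + TPA + DA, overlaps and ratio matrix."""
    pcfg = config.proteins
    pcfg = ProteinTableConfig(**{**asdict(pcfg), "seed": seed, "groups": [tuple(g) for g in pcfg.groups]})
    table, truth = generate_protein_table(pcfg)
    filtered = proteome.filter_group_presence(
        proteome.filter_min_unique_peptides(table, k=2), min_frac=0.6
    )
    tpa = proteome.compute_tpa(filtered)
    dap_tables = {}
    dap_sets = {}
    for a, b in config.comparisons:
        recs = proteome.differential_abundance(
            tpa,
            (a, b),
            fc_threshold=config.stats.fc_threshold,
            alpha=config.stats.alpha,
        )
        label = f"{a} vs {b}"
        dap_tables[label] = proteome.dap_frame(recs)
        dap_sets[label] = proteome.significant_ids(recs)
    overlap = (
        proteome.overlap_sets({k: dap_sets[k] for k in list(dap_sets)[:3]})
        if len(dap_sets) >= 2
        else {}
    )
    planted_ids = truth.index[truth["planted"]].tolist()
    subset = [p for p in planted_ids if p in tpa.conc.index][:10]
    ratio_matrix = (
        proteome.group_ratio_matrix(tpa, config.comparisons, subset)
        if subset
        else pd.DataFrame()
    )
    return table, truth, tpa, dap_tables, overlap, ratio_matrix


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def report_checksums(out_dir) -> dict[str, str]:
    """Checksums of every report file except the (timing-bearing) run log."""
    out_dir = Path(out_dir)
    return {
        p.name: _sha256(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "run.log"
    }


def run_study(config: StudyConfig, out_dir) -> StudyReport:
    """Run all stages and write the report bundle; bit-reproducible per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    log_lines = []
    values: dict = {"seed": config.seed, "stage_seeds": seeds}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - abort with stage-named error
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log_lines.append(
            f"stage={name} seed={seeds.get(name, config.seed)} "
            f"elapsed_s={time.perf_counter() - t0:.2f}"
        )
        return result

    spines, scenes = _stage(
        "morphology", lambda: run_morphology_stage(config, seeds["morphology"])
    )
    spine_stats = run_spine_stats(config, spines, scenes)
    scores = _stage("behavior", lambda: run_behavior_stage(config, seeds["behavior"]))
    behavior_stats = run_behavior_stats(config, scores)
    table, truth, tpa, dap_tables, overlap, ratio_matrix = _stage(
        "proteome", lambda: run_proteome_stage(config, seeds["proteome"])
    )

    fmt = "%.10g"
    spines.to_csv(out_dir / "spine_measurements.csv", index=False, float_format=fmt)
    scenes.to_csv(out_dir / "spine_scenes.csv", index=False, float_format=fmt)
    spine_stats.to_csv(out_dir / "spine_stats.csv", index=False, float_format=fmt)
    scores.to_csv(out_dir / "behavior_scores.csv", index=False, float_format=fmt)
    behavior_stats.to_csv(out_dir / "behavior_stats.csv", index=False, float_format=fmt)
    for label, frame in dap_tables.items():
        safe = label.replace(" ", "_")
        frame.to_csv(out_dir / f"dap_{safe}.csv", index=False, float_format=fmt)
    with open(out_dir / "overlap.json", "w") as fh:
        json.dump(overlap, fh, indent=1, sort_keys=True)
    ratio_matrix.to_csv(out_dir / "ratio_matrix.csv", float_format=fmt)

    values["n_spines_measured"] = int(len(spines))
    values["n_daps"] = {
        label: int((frame["direction"] != "ns").sum())
        for label, frame in dap_tables.items()
    }
    manifest = {
        "config": _config_dict(config),
        "stage_seeds": seeds,
        "values": values,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    checksums = report_checksums(out_dir)
    files = sorted(checksums)
    return StudyReport(
        out_dir=out_dir, values=values, files=files, checksums=checksums
    )


def _config_dict(config: StudyConfig) -> dict:
    raw = asdict(config)
    raw["comparisons"] = [list(c) for c in config.comparisons]
    return raw
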