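"""End-to-end pipeline: label images → morphology → networks → progressions
→ growth variables → clustering; spheroid stacks → invasion; correlations.

Inputs are two manifests:

* a 2D manifest CSV with columns
  ``clone_id,image_id,path,pixel_size[,time_h]`` listing label-image TIFFs;
* an optional 3D manifest CSV with columns
  ``clone_id,spheroid_id,path,pixel_size,z_spacing`` listing z-stacks.

All thresholds live in :class:`PipelineConfig`, which round-trips through
YAML; every output is stamped with the config hash so reruns are auditable.
Given a fixed seed the run is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as clustering_mod
from . import correlation as correlation_mod
from . import spheroid as spheroid_mod
from .io import LabelImage, read_label_image, read_zstack, write_network
from .morphology import snapshot
from .network import build_network, network_metrics
from .progression import DEFAULT_ANCHORS, CloneProgression, growth_variables

log = logging.getLogger("clonemorph")


@dataclass
class PipelineConfig:
    adjacency_threshold_um: float = 5.0
    polynomial_degree: int = 2
    anchors: tuple[float, float, float] = DEFAULT_ANCHORS
    k_superclasses: int = 2
    k_subclasses: int = 3
    chromatic_exact_limit: int = 20
    spheroid_window_um: float = 75.0
    spheroid_min_area_um2: float = 50.0
    min_protrusion_length_um: float = 20.0
    correlation_threshold: float = 0.8
    invasion_correlation_threshold: float = 0.3
    correlation_anchor: str = "m"  # which anchor feeds the clone-level table
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("adjacency_threshold_um", "spheroid_window_um",
                     "spheroid_min_area_um2", "min_protrusion_length_um",
                     "correlation_threshold", "invasion_correlation_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["anchors"] = list(data["anchors"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "anchors" in data:
            data["anchors"] = tuple(data["anchors"])
        return cls(**data)

    def digest(self) -> str:
        data = dataclasses.asdict(self)
        data["anchors"] = list(data["anchors"])
        return hashlib.sha1(json.dumps(data, sort_keys=True).encode()).hexdigest()[:12]


def process_label_image(img: LabelImage, config: PipelineConfig) -> dict[str, float]:
    """One image → one property row (morphology summaries + topology metrics)."""
    snap = snapshot(img)
    row = snap.to_row()
    if img.n_cells:
        net = build_network(img, adjacency_threshold=config.adjacency_threshold_um)
        metrics = network_metrics(net, foreground=img.foreground,
                                  exact_limit=config.chromatic_exact_limit)
        row.update(metrics.to_row())
    return row


def run_pipeline(manifest_2d: str | Path, out_dir: str | Path,
                 manifest_3d: str | Path | None = None,
                 config: PipelineConfig | None = None) -> Path:
    """Run every stage and write all outputs under ``out_dir``.

    Stage failures raise with the stage and offending file named. Returns
    the output directory.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = config.digest()
    config.to_yaml(out / "config.yaml")
    log_lines = [f"config_hash: {stamp}"]

    # stage 1-2: per-image morphology + topology
    manifest = pd.read_csv(manifest_2d)
    rows = []
    for rec in manifest.to_dict("records"):
        try:
            img = read_label_image(rec["path"], pixel_size=float(rec["pixel_size"]),
                                   image_id=str(rec["image_id"]),
                                   clone_id=str(rec["clone_id"]),
                                   time_h=float(rec["time_h"]) if "time_h" in rec and pd.notna(rec.get("time_h")) else None)
        except Exception as exc:
            raise RuntimeError(f"stage measure: failed on {rec['path']}: {exc}") from exc
        row = process_label_image(img, config)
        row["clone_id"] = str(rec["clone_id"])
        row["image_id"] = str(rec["image_id"])
        rows.append(row)
        if img.n_cells:
            net = build_network(img, adjacency_threshold=config.adjacency_threshold_um)
            write_network(net, out / f"network_{rec['image_id']}.graphml")
    images_df = pd.DataFrame(rows)
    images_df.to_csv(out / "image_properties.csv", index=False)
    log_lines.append(f"images: {len(images_df)}")

    # stage 3: progressions and growth variables
    vectors = []
    for clone_id, group in images_df.groupby("clone_id"):
        pts = group.drop(columns=["clone_id", "image_id"]).to_dict("records")
        prog = CloneProgression(clone_id=str(clone_id), points=pts)
        prog.fit_all(degree=config.polynomial_degree)
        vectors.append(growth_variables(prog, anchors=config.anchors))
    gv_df = pd.DataFrame({v.clone_id: v.values for v in vectors}).T
    gv_df.index.name = "clone_id"
    gv_df.to_csv(out / "growth_variables.csv")
    log_lines.append(f"clones: {len(gv_df)}")

    # stage 4: clustering (needs enough clones)
    if len(gv_df) >= config.k_superclasses * config.k_subclasses:
        try:
            nested = clustering_mod.two_stage_clustering(
                gv_df.dropna(axis=1, how="any"),
                k_super=config.k_superclasses, k_sub=config.k_subclasses)
            flat = nested.flat_subclass_labels()
            pd.DataFrame(
                [(cid, s, b) for cid, (s, b) in flat.items()],
                columns=["clone_id", "superclass", "subclass"],
            ).to_csv(out / "cluster_labels.csv", index=False)
        except ValueError as exc:
            log_lines.append(f"clustering skipped: {exc}")
    else:
        log_lines.append("clustering skipped: too few clones")

    # stage 5: spheroids and invasion
    clone_table = gv_df.copy()
    if manifest_3d is not None:
        manifest3 = pd.read_csv(manifest_3d)
        measurements = []
        for rec in manifest3.to_dict("records"):
            try:
                stack = read_zstack(rec["path"], pixel_size=float(rec["pixel_size"]),
                                    z_spacing=float(rec["z_spacing"]),
                                    spheroid_id=str(rec["spheroid_id"]))
                measurements.append(spheroid_mod.measure_stack(
                    stack, clone_id=str(rec["clone_id"]),
                    window_um=config.spheroid_window_um,
                    min_area_um2=config.spheroid_min_area_um2,
                    min_protrusion_length_um=config.min_protrusion_length_um))
            except Exception as exc:
                raise RuntimeError(f"stage spheroid: failed on {rec['path']}: {exc}") from exc
        pd.DataFrame([{"spheroid_id": m.spheroid_id, "clone_id": m.clone_id,
                       **m.metric_row()} for m in measurements]
                     ).to_csv(out / "spheroid_metrics.csv", index=False)
        if len({m.clone_id for m in measurements}) >= 2:
            scores = spheroid_mod.invasion_score(measurements)
            inv_df = pd.DataFrame([{"clone_id": s.clone_id, "invasion3D": s.invasion3d,
                                    **{f"norm_{k}": v for k, v in s.normalized.items()}}
                                   for s in scores]).set_index("clone_id")
            inv_df.to_csv(out / "invasion_scores.csv")
            clone_table = clone_table.join(inv_df[["invasion3D"]], how="left")

    # stage 6: correlations (one value per clone; 2D variables at one anchor)
    suffix = f"_{config.correlation_anchor}"
    cols = [c for c in clone_table.columns if c.endswith(suffix) or c == "invasion3D"]
    corr_table = clone_table[cols].dropna(axis=1, how="all")
    if len(corr_table) >= 3 and corr_table.shape[1] >= 2:
        matrix = correlation_mod.spearman_matrix(corr_table)
        matrix.to_csv(out / "spearman_matrix.csv")
        cg = correlation_mod.correlation_graph(matrix, threshold=config.correlation_threshold)
        correlation_mod.write_correlation_graph(cg, out / "correlation_graph.graphml")
        if "invasion3D" in corr_table.columns:
            star = correlation_mod.invasion_correlations(
                corr_table, threshold=config.invasion_correlation_threshold)
            correlation_mod.write_correlation_graph(star, out / "invasion_correlations.graphml")
    else:
        log_lines.append("correlation skipped: too few clones or variables")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
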