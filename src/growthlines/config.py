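"""Pipeline configuration, the end-to-end demo, and input-format validation.

One human-readable YAML config drives every stage; unknown keys are
rejected so typos cannot silently fall back to defaults, and the effective
config (defaults merged with the file and CLI overrides) is serialised next
to the outputs of every run — no hidden numeric decisions.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("growthlines")

#: schema: every known key with its default.  ``None`` marks a value that
#: must be provided explicitly by the user when the stage is run.
DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "seed": 0,
    "mesh": {"n_axial": 24, "n_circ": 16, "length": 4.0, "radius": 0.5},
    "zones": {"n_axial": 4, "n_angular": 3},
    "injections": {"n_per_zone": 3, "jitter": 0.0, "radius": 0.35, "samples_per_face": 10},
    "scoring": {"min_overlap": 0.05},
    "shape": {"t_line": 2.5, "t_v_deg": 150.0, "t_arm_frac": 0.25, "grey_band": [2.0, 3.0]},
    "expression": {"n_cells": 400, "n_genes": 300, "n_bins": 12, "n_ctrl": 10},
    "morphometry": {
        # deliberately no defaults: threshold values must be explicit
        "area_threshold": None,
        "despeckle_radius": None,
        "outlier_threshold": None,
    },
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict, schema: dict | None = None, path: str = "") -> None:
    """Reject unknown keys anywhere in the nested config."""
    schema = DEFAULT_CONFIG if schema is None else schema
    for key, value in cfg.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(schema[key], dict) and isinstance(value, dict):
            validate_config(value, schema[key], where)


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults <- config file <- overrides, validated against the schema."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        validate_config(user)
        _deep_update(cfg, user)
    if overrides:
        validate_config(overrides)
        _deep_update(cfg, overrides)
    return cfg


def require(cfg: dict, *keys: str):
    """Fetch a config value that has no default, erroring with its key name."""
    node = cfg
    for k in keys:
        if not isinstance(node, dict) or k not in node:
            raise ConfigError(f"missing required config key: {'.'.join(keys)}")
        node = node[k]
    if node is None:
        raise ConfigError(f"missing required config key: {'.'.join(keys)}")
    return node


def _deep_update(base: dict, other: dict) -> None:
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


# -- demo pipeline ------------------------------------------------------------------


@dataclass
class DemoResult:
    outdir: Path
    n_injections: int
    truth_agreement: float  # fraction of records whose assigned areas == truth
    frequency_csv: Path
    metrics_csv: Path
    geneset_csv: Path


def run_demo(config: dict, outdir, seed: int | None = None) -> DemoResult:
    """Simulate -> inject -> propagate -> metrics -> score -> report.

    Every stage logs its parameters; the effective config plus its hash are
    written next to the outputs.  Identical config and seed reproduce the
    bundle byte for byte.
    """
    from . import dye, genesets, io, metrics, scoring, synthetic
    from .metrics import AxisFrame, ShapeThresholds

    cfg = copy.deepcopy(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(cfg["seed"])

    logger.info("stage=simulate mesh=%s seed=%d", cfg["mesh"], rng_seed)
    base = synthetic.tube(**{k: cfg["mesh"][k] for k in ("n_axial", "n_circ", "length", "radius")})
    spec = synthetic.default_deformation(base, rng_seed=rng_seed)
    series, truth = synthetic.generate_stage_series(base, spec)
    io.save_series(series, outdir / "meshes")

    zones = synthetic.partition_zones(series[0], **cfg["zones"])
    regions_faces = synthetic.default_outcome_region_faces(series[-1])
    region_set = scoring.OutcomeRegionSet(regions_faces)
    pd.DataFrame(
        [(name, int(f)) for name, faces in regions_faces.items() for f in faces],
        columns=["region", "face_index"],
    ).to_csv(outdir / "regions.csv", index=False)

    inj_cfg = cfg["injections"]
    logger.info("stage=injections %s", inj_cfg)
    records = synthetic.generate_injection_set(
        series,
        zones,
        n_per_zone=inj_cfg["n_per_zone"],
        jitter=inj_cfg["jitter"],
        rng_seed=rng_seed,
        radius=inj_cfg["radius"],
        regions=regions_faces,
        min_overlap=cfg["scoring"]["min_overlap"],
    )

    thresholds = ShapeThresholds(
        t_line=cfg["shape"]["t_line"],
        t_v_deg=cfg["shape"]["t_v_deg"],
        t_arm_frac=cfg["shape"]["t_arm_frac"],
        grey_band=tuple(cfg["shape"]["grey_band"]),
    )
    v0 = series[0].vertices
    ap_line = np.array(
        [[x, series[0].vertices[:, 1].max(), 0.0] for x in np.linspace(v0[:, 0].min(), v0[:, 0].max(), 8)]
    )
    frame = AxisFrame(ap_polyline=ap_line, target=np.asarray(spec.attractor_point))

    final_s = series.n_stages - 1
    metric_rows = []
    outcome_records = []
    agree = 0
    chash = config_hash(cfg)
    for rec in records:
        patch0 = dye.inject(
            series[0],
            rec.seed,
            rec.radius,
            samples_per_face=inj_cfg["samples_per_face"],
            rng_seed=rng_seed,
            meta={"sample_id": rec.sample_id, "zone": rec.zone},
        )
        patch1 = dye.propagate(patch0, series, final_s)
        m = metrics.measure(patch0, patch1, frame, thresholds)
        metric_rows.append(
            {
                "sample_id": rec.sample_id,
                "zone": rec.zone,
                "stage": final_s,
                "area_ratio": m.area_ratio,
                "elongation": m.elongation,
                "orientation_deg": m.orientation_deg,
                "centroid_displacement": m.centroid_displacement,
                "convergence_distance": m.convergence_distance,
                "shape_class": m.shape_class,
                "v_angle_deg": m.v_angle_deg,
                "config_hash": chash,
            }
        )
        assignment = scoring.assign(patch1, region_set, cfg["scoring"]["min_overlap"])
        logger.debug(
            "sample=%s zone=%s areas=%s truth=%s",
            rec.sample_id, rec.zone, sorted(assignment.labels), sorted(rec.truth_areas),
        )
        if assignment.labels == rec.truth_areas:
            agree += 1
        outcome_records.append(
            scoring.OutcomeRecord(
                sample_id=rec.sample_id, zones=(rec.zone,), areas=assignment.labels
            )
        )

    metrics_csv = outdir / "growth_metrics.csv"
    pd.DataFrame(metric_rows).to_csv(metrics_csv, index=False)

    fm = scoring.frequency_matrix(outcome_records)
    frequency_csv = outdir / "frequency_matrix.csv"
    fm.pct.to_csv(frequency_csv)
    fm.counts.to_csv(outdir / "frequency_counts.csv")
    fm.row_n.to_csv(outdir / "frequency_row_n.csv", header=["n"])
    scoring.render_thumbnails(fm, region_set, series[-1], outdir=outdir / "thumbnails")

    ex_cfg = cfg["expression"]
    logger.info("stage=geneset %s", ex_cfg)
    planted = synthetic.PlantedDesign(
        exclusion_positive={"Foxa1": 12, "Shh": 8, "Foxb1": 6},
        set_effects=[(("Mki67", "Top2a", "Pcna"), 6, 4.0), (("Neurod1", "Dcx", "Tubb3"), 3, 4.0)],
    )
    adata, ex_truth = synthetic.generate_expression_matrix(
        n_cells=ex_cfg["n_cells"], n_genes=ex_cfg["n_genes"], planted=planted, rng_seed=rng_seed
    )
    filtered, report = genesets.filter_cells(adata)
    norm = genesets.normalize_log1p_cp10k(filtered)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        scores = genesets.score_table(
            norm, n_bins=ex_cfg["n_bins"], n_ctrl=ex_cfg["n_ctrl"], rng_seed=rng_seed
        )
    summary = genesets.cluster_summary(scores, norm.obs["cluster"])
    geneset_csv = outdir / "geneset_cluster_means.csv"
    summary.means.to_csv(geneset_csv)
    scores.to_csv(outdir / "geneset_cell_scores.csv")
    (outdir / "geneset_report.json").write_text(
        json.dumps(
            {
                "filter": report.__dict__,
                "top_cluster": summary.top_cluster,
                "normalisation": norm.uns["normalisation"],
            },
            indent=2,
        )
    )

    effective = dict(cfg)
    effective["config_hash"] = chash
    (outdir / "effective_config.yaml").write_text(yaml.safe_dump(effective, sort_keys=True))

    return DemoResult(
        outdir=outdir,
        n_injections=len(records),
        truth_agreement=agree / len(records),
        frequency_csv=frequency_csv,
        metrics_csv=metrics_csv,
        geneset_csv=geneset_csv,
    )


# -- input validation ---------------------------------------------------------------


def validate_inputs(paths) -> list[dict]:
    """Per-file format verdicts for OBJ/PLY/CSV/TSV/MTX/TIFF inputs.

    Report-only: never raises for a bad file.  OBJ files are additionally
    cross-checked for identical face blocks (the stage-correspondence
    requirement).
    """
    results = []
    obj_faces: dict[str, list[str]] = {}
    for p in map(Path, paths):
        verdict = {"path": str(p), "format": p.suffix.lstrip(".").lower(), "ok": True, "detail": ""}
        try:
            if not p.exists():
                raise FileNotFoundError("file not found")
            suffix = p.suffix.lower()
            if suffix == ".obj":
                nv = nf = 0
                faces = []
                for line in p.read_text().splitlines():
                    if line.startswith("v "):
                        nv += 1
                    elif line.startswith("f "):
                        nf += 1
                        faces.append(line.strip())
                if nv == 0 or nf == 0:
                    raise ValueError(f"OBJ has {nv} vertices and {nf} faces")
                obj_faces[str(p)] = faces
                verdict["detail"] = f"{nv} vertices, {nf} faces"
            elif suffix == ".ply":
                from .io import read_ply

                m = read_ply(p)
                verdict["detail"] = f"{m.n_vertices} vertices, {m.n_faces} faces"
            elif suffix in (".csv", ".tsv"):
                sep = "," if suffix == ".csv" else "\t"
                df = pd.read_csv(p, sep=sep, nrows=5)
                verdict["detail"] = f"{len(df.columns)} columns"
            elif suffix == ".mtx":
                verdict["detail"] = _check_mtx(p)
            elif suffix in (".tif", ".tiff"):
                import tifffile

                arr = tifffile.imread(p)
                verdict["detail"] = f"shape {arr.shape}"
            else:
                raise ValueError(f"unrecognised format {suffix!r}")
        except Exception as exc:  # noqa: BLE001 - report, never throw
            verdict["ok"] = False
            verdict["detail"] = f"{type(exc).__name__}: {exc}"
        results.append(verdict)

    if len(obj_faces) > 1:
        blocks = list(obj_faces.values())
        if any(b != blocks[0] for b in blocks[1:]):
            for v in results:
                if v["path"] in obj_faces:
                    v["ok"] = False
                    v["detail"] += "; face blocks differ between OBJ stage files"
    return results


def _check_mtx(path: Path) -> str:
    import scipy.io as sio

    m = sio.mmread(str(path))
    detail = f"matrix {m.shape[0]} x {m.shape[1]}"
    genes = path.parent / "genes.tsv"
    barcodes = path.parent / "barcodes.tsv"
    if genes.exists():
        n = sum(1 for _ in open(genes))
        if n != m.shape[0]:
            raise ValueError(f"MTX rows {m.shape[0]} != genes.tsv lines {n}")
        detail += f", genes.tsv {n}"
    if barcodes.exists():
        n = sum(1 for _ in open(barcodes))
        if n != m.shape[1]:
            raise ValueError(f"MTX cols {m.shape[1]} != barcodes.tsv lines {n}")
        detail += f", barcodes.tsv {n}"
    return detail
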