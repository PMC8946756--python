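"""End-to-end pipeline orchestration, cohort-table I/O and run manifests.

The pipeline runs the stages in the method's order:

    synthesis (optional) -> preprocessing -> SBA + ICA -> network scoring
    -> group statistics -> classification

driven by a single YAML/dict configuration tree with per-stage sections.
Every stochastic stage derives its seed from the top-level ``seed`` entry
and the manifest records the configuration snapshot, seeds, package version
and result hashes, so a rerun with the same manifest reproduces the same
hashes bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import build_feature_models, evaluate_cv, results_table
from .groupstats import voxelwise_perm_correlation
from .ica import build_group_templates, pick_network_component, run_subject_ica
from .networks import NETWORK_NAMES, NetworkModel, default_synthetic_model
from .preproc import PreprocConfig, preprocess_run
from .sba import DEFAULT_THRESHOLD_Z, combine_left_right, sba_subject
from .scoring import build_profile, cohort_network_summary
from .synthcohort import (
    COHORT_COLUMNS,
    DIAGNOSES,
    ETIOLOGIES,
    CohortSpec,
    SubjectRecord,
    generate_cohort,
    records_to_table,
)

logger = logging.getLogger(__name__)

CONFIG_SECTIONS = {
    "seed": None,
    "out_dir": None,
    "cohort": {f.name for f in dataclasses.fields(CohortSpec)} - {"rng_seed"},
    "preproc": {f.name for f in dataclasses.fields(PreprocConfig)},
    "sba": {"threshold_z"},
    "ica": {"n_components", "z_thresh"},
    "groupstats": {"n_permutations", "subscale"},
    "classify": {"models", "cv", "n_boot"},
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Validate the config tree against the schema; unknown keys are errors
    listing every offending key.  Returns the config with defaults filled."""
    bad: list[str] = []
    for key in config:
        if key not in CONFIG_SECTIONS:
            bad.append(key)
    for section, allowed in CONFIG_SECTIONS.items():
        if allowed is None:
            continue
        for key in config.get(section) or {}:
            if key not in allowed:
                bad.append(f"{section}.{key}")
    if bad:
        raise ConfigError(f"unknown configuration key(s): {sorted(bad)}")
    out = {
        "seed": int(config.get("seed", 0)),
        "cohort": dict(config.get("cohort") or {}),
        "preproc": dict(config.get("preproc") or {}),
        "sba": {"threshold_z": DEFAULT_THRESHOLD_Z, **(config.get("sba") or {})},
        "ica": {"n_components": 30, "z_thresh": 3.0, **(config.get("ica") or {})},
        "groupstats": {"n_permutations": 999, "subscale": "crs_r_visual", **(config.get("groupstats") or {})},
        "classify": {
            "models": ["rating", "intensity", "mri", "rating+mri", "intensity+mri", "clinical"],
            "cv": "loocv",
            "n_boot": 2000,
            **(config.get("classify") or {}),
        },
        "out_dir": config.get("out_dir"),
    }
    if "grid_shape" in out["cohort"]:
        out["cohort"]["grid_shape"] = tuple(out["cohort"]["grid_shape"])
    if "etiology_mix" in out["cohort"]:
        out["cohort"]["etiology_mix"] = tuple(out["cohort"]["etiology_mix"])
    # fail fast: the preproc band must respect the cohort TR
    spec = CohortSpec(rng_seed=out["seed"], **out["cohort"])
    PreprocConfig(**out["preproc"]).validate(spec.tr_seconds)
    return out


def load_config(path: str | Path) -> dict:
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    result_hashes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["config"] = _jsonable(payload["config"])
        return json.dumps(payload, indent=2, default=str)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(np.round(np.asarray(arr, dtype=np.float64), 10)).tobytes()).hexdigest()


def run_pipeline(config: dict, model: NetworkModel | None = None) -> dict:
    """Execute the full pipeline on a synthetic cohort.

    Returns a dict with the subject profiles, detection summary, group-level
    voxelwise result, classification results and the :class:`RunManifest`.
    """
    cfg = validate_config(config)
    seed = cfg["seed"]
    seeds = {"cohort": seed, "ica": seed + 1, "groupstats": seed + 2, "classify": seed + 3}
    manifest = RunManifest(config=cfg, seeds=seeds, version=__version__)
    t0 = time.time()

    spec = CohortSpec(rng_seed=seeds["cohort"], **cfg["cohort"])
    if model is None:
        model = default_synthetic_model(spec.voxel_size_mm)
    records, runs, structurals = generate_cohort(spec, model)
    manifest.stage_seconds["synth"] = round(time.time() - t0, 2)

    # preprocessing
    t0 = time.time()
    pconf = PreprocConfig(**cfg["preproc"])
    pre_runs = []
    for run in runs:
        pre, _report = preprocess_run(run, pconf, spec.voxel_size_mm)
        pre_runs.append(pre)
    manifest.stage_seconds["preproc"] = round(time.time() - t0, 2)

    shape = spec.grid_shape
    node_masks = {net: model.network_mask(net, shape) for net in NETWORK_NAMES}

    # group ICA templates from controls; node-ROI masks are the fallback
    t0 = time.time()
    controls = [p for p, r in zip(pre_runs, records) if r.diagnosis == "control"]
    brain_mask = runs[0].brain_mask
    n_comp = int(cfg["ica"]["n_components"])
    z_thresh = float(cfg["ica"]["z_thresh"])
    if len(controls) >= 2:
        try:
            templates = build_group_templates(
                [c.data for c in controls], brain_mask, node_masks, n_comp, z_thresh, seeds["ica"]
            )
        except ValueError as exc:
            manifest.warnings.append(f"group templates fell back to node-ROI masks: {exc}")
            templates = node_masks
    else:
        manifest.warnings.append("fewer than 2 controls: node-ROI masks used as templates")
        templates = node_masks
    manifest.stage_seconds["templates"] = round(time.time() - t0, 2)

    # per-patient SBA + ICA + scoring
    t0 = time.time()
    profiles = []
    patient_records = []
    sba_fused: dict[str, list[np.ndarray]] = {net: [] for net in NETWORK_NAMES}
    sba_ratings: dict[str, list[float]] = {net: [] for net in NETWORK_NAMES}
    for i, (rec, pre, struct) in enumerate(zip(records, pre_runs, structurals)):
        if rec.diagnosis == "control":
            continue
        maps = sba_subject(pre, model, struct, float(cfg["sba"]["threshold_z"]))
        comps = run_subject_ica(pre.data, pre.brain_mask, n_comp, seeds["ica"] + 10 + i)
        ica_maps: dict[str, np.ndarray | None] = {}
        for net in NETWORK_NAMES:
            pick = pick_network_component(comps, templates[net], spec.tr_seconds)
            if pick is None:
                ica_maps[net] = None
            else:
                k, _vet = pick
                thr = np.where(comps.spatial_maps[k] >= z_thresh, comps.spatial_maps[k], 0.0)
                ica_maps[net] = thr
        profile = build_profile(
            rec.subject_id,
            model,
            {name: m.z_values for name, m in maps.items()},
            ica_maps,
            templates,
            rec.mri_node_ratings,
            shape,
        )
        profiles.append(profile)
        patient_records.append(rec)
        # L/R max-fused SBA maps + the network's best rating for exclusion
        for net in NETWORK_NAMES:
            nodes = model.nodes(net)
            l_map = np.zeros(shape)
            r_map = np.zeros(shape)
            for nd in nodes:
                m = maps[nd.name].z_values
                if nd.hemisphere == "L":
                    l_map = combine_left_right(l_map, m)
                else:
                    r_map = combine_left_right(r_map, m)
            sba_fused[net].append(combine_left_right(l_map, r_map))
            sba_ratings[net].append(
                max(profile.ratings[nd.name]["SBA"] for nd in nodes)
            )
    manifest.stage_seconds["subject_maps"] = round(time.time() - t0, 2)

    # detection summary
    det_rows = []
    for rec, prof in zip(patient_records, profiles):
        row = {
            "subject_id": rec.subject_id,
            "diagnosis": rec.diagnosis,
            "etiology": rec.etiology,
            "crs_r_total": rec.crs_r_total,
            "disease_duration_months": rec.disease_duration_months,
        }
        row.update({net: prof.presence[net] for net in NETWORK_NAMES})
        det_rows.append(row)
    detections = pd.DataFrame(det_rows)
    summary = cohort_network_summary(detections)

    # voxelwise group analysis: visual network SBA maps vs the visual subscale
    t0 = time.time()
    subscale_col = cfg["groupstats"]["subscale"]
    subscale_map = {"crs_r_visual": "visual", "crs_r_auditory": "auditory", "crs_r_motor": "motor"}
    voxelwise = {}
    for net in ("MVIS", "LVIS"):
        stacked = np.array([m[brain_mask] for m in sba_fused[net]])
        scores = np.array(
            [r.subscale_scores[subscale_map.get(subscale_col, "visual")] for r in patient_records],
            dtype=float,
        )
        try:
            voxelwise[net] = voxelwise_perm_correlation(
                stacked,
                scores,
                int(cfg["groupstats"]["n_permutations"]),
                seeds["groupstats"],
                exclusion_ratings=np.array(sba_ratings[net]),
                score_name=subscale_col,
            )
        except ValueError as exc:
            manifest.warnings.append(f"voxelwise analysis skipped for {net}: {exc}")
    manifest.stage_seconds["groupstats"] = round(time.time() - t0, 2)

    # classification (VS/UWS vs MCS only)
    t0 = time.time()
    cls_idx = [i for i, r in enumerate(patient_records) if r.diagnosis in ("VS/UWS", "MCS")]
    cls_profiles = [profiles[i] for i in cls_idx]
    cls_records = [patient_records[i] for i in cls_idx]
    tables = build_feature_models(cls_profiles, cls_records, model, scope="all4")
    results = {}
    for mid in cfg["classify"]["models"]:
        results[mid] = evaluate_cv(
            tables[mid],
            rng_seed=seeds["classify"],
            cv=cfg["classify"]["cv"],
            n_boot=int(cfg["classify"]["n_boot"]),
        )
    manifest.stage_seconds["classify"] = round(time.time() - t0, 2)

    manifest.result_hashes = {
        "detections": hashlib.sha256(
            detections.to_csv(sep="\t", index=False).encode()
        ).hexdigest(),
        "profiles_intensity": _sha256(
            np.array(
                [[p.left_intensity_sum[n] + p.right_intensity_sum[n] for n in NETWORK_NAMES] for p in profiles]
            )
        ),
        **{
            f"voxelwise_rho_{net}": _sha256(vr.rho) for net, vr in voxelwise.items()
        },
        **{
            f"classify_{mid}": _sha256(res.probabilities) for mid, res in results.items()
        },
    }

    out = {
        "spec": spec,
        "records": patient_records,
        "profiles": profiles,
        "detections": detections,
        "summary": summary,
        "voxelwise": voxelwise,
        "classification": results,
        "manifest": manifest,
    }
    if cfg.get("out_dir"):
        _write_outputs(Path(cfg["out_dir"]), out)
    return out


def _write_outputs(out_dir: Path, results: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    results["detections"].to_csv(out_dir / "detections.tsv", sep="\t", index=False)
    results["summary"]["table"].to_csv(out_dir / "network_summary.tsv", sep="\t", index=False)
    results_table(list(results["classification"].values())).to_csv(
        out_dir / "classification.tsv", sep="\t", index=False
    )
    (out_dir / "manifest.json").write_text(results["manifest"].to_json())


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------


def read_cohort_table(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort TSV/CSV into typed subject records.

    Categorical columns are validated against the diagnosis/etiology
    vocabularies; offending rows are reported by number.  MRI node ratings
    are read from ``mri_<node>`` columns; ground-truth presence (a synthetic-
    data concept) is not represented in the table and defaults to False.
    """
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated subject_id(s): {sorted(set(dup))}")
    records = []
    mri_cols = [c for c in df.columns if c.startswith("mri_")]
    for i, row in df.iterrows():
        if row["diagnosis"] not in DIAGNOSES:
            raise ValueError(f"row {i + 1}: unknown diagnosis {row['diagnosis']!r}")
        if row["etiology"] not in ETIOLOGIES + ("none",):
            raise ValueError(f"row {i + 1}: unknown etiology {row['etiology']!r}")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                diagnosis=row["diagnosis"],
                etiology=row["etiology"],
                age_years=int(row["age_years"]),
                disease_duration_months=float(row["disease_duration_months"]),
                crs_r_total=int(row["crs_r_total"]),
                crs_r_modified=int(row["crs_r_modified"]),
                subscale_scores={
                    "motor": int(row["crs_r_motor"]),
                    "auditory": int(row["crs_r_auditory"]),
                    "visual": int(row["crs_r_visual"]),
                },
                mri_node_ratings={c[len("mri_") :]: float(row[c]) for c in mri_cols},
                ground_truth_presence={n: False for n in NETWORK_NAMES},
            )
        )
    return records


def write_cohort_table(records: list[SubjectRecord], path: str | Path) -> None:
    records_to_table(records).to_csv(path, sep="\t", index=False)
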