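"""Cohort orchestration: extract -> profile -> spatial -> group stats.

A cohort manifest is a CSV with columns participant_id, age_group, sex,
muscle, ff_path, mask_path; each row is processed independently (failures are
recorded and the cohort continues), per-participant artifacts are written as
JSON/CSV, and the pooled tessellation metrics feed the group-inference stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .extraction import GrowthParams, extract_imf
from .groupstats import CohortTable, StatReport, analyze_metric
from .phantom import cohort_specs, generate_phantom
from .profiles import profile_correlation, slice_metrics
from .spatial import delaunay_summary, ripley_analysis
from .volumes import load_volume, mask_to_point_cloud

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["participant_id", "age_group", "sex", "muscle", "ff_path", "mask_path"]
METRICS = ["mean_edge_length", "mean_tet_volume"]


@dataclass
class CohortManifest:
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if len(self.rows) == 0:
            raise ValueError("empty manifest")
        if self.rows.duplicated(["participant_id", "muscle"]).any():
            raise ValueError("duplicate (participant, muscle) rows in manifest")

    @classmethod
    def from_csv(cls, path) -> "CohortManifest":
        return cls(pd.read_csv(path))


@dataclass
class CohortRunResult:
    cohort_table: CohortTable
    reports: dict[str, StatReport]
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def analyze_participant(
    ff, mask, params: GrowthParams, radii=None, n_sims: int = 99, seed: int = 0
) -> dict:
    """Run the full single-participant pipeline and return a JSON-able dict."""
    result = extract_imf(ff, mask, params)
    out: dict = {
        "n_imf_voxels": result.n_imf_voxels,
        "removed_small_clusters": result.removed_small_clusters,
        "skipped_slices": result.skipped_slices,
        "ff_median_per_slice": [s.ff_median for s in result.per_slice],
    }
    profiles = slice_metrics(ff, result)
    out["profiles"] = [
        {
            "slice": p.slice_index,
            "percent_length": p.percent_length,
            "mean_ff_percent": 100.0 * p.mean_ff,
            "ff_pixel_percentage": p.ff_pixel_percentage,
        }
        for p in profiles
    ]
    mff = [p.mean_ff for p in profiles]
    fpp = [p.ff_pixel_percentage for p in profiles]
    try:
        out["pearson_r"] = profile_correlation(mff, fpp)
    except ValueError:
        out["pearson_r"] = None
    cloud = mask_to_point_cloud(result.imf_mask, mask)
    tess = delaunay_summary(cloud)
    out["tessellation"] = {
        "mean_edge_length": tess.mean_edge_length,
        "mean_tet_volume": tess.mean_tet_volume,
        "normalized_mean_edge": tess.normalized_mean_edge,
        "normalized_mean_volume": tess.normalized_mean_volume,
        "n_points": tess.n_points,
        "muscle_volume": tess.muscle_volume,
    }
    if radii is not None:
        rip = ripley_analysis(cloud, radii, n_sims=n_sims, seed=seed)
        out["ripley"] = {
            "radii": list(map(float, rip.radii)),
            "K": list(map(float, rip.K)),
            "L": list(map(float, rip.L)),
            "csr": list(map(float, rip.csr)),
            "max_clustering_distance": rip.max_clustering_distance,
        }
    return out


def run_cohort(
    manifest: CohortManifest,
    params: GrowthParams | None = None,
    out_dir: str | Path | None = None,
    radii=None,
    seed: int = 0,
) -> CohortRunResult:
    """Process every manifest row; pool tessellation metrics; run inference.

    A participant failure is logged and recorded, not fatal. Deterministic
    for fixed seeds and inputs.
    """
    params = params or GrowthParams()
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    failures = []
    for _, row in manifest.rows.iterrows():
        try:
            ff = load_volume(row.ff_path, "ff")
            mask = load_volume(row.mask_path, "mask", muscle_label=row.muscle)
            res = analyze_participant(ff, mask, params, radii, seed=seed)
            if out_dir:
                with open(out_dir / f"{row.participant_id}_{row.muscle}.json", "w") as fh:
                    json.dump(res, fh, indent=1, sort_keys=True)
            for metric in METRICS:
                rows.append({
                    "participant_id": row.participant_id,
                    "age_group": row.age_group,
                    "sex": row.sex,
                    "muscle": row.muscle,
                    "metric_name": metric,
                    "value": res["tessellation"][metric],
                })
        except Exception as exc:  # cohort keeps going on per-participant failure
            logger.error("participant %s / %s failed: %s",
                         row.participant_id, row.muscle, exc)
            failures.append((str(row.participant_id), str(row.muscle), str(exc)))
    if not rows:
        raise ValueError("all participants failed; no cohort table")
    table = CohortTable(pd.DataFrame(rows))
    reports = {}
    for muscle in table.muscles:
        for metric in METRICS:
            try:
                rep = analyze_metric(table, metric, muscle)
                reports[f"{muscle}/{metric}"] = rep
            except Exception as exc:
                logger.error("inference failed for %s/%s: %s", muscle, metric, exc)
    if out_dir:
        table.data.to_csv(out_dir / "cohort_table.csv", index=False)
        with open(out_dir / "stat_reports.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in reports.items()},
                      fh, indent=1, sort_keys=True)
    return CohortRunResult(table, reports, failures)


def simulate_cohort(
    n_young: int = 10,
    n_old: int = 10,
    seed: int = 0,
    params: GrowthParams | None = None,
) -> CohortTable:
    """Phantom cohort: generate, extract and tessellate per participant,
    assigning sex labels at random (age is the only real effect)."""
    params = params or GrowthParams()
    rng = np.random.default_rng(seed)
    # random but balanced sex assignment within each age group, so every
    # age x sex cell is populated and sex carries no real effect
    def random_sexes(n):
        sexes = ["male"] * (n // 2 + n % 2) + ["female"] * (n // 2)
        return list(rng.permutation(sexes))

    sex_labels = random_sexes(n_young) + random_sexes(n_old)
    rows = []
    for i, (age_group, spec) in enumerate(cohort_specs(n_young, n_old, seed)):
        ph = generate_phantom(spec)
        res = extract_imf(ph.ff, ph.muscle, params)
        cloud = mask_to_point_cloud(res.imf_mask, ph.muscle)
        tess = delaunay_summary(cloud)
        sex = sex_labels[i]
        for metric, value in (("mean_edge_length", tess.mean_edge_length),
                              ("mean_tet_volume", tess.mean_tet_volume)):
            rows.append({
                "participant_id": f"P{i:03d}",
                "age_group": age_group,
                "sex": sex,
                "muscle": "phantom",
                "metric_name": metric,
                "value": value,
            })
    return CohortTable(pd.DataFrame(rows))
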