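"""End-to-end orchestration: simulate -> reconstruct -> quantify -> classify -> stats.

A single JSON-serializable :class:`RunConfig` drives a seeded, reproducible
run that persists every intermediate (cohort CSV, per-subject NIfTI volumes,
measures CSV, table analogs) and a flat metrics JSON.  ``skip_recon`` runs
the calibrated measure-level sampler instead of the image chain, for fast
statistical studies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .classification import classify_measure
from .core import VoxelGrid
from .quant import (
    aggregate_hemispheres,
    composite_score,
    n1_volume_smwi,
    nms_contrast_range,
    optimize_threshold,
    select_analysis_slices,
    thresholded_volume,
)
from .smwi import smwi_from_series
from .stats import bonferroni_alpha, chi_square_2x2, kendall_tau_b, mann_whitney, spearman, t_test
from .synthetic import (
    MEASURES,
    CohortSpec,
    _subject_seed,
    cohort_frame,
    generate_cohort,
    head_support,
    render_phantom,
    sample_measures,
    simulate_multiecho_gre,
    write_subject_volumes,
)

ALL_MEASURES = MEASURES + ("composite",)


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pd: int = Field(82, ge=0)
    n_hc: int = Field(107, ge=0)
    degeneration_scale: float = Field(1.0, ge=0.0)
    shared_factor_loading: float = Field(0.3, ge=0.0, le=1.0)
    left_degeneration_offset: float = 0.05


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dims: tuple[int, int, int] = (96, 96, 32)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 1.0)
    slice_axis: int = Field(2, ge=0, le=2)

    def to_grid(self) -> VoxelGrid:
        return VoxelGrid(dims=self.dims, voxel_size=self.voxel_size, slice_axis=self.slice_axis)


class AcquisitionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    te_list: tuple[float, ...] = (13.77, 26.39, 39.0)
    b0: float = Field(3.0, gt=0)
    n_channels: int = Field(2, ge=1)
    noise_sd: float = Field(0.01, ge=0)

    @field_validator("te_list")
    @classmethod
    def _te_increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) == 0 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("acquisition.te_list must be nonempty and strictly increasing")
        return v


class ReconConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    delta: float = 0.1
    n_iter: int = Field(30, ge=0)
    smv_radius_mm: float = Field(2.0, gt=0)

    @field_validator("delta")
    @classmethod
    def _delta_range(cls, v: float) -> float:
        if not 0.0 < v < 1.0 / 3.0:
            raise ValueError("recon.delta must lie in (0, 1/3)")
        return v


class SmwiConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chi_threshold: float = Field(150.0, gt=0)
    power: int = Field(4, ge=1)


class QuantConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    qsm_threshold: Literal["auto"] | float = "auto"
    nms_threshold: Literal["auto"] | float = "auto"
    n_threshold_grid: int = Field(25, ge=2)
    rn_fraction: float = Field(0.1, gt=0, lt=1)
    rel_threshold: float = Field(0.7, gt=0)


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(0.05, gt=0, lt=1)
    m_override: int | None = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cohort: CohortConfig = CohortConfig()
    grid: GridConfig = GridConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    recon: ReconConfig = ReconConfig()
    smwi: SmwiConfig = SmwiConfig()
    quant: QuantConfig = QuantConfig()
    stats: StatsConfig = StatsConfig()
    output_dir: str = "nigra_run"
    seed: int = 0
    skip_recon: bool = True
    save_volumes: bool = False


def validate_config(document: str | dict) -> RunConfig:
    """Parse and validate a JSON run configuration; defaults fill gaps."""
    if isinstance(document, str):
        document = json.loads(document)
    return RunConfig.model_validate(document)


@dataclass
class RunReport:
    tables: dict[str, Path]
    metrics: dict[str, float]
    provenance: dict = dc_field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str, subject: str | None = None):
        self.stage = stage
        self.subject = subject
        where = f"stage '{stage}'" + (f", subject {subject}" if subject else "")
        super().__init__(f"{where}: {message}")


def _cohort_spec(config: RunConfig) -> CohortSpec:
    c = config.cohort
    return CohortSpec(
        n_pd=c.n_pd, n_hc=c.n_hc, seed=config.seed,
        degeneration_scale=c.degeneration_scale,
        shared_factor_loading=c.shared_factor_loading,
        left_degeneration_offset=c.left_degeneration_offset,
    )


def _image_measures(config: RunConfig, cohort, out_dir: Path) -> pd.DataFrame:
    """Full image chain: phantom -> GRE -> QSM/SMWI -> per-hemisphere measures."""
    grid = config.grid.to_grid()
    acq, rec = config.acquisition, config.recon
    support = head_support(grid)
    per_subject: dict[str, dict] = {}
    for idx, (subject, latent) in enumerate(cohort):
        try:
            chi_true, nms, masks = render_phantom(
                latent, grid, seed=_subject_seed(config.seed, idx, 3)
            )
            series = simulate_multiecho_gre(
                chi_true, grid, te_list_ms=acq.te_list, b0_tesla=acq.b0,
                n_channels=acq.n_channels, noise_sd=acq.noise_sd,
                seed=_subject_seed(config.seed, idx, 4), support=support,
            )
            smwi_vol, chi_map = smwi_from_series(
                series, chi_threshold_ppb=config.smwi.chi_threshold,
                power=config.smwi.power, smv_radius_mm=rec.smv_radius_mm,
                delta=rec.delta, n_iter=rec.n_iter,
            )
            slices = select_analysis_slices(
                masks["RN_L"] | masks["RN_R"], grid, fraction=config.quant.rn_fraction
            )
            per_subject[subject.id] = {
                "group": subject.group, "slices": slices, "masks": masks,
                "chi": chi_map, "nms": nms, "smwi": smwi_vol,
            }
            if config.save_volumes:
                write_subject_volumes(out_dir / "volumes", subject.id, chi_true, nms, masks, series)
        except Exception as exc:  # noqa: BLE001 - stage errors name the subject
            raise StageError("reconstruct", str(exc), subject=subject.id) from exc

    sel_cache = {}

    def region_values(info, image, side):
        sn = info["masks"][f"SN_{side}"]
        axis = grid.slice_axis
        key = info["slices"]
        if key not in sel_cache:
            sel = np.zeros(grid.dims, dtype=bool)
            ix: list = [slice(None)] * 3
            ix[axis] = list(key)
            sel[tuple(ix)] = True
            sel_cache[key] = sel
        return image[sn & sel_cache[key]]

    labels = {sid: info["group"] for sid, info in per_subject.items()}
    thresholds = {}
    for name, direction, img_key in (
        ("qsm", "below", "chi"), ("nms", "above", "nms")
    ):
        configured = getattr(config.quant, f"{name}_threshold")
        if configured == "auto":
            pooled = {
                sid: np.concatenate([
                    region_values(info, info[img_key].values_ppb if img_key == "chi" else info[img_key], s)
                    for s in ("L", "R")
                ])
                for sid, info in per_subject.items()
            }
            all_vals = np.concatenate(list(pooled.values()))
            grid_t = np.quantile(all_vals, np.linspace(0.05, 0.95, config.quant.n_threshold_grid))
            result = optimize_threshold(pooled, labels, grid_t, direction,
                                        voxel_volume_mm3=grid.voxel_volume_mm3)
            thresholds[name] = result.threshold
        else:
            thresholds[name] = float(configured)

    rows = []
    for sid, info in per_subject.items():
        for side in ("L", "R"):
            sn = info["masks"][f"SN_{side}"]
            try:
                qsm_vol = thresholded_volume(info["chi"].values_ppb, sn, info["slices"],
                                             thresholds["qsm"], "below", grid)
                nms_vol = thresholded_volume(info["nms"], sn, info["slices"],
                                             thresholds["nms"], "above", grid)
                ncr = nms_contrast_range(info["nms"], sn, info["slices"], grid)
                n1 = n1_volume_smwi(info["smwi"], sn, info["slices"],
                                    rel_threshold=config.quant.rel_threshold,
                                    brain_mask=info["chi"].mask)
            except Exception as exc:  # noqa: BLE001
                raise StageError("quantify", str(exc), subject=sid) from exc
            rows.append({
                "subject_id": sid, "group": info["group"], "side": side,
                "qsm_based_volume": qsm_vol, "nms_based_volume": nms_vol,
                "nms_contrast_range": ncr, "n1_volume": n1,
            })
    return pd.DataFrame(rows)


def build_table3(measures: pd.DataFrame) -> pd.DataFrame:
    """Classification summary per measure for Left / Right / aggregate scores."""
    rows = []
    for measure in ALL_MEASURES:
        wide = measures.pivot_table(index=["subject_id", "group"], columns="side",
                                    values=measure).reset_index()
        if wide["group"].nunique() < 2:
            raise StageError("classify", "both PD and HC groups required")
        wide["aggregate"] = [
            aggregate_hemispheres(l, r, "mean") for l, r in zip(wide["L"], wide["R"])
        ]
        for side in ("aggregate", "L", "R"):
            s = classify_measure(wide[side].to_numpy(), wide["group"].to_numpy(),
                                 orientation="lower_is_positive")
            rows.append({
                "model": measure, "side": side,
                "auc": round(s.auc, 3), "accuracy_pct": round(s.accuracy_pct, 2),
                "sensitivity_pct": round(s.sensitivity_pct, 2),
                "specificity_pct": round(s.specificity_pct, 2),
                "youden": round(s.youden, 2), "cutoff": s.cutoff,
                "tp": s.counts[0], "fn": s.counts[1], "tn": s.counts[2], "fp": s.counts[3],
            })
    return pd.DataFrame(rows)


def _median_iqr(v: pd.Series) -> str:
    q1, med, q3 = np.percentile(v.dropna(), [25, 50, 75])
    return f"{med:.3f} ({q1:.3f}-{q3:.3f})"


def build_table1(cohort_df: pd.DataFrame, measures: pd.DataFrame) -> pd.DataFrame:
    pd_df = cohort_df[cohort_df.group == "PD"]
    hc_df = cohort_df[cohort_df.group == "HC"]
    rows = []
    if len(pd_df) >= 2 and len(hc_df) >= 2:
        _, p_age = t_test(pd_df.age.to_numpy(), hc_df.age.to_numpy())
        rows.append({"variable": "age", "PD": f"{pd_df.age.mean():.2f} ({pd_df.age.std():.2f})",
                     "HC": f"{hc_df.age.mean():.2f} ({hc_df.age.std():.2f})", "p_value": p_age})
        a, b = (pd_df.sex == "M").sum(), (pd_df.sex == "F").sum()
        c, d = (hc_df.sex == "M").sum(), (hc_df.sex == "F").sum()
        if min(a + b, c + d, a + c, b + d) > 0:
            _, p_sex = chi_square_2x2(a, b, c, d)
            rows.append({"variable": "sex_male", "PD": f"{a} ({100*a/(a+b):.0f}%)",
                         "HC": f"{c} ({100*c/(c+d):.0f}%)", "p_value": p_sex})
        _, p_updrs = mann_whitney(pd_df.updrs3.to_numpy(), hc_df.updrs3.to_numpy())
        rows.append({"variable": "updrs3", "PD": _median_iqr(pd_df.updrs3),
                     "HC": _median_iqr(hc_df.updrs3), "p_value": p_updrs})
    agg = measures.groupby(["subject_id", "group"], as_index=False)[list(MEASURES)].mean()
    for m in MEASURES:
        x = agg.loc[agg.group == "PD", m].to_numpy()
        y = agg.loc[agg.group == "HC", m].to_numpy()
        _, p = mann_whitney(x, y)
        rows.append({"variable": m, "PD": _median_iqr(agg.loc[agg.group == "PD", m]),
                     "HC": _median_iqr(agg.loc[agg.group == "HC", m]), "p_value": p})
    return pd.DataFrame(rows)


def build_table2(measures: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for m in MEASURES:
        for side in ("L", "R"):
            sub = measures[measures.side == side]
            x = sub.loc[sub.group == "PD", m].to_numpy()
            y = sub.loc[sub.group == "HC", m].to_numpy()
            _, p = mann_whitney(x, y)
            rows.append({"measure": m, "side": side,
                         "PD": _median_iqr(sub.loc[sub.group == "PD", m]),
                         "HC": _median_iqr(sub.loc[sub.group == "HC", m]), "p_value": p})
    return pd.DataFrame(rows)


CLINICAL_TESTS = (("updrs3", "spearman"), ("hy_stage", "kendall_tau_b"),
                  ("ledd", "spearman"), ("duration", "spearman"))


def build_table4(cohort_df: pd.DataFrame, measures: pd.DataFrame,
                 alpha: float = 0.05, m_override: int | None = None) -> pd.DataFrame:
    """PD-only per-hemisphere correlations with clinical variables."""
    pd_meas = measures[measures.group == "PD"].merge(
        cohort_df[["id", "updrs3", "hy_stage", "ledd", "duration"]],
        left_on="subject_id", right_on="id",
    )
    cells = []
    for measure in ALL_MEASURES:
        for side in ("L", "R"):
            sub = pd_meas[pd_meas.side == side]
            for clin, method in CLINICAL_TESTS:
                pairs = sub[[measure, clin]].dropna()
                cells.append((measure, side, clin, method, pairs))
    m = m_override if m_override is not None else len(cells)
    alpha_adj = bonferroni_alpha(alpha, m)
    rows = []
    for measure, side, clin, method, pairs in cells:
        try:
            fn = spearman if method == "spearman" else kendall_tau_b
            res = fn(pairs[measure].to_numpy(), pairs[clin].to_numpy(), alpha_adjusted=alpha_adj)
            coeff, p, sig = res.coefficient, res.p_value, res.significant_after_bonferroni
        except ValueError:
            coeff, p, sig = np.nan, np.nan, False
        rows.append({"measure": measure, "side": side, "clinical": clin, "method": method,
                     "coefficient": coeff, "p_value": p, "n": len(pairs),
                     "significant_after_bonferroni": sig})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full seeded pipeline and persist all artifacts."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = _cohort_spec(config)
    try:
        cohort = generate_cohort(spec)
    except ValueError as exc:
        raise StageError("simulate", str(exc)) from exc
    cohort_df = cohort_frame(cohort)
    cohort_df.to_csv(out_dir / "cohort.csv", index=False)

    if config.skip_recon:
        measures = sample_measures(spec, cohort)
    else:
        measures = _image_measures(config, cohort, out_dir)
    measures["composite"] = [
        composite_score(q, n, c) for q, n, c in zip(
            measures.qsm_based_volume, measures.nms_based_volume, measures.nms_contrast_range
        )
    ]
    measures.to_csv(out_dir / "measures.csv", index=False)

    table3 = build_table3(measures)
    table1 = build_table1(cohort_df, measures)
    table2 = build_table2(measures)
    table4 = build_table4(cohort_df, measures, alpha=config.stats.alpha,
                          m_override=config.stats.m_override)
    tables = {}
    for name, df in (("table1", table1), ("table2", table2),
                     ("table3", table3), ("table4", table4)):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        tables[name] = path

    metrics: dict[str, float] = {}
    for _, row in table3.iterrows():
        key = f"{row.model}_{row.side}"
        for col in ("auc", "accuracy_pct", "sensitivity_pct", "specificity_pct", "youden", "cutoff"):
            metrics[f"{key}_{col}"] = float(row[col])
    config_json = config.model_dump_json()
    provenance = {
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump({"metrics": metrics, "provenance": provenance}, fh, indent=2)
    return RunReport(tables=tables, metrics=metrics, provenance=provenance)
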