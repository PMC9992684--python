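"""End-to-end orchestration: simulate -> build maps -> select features ->
train -> predict -> compare -> report.

Every stage draws its randomness from a named sub-stream of one master
seed, so the whole run is bit-reproducible and any stage/region can be
re-run in isolation. With the default atlases (90 GM + 90 FC + 48 FA) a
full run trains exactly 228 region models.
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

from . import __version__
from .age_model import RegionAgeModel, apply_model, train_region_model
from .features import SelectionParams, select_features
from .maps import build_fc_map, parcellate_volume
from .seeding import stream
from .stats import (
    DEFAULT_ANCOVA_COVARIATES,
    DEFAULT_CLINICAL_PREDICTORS,
    ancova_gap,
    clinical_regression,
    cpz_regression,
    fdr_adjust,
)
from .synthetic import (
    Atlas,
    CohortMaps,
    SyntheticConfig,
    assemble_volume,
    generate_bold,
    generate_region_maps,
    generate_subjects,
    inject_pathology,
    make_atlas,
    subjects_to_frame,
)

__all__ = ["PipelineConfig", "ResultBundle", "run_full", "write_report"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


@dataclass
class PipelineConfig:
    """Everything one run needs; one master seed governs all stages."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    selection: SelectionParams = field(default_factory=SelectionParams)
    k_folds: int = 5
    n_restarts: int = 3
    alpha_level: float = 0.05
    fdr_family: str = "modality"        # "modality" | "joint"
    regression_form: str = "joint"      # "joint" | "simple"
    fc_from_bold: bool = False          # build FC maps from synthetic BOLD series
    fc_scope: str = "region"            # "region" | "volume" averaging for FC
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie in (0, 1)")
        if self.fdr_family not in ("modality", "joint"):
            raise ValueError("fdr_family must be 'modality' or 'joint'")
        if self.fc_scope not in ("region", "volume"):
            raise ValueError("fc_scope must be 'region' or 'volume'")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["atlas_spec"] = {
            m: dataclasses.asdict(s) for m, s in self.synthetic.atlas_spec.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .synthetic import ModalitySpec

        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        if "atlas_spec" in syn:
            syn["atlas_spec"] = {m: ModalitySpec(**s) for m, s in syn["atlas_spec"].items()}
        if "age_range" in syn:
            syn["age_range"] = tuple(syn["age_range"])
        if "effect_spec" in syn:
            syn["effect_spec"] = {m: {int(k): float(v) for k, v in spec.items()}
                                  for m, spec in syn["effect_spec"].items()}
        sel = dict(d.pop("selection", {}))
        return cls(synthetic=SyntheticConfig(**syn), selection=SelectionParams(**sel), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """All artifacts of one run.

    ``models`` is empty when a bundle is reloaded from disk; the tables are
    sufficient to regenerate the report byte-for-byte.
    """

    config: PipelineConfig | None
    models: dict[tuple[str, int], RegionAgeModel]
    performance: pd.DataFrame       # modality, region_id, n_features, cv_mae, cv_r, alpha, beta
    estimates: pd.DataFrame         # per subject x region brain-age estimates (test cohorts)
    group_results: pd.DataFrame     # ANCOVA per region
    clinical_results: pd.DataFrame  # clinical regression rows
    cpz_results: pd.DataFrame       # CPZ regression rows
    subjects: pd.DataFrame
    provenance: dict

    _TABLES = ("performance", "estimates", "group_results",
               "clinical_results", "cpz_results", "subjects")

    @property
    def n_models(self) -> int:
        return int(self.provenance.get("n_models", len(self.models)))

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False,
                                       float_format=_FLOAT_FMT)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1, sort_keys=True))
        return out

    @classmethod
    def load(cls, out_dir) -> "ResultBundle":
        out = Path(out_dir)
        missing = [n for n in cls._TABLES if not (out / f"{n}.tsv").exists()]
        if missing or not (out / "provenance.json").exists():
            raise FileNotFoundError(f"incomplete bundle at {out}: missing "
                                    f"{missing + ['provenance.json'] if missing else ['provenance.json']}")
        tables = {n: pd.read_csv(out / f"{n}.tsv", sep="\t") for n in cls._TABLES}
        prov = json.loads((out / "provenance.json").read_text())
        return cls(config=None, models={}, provenance=prov, **tables)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _simulate(config: PipelineConfig):
    syn = config.synthetic
    subjects = generate_subjects(syn, stream(config.seed, "simulate"))
    atlases = {m: make_atlas(m, s.n_regions, s.n_voxels) for m, s in syn.atlas_spec.items()}
    maps: dict[str, CohortMaps] = {}
    for mod, atlas in atlases.items():
        m = generate_region_maps(subjects, atlas, syn, stream(config.seed, "maps", mod))
        eff = syn.effect_spec.get(mod, {})
        if eff:
            m = inject_pathology(m, subjects, eff, syn)
        maps[mod] = m
    return subjects, atlases, maps


def _fc_maps_from_bold(subjects, atlas: Atlas, config: PipelineConfig) -> CohortMaps:
    """Replace direct FC maps by maps built from synthetic BOLD series."""
    syn = config.synthetic
    values = {reg.region_id: np.empty((len(subjects), reg.voxel_indices.size))
              for reg in atlas.regions}
    for i, subj in enumerate(subjects):
        series, _ = generate_bold([subj], atlas, syn,
                                  stream(config.seed, "bold", subj.subject_id))
        ts = series[subj.subject_id]
        if config.fc_scope == "volume":
            fc = build_fc_map(ts)
            offset = 0
            for reg in atlas.regions:
                values[reg.region_id][i] = fc[offset:offset + reg.voxel_indices.size]
                offset += reg.voxel_indices.size
        else:
            offset = 0
            for reg in atlas.regions:
                k = reg.voxel_indices.size
                values[reg.region_id][i] = build_fc_map(ts[offset:offset + k])
                offset += k
    return CohortMaps(modality=atlas.modality,
                      subject_ids=[s.subject_id for s in subjects],
                      values=values,
                      informative={r.region_id: np.array([], dtype=int) for r in atlas.regions})


def _rebuild_via_parcellation(maps: CohortMaps, atlas: Atlas) -> CohortMaps:
    """Exercise the map-building path: assemble each subject's volume and
    parcellate it back into region matrices."""
    out = {rid: np.empty_like(v) for rid, v in maps.values.items()}
    for i, sid in enumerate(maps.subject_ids):
        vol = assemble_volume({rid: maps.values[rid][i] for rid in maps.values}, atlas)
        for rm in parcellate_volume(vol, atlas, subject_id=sid):
            out[rm.region_id][i] = rm.values
    return CohortMaps(modality=maps.modality, subject_ids=list(maps.subject_ids),
                      values=out, informative=maps.informative)


def run_full(config: PipelineConfig | None = None, out_dir=None) -> ResultBundle:
    """Execute the whole pipeline and return (optionally persist) the bundle."""
    config = config if config is not None else PipelineConfig()
    syn = config.synthetic
    subjects, atlases, maps = _simulate(config)
    logger.info("simulated %d subjects, %d atlas regions total",
                len(subjects), sum(len(a.regions) for a in atlases.values()))

    if config.fc_from_bold and "FC" in atlases:
        maps["FC"] = _fc_maps_from_bold(subjects, atlases["FC"], config)

    # build-maps stage: volumes -> parcellation -> region matrices
    maps = {mod: _rebuild_via_parcellation(m, atlases[mod]) for mod, m in maps.items()}

    is_train = np.array([s.subject_id.startswith("TRN") for s in subjects])
    is_test = ~is_train
    ages = np.array([s.chronological_age for s in subjects])
    train_ages = ages[is_train]
    test_subjects = [s for s, t in zip(subjects, is_test) if t]
    test_ids = [s.subject_id for s in test_subjects]
    test_frame = subjects_to_frame(test_subjects)
    both_groups = 0 < sum(s.group == "SCZ" for s in test_subjects) < len(test_subjects)

    models: dict[tuple[str, int], RegionAgeModel] = {}
    perf_rows, est_frames, group_rows = [], [], []
    for mod, atlas in atlases.items():
        for reg in atlas.regions:
            rid = reg.region_id
            vals = maps[mod].values[rid]
            mask = select_features(vals[is_train], train_ages, config.selection,
                                   stream(config.seed, "select", mod, rid),
                                   modality=mod, region_id=rid)
            model = train_region_model(
                vals[is_train], train_ages, modality=mod, region_id=rid, mask=mask,
                k_folds=config.k_folds, n_restarts=config.n_restarts,
                rng=stream(config.seed, "train", mod, rid))
            models[(mod, rid)] = model
            perf_rows.append({
                "modality": mod, "region_id": rid,
                "n_features": int(mask.feature_voxels.size),
                "cv_mae": model.cv_mae, "cv_r": model.cv_r, "cv_raw_r": model.cv_raw_r,
                "alpha": model.alpha, "beta": model.beta,
            })
            est = apply_model(model, vals[is_test], test_ids, ages[is_test])
            est_frames.append(est)
            if both_groups:
                res = ancova_gap(est["brain_age_gap"].to_numpy(), test_frame,
                                 DEFAULT_ANCOVA_COVARIATES, modality=mod, region_id=rid)
                group_rows.append(res)
            logger.info("%s region %d: %d features, cv_mae=%.2f, cv_r=%.3f",
                        mod, rid, mask.feature_voxels.size, model.cv_mae, model.cv_r)

    performance = pd.DataFrame(perf_rows)
    estimates = pd.concat(est_frames, ignore_index=True)

    group_cols = ["modality", "region_id", "f_stat", "p_value", "partial_eta_sq",
                  "hc_mean_gap", "scz_mean_gap", "n_hc", "n_scz"]
    group = pd.DataFrame([{
        "modality": r.modality, "region_id": r.region_id, "f_stat": r.f_stat,
        "p_value": r.p_value, "partial_eta_sq": r.partial_eta_sq,
        "hc_mean_gap": r.group_means[0], "scz_mean_gap": r.group_means[1],
        "n_hc": r.n_per_group[0], "n_scz": r.n_per_group[1],
    } for r in group_rows], columns=group_cols)
    group["p_adjusted"] = (_family_fdr(group, config.fdr_family)
                           if len(group) else pd.Series(dtype=float))

    clinical, cpz = _run_regressions(estimates, test_frame, config)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_models": len(models),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "alpha_level": config.alpha_level,
        "fdr_family": config.fdr_family,
    }
    bundle = ResultBundle(config=config, models=models, performance=performance,
                          estimates=estimates, group_results=group,
                          clinical_results=clinical, cpz_results=cpz,
                          subjects=subjects_to_frame(subjects), provenance=provenance)
    expected = sum(len(a.regions) for a in atlases.values())
    if len(models) != expected:
        raise RuntimeError(f"model count {len(models)} != region total {expected}")
    if out_dir is not None:
        bundle.save(out_dir)
    return bundle


def _family_fdr(group: pd.DataFrame, family: str) -> np.ndarray:
    adj = np.empty(len(group))
    if family == "joint":
        adj[:] = fdr_adjust(group["p_value"].to_numpy())
    else:
        for mod in group["modality"].unique():
            sel = (group["modality"] == mod).to_numpy()
            adj[sel] = fdr_adjust(group.loc[sel, "p_value"].to_numpy())
    return adj


def _run_regressions(estimates: pd.DataFrame, test_frame: pd.DataFrame,
                     config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical and dose regressions per region (patients only), FDR per
    predictor across regions within each modality."""
    scz_frame = test_frame[test_frame["group"] == "SCZ"].reset_index(drop=True)
    clin_rows, cpz_rows = [], []
    if len(scz_frame) > len(DEFAULT_CLINICAL_PREDICTORS) + 3:
        gap_tab = estimates.pivot_table(index="subject_id", columns=["modality", "region_id"],
                                        values="brain_age_gap")
        gap_tab = gap_tab.loc[scz_frame["subject_id"]]
        for mod, rid in gap_tab.columns:
            gaps = gap_tab[(mod, rid)].to_numpy()
            try:
                for r in clinical_regression(gaps, scz_frame, modality=mod, region_id=rid):
                    clin_rows.append(r)
            except ValueError as exc:
                logger.warning("clinical regression skipped for %s region %d: %s", mod, rid, exc)
            try:
                cpz_rows.append(cpz_regression(gaps, scz_frame, modality=mod, region_id=rid))
            except ValueError as exc:
                logger.warning("cpz regression skipped for %s region %d: %s", mod, rid, exc)

    def to_frame(rows):
        return pd.DataFrame([{
            "modality": r.modality, "region_id": r.region_id, "predictor": r.predictor,
            "beta": r.beta, "t_stat": r.t_stat, "p_value": r.p_value, "n": r.n,
        } for r in rows], columns=["modality", "region_id", "predictor",
                                   "beta", "t_stat", "p_value", "n"])

    clinical = to_frame(clin_rows)
    cpz = to_frame([r for r in cpz_rows])
    for frame in (clinical, cpz):
        if len(frame):
            adj = np.empty(len(frame))
            for (mod, pred), grp in frame.groupby(["modality", "predictor"]):
                adj[grp.index.to_numpy()] = fdr_adjust(grp["p_value"].to_numpy())
            frame["p_adjusted"] = adj
        else:
            frame["p_adjusted"] = pd.Series(dtype=float)
    return clinical, cpz


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def write_report(bundle: ResultBundle, out_dir) -> Path:
    """Emit summary tables: per-region performance, significant regions
    (sorted by descending partial eta-squared, ties by region id) and the
    clinical/dose regression tables, as TSV plus a JSON summary."""
    missing = [n for n in ResultBundle._TABLES
               if not isinstance(getattr(bundle, n, None), pd.DataFrame)]
    if missing:
        raise ValueError(f"incomplete bundle; missing tables: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alpha = float(bundle.provenance.get("alpha_level", 0.05))

    def rounded(df: pd.DataFrame) -> pd.DataFrame:
        # 6-decimal values throughout so a report regenerated from a
        # persisted (6-decimal TSV) bundle is byte-identical
        out_df = df.copy()
        for c in out_df.columns:
            if out_df[c].dtype.kind == "f":
                out_df[c] = out_df[c].round(6)
        return out_df

    perf = rounded(bundle.performance).sort_values(
        ["modality", "region_id"]).reset_index(drop=True)
    perf.to_csv(out / "performance.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    grp = rounded(bundle.group_results)
    sig = grp[grp["p_adjusted"] < alpha].sort_values(
        ["partial_eta_sq", "region_id"], ascending=[False, True])
    sig.to_csv(out / "significant_regions.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    for name, src in (("clinical_regressions.tsv", rounded(bundle.clinical_results)),
                      ("cpz_regressions.tsv", rounded(bundle.cpz_results))):
        src.sort_values(["modality", "region_id", "predictor"]
                        if "predictor" in src.columns else ["modality", "region_id"]).to_csv(
            out / name, sep="\t", index=False, float_format=_FLOAT_FMT)

    summary = {
        "n_models": bundle.n_models,
        "n_significant_regions": int(len(sig)),
        "significant_by_modality": {
            m: int((sig["modality"] == m).sum()) for m in perf["modality"].unique()},
        "mean_cv_mae_by_modality": {
            m: round(float(perf.loc[perf["modality"] == m, "cv_mae"].mean()), 6)
            for m in sorted(perf["modality"].unique())},
        "mean_cv_r_by_modality": {
            m: round(float(perf.loc[perf["modality"] == m, "cv_r"].mean()), 6)
            for m in sorted(perf["modality"].unique())},
        "provenance": bundle.provenance,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return out
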