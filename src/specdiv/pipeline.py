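"""Configuration-driven orchestration of the full analysis.

Stage order: synth -> spectral -> classify -> grid -> model -> community ->
traits -> darkdiv.  Every stage writes plain CSV/JSON/NPY artifacts into the
output directory and registers them (with SHA-256 checksums) in a run
manifest; all randomness derives from the config seed, so reruns with the
same config reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import community as comm
from . import darkdiv as dd
from . import functional as fn
from . import gridding as gr
from . import scglr as sc
from . import spectral as sp
from . import synthgen as sg

logger = logging.getLogger(__name__)

STAGES = ("synth", "spectral", "classify", "grid", "model", "community", "traits", "darkdiv")


@dataclass
class RunConfig:
    """Every stage parameter and seed of a pipeline run."""

    out_dir: str = "runs/demo"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    # synth
    n_species: int = 20
    n_pas: int = 4
    pa_specific_fraction: float = 0.3
    cells_per_pa: tuple[int, int] = (2, 2)
    scene_px: tuple[int, int] = (250, 250)
    noise_sd: float = 0.002
    brightness_range: tuple[float, float] = (0.85, 1.15)
    forest_fraction: float = 0.75
    climate_noise_sd: float = 0.05
    n_quadrats: int = 40

    # spectral / classify
    ndvi_threshold_dry: float = 0.4
    ndvi_threshold_wet: float = 0.6
    mnf_snr_threshold: float = 2.0
    mnf_max_components: int = 20
    train_fraction: float = 0.75
    max_train_per_class: int = 1200
    smote_k: int = 5
    rf_mtry_grid: list[int] | None = None
    rf_ntree_grid: list[int] = field(default_factory=lambda: [200])
    classification_map_paths: dict[str, str] | None = None

    # grid
    n_plots: int = 3
    min_forest_fraction: float = 0.70

    # model
    scglr_k: int = 3
    scglr_s: float = 0.5
    scglr_l: float = 1.0
    n_blocks: int = 23

    # community
    n_types: int = 4
    n_ca_axes: int = 5
    n_boot: int = 50

    # darkdiv
    dd_quantile: float = 0.05
    dd_min_richness: int = 5

    def to_yaml(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.cells_per_pa = tuple(cfg.cells_per_pa)
        cfg.scene_px = tuple(cfg.scene_px)
        cfg.brightness_range = tuple(cfg.brightness_range)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def add(self, stage: str, outdir: Path, files: list[str], elapsed: float,
            warnings: list[str] | None = None) -> None:
        self.stages[stage] = {
            "files": {f: _sha256(outdir / f) for f in files},
            "elapsed_s": round(elapsed, 3),
            "warnings": warnings or [],
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config_hash": self.config_hash, "version": self.version, "stages": self.stages},
            indent=2, sort_keys=True,
        ))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _ndvi_threshold(cfg: RunConfig, pa: int) -> float:
    return cfg.ndvi_threshold_dry if pa < cfg.n_pas / 2 else cfg.ndvi_threshold_wet


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> RunManifest:
    """Execute the configured stages in dependency order.

    ``stop_after`` truncates the stage list.  A stage failure aborts the run
    with the stage name; artifacts of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = RunManifest(config_hash=config.config_hash(), version=_package_version())

    stages = [s for s in STAGES if s in config.stages]
    if stop_after is not None:
        if stop_after not in STAGES:
            raise ValueError(f"unknown stage {stop_after!r}")
        stages = stages[: stages.index(stop_after) + 1] if stop_after in stages else stages

    state: dict = {}
    for stage in stages:
        t0 = time.perf_counter()
        logger.info("stage %s: start (seed=%d)", stage, config.seed)
        try:
            files = _STAGE_FUNCS[stage](config, out, state)
        except Exception:
            logger.error("stage %s failed; partial artifacts retained in %s", stage, out)
            raise
        elapsed = time.perf_counter() - t0
        manifest.add(stage, out, files, elapsed)
        logger.info("stage %s: done in %.1fs", stage, elapsed)
        manifest.write(out / "manifest.json")
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_synth(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    pool = sg.generate_species_pool(
        cfg.n_species, cfg.n_pas, cfg.pa_specific_fraction, seed=cfg.seed
    )
    grids = sg.generate_climate_grids(
        cfg.n_pas, cells_per_pa=cfg.cells_per_pa, noise_sd=cfg.climate_noise_sd,
        seed=cfg.seed + 1,
    )
    state["pool"], state["grids"] = pool, grids

    scenes, surveys = {}, {}
    for p, pa_id in enumerate(grids.pa_ids):
        scene = sg.generate_scene(
            pool, grids, p, size=cfg.scene_px, noise_sd=cfg.noise_sd,
            brightness_range=cfg.brightness_range, forest_fraction=cfg.forest_fraction,
            seed=cfg.seed + 100 + p,
        )
        scenes[pa_id] = scene
        surveys[pa_id] = sg.generate_field_survey(
            scene, cfg.n_quadrats, seed=cfg.seed + 200 + p
        )
    state["scenes"], state["surveys"] = scenes, surveys

    files = []
    pool_df = pd.DataFrame(
        {
            "species": pool.species_ids,
            "phenology": pool.phenology,
            "wood_density": pool.wood_density,
            "mean_canopy_spread": pool.mean_canopy_spread,
            **{f"in_{pa}": pool.membership[:, i] for i, pa in enumerate(grids.pa_ids)},
        }
    )
    pool_df.to_csv(out / "species_pool.csv", index=False)
    files.append("species_pool.csv")

    clim = pd.DataFrame(
        grids.covariate_array().reshape(-1, 6), columns=list(sg.CLIMATE_COVARIATES)
    )
    clim["elevation"] = grids.elevation.ravel()
    clim["soil"] = grids.soil.ravel()
    clim["pa_id"] = [grids.pa_ids[i] for i in grids.pa_index.ravel()]
    clim.to_csv(out / "climate_grid.csv", index=False)
    files.append("climate_grid.csv")

    for pa_id, scene in scenes.items():
        np.save(out / f"truth_{pa_id}.npy", scene.truth_map)
        files.append(f"truth_{pa_id}.npy")
        recs = [
            {"quadrat": qi, "species": r.species_id, "dbh_m": r.dbh_m,
             "height_m": r.height_m, "canopy_spread_m": r.canopy_spread_m}
            for qi, q in enumerate(surveys[pa_id].quadrats) for r in q.records
        ]
        pd.DataFrame(recs, columns=["quadrat", "species", "dbh_m", "height_m",
                                    "canopy_spread_m"]).to_csv(
            out / f"survey_{pa_id}.csv", index=False)
        files.append(f"survey_{pa_id}.csv")
    return files


def _stage_spectral(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    scenes = state["scenes"]
    band_info = {}
    state["features"], state["masks"], state["mnf"], state["indices"] = {}, {}, {}, {}
    for p, (pa_id, scene) in enumerate(scenes.items()):
        cube = scene.cube
        usable = sp.select_usable_bands(cube)
        cls_bands = sp.select_classification_bands(usable, cube)
        mask = sp.compute_ndvi_mask(cube, _ndvi_threshold(cfg, p))
        stack = np.moveaxis(cube.reflectance[cls_bands.indices], 0, -1).astype(float)
        flat = stack.reshape(-1, stack.shape[-1])
        normed = sp.brightness_normalize(flat).reshape(stack.shape)
        mnf = sp.fit_mnf(normed, mask=mask)
        n_comp = min(mnf.n_components_above(cfg.mnf_snr_threshold), cfg.mnf_max_components)
        scores = mnf.transform(normed.reshape(-1, normed.shape[-1]), n_comp)
        state["features"][pa_id] = scores.reshape(stack.shape[0], stack.shape[1], n_comp)
        state["masks"][pa_id] = mask
        state["mnf"][pa_id] = mnf
        state["indices"][pa_id] = sp.compute_indices(cube)
        band_info[pa_id] = {
            "n_usable": len(usable),
            "n_classification": len(cls_bands),
            "n_mnf_components": int(n_comp),
            "ndvi_threshold": _ndvi_threshold(cfg, p),
            "forest_pixels": int(mask.sum()),
        }
    (out / "band_selection.json").write_text(json.dumps(band_info, indent=2, sort_keys=True))
    eig = pd.DataFrame({pa: state["mnf"][pa].eigenvalues for pa in scenes})
    eig.to_csv(out / "mnf_eigenvalues.csv", index=False)
    return ["band_selection.json", "mnf_eigenvalues.csv"]


def _stage_classify(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    files = []
    state["maps"], state["reports"] = {}, {}
    if cfg.classification_map_paths:
        for pa_id, path in cfg.classification_map_paths.items():
            data = np.load(path, allow_pickle=True)
            legend = json.loads(str(data["legend_json"]))
            state["maps"][pa_id] = clf.ClassificationMap(
                labels=data["labels"], mask=data["mask"].astype(bool),
                legend={int(k): v for k, v in legend.items()},
            )
        logger.info("classify stage skipped: %d maps loaded from disk", len(state["maps"]))
        return files

    accuracy_rows = []
    for p, (pa_id, scene) in enumerate(state["scenes"].items()):
        feats = state["features"][pa_id]
        mask = state["masks"][pa_id]
        ts = clf.extract_training_spectra(feats, mask, scene.crowns, truth_map=scene.truth_map)
        ts = clf.pool_rare_classes(ts)
        ts = clf.split_train_test(ts, cfg.train_fraction, seed=cfg.seed + 300 + p)
        xtr, ytr = ts.subset("train")
        xte, yte = ts.subset("test")
        xtr, ytr = clf.subsample_per_class(
            xtr, ytr, cfg.max_train_per_class, seed=cfg.seed + 350 + p
        )
        xb, yb = clf.smote_balance(xtr, ytr, k_neighbors=cfg.smote_k, seed=cfg.seed + 400 + p)
        forest = clf.train_rf(xb, yb, cfg.rf_mtry_grid, cfg.rf_ntree_grid,
                              seed=cfg.seed + 500 + p)
        legend = {i: str(c) for i, c in enumerate(forest.classes_)}
        cmap = clf.predict_map(forest, feats, mask, legend=legend)
        report = clf.assess_accuracy(yte, forest.predict(xte), oob_error=forest.oob_error)
        state["maps"][pa_id] = cmap
        state["reports"][pa_id] = report

        np.savez(out / f"classmap_{pa_id}.npz", labels=cmap.labels, mask=cmap.mask,
                 legend_json=json.dumps(legend, sort_keys=True))
        report.matrix.to_csv(out / f"confusion_{pa_id}.csv")
        files += [f"classmap_{pa_id}.npz", f"confusion_{pa_id}.csv"]
        accuracy_rows.append(
            {"pa_id": pa_id, "overall_accuracy_pct": report.overall_accuracy,
             "kappa": report.kappa, "oob_error_pct": report.oob_error,
             "mtry": forest.mtry, "ntree": forest.ntree}
        )
    pd.DataFrame(accuracy_rows).to_csv(out / "accuracy.csv", index=False)
    files.append("accuracy.csv")
    return files


def _canopy_spread_by_code(legend: dict[int, str], pool: sg.SpeciesPool) -> dict[int, float]:
    name_to_spread = dict(zip(pool.species_ids, pool.mean_canopy_spread))
    pooled = float(np.mean(pool.mean_canopy_spread))
    return {code: name_to_spread.get(name, pooled) for code, name in legend.items()}


def _stage_grid(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    pool, grids = state["pool"], state["grids"]
    matrices, excluded_all, cells_by_pa = [], [], {}
    for p, (pa_id, cmap) in enumerate(state["maps"].items()):
        spread = _canopy_spread_by_code(cmap.legend, pool)
        rsl, csl = grids.pa_block(p)
        am, cells, excluded = gr.build_abundance_matrix(
            cmap, grids, (rsl.start, csl.start), spread, pa_id=pa_id,
            n_plots=cfg.n_plots, min_forest_fraction=cfg.min_forest_fraction,
            seed=cfg.seed + 600 + p,
        )
        matrices.append(am)
        cells_by_pa[pa_id] = cells
        excluded_all += [(pa_id, e) for e in excluded]
    am = gr.concat_abundance(matrices)
    state["abundance"], state["cells_by_pa"] = am, cells_by_pa
    am.to_frame().to_csv(out / "abundance.csv")
    pd.DataFrame(excluded_all, columns=["pa_id", "cell_id"]).to_csv(
        out / "excluded_cells.csv", index=False)
    return ["abundance.csv", "excluded_cells.csv"]


def _stage_model(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    am: gr.AbundanceMatrix = state["abundance"]
    X = am.covariates[list(sg.CLIMATE_COVARIATES)]
    extra = am.covariates[["elevation", "soil"]]
    Y = am.counts
    model = sc.fit_scglr(X, Y, extra, K=cfg.scglr_k, s=cfg.scglr_s, l=cfg.scglr_l,
                         seed=cfg.seed)
    state["model"] = model

    blocks = sc.make_spatial_blocks(am.coords[["x", "y"]].to_numpy(),
                                    min(cfg.n_blocks, len(am.counts)))
    cv = sc.cross_validate(X, Y, extra, blocks, K=cfg.scglr_k, s=cfg.scglr_s,
                           l=cfg.scglr_l, seed=cfg.seed)
    state["cv"], state["blocks"] = cv, blocks

    inertia = sc.component_inertia(model)
    pd.DataFrame({"share_pct": inertia.share, "cumulative_pct": inertia.cumulative}).to_csv(
        out / "component_inertia.csv", index=False)
    cv.species_rho.rename("rho").to_csv(out / "cv_species_rho.csv")
    payload = {
        "x_names": model.x_names,
        "x_mean": model.x_mean.tolist(),
        "x_sd": model.x_sd.tolist(),
        "extra_names": model.extra_names,
        "loadings": model.loadings.tolist(),
        "coefs": {sp_: model.coefs.loc[sp_].to_dict() for sp_ in model.species},
        "config": {"K": model.K, "s": model.s, "l": model.l},
        "median_rho_cv": cv.median_rho,
    }
    (out / "scglr_model.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return ["component_inertia.csv", "cv_species_rho.csv", "scglr_model.json"]


def _stage_community(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    am: gr.AbundanceMatrix = state["abundance"]
    model: sc.SCGLRModel = state["model"]
    X = am.covariates[list(sg.CLIMATE_COVARIATES)]
    extra = am.covariates[["elevation", "soil"]]
    predicted = sc.predict_abundance(model, X, extra)
    predicted.index = am.counts.index

    ca = comm.correspondence_analysis(am.counts)
    pred_scores = comm.project_rows(ca, predicted)
    typing = comm.assemblage_types(pred_scores, k=cfg.n_types, n_axes=cfg.n_ca_axes,
                                   n_boot=cfg.n_boot, seed=cfg.seed)
    state["ca"], state["typing"], state["predicted"] = ca, typing, predicted

    ca.row_scores.to_csv(out / "ca_row_scores.csv")
    pd.DataFrame({"inertia": ca.axis_inertia,
                  "share_pct": ca.axis_inertia / ca.total_inertia * 100.0}).to_csv(
        out / "ca_inertia.csv", index=False)
    typ = pd.DataFrame({"type": typing.labels, "uncertainty": typing.uncertainty,
                        "pa_id": am.pa_id})
    typ.to_csv(out / "assemblage_types.csv")

    sims = []
    for t1 in sorted(typing.labels.unique()):
        for t2 in sorted(typing.labels.unique()):
            if t2 <= t1:
                continue
            s = comm.type_similarity(
                typing.labels.index[typing.labels == t1],
                typing.labels.index[typing.labels == t2],
                am.counts,
            )
            sims.append({"type_a": int(t1), "type_b": int(t2), "similarity_pct": s})
    pd.DataFrame(sims, columns=["type_a", "type_b", "similarity_pct"]).to_csv(
        out / "type_similarity.csv", index=False)
    return ["ca_row_scores.csv", "ca_inertia.csv", "assemblage_types.csv",
            "type_similarity.csv"]


def _stage_traits(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    pool = state["pool"]
    index_means = {
        pa: fn.species_index_means(scene, state["indices"][pa])
        for pa, scene in state["scenes"].items()
    }
    traits = fn.build_trait_table(pool, state["surveys"], index_means)
    # pooled "others" class takes pool-average traits
    others = [c for c in state["abundance"].counts.columns if c not in traits.index]
    for name in others:
        traits.loc[name] = traits.mean(numeric_only=True)
    state["traits"] = traits

    am = state["abundance"]
    cwm_obs = fn.cwm_table(am.counts, traits)
    cwm_pred = fn.cwm_table(state["predicted"].round().astype(int), traits)
    fd_bio = fn.fd_table(am.counts, traits, fn.BIOPHYSICAL_TRAITS)
    fd_chem = fn.fd_table(am.counts, traits, fn.BIOCHEMICAL_TRAITS)
    state["cwm_obs"], state["cwm_pred"] = cwm_obs, cwm_pred

    traits.to_csv(out / "trait_table.csv")
    cwm_obs.to_csv(out / "cwm_observed.csv")
    cwm_pred.to_csv(out / "cwm_predicted.csv")
    fd = fd_bio.add_suffix("_biophysical").join(fd_chem.add_suffix("_biochemical"))
    fd.to_csv(out / "functional_diversity.csv")
    summary_pa = fn.summarize_fd(fd_bio, am.pa_id)
    summary_type = fn.summarize_fd(fd_bio, state["typing"].labels)
    pd.concat({"by_pa": summary_pa, "by_type": summary_type}).to_csv(out / "fd_summary.csv")
    return ["trait_table.csv", "cwm_observed.csv", "cwm_predicted.csv",
            "functional_diversity.csv", "fd_summary.csv"]


def _stage_darkdiv(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    plots, plot_ids, regions = [], [], []
    for p, (pa_id, cells) in enumerate(state["cells_by_pa"].items()):
        legend = state["maps"][pa_id].legend
        for cell in cells:
            for i, plot in enumerate(cell.plots):
                plots.append({legend.get(c, str(c)): n for c, n in plot.abundance.items()})
                plot_ids.append(f"{cell.cell_id}_p{i}")
                regions.append("drier" if p < cfg.n_pas / 2 else "wetter")
    species = sorted({s for ab in plots for s, n in ab.items() if n > 0})
    X = pd.DataFrame(
        [[1 if ab.get(s, 0) > 0 else 0 for s in species] for ab in plots],
        index=plot_ids, columns=species,
    )
    b = dd.beals_matrix(X)
    th = dd.species_thresholds(b, X, q=cfg.dd_quantile)
    member = dd.dark_diversity(X, b, th, min_richness=cfg.dd_min_richness)
    report = dd.dd_summaries(member, X, min_richness=cfg.dd_min_richness,
                             regions=pd.Series(regions, index=X.index))
    state["dd_report"] = report

    X.to_csv(out / "presence.csv")
    b.to_csv(out / "beals.csv")
    th.rename("threshold").to_csv(out / "dd_thresholds.csv")
    member.astype(int).to_csv(out / "dd_membership.csv")
    (out / "dd_report.json").write_text(json.dumps(
        {
            "mean_dd_per_plot": report.mean_dd_per_plot,
            "n_eligible_plots": int(report.eligible.sum()),
            "frequent_species": report.frequent_species,
            "per_region_plots_with_dd": (
                report.per_region_counts.to_dict() if report.per_region_counts is not None else {}
            ),
        },
        indent=2, sort_keys=True,
    ))
    return ["presence.csv", "beals.csv", "dd_thresholds.csv", "dd_membership.csv",
            "dd_report.json"]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "spectral": _stage_spectral,
    "classify": _stage_classify,
    "grid": _stage_grid,
    "model": _stage_model,
    "community": _stage_community,
    "traits": _stage_traits,
    "darkdiv": _stage_darkdiv,
}


# ---------------------------------------------------------------------------
# output validation
# ---------------------------------------------------------------------------


def validate_outputs(artifact_dir: str | Path) -> dict:
    """Schema and invariant checks over a run directory.

    Returns ``{"ok": bool, "checks": {file: {"status": pass|fail|missing,
    "detail": str}}}``; missing files are reported but non-fatal to the
    checker itself.
    """
    out = Path(artifact_dir)
    checks: dict[str, dict] = {}

    def record(name: str, fn) -> None:
        path = out / name
        if not path.exists():
            checks[name] = {"status": "missing", "detail": "file not found"}
            return
        try:
            fn(path)
            checks[name] = {"status": "pass", "detail": ""}
        except Exception as e:  # noqa: BLE001 - report, don't raise
            checks[name] = {"status": "fail", "detail": str(e)}

    def _check_abundance(path: Path) -> None:
        df = pd.read_csv(path, index_col=0)
        meta = {"pa_id", "x", "y", "lon", "lat", "elevation", "soil",
                *sg.CLIMATE_COVARIATES}
        sp_cols = [c for c in df.columns if c not in meta]
        counts = df[sp_cols]
        if (counts < 0).any().any():
            raise ValueError("negative abundance count")
        if not np.allclose(counts, counts.round()):
            raise ValueError("non-integer abundance")
        if (counts.sum(axis=1) <= 0).any():
            raise ValueError("retained cell with zero total abundance")
        if df[list(sg.CLIMATE_COVARIATES)].isna().any().any():
            raise ValueError("missing covariates on retained cells")

    def _check_beals(path: Path) -> None:
        b = pd.read_csv(path, index_col=0)
        if ((b < -1e-12) | (b > 1 + 1e-12)).any().any():
            raise ValueError("Beals values outside [0, 1]")

    def _check_accuracy(path: Path) -> None:
        df = pd.read_csv(path)
        if not ((df["overall_accuracy_pct"] >= 0) & (df["overall_accuracy_pct"] <= 100)).all():
            raise ValueError("overall accuracy outside [0, 100]")
        if not ((df["kappa"] >= -1) & (df["kappa"] <= 1)).all():
            raise ValueError("kappa outside [-1, 1]")

    def _check_ca(path: Path) -> None:
        df = pd.read_csv(path)
        if (df["inertia"] < 0).any():
            raise ValueError("negative axis inertia")

    def _check_types(path: Path) -> None:
        df = pd.read_csv(path, index_col=0)
        if ((df["uncertainty"] < 0) | (df["uncertainty"] > 1)).any():
            raise ValueError("uncertainty outside [0, 1]")

    def _check_traits(path: Path) -> None:
        df = pd.read_csv(path, index_col=0)
        if (df["max_dbh"] <= 0).any():
            raise ValueError("non-positive max DBH")

    def _check_manifest(path: Path) -> None:
        json.loads(path.read_text())

    record("manifest.json", _check_manifest)
    record("config.yaml", lambda p: yaml.safe_load(p.read_text()))
    record("abundance.csv", _check_abundance)
    record("accuracy.csv", _check_accuracy)
    record("ca_inertia.csv", _check_ca)
    record("assemblage_types.csv", _check_types)
    record("trait_table.csv", _check_traits)
    record("beals.csv", _check_beals)

    ok = all(c["status"] == "pass" for c in checks.values())
    return {"ok": ok, "checks": checks}
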