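"""End-to-end driver: VBM -> seed definition -> CaSCN -> region masks -> EBM.

Each stage's artefacts are written as they complete, so a failing stage
leaves partial outputs in place and aborts with the stage name.  Every run
is reproducible from configuration + seed alone; a provenance sidecar
records the configuration hash, the thresholds actually applied and library
versions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import cascn as cascn_mod
from . import ebm as ebm_mod
from . import io as io_mod
from . import vbm_stats

logger = logging.getLogger("atroseq.pipeline")

__all__ = ["PipelineStageError", "run_pipeline", "synthetic_run_config"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it, partial outputs remain."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineStageError(name, str(exc)) from exc

        return wrapper

    return deco


@_stage("load_cohort")
def _load(cfg):
    records, maps, affine = io_mod.read_cohort(cfg.cohort_dir)
    logger.info("loaded %d subjects, grid %s", len(records), maps.shape[1:])
    return records, maps, affine


@_stage("vbm")
def _vbm(cfg, records, maps, affine, out):
    sm = vbm_stats.fit_group_glm(maps, records,
                                 mask_threshold=cfg.mask_threshold,
                                 affine=affine)
    fdr = vbm_stats.fdr_correct(sm, q=cfg.vbm_q)
    clusters = vbm_stats.extract_clusters(fdr, stat=sm.stat,
                                          min_extent=cfg.vbm_extent,
                                          connectivity=cfg.connectivity,
                                          affine=affine)
    io_mod.write_stat_map(sm.stat, affine, out / "vbm_t.nii")
    io_mod.write_stat_map(sm.p, affine, out / "vbm_p.nii")
    io_mod.write_stat_map(fdr.astype(np.uint8), affine, out / "vbm_fdr_mask.nii")
    io_mod.write_cluster_table(clusters, out / "vbm_clusters.tsv")
    logger.info("vbm: q=%g extent=%d -> %d clusters", cfg.vbm_q,
                cfg.vbm_extent, len(clusters))
    return sm, fdr, clusters


@_stage("seed_definition")
def _seed(cfg, sm, affine, out):
    atlas_path = Path(cfg.atlas_mask)
    if not atlas_path.exists():
        raise PipelineStageError(
            "seed_definition",
            f"atlas mask not found: {atlas_path} — pass an existing NIfTI "
            "mask via RunConfig.atlas_mask",
        )
    atlas = io_mod.read_mask(atlas_path)
    fwe = vbm_stats.fwe_correct(sm, alpha=cfg.seed_alpha)
    seed = vbm_stats.define_seed(sm, fwe, atlas, min_extent=cfg.seed_extent,
                                 connectivity=cfg.connectivity)
    io_mod.write_stat_map(seed.mask.astype(np.uint8), affine, out / "seed_mask.nii")
    logger.info("seed: alpha=%g extent=%d -> %d voxels", cfg.seed_alpha,
                cfg.seed_extent, int(seed.mask.sum()))
    return seed


@_stage("cascn")
def _cascn(cfg, records, maps, seed, affine, out):
    patients = records[records["diagnosis"] == "patient"].reset_index(drop=True)
    pmaps = maps[(records["diagnosis"] == "patient").to_numpy()]
    pts = cascn_mod.build_pseudo_timeseries(patients, pmaps, seed)
    gmap, clusters = cascn_mod.cascn_map(
        pmaps, pts, q=cfg.cascn_q, extent=cfg.cascn_extent,
        mask_threshold=cfg.mask_threshold, connectivity=cfg.connectivity,
        affine=affine)
    io_mod.write_stat_map(gmap.b, affine, out / "cascn_b.nii")
    io_mod.write_stat_map(gmap.z, affine, out / "cascn_z.nii")
    io_mod.write_cluster_table(clusters, out / "cascn_clusters.tsv")
    (out / "cascn_meta.json").write_text(
        json.dumps({**gmap.meta, "df": gmap.df, "n_failed": gmap.n_failed},
                   indent=2, sort_keys=True))
    logger.info("cascn: q=%g extent=%d -> %d clusters (%d voxel fits failed)",
                cfg.cascn_q, cfg.cascn_extent, len(clusters), gmap.n_failed)
    return pts, gmap, clusters


@_stage("region_extraction")
def _regions(cfg, clusters, seed, shape):
    masks = {"seed_" + seed.name: seed.mask}
    masks.update(cascn_mod.extract_region_masks(clusters, shape))
    return masks


@_stage("ebm")
def _ebm(cfg, maps, masks, records, out):
    bm = ebm_mod.prepare_biomarkers(maps, masks, records,
                                    adjust=cfg.adjust_biomarkers)
    bm.data.assign(diagnosis=bm.labels.to_numpy()).to_csv(
        out / "biomarkers.tsv", sep="\t", index_label="id")
    cv = ebm_mod.cross_validate(
        bm, repeats=cfg.repeats, folds=cfg.folds, rng_seed=cfg.rng_seed,
        greedy_iters=cfg.greedy_iters, n_chains=cfg.ebm_chains,
        mcmc_iters=cfg.mcmc_iters)
    names = cv.event_names
    result = {
        "final_sequence": [names[i] for i in cv.final_order],
        "n_models": len(cv.sequences),
        "sequences": [[names[i] for i in s.order] for s in cv.sequences],
        "model_loglik": [s.loglik for s in cv.sequences],
        "holdout_loglik": cv.holdout_loglik.tolist(),
        "event_names": names,
    }
    (out / "ebm_result.json").write_text(json.dumps(result, indent=2,
                                                    sort_keys=True))
    import pandas as pd

    pd.DataFrame(cv.positional_variance, index=names,
                 columns=[f"pos{p+1}" for p in range(len(names))]).to_csv(
        out / "positional_variance.tsv", sep="\t", index_label="event")
    fig = ebm_mod.plot_positional_variance(cv.positional_variance, names)
    fig.savefig(out / "positional_variance.png", dpi=120)
    logger.info("ebm: %d CV models, final sequence %s", len(cv.sequences),
                result["final_sequence"])
    return bm, cv, result


def run_pipeline(cfg: io_mod.RunConfig) -> dict:
    """Run the full inference chain; returns a summary dict with paths/results.

    Stage order: group VBM -> FWE seed definition -> severity-ranked
    pseudo-time Granger mapping -> cluster region extraction -> event-based
    model with repeated stratified cross-validation.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, maps, affine = _load(cfg)
    sm, fdr, vbm_clusters = _vbm(cfg, records, maps, affine, out)
    seed = _seed(cfg, sm, affine, out)
    pts, gmap, cascn_clusters = _cascn(cfg, records, maps, seed, affine, out)
    masks = _regions(cfg, cascn_clusters, seed, maps.shape[1:])
    bm, cv, ebm_result = _ebm(cfg, maps, masks, records, out)

    io_mod.write_provenance(
        out / "provenance.json", cfg,
        extra={"thresholds_applied": {
            "vbm_q": cfg.vbm_q, "vbm_extent": cfg.vbm_extent,
            "seed_alpha": cfg.seed_alpha, "seed_extent": cfg.seed_extent,
            "cascn_q": cfg.cascn_q, "cascn_extent": cfg.cascn_extent,
            "connectivity": cfg.connectivity,
            "mask_threshold": cfg.mask_threshold,
        }})
    return {
        "out_dir": str(out),
        "n_vbm_clusters": len(vbm_clusters),
        "seed_voxels": int(seed.mask.sum()),
        "n_cascn_clusters": len(cascn_clusters),
        "masks": masks,
        "region_masks": {k: int(v.sum()) for k, v in masks.items()},
        "final_sequence": ebm_result["final_sequence"],
        "n_models": ebm_result["n_models"],
        "cv": cv,
        "biomarkers": bm,
    }


def synthetic_run_config(cohort_dir, out_dir, atlas_mask=None,
                         rng_seed: int = 0) -> io_mod.RunConfig:
    """RunConfig with thresholds scaled to the default synthetic grid.

    The default synthetic regions are 125-voxel blocks on a 24^3 lattice,
    two orders of magnitude below whole-brain dimensions, so the cluster
    extent thresholds are scaled accordingly (40 / 40 / 20 voxels for the
    VBM, seed and CaSCN stages) and the MCMC chain is shortened to 50,000
    iterations — ample for 8-event permutation spaces.
    """
    cohort_dir = Path(cohort_dir)
    if atlas_mask is None:
        atlas_mask = cohort_dir / "masks" / "insula_ant.nii"
    return io_mod.RunConfig(
        cohort_dir=str(cohort_dir), atlas_mask=str(atlas_mask),
        out_dir=str(out_dir),
        vbm_extent=40, seed_extent=40, cascn_extent=20,
        mcmc_iters=50000, rng_seed=rng_seed,
    )
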