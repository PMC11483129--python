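"""End-to-end orchestration: phantom -> cohort -> depth maps -> statistics.

``run_pipeline`` executes the full analysis on a synthetic cohort:

1. build the phantom geometry,
2. generate subjects (planted fixel fields + simulated tapping),
3. solve the Laplace potential and trace laminar streamlines,
4. sample total/par/tan AFD at the configured depths and smooth,
5. summarize tapping behavior,
6. vertex-wise correlation with cluster permutation correction,
7. regularized CCA with permutation loading intervals,

writing every intermediate artifact, a JSON manifest (parameters, seeds,
output hashes) and a structured log into the output directory.
Re-running with the same configuration reproduces identical outputs.
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

from . import io as ufio
from .cohort import generate_cohort
from .fixel_afd import sample_cohort, smooth_surface_metric
from .laplace import gradient_field, solve_laplace
from .phantom import make_phantom
from .rcca import grid_search_lambdas, permutation_loading_cis
from .streamlines import trace_streamlines
from .surface_stats import (cluster_correction, roi_aggregate,
                            vertexwise_correlation)
from .tap_metrics import behavior_matrix, summarize_subject, summary_to_frame

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("ufiberlab")


@dataclass
class PipelineConfig:
    """All knobs of one reproducible run; round-trips through YAML."""

    # phantom
    outer_radius: float = 20.0
    inner_radius: float = 10.0
    voxel_size: float = 1.0
    mesh_order: int = 3
    gyrification_amplitude: float = 0.0
    # cohort
    n_subjects: int = 32
    rho_planted: float = -0.6
    roi_id: int = 1
    trials_per_interval: int = 10
    afd_noise_sd: float = 0.02
    seed: int = 0
    # sampling / smoothing
    depths: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    smoothing_fwhm: float = 3.0  # mm; scaled to the 20 mm phantom
    analysis_depth: float = 1.5
    behavior_metric: str = "mean_abs_asynchrony"
    behavior_modality: str = "auditory"
    behavior_target: float = 650.0
    # solver
    laplace_tol: float = 1e-6
    laplace_max_iter: int = 10_000
    step_mm: float = 0.1
    max_length_mm: float = 5.0
    # statistics
    p_cft: float = 0.001
    n_perm_cluster: int = 5000
    alpha_cluster: float = 0.001
    # rcca
    rcca_grid_per_side: int = 3
    rcca_n_perm: int = 500
    rcca_level: float = 0.99
    # output
    out_dir: str = "ufiberlab_run"

    def to_yaml(self, path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return Path(path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "depths" in d:
            d["depths"] = tuple(d["depths"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run manifest (also written as JSON).

    On a stage failure the manifest records the failed stage and the
    partial outputs are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {"config": asdict(config), "stages": {}, "failed_stage": None}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s started", name)
            try:
                outputs = fn()
            except Exception as exc:  # record, then re-raise after writing
                manifest["failed_stage"] = name
                manifest["error"] = repr(exc)
                _write_manifest(out, manifest)
                log.exception("stage %s failed", name)
                log.removeHandler(handler)
                raise
            manifest["stages"][name] = {
                "outputs": {k: _sha256(Path(v)) for k, v in outputs.items()},
                "seconds": round(time.time() - t0, 3),
            }
            log.info("stage %s done in %.1fs", name, time.time() - t0)
            return outputs
        return deco

    state: dict = {}

    @stage("phantom")
    def _phantom():
        ph = make_phantom(config.outer_radius, config.inner_radius,
                          config.voxel_size, config.gyrification_amplitude,
                          config.mesh_order, seed=config.seed)
        state["phantom"] = ph
        A = ph.affine()
        return {
            "wm_mask": ufio.save_nifti(out / "wm_mask.nii", ph.wm_mask, A),
            "ventricle_mask": ufio.save_nifti(out / "ventricle_mask.nii",
                                              ph.ventricle_mask, A),
            "surface": ufio.save_surface_gifti(out / "surface.gii", ph.surface),
            "roi_labels": ufio.save_vertex_table(out / "roi_labels.csv",
                                                 ph.roi_labels, ["roi"]),
        }

    @stage("cohort")
    def _cohort():
        fields, sessions, truth = generate_cohort(
            config.n_subjects, config.rho_planted, config.roi_id,
            seed=config.seed, phantom=state["phantom"],
            afd_noise_sd=config.afd_noise_sd,
            trials_per_interval=config.trials_per_interval)
        state.update(fields=fields, sessions=sessions, truth=truth)
        log.info("cohort: %d subjects, %d fixels (subject 0), %d trials each",
                 len(fields), fields[0].n_fixels, len(sessions[0].trials))
        truth_path = out / "cohort_truth.json"
        with open(truth_path, "w") as fh:
            json.dump({
                "rho_planted": truth.rho_planted,
                "roi_id": truth.roi_id,
                "tan_amplitude": truth.tan_amplitudes.tolist(),
                "asynchrony_scale": truth.asynchrony_scales.tolist(),
            }, fh, indent=1)
        return {
            "events": ufio.save_sessions_csv(out / "events.csv", sessions),
            "fixels_subject0": ufio.save_fixel_dir(out / "fixels_s0",
                                                   fields[0]) / "index.nii",
            "truth": truth_path,
        }

    @stage("laplace")
    def _laplace():
        fld = solve_laplace(state["phantom"], tol=config.laplace_tol,
                            max_iter=config.laplace_max_iter)
        if not fld.converged:
            log.warning("Laplace relaxation hit max_iter (residual %.2e)",
                        fld.residual)
        g, n_zero = gradient_field(fld)
        log.info("laplace: %d iters, residual %.2e, %d zero-gradient voxels",
                 fld.n_iter, fld.residual, n_zero)
        state.update(potential=fld, gradient=g)
        return {"phi": ufio.save_nifti(out / "phi.nii", fld.phi.astype(np.float32),
                                       state["phantom"].affine())}

    @stage("streamlines")
    def _stream():
        sls = trace_streamlines(state["phantom"], state["gradient"],
                                config.step_mm, config.max_length_mm)
        state["streamlines"] = sls
        from collections import Counter
        log.info("streamlines: %s", dict(Counter(s.termination for s in sls)))
        df = ufio.streamlines_to_frame(sls)
        p = out / "streamlines.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        return {
            "tck": ufio.save_streamlines_tck(out / "streamlines.tck", sls),
            "csv": p,
        }

    @stage("sampling")
    def _sampling():
        mat = sample_cohort(state["fields"], state["streamlines"], config.depths)
        state["samples"] = mat
        S, V, D, _ = mat.values.shape
        rows = []
        for s in range(S):
            for d in range(D):
                rows.append(pd.DataFrame({
                    "subject": s, "vertex_id": np.arange(V),
                    "depth_mm": mat.depths[d],
                    "total": mat.values[s, :, d, 0],
                    "par": mat.values[s, :, d, 1],
                    "tan": mat.values[s, :, d, 2],
                }))
        p = out / "afd_samples.csv"
        pd.concat(rows, ignore_index=True).to_csv(p, index=False,
                                                  float_format="%.10g")
        # smooth the analysis-depth tangential map per subject
        di = int(np.argmin(np.abs(mat.depths - config.analysis_depth)))
        tan = mat.metric("tan")[:, :, di]
        sm = np.stack([
            smooth_surface_metric(state["phantom"].surface, tan[s],
                                  config.smoothing_fwhm)
            for s in range(S)])
        state["tan_smoothed"] = sm
        ps = out / "tan_afd_smoothed.csv"
        pd.DataFrame(sm.T).rename_axis("vertex_id").to_csv(
            ps, float_format="%.10g")
        return {"samples": p, "tan_smoothed": ps}

    @stage("behavior")
    def _behavior():
        summaries = [summarize_subject(s) for s in state["sessions"]]
        state["summaries"] = summaries
        df = summary_to_frame(summaries)
        p = out / "behavior_summary.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        return {"summary": p}

    @stage("surface_stats")
    def _stats():
        beh = np.array([
            s.value(config.behavior_modality, config.behavior_target,
                    config.behavior_metric)
            for s in state["summaries"]])
        res = vertexwise_correlation(state["tan_smoothed"], beh,
                                     depth_mm=config.analysis_depth)
        res = cluster_correction(res, state["phantom"].surface,
                                 state["tan_smoothed"], beh,
                                 p_cft=config.p_cft,
                                 n_perm=config.n_perm_cluster,
                                 alpha_cluster=config.alpha_cluster,
                                 seed=config.seed + 1)
        state["stats"] = res
        roi = roi_aggregate(res, state["phantom"].roi_labels,
                            config.alpha_cluster)
        log.info("surface stats: %d clusters, %d significant",
                 len(res.clusters),
                 sum(c["p_cluster"] < config.alpha_cluster for c in res.clusters))
        pmap = out / "vertex_stats.csv"
        ufio.save_vertex_table(
            pmap, np.column_stack([res.r_map, res.r2_map, res.p_map]),
            ["r", "r2", "p"])
        ctab = out / "clusters.csv"
        pd.DataFrame([
            {"cluster_id": i, "n_vertices": c["size"],
             "p_cluster": c["p_cluster"],
             "peak_vertex": int(c["vertices"][np.argmax(
                 np.abs(res.r_map[c["vertices"]]))])}
            for i, c in enumerate(res.clusters)
        ], columns=["cluster_id", "n_vertices", "p_cluster", "peak_vertex"]
        ).to_csv(ctab, index=False, float_format="%.10g")
        rtab = out / "roi_summary.csv"
        pd.DataFrame([
            {"roi": k, **v} for k, v in sorted(roi.rois.items())
        ]).to_csv(rtab, index=False, float_format="%.10g")
        return {"vertex_stats": pmap, "clusters": ctab, "roi_summary": rtab}

    @stage("rcca")
    def _rcca():
        X = behavior_matrix(state["summaries"])
        Y = state["tan_smoothed"]
        keep = ~np.isnan(X.to_numpy()).any(axis=1) & ~np.isnan(Y).any(axis=1)
        Xc, Yc = X.to_numpy()[keep], Y[keep]
        vals = np.logspace(-2, 1, config.rcca_grid_per_side)
        grid = [(a, b) for a in vals for b in vals]
        k_folds = max(2, min(5, len(Xc) // 3))
        lam, fit = grid_search_lambdas(Xc, Yc, grid, k_folds=k_folds,
                                       seed=config.seed + 2)
        res = permutation_loading_cis(Xc, Yc, lam, config.rcca_n_perm,
                                      config.rcca_level, seed=config.seed + 3)
        res.cv_corr = fit.cv_corr
        state["rcca"] = res
        log.info("rcca: lambda=%s, canonical corr %.3f", lam, res.canonical_corr)
        lp = out / "rcca_behavior_loadings.csv"
        pd.DataFrame({
            "variable": X.columns, "loading": res.loadings_x,
            "ci_lo": res.ci99_x[:, 0] if res.ci99_x is not None else np.nan,
            "ci_hi": res.ci99_x[:, 1] if res.ci99_x is not None else np.nan,
            "flagged": res.flagged_x() if res.ci99_x is not None else False,
        }).to_csv(lp, index=False, float_format="%.10g")
        vp = out / "rcca_vertex_loadings.csv"
        ufio.save_vertex_table(
            vp, np.column_stack([
                res.loadings_y,
                res.flagged_y().astype(int) if res.ci99_y is not None
                else np.zeros(len(res.loadings_y)),
            ]), ["loading", "flagged"])
        up = out / "rcca_variates.csv"
        pd.DataFrame({"subject": np.flatnonzero(keep), "U": res.U, "V": res.V}
                     ).to_csv(up, index=False, float_format="%.10g")
        return {"behavior_loadings": lp, "vertex_loadings": vp, "variates": up}

    manifest["canonical_corr"] = float(state["rcca"].canonical_corr)
    manifest["n_significant_clusters"] = int(sum(
        c["p_cluster"] < config.alpha_cluster for c in state["stats"].clusters))
    _write_manifest(out, manifest)
    log.removeHandler(handler)
    handler.close()
    return manifest


def _write_manifest(out: Path, manifest: dict):
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
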