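"""Pipeline orchestration: GLM -> selection -> correlation -> inference -> controls.

``run_pipeline`` drives the full analysis over an in-memory
:class:`~flashmvpa.synth.VoxelDataset` (synthetic or loaded from disk) and
returns a JSON-serializable report; with an output directory it also writes
per-stage TSV/JSON artifacts.  All randomness descends from one master seed
through named children, so identical configuration and seed give identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import controls as ctl
from .glm import (GLMResult, SELECTION_CONTRAST, SNR_CONTRAST, contrast_t,
                  select_voxels)
from .inference import GroupInference, NullDistribution, group_inference, permutation_null
from .mvpa import MIN_VOXELS, correlate_maps, difference_map
from .stimulus import compare_directions, effect_size_from_adjustments
from .synth import VoxelDataset
from scipy import stats

log = logging.getLogger("flashmvpa")


@dataclass
class PipelineConfig:
    """Analysis parameters; the master seed is mandatory."""

    seed: int
    censor_threshold: float = 0.3
    selection_alpha: float = 0.01
    n_perms: int = 1000
    n_boot: int = 1000
    n_clusters: int = 1500
    cluster_mode: str = "matched-count"
    effect_size_roi: str | None = None      # default: first ROI of the dataset
    run_clusters: bool = True
    run_split_half: bool = True
    run_no_selection: bool = True
    run_confounds: bool = True
    n_shuffles_confound: int = 1000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        for name in ("censor_threshold", "selection_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_perms", "n_boot", "n_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class ParticipantFit:
    """Everything computed from one participant's unshuffled data."""

    participant_id: str
    result: GLMResult
    censored: np.ndarray | None
    censored_fraction: float
    sel_p: np.ndarray                      # full-grid one-tailed selection p
    snr_t: np.ndarray                      # all-stimulus > fixation t map
    shift_t: np.ndarray                    # CLW-S > CCW-S t map
    selected: dict[str, np.ndarray]
    retained_fraction: dict[str, float]
    corr: dict[str, object]                # roi -> CorrelationResult


# ---------------------------------------------------------------------------
# Stage 1: per-participant GLM, selection, correlation
# ---------------------------------------------------------------------------

def fit_participants(dataset: VoxelDataset, params: PipelineConfig
                     ) -> list[ParticipantFit]:
    correction_n = sum(len(v) for v in dataset.roi_voxels.values())
    fits = []
    for p in dataset.participants:
        res, censored = ctl.participant_glm(p, params.censor_threshold)
        cf = 0.0 if censored is None else float(np.mean(censored))
        sel_t = contrast_t(res, SELECTION_CONTRAST)
        sel_p = stats.t.sf(sel_t, res.df)
        snr_t = contrast_t(res, SNR_CONTRAST)
        shift_t = contrast_t(res, {"CLW-S": 1.0, "CCW-S": -1.0})
        selected, frac, corr = {}, {}, {}
        for roi, vox in dataset.roi_voxels.items():
            sel, f = select_voxels(res, vox, params.selection_alpha,
                                   correction_n, t_map=sel_t)
            selected[roi], frac[roi] = sel, f
            if sel.size >= MIN_VOXELS:
                corr[roi] = correlate_maps(
                    difference_map(res, "CLW-M", "CCW-M", sel, roi),
                    difference_map(res, "CLW-S", "CCW-S", sel, roi),
                    participant_id=p.participant_id)
        log.info("%s: censored %.1f%%, selected %s", p.participant_id,
                 100 * cf, {r: int(len(s)) for r, s in selected.items()})
        fits.append(ParticipantFit(
            participant_id=p.participant_id, result=res, censored=censored,
            censored_fraction=cf, sel_p=sel_p, snr_t=snr_t, shift_t=shift_t,
            selected=selected, retained_fraction=frac, corr=corr))
    return fits


# ---------------------------------------------------------------------------
# Stage 2: permutation nulls and group inference
# ---------------------------------------------------------------------------

def permutation_stage(dataset: VoxelDataset, fits: list[ParticipantFit],
                      params: PipelineConfig,
                      voxel_sets: dict[str, list[np.ndarray]] | None = None,
                      seed_key: str = "permutation"
                      ) -> dict[str, list[NullDistribution]]:
    """Per-participant, per-ROI shuffled-label null distributions.

    ``voxel_sets`` (roi -> one voxel array per participant) overrides the
    selected sets, as used by the no-selection variant.
    """
    master = np.random.SeedSequence([params.seed, _key_int(seed_key)])
    child = {p.participant_id: rng for p, rng in
             zip(dataset.participants,
                 [np.random.default_rng(s) for s in master.spawn(len(dataset.participants))])}
    nulls: dict[str, list[NullDistribution]] = {roi: [] for roi in dataset.roi_voxels}
    for i, (p, fit) in enumerate(zip(dataset.participants, fits)):
        for roi in dataset.roi_voxels:
            vox = (voxel_sets[roi][i] if voxel_sets is not None
                   else fit.selected[roi])
            if vox.size < MIN_VOXELS:
                continue
            ds_vals = (fit.result.condition_betas("CLW-S")
                       - fit.result.condition_betas("CCW-S"))[vox]
            nd = permutation_null(
                p.bold[vox], p.schedule, ds_vals,
                motion_params=p.motion_params, censored=fit.censored,
                n_perms=params.n_perms, rng=child[p.participant_id],
                participant_id=p.participant_id, roi=roi)
            nulls[roi].append(nd)
    return nulls


def group_stage(nulls: dict[str, list[NullDistribution]], params: PipelineConfig,
                seed_key: str = "bootstrap") -> dict[str, GroupInference]:
    out = {}
    for roi, nds in nulls.items():
        if len(nds) < 2:
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, _key_int(seed_key), _key_int(roi)]))
        out[roi] = group_inference(roi, nds, n_boot=params.n_boot, rng=rng)
    return out


def _key_int(key: str) -> int:
    return int.from_bytes(key.encode()[:4].ljust(4, b"\0"), "little") % (2 ** 31)


# ---------------------------------------------------------------------------
# Stage 3: controls
# ---------------------------------------------------------------------------

def effect_size_stage(dataset: VoxelDataset, fits: list[ParticipantFit],
                      roi: str) -> dict:
    estimates = []
    for p, fit in zip(dataset.participants, fits):
        vox = fit.selected[roi]
        if vox.size < MIN_VOXELS or p.effect_size is None:
            continue
        dm = (fit.result.condition_betas("CLW-M")
              - fit.result.condition_betas("CCW-M"))[vox]
        ds = (fit.result.condition_betas("CLW-S")
              - fit.result.condition_betas("CCW-S"))[vox]
        estimates.append(ctl.effect_size_estimate(
            dm, ds, p.effect_size.matched_shift_deg, p.participant_id))
    ratios = np.array([e.ratio for e in estimates])
    degrees = np.array([e.degrees for e in estimates])
    n = len(estimates)
    return {
        "roi": roi,
        "per_participant_ratio": ratios.tolist(),
        "mean_ratio_pct": float(100 * ratios.mean()) if n else None,
        "se_ratio_pct": float(100 * ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        "mean_degrees": float(degrees.mean()) if n else None,
        "se_degrees": float(degrees.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
    }


def confound_stage(dataset: VoxelDataset, fits: list[ParticipantFit],
                   params: PipelineConfig) -> dict:
    rois = list(dataset.roi_voxels)
    z = np.array([[fit.corr[roi].z if roi in fit.corr else np.nan for roi in rois]
                  for fit in fits])
    ok = ~np.isnan(z).any(axis=1)
    metrics = {
        "snr": np.array([[fit.snr_t[fit.selected[roi]].mean() if roi in fit.corr
                          else np.nan for roi in rois] for fit in fits]),
        "n_selected": np.array([[len(fit.selected[roi]) for roi in rois]
                                for fit in fits], dtype=float),
        "roi_size": np.array([[len(dataset.roi_voxels[roi]) for roi in rois]
                              for _ in fits], dtype=float),
        "shift_coding": np.array([[np.abs(fit.shift_t[fit.selected[roi]]).mean()
                                   if roi in fit.corr else np.nan for roi in rois]
                                  for fit in fits]),
    }
    out = {}
    for name, m in metrics.items():
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, _key_int("confound"), _key_int(name)]))
        cc = ctl.confound_correlation(m[ok], z[ok], params.n_shuffles_confound,
                                      rng, metric_name=name)
        out[name] = {"r": cc.r, "p_lower": cc.p_lower, "p_greater": cc.p_greater,
                     "valid": cc.valid}
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(dataset: VoxelDataset, params: PipelineConfig,
                 out_dir: str | Path | None = None) -> dict:
    """Run every stage and assemble the summary report."""
    rois = list(dataset.roi_voxels)
    effect_roi = params.effect_size_roi or rois[0]

    report: dict = {"parameters": dataclasses.asdict(params)}

    # psychophysics
    if dataset.sessions:
        effects = effect_size_from_adjustments(dataset.sessions)
        t, p = compare_directions(effects)
        report["psychophysics"] = {
            "clw_mean_deg": float(np.mean([abs(e.clw_shift) for e in effects])),
            "ccw_mean_deg": float(np.mean([abs(e.ccw_shift) for e in effects])),
            "direction_t": t, "direction_p_two_tailed": p,
        }

    fits = fit_participants(dataset, params)
    report["participants"] = [
        {"participant": f.participant_id,
         "censored_fraction": f.censored_fraction,
         "rois": {roi: {"n_selected": int(len(f.selected[roi])),
                        "retained_fraction": f.retained_fraction[roi],
                        "r": f.corr[roi].r if roi in f.corr else None,
                        "z": f.corr[roi].z if roi in f.corr else None}
                  for roi in rois}}
        for f in fits]

    nulls = permutation_stage(dataset, fits, params)
    groups = group_stage(nulls, params)
    report["rois"] = {}
    for roi in rois:
        entry: dict = {
            "mean_r": float(np.mean([f.corr[roi].r for f in fits if roi in f.corr])),
            "mean_z": float(np.mean([f.corr[roi].z for f in fits if roi in f.corr])),
            "permutation_p": [nd.p for nd in nulls[roi]],
        }
        if roi in groups:
            g = groups[roi]
            entry.update({"bootstrap_p": g.bootstrap_p, "paired_t": g.t,
                          "df": g.df, "paired_t_p": g.t_p})
        report["rois"][roi] = entry

    report["effect_size"] = effect_size_stage(dataset, fits, effect_roi)

    if params.run_confounds and len(rois) >= 2:
        report["confounds"] = confound_stage(dataset, fits, params)

    if params.run_clusters:
        maps = [{"dm": f.result.condition_betas("CLW-M") - f.result.condition_betas("CCW-M"),
                 "ds": f.result.condition_betas("CLW-S") - f.result.condition_betas("CCW-S"),
                 "sel_p": f.sel_p} for f in fits]
        target_mean_z = report["rois"][effect_roi]["mean_z"]
        if params.cluster_mode == "matched-count":
            target_n = int(round(np.mean([len(f.selected[effect_roi]) for f in fits])))
        else:
            target_n = len(dataset.roi_voxels[effect_roi])
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, _key_int("clusters")]))
        cres = ctl.cluster_specificity_null(
            dataset, target_mean_z, max(target_n, MIN_VOXELS),
            n_clusters=params.n_clusters, mode=params.cluster_mode, rng=rng,
            alpha=params.selection_alpha, target_roi=effect_roi, maps=maps)
        report["cluster_control"] = {
            "target_roi": cres.target_roi, "mode": cres.mode,
            "target_n": int(max(target_n, MIN_VOXELS)),
            "target_mean_z": cres.target_mean_z, "p": cres.p,
            "n_clusters": cres.n_clusters, "n_valid": cres.n_valid,
            "null_mean": float(cres.null_means.mean()),
        }

    if params.run_split_half and dataset.participants[0].schedule.n_runs >= 2:
        sh = ctl.split_half_validation(dataset, effect_roi,
                                       alpha_full=params.selection_alpha,
                                       censor_threshold=params.censor_threshold)
        report["split_half"] = {
            "roi": sh.roi, "overlap": sh.overlap,
            "t_odd": sh.t_odd, "p_odd": sh.p_odd,
            "t_even": sh.t_even, "p_even": sh.p_even,
        }

    if params.run_no_selection:
        voxel_sets = {roi: [dataset.roi_voxels[roi] for _ in fits] for roi in rois}
        ns_nulls = permutation_stage(dataset, fits, params, voxel_sets=voxel_sets,
                                     seed_key="no-selection")
        ns_groups = group_stage(ns_nulls, params, seed_key="no-sel-boot")
        report["no_selection"] = {
            roi: {"mean_z": float(np.mean([nd.observed_z for nd in ns_nulls[roi]])),
                  "bootstrap_p": ns_groups[roi].bootstrap_p if roi in ns_groups else None,
                  "paired_t_p": ns_groups[roi].t_p if roi in ns_groups else None}
            for roi in rois if ns_nulls[roi]}

    if out_dir is not None:
        _write_artifacts(Path(out_dir), report, fits, nulls, rois)
    return report


def _write_artifacts(out_dir: Path, report: dict, fits, nulls, rois) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [{"participant": f.participant_id, "roi": roi,
             "r": f.corr[roi].r, "z": f.corr[roi].z,
             "n_voxels": f.corr[roi].n_voxels}
            for f in fits for roi in rois if roi in f.corr]
    pd.DataFrame(rows).to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    null_dir = out_dir / "nulls"
    null_dir.mkdir(exist_ok=True)
    for roi, nds in nulls.items():
        for nd in nds:
            pd.DataFrame({"z": nd.z}).to_csv(
                null_dir / f"{nd.participant_id}_{roi}.tsv", sep="\t", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))


def run_from_directory(dataset_dir: str | Path, params: PipelineConfig,
                       out_dir: str | Path | None = None) -> dict:
    """Load a serialized dataset and run the pipeline on it."""
    from .io import read_dataset

    return run_pipeline(read_dataset(dataset_dir), params, out_dir)
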