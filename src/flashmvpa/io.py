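"""Dataset serialization: NIfTI volumes, BIDS-like events TSV, motion text.

On-disk layout of a dataset directory::

    config.json                   simulation / design parameters
    roi_labels.nii.gz             3D integer ROI label map (0 = none)
    shared_mask.nii.gz            3D shared gray-matter mask (>=4 rule)
    psychophysics.tsv             adjustment-task settings
    sub-01/
        bold_run-01.nii.gz ...    4D runs (x, y, z, t), voxel-index space
        events_run-01.tsv ...     onset / duration / trial_type (0-based s)
        motion.txt                6 columns, one row per TR, whole session
        gm_mask.nii.gz            participant gray-matter mask

Reading validates grid dimensions, per-run TR counts against the configured
schedule, and block non-overlap; any mismatch is a hard failure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import ExperimentSchedule
from .stimulus import AdjustmentSession, effect_size_from_adjustments
from .synth import (ParticipantData, ROISpec, SyntheticConfig, VoxelDataset)

_AFFINE = np.eye(4)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["roi_specs"] = [dataclasses.asdict(s) for s in config.roi_specs]
    d["grid_shape"] = list(config.grid_shape)
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    d["roi_specs"] = tuple(ROISpec(**s) for s in d["roi_specs"])
    d["grid_shape"] = tuple(d["grid_shape"])
    return SyntheticConfig(**d)


def _save_vol(path: Path, flat: np.ndarray, grid_shape, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(flat, dtype=dtype).reshape(grid_shape,
                                                                order="C"), _AFFINE)
    nib.save(img, str(path))


def schedule_to_events(schedule: ExperimentSchedule, run: int) -> pd.DataFrame:
    b = schedule.blocks
    g = b[b["run"] == run].sort_values("onset_s")
    return pd.DataFrame({"onset": g["onset_s"].to_numpy(),
                         "duration": g["duration_s"].to_numpy(),
                         "trial_type": g["condition"].to_numpy()})


def events_to_schedule(events_per_run: list[pd.DataFrame], tr: float,
                       n_trs_per_run: int) -> ExperimentSchedule:
    rows = []
    for run, ev in enumerate(events_per_run):
        for _, row in ev.iterrows():
            rows.append({"run": run, "onset_s": float(row["onset"]),
                         "duration_s": float(row["duration"]),
                         "condition": str(row["trial_type"])})
    return ExperimentSchedule(tr=tr, n_runs=len(events_per_run),
                              n_trs_per_run=n_trs_per_run,
                              blocks=pd.DataFrame(rows))


def write_dataset(dataset: VoxelDataset, outdir: str | Path) -> Path:
    """Serialize a dataset; ground-truth betas/patterns are not persisted
    (the written form is the real-data interface)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    (outdir / "config.json").write_text(json.dumps(config_to_dict(cfg), indent=2))

    labels = np.zeros(dataset.n_grid, dtype=np.int16)
    for i, spec in enumerate(cfg.roi_specs):
        labels[dataset.roi_voxels[spec.name]] = i + 1
    _save_vol(outdir / "roi_labels.nii.gz", labels, dataset.grid_shape, np.int16)
    _save_vol(outdir / "shared_mask.nii.gz", dataset.shared_mask,
              dataset.grid_shape, np.uint8)

    rows = [{"participant": s.participant_id, "condition": s.condition,
             "adjustment_1": s.adjustments[0], "adjustment_2": s.adjustments[1],
             "adjustment_3": s.adjustments[2], "initial_offset": s.initial_offset}
            for s in dataset.sessions]
    pd.DataFrame(rows).to_csv(outdir / "psychophysics.tsv", sep="\t", index=False)

    for p in dataset.participants:
        pdir = outdir / p.participant_id
        pdir.mkdir(exist_ok=True)
        _save_vol(pdir / "gm_mask.nii.gz", p.gm_mask, dataset.grid_shape, np.uint8)
        if p.motion_params is not None:
            np.savetxt(pdir / "motion.txt", p.motion_params, fmt="%.17g")
        if p.bold is not None:
            n = p.schedule.n_trs_per_run
            for r in range(p.schedule.n_runs):
                vol = p.bold[:, r * n:(r + 1) * n].reshape(
                    dataset.grid_shape + (n,), order="C")
                nib.save(nib.Nifti1Image(vol.astype(np.float64), _AFFINE),
                         str(pdir / f"bold_run-{r + 1:02d}.nii.gz"))
        for r in range(p.schedule.n_runs):
            schedule_to_events(p.schedule, r).to_csv(
                pdir / f"events_run-{r + 1:02d}.tsv", sep="\t", index=False,
                float_format="%.17g")
    return outdir


def read_dataset(indir: str | Path) -> VoxelDataset:
    """Load a dataset directory into memory, validating its consistency."""
    indir = Path(indir)
    cfg = config_from_dict(json.loads((indir / "config.json").read_text()))
    grid_shape = cfg.grid_shape

    labels_img = nib.load(str(indir / "roi_labels.nii.gz"))
    if tuple(labels_img.shape) != grid_shape:
        raise ValueError("ROI label map does not match the configured grid")
    labels = np.asarray(labels_img.dataobj).reshape(-1, order="C")
    roi_voxels = {spec.name: np.flatnonzero(labels == i + 1)
                  for i, spec in enumerate(cfg.roi_specs)}
    shared = np.asarray(nib.load(str(indir / "shared_mask.nii.gz")).dataobj
                        ).reshape(-1, order="C").astype(bool)

    psy = pd.read_csv(indir / "psychophysics.tsv", sep="\t")
    sessions = [AdjustmentSession(
        participant_id=str(r["participant"]), condition=str(r["condition"]),
        adjustments=(float(r["adjustment_1"]), float(r["adjustment_2"]),
                     float(r["adjustment_3"])),
        initial_offset=float(r["initial_offset"])) for _, r in psy.iterrows()]
    effects = {e.participant_id: e for e in effect_size_from_adjustments(sessions)}

    participants = []
    for pdir in sorted(d for d in indir.iterdir() if d.is_dir()):
        pid = pdir.name
        gm = np.asarray(nib.load(str(pdir / "gm_mask.nii.gz")).dataobj
                        ).reshape(-1, order="C").astype(bool)
        run_files = sorted(pdir.glob("bold_run-*.nii.gz"))
        event_files = sorted(pdir.glob("events_run-*.tsv"))
        if run_files and len(run_files) != len(event_files):
            raise ValueError(f"{pid}: run and events files do not pair up")
        events = [pd.read_csv(f, sep="\t") for f in event_files]
        schedule = events_to_schedule(events, cfg.tr, cfg.n_trs_per_run)
        if schedule.n_runs != cfg.n_runs:
            raise ValueError(f"{pid}: {schedule.n_runs} runs, expected {cfg.n_runs}")
        bold = None
        if run_files:
            mats = []
            for f in run_files:
                img = nib.load(str(f))
                if tuple(img.shape[:3]) != grid_shape:
                    raise ValueError(f"{f.name}: grid {img.shape[:3]} does not "
                                     f"match configured {grid_shape}")
                if img.shape[3] != cfg.n_trs_per_run:
                    raise ValueError(f"{f.name}: {img.shape[3]} TRs against a "
                                     f"{cfg.n_trs_per_run}-TR schedule")
                mats.append(np.asarray(img.dataobj).reshape(-1, img.shape[3],
                                                            order="C"))
            bold = np.concatenate(mats, axis=1)
        motion = None
        if (pdir / "motion.txt").exists():
            motion = np.loadtxt(pdir / "motion.txt", ndmin=2)
            if motion.shape != (schedule.total_trs, 6):
                raise ValueError(f"{pid}: motion parameters shaped "
                                 f"{motion.shape}, expected "
                                 f"({schedule.total_trs}, 6)")
        participants.append(ParticipantData(
            participant_id=pid, schedule=schedule, gm_mask=gm,
            bold=bold, motion_params=motion, effect_size=effects.get(pid)))
    return VoxelDataset(config=cfg, grid_shape=grid_shape, roi_voxels=roi_voxels,
                        kappa={s.name: s.kappa for s in cfg.roi_specs},
                        shared_mask=shared, participants=participants,
                        sessions=sessions)
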