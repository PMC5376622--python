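"""Specificity and confound controls for the difference-map correlation.

These analyses probe whether a high correlation between motion-shift and
physical-shift difference maps is (a) spatially specific to the analyzed ROIs
rather than obtainable from arbitrary gray matter (random-cluster null),
(b) explainable by signal-to-noise, voxel counts or the strength of
physical-shift coding (ROI-shuffle confound correlations), (c) an artifact
of the voxel-selection criterion (split-half selection and the no-selection
variant handled by the pipeline), and finally (d) how large the perceptual
effect is in stimulus units (mean-absolute-deviation ratio of the maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import (ExperimentSchedule, SELECTION_CONTRAST, build_design,
                  censor_trs, contrast_t, fit_glm, select_voxels)
from .mvpa import MIN_VOXELS, correlate_maps, difference_map, fisher_z
from .synth import ParticipantData, VoxelDataset


@dataclass
class ROIMask:
    """A named voxel set on the shared grid."""

    name: str
    voxels: np.ndarray
    source: str = "defined"          # "defined" or "random-cluster"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.size == 0:
            raise ValueError("empty ROI mask")
        if self.source not in ("defined", "random-cluster"):
            raise ValueError("source must be 'defined' or 'random-cluster'")


@dataclass
class EffectSizeEstimate:
    """Perceptual/physical fMRI effect ratio, and its degrees equivalent."""

    participant_id: str
    ratio: float                     # MAD(motion map) / MAD(physical map)
    degrees: float                   # ratio x matched physical shift


# ---------------------------------------------------------------------------
# Random gray-matter clusters
# ---------------------------------------------------------------------------

def random_cluster(shared_mask: np.ndarray, grid_shape: tuple[int, int, int],
                   target_n: int, rng: np.random.Generator | int | None = None,
                   exclude: np.ndarray | None = None,
                   name: str = "cluster") -> ROIMask:
    """Grow a sphere around a random in-mask seed to exactly ``target_n`` voxels.

    The radius grows (Euclidean distance, voxel units) until the in-mask
    count reaches ``target_n``; excess voxels on the outermost shell are
    dropped at random.  Voxels in ``exclude`` (the analyzed ROI set) are
    never used.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shared_mask = np.asarray(shared_mask, dtype=bool)
    eligible = shared_mask.copy()
    if exclude is not None and len(exclude):
        eligible[np.asarray(exclude)] = False
    candidates = np.flatnonzero(eligible)
    if candidates.size < target_n:
        raise ValueError(f"cannot reach target_n={target_n}: only "
                         f"{candidates.size} eligible voxels")
    seed = int(rng.choice(candidates))
    coords = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    d = np.linalg.norm(coords[candidates] - coords[seed], axis=1)
    order = np.argsort(d, kind="stable")
    r_star = d[order[target_n - 1]]
    inner = candidates[d < r_star - 1e-9]
    shell = candidates[np.abs(d - r_star) <= 1e-9]
    need = target_n - inner.size
    picked = rng.choice(shell, size=need, replace=False)
    return ROIMask(name=name, voxels=np.sort(np.concatenate([inner, picked])),
                   source="random-cluster")


# ---------------------------------------------------------------------------
# Shared fitting helper (full-grid GLMs for control analyses)
# ---------------------------------------------------------------------------

def participant_glm(p: ParticipantData, censor_threshold: float = 0.3,
                    runs: list[int] | None = None):
    """Fit the full-grid GLM of one participant; returns (GLMResult, censored).

    ``runs`` optionally restricts the fit to a subset of runs (renumbered),
    as used by the split-half control.
    """
    schedule, Y, motion = p.schedule, p.bold, p.motion_params
    if Y is None:
        raise ValueError(f"participant {p.participant_id} has no time series")
    if runs is not None:
        schedule, Y, motion = _subset_runs(schedule, Y, motion, runs)
    censored = None
    if motion is not None:
        censored = censor_trs(motion, [schedule.n_trs_per_run] * schedule.n_runs,
                              censor_threshold)
    design = build_design(schedule, motion)
    return fit_glm(Y, design, censored=censored), censored


def _subset_runs(schedule: ExperimentSchedule, Y: np.ndarray,
                 motion: np.ndarray | None, runs: list[int]):
    n = schedule.n_trs_per_run
    trs = np.concatenate([np.arange(r * n, (r + 1) * n) for r in runs])
    blocks = schedule.blocks[schedule.blocks["run"].isin(runs)].copy()
    blocks["run"] = blocks["run"].map({r: i for i, r in enumerate(runs)})
    sub = ExperimentSchedule(schedule.tr, len(runs), n, blocks.reset_index(drop=True))
    return sub, Y[:, trs], None if motion is None else motion[trs]


# ---------------------------------------------------------------------------
# Cluster specificity null
# ---------------------------------------------------------------------------

@dataclass
class ClusterNullResult:
    target_roi: str
    target_mean_z: float
    null_means: np.ndarray           # group-mean z of each valid cluster
    p: float                         # proportion of cluster means >= target
    n_clusters: int
    n_valid: int
    mode: str


def cluster_specificity_null(dataset: VoxelDataset, target_mean_z: float,
                             target_n: int, n_clusters: int = 1500,
                             mode: str = "matched-count",
                             rng: np.random.Generator | int | None = None,
                             alpha: float = 0.01,
                             min_participants: int = 4,
                             target_roi: str = "V1",
                             maps: list[dict] | None = None,
                             censor_threshold: float = 0.3) -> ClusterNullResult:
    """Null distribution of group-mean z' over random gray-matter clusters.

    ``mode="matched-count"``: clusters of exactly ``target_n`` voxels (the
    average *selected* count of the target ROI), correlated without further
    selection.  ``mode="matched-size-with-selection"``: clusters match the
    ROI's total size and undergo the same Bonferroni voxel selection
    (corrected within the cluster) before correlating; participants with
    fewer than three surviving voxels are dropped and clusters valid in
    fewer than ``min_participants`` participants are excluded entirely.

    ``maps`` may carry precomputed per-participant dicts with keys ``dm``,
    ``ds`` (full-grid difference maps) and ``sel_p`` (one-tailed selection
    p per voxel); otherwise the GLMs are fit here.
    """
    if mode not in ("matched-count", "matched-size-with-selection"):
        raise ValueError("unknown mode")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if maps is None:
        maps = dataset_maps(dataset, censor_threshold)
    exclude = np.concatenate(list(dataset.roi_voxels.values()))
    null_means = []
    for c in range(n_clusters):
        cluster = random_cluster(dataset.shared_mask, dataset.grid_shape,
                                 target_n, rng, exclude=exclude,
                                 name=f"cluster{c}")
        zs = []
        for m in maps:
            vox = cluster.voxels
            if mode == "matched-size-with-selection":
                keep = m["sel_p"][vox] < alpha / len(vox)
                vox = vox[keep]
                if len(vox) <= 2:
                    continue
            dm, ds = m["dm"][vox], m["ds"][vox]
            if len(vox) < MIN_VOXELS or np.std(dm) == 0 or np.std(ds) == 0:
                continue
            zs.append(fisher_z(float(np.corrcoef(dm, ds)[0, 1])))
        if len(zs) >= min(min_participants, len(maps)):
            null_means.append(np.mean(zs))
    null_means = np.asarray(null_means)
    if null_means.size == 0:
        raise ValueError("no valid clusters")
    p = float(np.mean(null_means >= target_mean_z))
    return ClusterNullResult(target_roi=target_roi, target_mean_z=target_mean_z,
                             null_means=null_means, p=p, n_clusters=n_clusters,
                             n_valid=int(null_means.size), mode=mode)


def dataset_maps(dataset: VoxelDataset, censor_threshold: float = 0.3) -> list[dict]:
    """Full-grid difference maps and selection p per participant.

    Fits each participant's GLM over every grid voxel and returns dicts with
    ``dm`` (CLW-M - CCW-M), ``ds`` (CLW-S - CCW-S) and ``sel_p`` (one-tailed
    p of the selection contrast), all of length n_grid.
    """
    out = []
    for p in dataset.participants:
        res, _ = participant_glm(p, censor_threshold)
        t = contrast_t(res, SELECTION_CONTRAST)
        out.append({
            "dm": res.condition_betas("CLW-M") - res.condition_betas("CCW-M"),
            "ds": res.condition_betas("CLW-S") - res.condition_betas("CCW-S"),
            "sel_p": stats.t.sf(t, res.df),
            "result": res,
        })
    return out


# ---------------------------------------------------------------------------
# Confound correlations with ROI-shuffle significance
# ---------------------------------------------------------------------------

@dataclass
class ConfoundCorrelation:
    metric: str
    r: float
    p_lower: float                   # fraction of shuffled r below observed
    p_greater: float                 # fraction of shuffled r at/above observed
    valid: bool = True


def confound_correlation(metric: np.ndarray, z: np.ndarray,
                         n_shuffles: int = 1000,
                         rng: np.random.Generator | int | None = None,
                         metric_name: str = "") -> ConfoundCorrelation:
    """Correlate a per-(participant, ROI) metric with the observed z' scores.

    ``metric`` and ``z`` are (n_participants, n_rois) arrays.  Pearson r is
    computed over all pairs; the null shuffles the metric among ROIs within
    each participant ``n_shuffles`` times.  Both tail conventions are
    reported: ``p_lower`` (fraction of shuffled correlations lower than the
    unshuffled, the convention as stated) and ``p_greater`` (upper tail,
    which is the significance of a *positive* confound correlation).
    A constant metric has no defined correlation and is flagged.
    """
    metric = np.asarray(metric, dtype=float)
    z = np.asarray(z, dtype=float)
    if metric.shape != z.shape:
        raise ValueError("metric and z must align over (participant, ROI)")
    if metric.shape[1] < 2:
        raise ValueError("need at least 2 ROIs")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if np.std(metric) == 0 or np.std(z) == 0:
        return ConfoundCorrelation(metric_name, float("nan"), float("nan"),
                                   float("nan"), valid=False)
    r_obs = float(np.corrcoef(metric.ravel(), z.ravel())[0, 1])
    z_flat = z.ravel()
    shuffled = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = np.array([row[rng.permutation(metric.shape[1])] for row in metric])
        shuffled[i] = np.corrcoef(perm.ravel(), z_flat)[0, 1]
    return ConfoundCorrelation(metric_name, r_obs,
                               p_lower=float(np.mean(shuffled < r_obs)),
                               p_greater=float(np.mean(shuffled >= r_obs)))


# ---------------------------------------------------------------------------
# Split-half voxel-selection validation
# ---------------------------------------------------------------------------

@dataclass
class SplitHalfResult:
    roi: str
    overlap: float                   # |half-selected ∩ full-selected| / |full|
    z_full: np.ndarray
    z_from_odd_selection: np.ndarray   # correlations on even data, odd selection
    z_from_even_selection: np.ndarray
    t_odd: float
    p_odd: float
    t_even: float
    p_even: float


def split_half_validation(dataset: VoxelDataset, roi: str,
                          alpha_full: float = 0.01, alpha_half: float = 0.05,
                          correction_n: int | None = None,
                          censor_threshold: float = 0.3) -> SplitHalfResult:
    """Select voxels on one half of the runs, correlate on the other.

    Odd/even splits by run parity.  The half-data selection threshold is
    relaxed to corrected p < ``alpha_half`` (0.05) to compensate for the
    reduced data; the full-data selection stays at ``alpha_full`` (0.01).
    Overlap is the fraction of full-data-selected voxels recovered by the
    independent half selection.  Two-tailed paired t-tests compare the
    full-data z' against each half-based z' across participants.
    """
    roi_vox = dataset.roi_voxels[roi]
    if correction_n is None:
        correction_n = sum(len(v) for v in dataset.roi_voxels.values())
    overlaps, z_full, z_odd, z_even = [], [], [], []
    for p in dataset.participants:
        if p.schedule.n_runs < 2:
            raise ValueError("split-half needs at least 2 runs")
        res_full, _ = participant_glm(p, censor_threshold)
        sel_full, _ = select_voxels(res_full, roi_vox, alpha_full, correction_n)
        halves = {}
        for parity, runs in (("odd", list(range(1, p.schedule.n_runs, 2))),
                             ("even", list(range(0, p.schedule.n_runs, 2)))):
            res_half, _ = participant_glm(p, censor_threshold, runs=runs)
            sel_half, _ = select_voxels(res_half, roi_vox, alpha_half, correction_n)
            if sel_half.size == 0:
                raise ValueError(f"empty selection in {parity} half for "
                                 f"{p.participant_id}")
            halves[parity] = (res_half, sel_half)
        for parity in ("odd", "even"):
            _, sel_half = halves[parity]
            if sel_full.size:
                overlaps.append(len(np.intersect1d(sel_half, sel_full)) / len(sel_full))

        def _corr(result, voxels):
            if voxels.size < MIN_VOXELS:
                return None
            c = correlate_maps(
                difference_map(result, "CLW-M", "CCW-M", voxels, roi),
                difference_map(result, "CLW-S", "CCW-S", voxels, roi))
            return c.z if c.valid else None

        # correlate on the data NOT used for selection; keep the participant
        # only if all three correlations are defined, so the paired tests
        # stay aligned
        zf = _corr(res_full, sel_full)
        zo = _corr(halves["even"][0], halves["odd"][1])
        ze = _corr(halves["odd"][0], halves["even"][1])
        if None not in (zf, zo, ze):
            z_full.append(zf)
            z_odd.append(zo)
            z_even.append(ze)
    z_full, z_odd, z_even = map(np.asarray, (z_full, z_odd, z_even))
    t_odd, p_odd = stats.ttest_rel(z_full, z_odd)
    t_even, p_even = stats.ttest_rel(z_full, z_even)
    return SplitHalfResult(roi=roi, overlap=float(np.mean(overlaps)),
                           z_full=z_full, z_from_odd_selection=z_odd,
                           z_from_even_selection=z_even,
                           t_odd=float(t_odd), p_odd=float(p_odd),
                           t_even=float(t_even), p_even=float(p_even))


# ---------------------------------------------------------------------------
# Effect size in stimulus units
# ---------------------------------------------------------------------------

def effect_size_estimate(dm_values: np.ndarray, ds_values: np.ndarray,
                         matched_shift_deg: float,
                         participant_id: str = "") -> EffectSizeEstimate:
    """MAD ratio of the two difference maps, converted to degrees of rotation.

    ``ratio = mean|dm| / mean|ds|`` over the shared voxel set; ``degrees``
    scales the participant's psychophysically matched physical shift (the
    direction-averaged magnitude) by that ratio.
    """
    dm_values = np.asarray(dm_values, dtype=float)
    ds_values = np.asarray(ds_values, dtype=float)
    if dm_values.shape != ds_values.shape:
        raise ValueError("difference maps cover different voxel sets")
    if matched_shift_deg <= 0:
        raise ValueError("matched_shift_deg must be positive")
    mad_s = float(np.mean(np.abs(ds_values)))
    if mad_s == 0:
        raise ValueError("physical-shift map has zero mean absolute deviation")
    ratio = float(np.mean(np.abs(dm_values))) / mad_s
    return EffectSizeEstimate(participant_id=participant_id, ratio=ratio,
                              degrees=ratio * matched_shift_deg)


def expected_mad_ratio(kappa: float, pattern_sd: float,
                       pattern_noise_sd: float = 0.0,
                       meas_sd_m: float = 0.0, meas_sd_s: float = 0.0) -> float:
    """Closed-form expectation of the MAD ratio under the Gaussian model.

    With P_v ~ N(0, pattern_sd^2), the motion map kappa P + eta + e_m and the
    physical map P + e_s are zero-mean Gaussian across voxels, so each MAD
    estimates sqrt(2/pi) times its standard deviation and the ratio tends to

        sqrt(kappa^2 sd_P^2 + sd_eta^2 + sd_em^2) / sqrt(sd_P^2 + sd_es^2).

    This also quantifies the positive bias at kappa = 0: noise alone gives a
    strictly positive ratio.
    """
    num = np.sqrt(kappa ** 2 * pattern_sd ** 2 + pattern_noise_sd ** 2 + meas_sd_m ** 2)
    den = np.sqrt(pattern_sd ** 2 + meas_sd_s ** 2)
    return float(num / den)


def debiased_mad_ratio(mad_m: float, mad_s: float,
                       se_m: float, se_s: float) -> float:
    """Remove measurement noise from an observed MAD ratio.

    ``se_m``/``se_s`` are the (root-mean-square) standard errors of the
    per-voxel beta differences entering each map.  Uses the Gaussian identity
    E[MAD]^2 = (2/pi) * variance; variances below the noise floor clip to 0.
    """
    var_m = max((np.pi / 2) * mad_m ** 2 - se_m ** 2, 0.0)
    var_s = max((np.pi / 2) * mad_s ** 2 - se_s ** 2, 0.0)
    if var_s == 0:
        raise ValueError("physical-shift map variance at or below noise floor")
    return float(np.sqrt(var_m / var_s))
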