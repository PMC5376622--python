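"""Synthetic multi-participant fMRI datasets with known ground truth.

The generator emulates the block design of the scanner experiment — per run,
randomly interleaved 12-s blocks of six conditions (motion-shift CLW-M/CCW-M
seven repetitions each; physical-shift CLW-S/CCW-S, motion-alone and fixation
four each) book-ended by 2 fixation TRs, 184 TRs of 2 s per run, 10 runs per
participant, 7 participants.

The encoding hypothesis is planted directly in the condition betas: each
participant carries a zero-mean spatial pattern ``P_v`` (the physical-shift
signature) and the motion-shift difference is ``kappa * P_v`` plus
independent pattern noise.  ``kappa`` is the per-ROI ground-truth "perceived
position encoding fraction", the analogue of the perceptual/physical fMRI
effect-size ratio; the default 0.2 puts the simulation in the empirically
reported ~20% regime.  Full BOLD time series add HRF-convolved block
responses, per-run polynomial drift, motion-coupled nuisance signal with
seeded spike artifacts, and Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .glm import ExperimentSchedule, build_design
from .stimulus import CONDITIONS, AdjustmentSession, EffectSize, effect_size_from_adjustments

DEFAULT_REPS = {"CLW-M": 7, "CCW-M": 7, "CLW-S": 4, "CCW-S": 4, "M": 4, "F": 4}


@dataclass(frozen=True)
class ROISpec:
    """A synthetic ROI: compact blob of ``n_voxels`` with encoding fraction
    ``kappa`` and a response-amplitude multiplier."""

    name: str
    n_voxels: int
    kappa: float
    amp_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and noise parameters of the simulation.

    Defaults reproduce the experiment's structure; ROI sizes echo the
    reported average V1 (264 voxels).  ``noise_sd`` (time-series units,
    relative to unit mean response amplitude) and the exponential amplitude
    distribution are set so that Bonferroni voxel selection retains roughly
    40-50% of ROI voxels, matching the reported retention regime.
    """

    n_participants: int = 7
    n_runs: int = 10
    n_trs_per_run: int = 184
    tr: float = 2.0
    block_len_s: float = 12.0
    reps: dict = field(default_factory=lambda: dict(DEFAULT_REPS))
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    roi_specs: tuple[ROISpec, ...] = (
        ROISpec("V1", 264, kappa=0.2),
        ROISpec("hMT", 264, kappa=0.0),
    )
    amp_mean: float = 1.0            # exponential mean of voxel response amplitude
    motion_amp_ratio: float = 1.0    # motion-condition amplitude relative to flash
    pattern_sd: float = 1.0          # sd of the physical-shift pattern P_v
    pattern_noise_sd: float = 0.15   # sd of the motion-map pattern noise eta_v
    noise_sd: float = 2.4            # i.i.d. Gaussian time-series noise
    noise_ar1: float = 0.0           # optional AR(1) coefficient of the noise
    drift_sd: float = 1.0            # sd of per-run Legendre drift coefficients
    motion_walk_sd: float = 0.02     # random-walk step sd of motion params
    motion_spike_rate: float = 0.055 # per-TR probability of a movement spike
    motion_spike_amplitude: float = 0.6  # spike step size (> censor threshold)
    motion_coupling_sd: float = 0.2  # sd of voxelwise motion-coupled signal
    gm_prob: float = 0.85            # per-voxel gray-matter membership prob
    shift_mean_deg: float = 12.5     # psychophysics: mean perceived shift
    shift_between_sd: float = 3.0    #   between-participant sd
    shift_direction_sd: float = 1.0  #   CLW/CCW asymmetry sd
    shift_within_sd: float = 1.5     #   between-adjustment sd

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        block_trs = self.block_len_s / self.tr
        if abs(block_trs - round(block_trs)) > 1e-9:
            raise ValueError("block length must be a whole number of TRs")
        total = sum(self.reps.values()) * int(round(block_trs)) + 4
        if total != self.n_trs_per_run:
            raise ValueError(
                f"block TRs + 4 boundary fixation TRs = {total}, "
                f"but n_trs_per_run = {self.n_trs_per_run}"
            )

    @property
    def n_grid(self) -> int:
        return int(np.prod(self.grid_shape))


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

def build_schedule(config: SyntheticConfig, rng: np.random.Generator | int | None = None
                   ) -> ExperimentSchedule:
    """Seeded random block order per run, 2 fixation TRs at start and end."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    boundary_s = 2 * config.tr
    labels = [c for c, k in config.reps.items() for _ in range(k)]
    for run in range(config.n_runs):
        order = [labels[i] for i in rng.permutation(len(labels))]
        rows.append({"run": run, "onset_s": 0.0, "duration_s": boundary_s,
                     "condition": "F"})
        t = boundary_s
        for cond in order:
            rows.append({"run": run, "onset_s": t, "duration_s": config.block_len_s,
                         "condition": cond})
            t += config.block_len_s
        rows.append({"run": run, "onset_s": t, "duration_s": boundary_s,
                     "condition": "F"})
    return ExperimentSchedule(tr=config.tr, n_runs=config.n_runs,
                              n_trs_per_run=config.n_trs_per_run,
                              blocks=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ROI geometry and gray matter
# ---------------------------------------------------------------------------

def _grid_coords(grid_shape: tuple[int, int, int]) -> np.ndarray:
    return np.indices(grid_shape).reshape(3, -1).T.astype(float)


def place_rois(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Deterministic compact, pairwise-disjoint ROI blobs on the grid.

    Centers are spread along the grid diagonal; each ROI takes its
    ``n_voxels`` nearest untaken voxels (Euclidean, voxel units).
    """
    coords = _grid_coords(config.grid_shape)
    n_rois = len(config.roi_specs)
    if sum(s.n_voxels for s in config.roi_specs) > config.n_grid:
        raise ValueError("ROIs do not fit on the grid")
    taken = np.zeros(config.n_grid, dtype=bool)
    out: dict[str, np.ndarray] = {}
    lo, hi = 0.2, 0.8
    for i, spec in enumerate(config.roi_specs):
        frac = lo + (hi - lo) * (i / max(n_rois - 1, 1)) if n_rois > 1 else 0.5
        center = frac * (np.array(config.grid_shape) - 1)
        d = np.linalg.norm(coords - center, axis=1)
        d[taken] = np.inf
        idx = np.argsort(d, kind="stable")[: spec.n_voxels]
        taken[idx] = True
        out[spec.name] = np.sort(idx)
    return out


def generate_gray_matter_mask(config: SyntheticConfig,
                              rng: np.random.Generator | int | None = None,
                              roi_voxels: dict[str, np.ndarray] | None = None,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant gray-matter masks and the shared (>=4 presence) mask.

    Returns ``(masks, shared)`` with ``masks`` boolean of shape
    (n_participants, n_grid).  A voxel enters the shared mask only if present
    in at least four individual masks; ROI voxels are present in every mask.
    """
    if config.n_participants < 4:
        raise ValueError("the shared-mask rule needs at least 4 participants")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    masks = rng.random((config.n_participants, config.n_grid)) < config.gm_prob
    if roi_voxels is None:
        roi_voxels = place_rois(config)
    for idx in roi_voxels.values():
        masks[:, idx] = True
    shared = masks.sum(axis=0) >= 4
    return masks, shared


# ---------------------------------------------------------------------------
# Betas and time series
# ---------------------------------------------------------------------------

@dataclass
class ParticipantTruth:
    """Ground truth behind one participant's betas."""

    pattern: np.ndarray          # P_v, the physical-shift difference map
    motion_pattern: np.ndarray   # kappa_v * P_v + eta_v
    amp: np.ndarray              # flash response amplitude per voxel


def kappa_map(config: SyntheticConfig, roi_voxels: dict[str, np.ndarray]) -> np.ndarray:
    k = np.zeros(config.n_grid)
    for spec in config.roi_specs:
        k[roi_voxels[spec.name]] = spec.kappa
    return k


def generate_betas(config: SyntheticConfig,
                   rng: np.random.Generator | int | None = None,
                   roi_voxels: dict[str, np.ndarray] | None = None,
                   ) -> tuple[np.ndarray, ParticipantTruth]:
    """Condition betas (n_grid, 6) for one participant.

    Construction (per voxel v):
      - physical-shift difference  beta(CLW-S) - beta(CCW-S) = P_v,
        with P_v ~ N(0, pattern_sd^2) zero-mean over voxels;
      - motion-shift difference    beta(CLW-M) - beta(CCW-M)
        = kappa_v P_v + eta_v,  eta_v ~ N(0, pattern_noise_sd^2);
      - all stimulus conditions ride on a positive response amplitude
        amp_v ~ Exp(amp_mean) so responsive voxels exceed fixation (beta=0).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if roi_voxels is None:
        roi_voxels = place_rois(config)
    n = config.n_grid
    amp = rng.exponential(config.amp_mean, size=n)
    for spec in config.roi_specs:
        amp[roi_voxels[spec.name]] *= spec.amp_scale
    pattern = rng.normal(0.0, config.pattern_sd, size=n)
    eta = rng.normal(0.0, config.pattern_noise_sd, size=n)
    motion_pattern = kappa_map(config, roi_voxels) * pattern + eta
    amp_m = config.motion_amp_ratio * amp
    betas = np.zeros((n, len(CONDITIONS)))
    cols = {c: i for i, c in enumerate(CONDITIONS)}
    betas[:, cols["CLW-M"]] = amp_m + motion_pattern / 2
    betas[:, cols["CCW-M"]] = amp_m - motion_pattern / 2
    betas[:, cols["CLW-S"]] = amp + pattern / 2
    betas[:, cols["CCW-S"]] = amp - pattern / 2
    betas[:, cols["M"]] = amp_m
    # fixation stays 0
    return betas, ParticipantTruth(pattern=pattern, motion_pattern=motion_pattern, amp=amp)


def generate_motion_params(config: SyntheticConfig, rng: np.random.Generator
                           ) -> np.ndarray:
    """Random-walk motion parameters with seeded spike artifacts.

    Spikes are permanent step changes of ``motion_spike_amplitude`` (exceeding
    the 0.3 censoring threshold by construction) in one random parameter;
    each run starts at a fresh offset (a between-run shift that censoring
    must ignore).
    """
    total = config.n_runs * config.n_trs_per_run
    steps = rng.normal(0.0, config.motion_walk_sd, size=(total, 6))
    for r in range(config.n_runs):
        steps[r * config.n_trs_per_run] = rng.normal(0.0, 0.2, size=6)
    spikes = rng.random(total) < config.motion_spike_rate
    spikes[[r * config.n_trs_per_run for r in range(config.n_runs)]] = False
    for k in np.flatnonzero(spikes):
        j = rng.integers(6)
        steps[k, j] += config.motion_spike_amplitude * rng.choice([-1.0, 1.0])
    return np.cumsum(steps, axis=0)


def generate_timeseries(betas: np.ndarray, schedule: ExperimentSchedule,
                        config: SyntheticConfig, rng: np.random.Generator | int | None = None,
                        motion_params: np.ndarray | None = None) -> np.ndarray:
    """Forward model: Y = X_cond beta + drift + motion coupling + noise.

    The condition regressors come from the same design constructor the GLM
    uses, so a noiseless simulation is exactly refittable.  Returns
    ``Y`` of shape (n_voxels, total_trs).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    betas = np.asarray(betas, dtype=float)
    design = build_design(schedule)  # condition + polynomial columns
    cond_cols = [design.condition_cols[c] for c in CONDITIONS]
    Xc = design.X[:, cond_cols]
    if betas.shape[1] != len(CONDITIONS):
        raise ValueError("betas must have one column per condition")
    total = schedule.total_trs
    n_vox = betas.shape[0]
    Y = betas @ Xc.T
    # per-run polynomial drift, voxel-specific coefficients
    from .glm import legendre_baselines

    base = legendre_baselines(schedule.n_trs_per_run, 3)
    for r in range(schedule.n_runs):
        coefs = rng.normal(0.0, config.drift_sd, size=(n_vox, 4))
        sl = slice(r * schedule.n_trs_per_run, (r + 1) * schedule.n_trs_per_run)
        Y[:, sl] += coefs @ base.T
    # motion-coupled nuisance
    if motion_params is not None and config.motion_coupling_sd > 0:
        coupling = rng.normal(0.0, config.motion_coupling_sd, size=n_vox)
        Y += np.outer(coupling, motion_params[:, 0])
    # Gaussian noise, optionally AR(1)
    if config.noise_sd > 0:
        eps = rng.normal(0.0, config.noise_sd, size=(n_vox, total))
        if config.noise_ar1:
            rho = config.noise_ar1
            for t in range(1, total):
                eps[:, t] = rho * eps[:, t - 1] + np.sqrt(1 - rho ** 2) * eps[:, t]
        Y += eps
    return Y


# ---------------------------------------------------------------------------
# Psychophysics
# ---------------------------------------------------------------------------

def generate_adjustments(config: SyntheticConfig, rng: np.random.Generator | int | None = None
                         ) -> list[AdjustmentSession]:
    """Synthetic adjustment-task data: 3 settings per direction per participant."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sessions = []
    for p in range(config.n_participants):
        pid = f"sub-{p + 1:02d}"
        base = rng.normal(config.shift_mean_deg, config.shift_between_sd)
        for cond, sign in (("CLW", 1.0), ("CCW", -1.0)):
            mag = max(base + rng.normal(0.0, config.shift_direction_sd), 1.0)
            adj = tuple(sign * (mag + rng.normal(0.0, config.shift_within_sd))
                        for _ in range(3))
            sessions.append(AdjustmentSession(
                participant_id=pid, condition=cond, adjustments=adj,
                initial_offset=float(rng.uniform(-20.0, 20.0))))
    return sessions


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class ParticipantData:
    participant_id: str
    schedule: ExperimentSchedule
    gm_mask: np.ndarray                      # boolean over the grid
    betas_true: np.ndarray | None = None     # (n_grid, 6)
    truth: ParticipantTruth | None = None
    bold: np.ndarray | None = None           # (n_grid, total_trs)
    motion_params: np.ndarray | None = None  # (total_trs, 6)
    effect_size: EffectSize | None = None


@dataclass
class VoxelDataset:
    """Everything the pipeline consumes, for all participants on one grid.

    Voxel arrays are indexed by flat (C-order) grid position; ``roi_voxels``
    maps ROI name to flat indices, ``shared_mask`` is the >=4-participant
    gray-matter mask used by the random-cluster control.
    """

    config: SyntheticConfig
    grid_shape: tuple[int, int, int]
    roi_voxels: dict[str, np.ndarray]
    kappa: dict[str, float]
    shared_mask: np.ndarray
    participants: list[ParticipantData]
    sessions: list[AdjustmentSession] = field(default_factory=list)

    @property
    def n_grid(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]


def generate_dataset(config: SyntheticConfig | None = None, seed: int | None = 0,
                     timeseries: bool = True) -> VoxelDataset:
    """Generate a complete, seeded multi-participant dataset.

    With ``timeseries=False`` only the ground-truth betas are produced (the
    fast path for beta-level analyses); otherwise full BOLD runs plus motion
    parameters are simulated per participant.
    """
    config = config or SyntheticConfig()
    master = np.random.default_rng(seed)
    roi_voxels = place_rois(config)
    gm_rng, psy_rng, *p_rngs = master.spawn(2 + config.n_participants)
    masks, shared = generate_gray_matter_mask(config, gm_rng, roi_voxels)
    sessions = generate_adjustments(config, psy_rng)
    effects = {e.participant_id: e for e in effect_size_from_adjustments(sessions)}
    participants = []
    for p, rng in enumerate(p_rngs):
        pid = f"sub-{p + 1:02d}"
        schedule = build_schedule(config, rng)
        betas, truth = generate_betas(config, rng, roi_voxels)
        bold = motion = None
        if timeseries:
            motion = generate_motion_params(config, rng)
            bold = generate_timeseries(betas, schedule, config, rng, motion)
        participants.append(ParticipantData(
            participant_id=pid, schedule=schedule, gm_mask=masks[p],
            betas_true=betas, truth=truth, bold=bold, motion_params=motion,
            effect_size=effects[pid]))
    return VoxelDataset(config=config, grid_shape=config.grid_shape,
                        roi_voxels=roi_voxels,
                        kappa={s.name: s.kappa for s in config.roi_specs},
                        shared_mask=shared, participants=participants,
                        sessions=sessions)


def small_config(**overrides) -> SyntheticConfig:
    """A reduced-size configuration for quick simulations and tests.

    2 runs of 88 TRs (14 six-TR blocks + boundary fixation), a 6x6x6 grid
    with two 40-voxel ROIs.  ``noise_sd`` is scaled down with the shorter
    session so that per-beta standard errors — and hence voxel-selection
    retention — stay in the same regime as the full-size design.
    """
    base = dict(
        n_participants=7, n_runs=2, n_trs_per_run=88,
        reps={"CLW-M": 3, "CCW-M": 3, "CLW-S": 2, "CCW-S": 2, "M": 2, "F": 2},
        grid_shape=(6, 6, 6),
        roi_specs=(ROISpec("V1", 40, kappa=0.2), ROISpec("hMT", 40, kappa=0.0)),
        noise_sd=0.8,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
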