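"""Permutation null via condition-label shuffling, and group-level tests.

The per-participant null distribution is built by shuffling the block labels
of the two motion-shift conditions (CLW-M / CCW-M) within each run — leaving
every other condition, the censoring and all nuisance regressors untouched —
refitting the GLM, recomputing the motion difference map, and correlating it
against the *observed* physical-shift map.  Because only the assignment of
blocks to the two motion columns changes, the refit reduces, by the
Frisch-Waugh-Lovell theorem, to a two-regressor problem after projecting out
the fixed columns once; this shortcut is exact and is the default.  A literal
full-refit path (``method="refit"``) is kept for verification.

Group level: (a) a bootstrap over participants of (observed z' minus a
randomly drawn shuffled z'), with p the fraction of mean differences below
zero; (b) a one-tailed paired t-test of observed z' against each
participant's null mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import (DesignMatrix, ExperimentSchedule, block_regressors,
                  build_design, censor_trs, fit_glm)
from .mvpa import fisher_z
from .stimulus import MOTION_SHIFT_CONDITIONS, t_to_p


@dataclass
class NullDistribution:
    """Shuffled-label correlation null for one participant and ROI."""

    participant_id: str
    roi: str
    z: np.ndarray                # one Fisher z' per permutation
    observed_z: float
    p: float                     # proportion of shuffled z >= observed
    n_perms: int
    seed: int | None = None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.z))


def shuffle_motion_labels(schedule: ExperimentSchedule,
                          rng: np.random.Generator | int | None = None
                          ) -> ExperimentSchedule:
    """Randomly reassign CLW-M/CCW-M block labels within each run.

    Per-run label counts are preserved; all other conditions are untouched.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    blocks = schedule.blocks.copy()
    motion = blocks["condition"].isin(MOTION_SHIFT_CONDITIONS)
    for run in blocks.loc[motion, "run"].unique():
        rows = blocks.index[motion & (blocks["run"] == run)]
        labels = blocks.loc[rows, "condition"].to_numpy()
        blocks.loc[rows, "condition"] = labels[rng.permutation(len(labels))]
    return schedule.with_blocks(blocks)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

class _MotionRelabeler:
    """Precomputed state for fast label-permutation refits of one session.

    Projects the per-block motion-shift regressors and the data onto the
    orthogonal complement of all fixed columns (other conditions, per-run
    polynomials, motion regressors) on the retained TRs, then each relabeling
    needs only a 2x2 solve.
    """

    def __init__(self, Y: np.ndarray, schedule: ExperimentSchedule,
                 motion_params: np.ndarray | None = None,
                 censored: np.ndarray | None = None,
                 censor_threshold: float = 0.3):
        Y = np.asarray(Y, dtype=float)
        design = build_design(schedule, motion_params)
        if censored is None and motion_params is not None:
            censored = censor_trs(motion_params,
                                  [schedule.n_trs_per_run] * schedule.n_runs,
                                  censor_threshold)
        keep = slice(None) if censored is None else ~np.asarray(censored, dtype=bool)
        R, info = block_regressors(schedule, list(MOTION_SHIFT_CONDITIONS))
        fixed_cols = [j for name, j in
                      ((n, i) for i, n in enumerate(design.names))
                      if name not in MOTION_SHIFT_CONDITIONS]
        Xf = design.X[keep][:, fixed_cols]
        Rk = R[keep]
        Yk = Y[:, keep] if censored is not None else Y
        # residualize against the fixed columns (SVD-based projection)
        coef_R, *_ = np.linalg.lstsq(Xf, Rk, rcond=None)
        Rt = Rk - Xf @ coef_R
        coef_Y, *_ = np.linalg.lstsq(Xf, Yk.T, rcond=None)
        Yt = Yk.T - Xf @ coef_Y            # (T_kept, n_vox)
        self.block_runs = info["run"].to_numpy()
        self.block_labels = info["condition"].to_numpy()
        self.G = Rt.T @ Rt                  # (n_blocks, n_blocks)
        self.C = Rt.T @ Yt                  # (n_blocks, n_vox)
        self.design = design
        self.censored = censored

    def difference_map(self, labels: np.ndarray) -> np.ndarray:
        """beta(CLW-M) - beta(CCW-M) per voxel under a block labeling."""
        a = labels == "CLW-M"
        b = ~a
        G = np.array([[self.G[np.ix_(a, a)].sum(), self.G[np.ix_(a, b)].sum()],
                      [self.G[np.ix_(b, a)].sum(), self.G[np.ix_(b, b)].sum()]])
        rhs = np.vstack([self.C[a].sum(axis=0), self.C[b].sum(axis=0)])
        beta = np.linalg.solve(G, rhs)
        return beta[0] - beta[1]

    def permuted_labels(self, rng: np.random.Generator) -> np.ndarray:
        labels = self.block_labels.copy()
        for run in np.unique(self.block_runs):
            rows = np.flatnonzero(self.block_runs == run)
            labels[rows] = labels[rows[rng.permutation(len(rows))]]
        return labels

    def all_labelings(self):
        """Every distinct within-run relabeling (for exhaustive enumeration)."""
        per_run = []
        runs = np.unique(self.block_runs)
        for run in runs:
            rows = np.flatnonzero(self.block_runs == run)
            n_clw = int((self.block_labels[rows] == "CLW-M").sum())
            per_run.append([set(c) for c in itertools.combinations(rows, n_clw)])
        for combo in itertools.product(*per_run):
            chosen = set().union(*combo) if combo else set()
            labels = np.array(["CLW-M" if i in chosen else "CCW-M"
                               for i in range(len(self.block_labels))])
            yield labels


def _corr_z(dm: np.ndarray, ds_centered: np.ndarray, ds_norm: float) -> float:
    dmc = dm - dm.mean()
    denom = np.linalg.norm(dmc) * ds_norm
    if denom == 0:
        return float("nan")
    r = float(np.clip(dmc @ ds_centered / denom, -1 + 1e-12, 1 - 1e-12))
    return float(np.arctanh(r))


def permutation_null(Y_sel: np.ndarray, schedule: ExperimentSchedule,
                     ds_values: np.ndarray,
                     motion_params: np.ndarray | None = None,
                     censored: np.ndarray | None = None,
                     n_perms: int = 1000,
                     rng: np.random.Generator | int | None = None,
                     method: str = "fwl",
                     exhaustive: bool = False,
                     smoothed: bool = False,
                     participant_id: str = "", roi: str = "") -> NullDistribution:
    """Shuffled-label null distribution of difference-map correlations.

    Parameters
    ----------
    Y_sel
        BOLD time series (n_selected_voxels, total_trs) of the voxels that
        survived selection — selection is label-agnostic (it only involves
        physical-shift and fixation regressors) and is therefore computed
        once from the unshuffled data and held fixed here.
    ds_values
        The *observed* physical-shift difference map over the same voxels.
    method
        ``"fwl"`` (fast exact shortcut, default) or ``"refit"`` (literal full
        GLM refit per permutation; identical results, for verification).
    exhaustive
        Enumerate every distinct within-run labeling instead of sampling
        (small designs only).
    smoothed
        Use the add-one estimate (1 + #{z >= obs}) / (1 + n) instead of the
        raw proportion.

    The returned ``p`` is the proportion of shuffled z' at or above the
    observed z'; a value of 0 should be read as "< 1/n_perms".
    """
    if n_perms < 1 and not exhaustive:
        raise ValueError("n_perms must be >= 1")
    if not any(schedule.blocks["condition"].isin(MOTION_SHIFT_CONDITIONS)):
        raise ValueError("schedule contains no motion-shift blocks")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ds_values = np.asarray(ds_values, dtype=float)
    ds_c = ds_values - ds_values.mean()
    ds_n = float(np.linalg.norm(ds_c))

    state = _MotionRelabeler(Y_sel, schedule, motion_params, censored)

    if method == "fwl":
        def dm_for(labels: np.ndarray) -> np.ndarray:
            return state.difference_map(labels)
    elif method == "refit":
        def dm_for(labels: np.ndarray) -> np.ndarray:
            blocks = schedule.blocks.copy()
            motion_rows = blocks.index[blocks["condition"].isin(MOTION_SHIFT_CONDITIONS)]
            blocks.loc[motion_rows, "condition"] = labels
            design = build_design(schedule.with_blocks(blocks), motion_params)
            res = fit_glm(Y_sel, design, censored=state.censored)
            return res.condition_betas("CLW-M") - res.condition_betas("CCW-M")
    else:
        raise ValueError("method must be 'fwl' or 'refit'")

    observed_z = _corr_z(dm_for(state.block_labels), ds_c, ds_n)
    if exhaustive:
        zs = np.array([_corr_z(dm_for(lab), ds_c, ds_n)
                       for lab in state.all_labelings()])
    else:
        zs = np.array([_corr_z(dm_for(state.permuted_labels(rng)), ds_c, ds_n)
                       for _ in range(n_perms)])
    k = int(np.sum(zs >= observed_z))
    p = (1 + k) / (1 + len(zs)) if smoothed else k / len(zs)
    return NullDistribution(participant_id=participant_id, roi=roi, z=zs,
                            observed_z=float(observed_z), p=float(p),
                            n_perms=len(zs))


# ---------------------------------------------------------------------------
# Group-level inference
# ---------------------------------------------------------------------------

@dataclass
class GroupInference:
    """Both group-level significance procedures for one ROI."""

    roi: str
    participant_ids: list[str]
    observed_z: np.ndarray
    null_mean_z: np.ndarray
    bootstrap_p: float
    boot_diffs: np.ndarray
    t: float
    df: int
    t_p: float                   # one-tailed (positive direction)


def bootstrap_group(observed_z: np.ndarray, nulls: list[NullDistribution],
                    n_boot: int = 1000,
                    rng: np.random.Generator | int | None = None
                    ) -> tuple[float, np.ndarray]:
    """Bootstrap of the mean over participants of (observed z' - drawn null z').

    Each iteration draws one sample from every participant's shuffled-z'
    distribution, subtracts it from that participant's observed z', and
    averages across participants; ``p`` is the fraction of the ``n_boot``
    mean differences that fall below zero (0 reads as "< 1/n_boot").
    """
    observed_z = np.asarray(observed_z, dtype=float)
    if len(observed_z) != len(nulls):
        raise ValueError("one null distribution per participant is required")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws = np.column_stack([nd.z[rng.integers(0, len(nd.z), size=n_boot)]
                             for nd in nulls])
    diffs = (observed_z[None, :] - draws).mean(axis=1)
    return float(np.mean(diffs < 0)), diffs


def paired_t_group(observed_z: np.ndarray, null_means: np.ndarray
                   ) -> tuple[float, int, float]:
    """One-tailed paired t-test of observed z' vs. per-participant null mean.

    Returns ``(t, df, one_tailed_p)``.  All-zero differences give t = 0,
    p = 0.5; nonzero constant differences (zero variance) are degenerate and
    raise.
    """
    observed_z = np.asarray(observed_z, dtype=float)
    null_means = np.asarray(null_means, dtype=float)
    if len(observed_z) < 2:
        raise ValueError("need at least 2 participants")
    d = observed_z - null_means
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, len(d) - 1, 0.5
        raise ValueError("zero variance of differences (degenerate t-test)")
    t = float(stats.ttest_rel(observed_z, null_means).statistic)
    df = len(d) - 1
    return t, df, t_to_p(t, df, tail="greater")


def group_inference(roi: str, nulls: list[NullDistribution],
                    n_boot: int = 1000,
                    rng: np.random.Generator | int | None = None) -> GroupInference:
    """Run both group tests from the per-participant null distributions."""
    valid = [nd for nd in nulls if np.isfinite(nd.observed_z)]
    if len(valid) < 2:
        raise ValueError("need at least 2 participants with valid correlations")
    observed = np.array([nd.observed_z for nd in valid])
    null_means = np.array([nd.null_mean for nd in valid])
    boot_p, diffs = bootstrap_group(observed, valid, n_boot=n_boot, rng=rng)
    t, df, t_p = paired_t_group(observed, null_means)
    return GroupInference(roi=roi,
                          participant_ids=[nd.participant_id for nd in valid],
                          observed_z=observed, null_mean_z=null_means,
                          bootstrap_p=boot_p, boot_diffs=diffs,
                          t=t, df=df, t_p=t_p)
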