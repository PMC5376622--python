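"""Block-design GLM: design matrix, motion censoring, OLS fit, contrasts.

The model for each voxel's time series is

    y = X b + e,   X = [condition regressors | per-run polynomials | motion]

with six condition regressors (HRF-convolved 12-s boxcars for CLW-M, CCW-M,
CLW-S, CCW-S, M, F), four Legendre polynomial baseline regressors per run
(constant, linear, quadratic, cubic) and six head-motion nuisance regressors
spanning all runs.  TRs whose motion-derivative Euclidean norm exceeds a
threshold are censored (together with the preceding TR) by row deletion
before the ordinary-least-squares fit.

Fixation is modeled explicitly as the sixth condition even though the blocks
tile the whole run; the resulting near-collinearity with the run constants is
confined to the overall-mean direction and all analysis contrasts are
condition differences, which remain well conditioned.  OLS is solved by SVD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus import CONDITIONS

#: Contrast weights over the six conditions for the voxel-selection test
#: (mean physical-shift response vs. fixation).
SELECTION_CONTRAST = {"CLW-S": 0.5, "CCW-S": 0.5, "F": -1.0}
#: All stimulus conditions vs. fixation (the SNR metric of the controls).
SNR_CONTRAST = {"CLW-M": 0.2, "CCW-M": 0.2, "CLW-S": 0.2, "CCW-S": 0.2,
                "M": 0.2, "F": -1.0}


# ---------------------------------------------------------------------------
# Experiment schedule
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSchedule:
    """Block/condition structure of a session: one row per block.

    ``blocks`` has columns ``run`` (0-based), ``onset_s`` (within-run, 0-based
    seconds), ``duration_s`` and ``condition``.  Runs are ``n_trs_per_run``
    TRs each and concatenate in order into the session time axis.
    """

    tr: float
    n_runs: int
    n_trs_per_run: int
    blocks: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"run", "onset_s", "duration_s", "condition"}
        if not required.issubset(self.blocks.columns):
            raise ValueError(f"blocks must have columns {sorted(required)}")
        bad = set(self.blocks["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s) {sorted(bad)}")
        run_len_s = self.n_trs_per_run * self.tr
        for run, grp in self.blocks.groupby("run"):
            g = grp.sort_values("onset_s")
            ends = (g["onset_s"] + g["duration_s"]).to_numpy()
            if (g["onset_s"].to_numpy() < -1e-9).any() or (ends > run_len_s + 1e-9).any():
                raise ValueError(f"run {run}: block outside the run")
            if (g["onset_s"].to_numpy()[1:] < ends[:-1] - 1e-9).any():
                raise ValueError(f"run {run}: overlapping blocks")

    @property
    def total_trs(self) -> int:
        return self.n_runs * self.n_trs_per_run

    def run_slices(self) -> list[slice]:
        n = self.n_trs_per_run
        return [slice(r * n, (r + 1) * n) for r in range(self.n_runs)]

    def with_blocks(self, blocks: pd.DataFrame) -> "ExperimentSchedule":
        return ExperimentSchedule(self.tr, self.n_runs, self.n_trs_per_run,
                                  blocks.reset_index(drop=True))

    def copy(self) -> "ExperimentSchedule":
        return self.with_blocks(self.blocks.copy())


# ---------------------------------------------------------------------------
# HRF and regressor construction
# ---------------------------------------------------------------------------

def double_gamma_hrf(dt: float, duration_s: float = 32.0,
                     peak_s: float = 5.0, undershoot_s: float = 15.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalized.

    Gamma shapes are chosen so the response peaks at ``peak_s`` and the
    undershoot troughs at ``undershoot_s`` (both seconds); sampled every
    ``dt`` seconds over ``duration_s``.
    """
    t = np.arange(0, duration_s, dt)
    # gamma pdf mode = (a - 1) * scale; scale fixed at 1 s
    peak = stats.gamma.pdf(t, a=peak_s + 1.0, scale=1.0)
    under = stats.gamma.pdf(t, a=undershoot_s + 1.0, scale=1.0)
    h = peak - undershoot_ratio * under
    return h / h.max()


def convolved_boxcar(onset_s: float, duration_s: float, n_trs: int, tr: float,
                     oversample: int = 10, hrf: np.ndarray | None = None) -> np.ndarray:
    """HRF-convolved boxcar regressor for one block, sampled at TR onsets."""
    dt = tr / oversample
    if hrf is None:
        hrf = double_gamma_hrf(dt)
    n_fine = n_trs * oversample
    x = np.zeros(n_fine)
    i0 = int(round(onset_s / dt))
    i1 = int(round((onset_s + duration_s) / dt))
    x[max(i0, 0):min(i1, n_fine)] = 1.0
    # normalize to unit sustained response so betas are in signal units
    y = np.convolve(x, hrf / hrf.sum())[:n_fine]
    return y[::oversample].copy()


def block_regressors(schedule: ExperimentSchedule, conditions: list[str] | None = None,
                     oversample: int = 10) -> tuple[np.ndarray, pd.DataFrame]:
    """One HRF-convolved column per block, over the session time axis.

    Returns ``(R, info)`` where ``R`` is (total_trs, n_blocks) and ``info``
    echoes the block rows used (run, onset, duration, condition).  These are
    the building bricks of both the condition regressors (their per-condition
    sums) and the fast label-permutation refits.
    """
    blocks = schedule.blocks
    if conditions is not None:
        blocks = blocks[blocks["condition"].isin(conditions)]
    blocks = blocks.reset_index(drop=True)
    dt = schedule.tr / oversample
    hrf = double_gamma_hrf(dt)
    R = np.zeros((schedule.total_trs, len(blocks)))
    for j, row in blocks.iterrows():
        col = convolved_boxcar(row["onset_s"], row["duration_s"],
                               schedule.n_trs_per_run, schedule.tr,
                               oversample, hrf)
        sl = slice(int(row["run"]) * schedule.n_trs_per_run,
                   (int(row["run"]) + 1) * schedule.n_trs_per_run)
        R[sl, j] = col
    return R, blocks


def legendre_baselines(n_trs: int, max_order: int = 3) -> np.ndarray:
    """Within-run Legendre polynomial baselines, orders 0..max_order.

    Orthogonal within run by construction; same span as raw polynomials.
    """
    x = np.linspace(-1.0, 1.0, n_trs)
    return np.column_stack(
        [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(max_order + 1)]
    )


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Full-session design: condition + per-run polynomial + motion columns."""

    X: np.ndarray                 # (total_trs, p)
    names: list[str]
    condition_cols: dict[str, int]
    n_runs: int
    n_trs_per_run: int
    tr: float

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def condition_weights(self, weights: dict[str, float]) -> np.ndarray:
        """Expand a condition->weight mapping to a full contrast vector."""
        unknown = set(weights) - set(self.condition_cols)
        if unknown:
            raise ValueError(f"unknown condition(s) {sorted(unknown)}")
        w = np.zeros(self.n_params)
        for cond, wt in weights.items():
            w[self.condition_cols[cond]] = wt
        return w


def build_design(schedule: ExperimentSchedule,
                 motion_params: np.ndarray | None = None,
                 poly_order: int = 3, oversample: int = 10) -> DesignMatrix:
    """Build the GLM design matrix from a schedule and motion parameters.

    Columns: 6 HRF-convolved condition regressors, ``poly_order + 1``
    Legendre baselines per run, and (if given) 6 motion regressors spanning
    all runs — 6 + 4*n_runs + 6 = 52 columns for the default 10-run session.
    """
    if motion_params is not None and motion_params.shape[0] != schedule.total_trs:
        raise ValueError("motion parameters do not cover the schedule's TRs")
    R, info = block_regressors(schedule, oversample=oversample)
    cols: list[np.ndarray] = []
    names: list[str] = []
    condition_cols: dict[str, int] = {}
    for cond in CONDITIONS:
        mask = (info["condition"] == cond).to_numpy()
        condition_cols[cond] = len(cols)
        cols.append(R[:, mask].sum(axis=1))
        names.append(cond)
    base = legendre_baselines(schedule.n_trs_per_run, poly_order)
    for r in range(schedule.n_runs):
        for k in range(poly_order + 1):
            col = np.zeros(schedule.total_trs)
            col[r * schedule.n_trs_per_run:(r + 1) * schedule.n_trs_per_run] = base[:, k]
            cols.append(col)
            names.append(f"run{r}_poly{k}")
    if motion_params is not None:
        for j in range(motion_params.shape[1]):
            cols.append(np.asarray(motion_params[:, j], dtype=float))
            names.append(f"motion{j}")
    X = np.column_stack(cols)
    return DesignMatrix(X=X, names=names, condition_cols=condition_cols,
                        n_runs=schedule.n_runs, n_trs_per_run=schedule.n_trs_per_run,
                        tr=schedule.tr)


# ---------------------------------------------------------------------------
# Motion censoring
# ---------------------------------------------------------------------------

def censor_trs(motion_params: np.ndarray, run_lengths: list[int] | np.ndarray,
               threshold: float = 0.3) -> np.ndarray:
    """Censor mask from the Euclidean norm of the motion-parameter derivative.

    The derivative is the backward difference within each run (zero at run
    starts, so between-run shifts are ignored).  Whenever the norm strictly
    exceeds ``threshold`` at TR k, both TR k and TR k-1 are marked censored.

    Returns a boolean array, True = censored.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    motion_params = np.asarray(motion_params, dtype=float)
    if sum(run_lengths) != motion_params.shape[0]:
        raise ValueError("run lengths do not match motion-parameter rows")
    deriv = np.zeros_like(motion_params)
    start = 0
    for n in run_lengths:
        deriv[start + 1:start + n] = np.diff(motion_params[start:start + n], axis=0)
        start += n
    enorm = np.sqrt((deriv ** 2).sum(axis=1))
    censored = np.zeros(motion_params.shape[0], dtype=bool)
    hit = enorm > threshold
    censored[hit] = True
    censored[:-1] |= hit[1:]
    return censored


# ---------------------------------------------------------------------------
# OLS fit and contrasts
# ---------------------------------------------------------------------------

@dataclass
class GLMResult:
    """Per-voxel OLS estimates: rows of ``betas`` index voxels."""

    betas: np.ndarray             # (n_voxels, p)
    sigma2: np.ndarray            # (n_voxels,) residual variance, df-corrected
    df: int                       # retained TRs - rank(X)
    rank: int
    xtx_pinv: np.ndarray          # (p, p) pseudo-inverse of X'X on retained rows
    design: DesignMatrix
    censored: np.ndarray | None = None

    def condition_betas(self, condition: str) -> np.ndarray:
        return self.betas[:, self.design.condition_cols[condition]]


def _ar1_prewhiten(A: np.ndarray, rho: float, run_lengths: list[int]) -> np.ndarray:
    """Within-run AR(1) quasi-differencing along axis 0."""
    out = A.astype(float).copy()
    start = 0
    for n in run_lengths:
        out[start + 1:start + n] -= rho * A[start:start + n - 1]
        out[start] *= np.sqrt(1.0 - rho ** 2)
        start += n
    return out


def fit_glm(Y: np.ndarray, design: DesignMatrix,
            censored: np.ndarray | None = None,
            ar1_rho: float | None = None) -> GLMResult:
    """Ordinary-least-squares fit of every voxel (rows of Y) to the design.

    ``censored`` TRs are removed by row deletion before the fit; ``ar1_rho``
    optionally applies within-run AR(1) prewhitening (a sensitivity flag; the
    default analysis uses plain OLS) before censoring.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if np.isnan(Y).any():
        raise ValueError("NaNs in the data matrix")
    if Y.shape[1] != design.X.shape[0]:
        raise ValueError("data and design cover different numbers of TRs")
    X = design.X
    if ar1_rho is not None:
        run_lengths = [design.n_trs_per_run] * design.n_runs
        X = _ar1_prewhiten(X, ar1_rho, run_lengths)
        Y = _ar1_prewhiten(Y.T, ar1_rho, run_lengths).T
    if censored is not None:
        keep = ~np.asarray(censored, dtype=bool)
        X = X[keep]
        Yk = Y[:, keep]
    else:
        Yk = Y
    betas, _, rank, _ = np.linalg.lstsq(X, Yk.T, rcond=None)
    resid = Yk.T - X @ betas
    df = X.shape[0] - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid ** 2).sum(axis=0) / df
    # residuals at round-off level are an exact fit: clamp to zero so the
    # downstream t maps flag them as infinite rather than astronomically large
    floor = (Yk ** 2).sum(axis=1) * (1e3 * np.finfo(float).eps) ** 2
    sigma2[sigma2 <= floor] = 0.0
    xtx_pinv = np.linalg.pinv(X.T @ X)
    return GLMResult(betas=betas.T, sigma2=sigma2, df=df, rank=rank,
                     xtx_pinv=xtx_pinv, design=design, censored=censored)


def contrast_t(result: GLMResult, weights: np.ndarray | dict[str, float]) -> np.ndarray:
    """Per-voxel t map for a contrast ``w`` (vector, or condition->weight map).

    ``t = w'b / sqrt(sigma2 * w' (X'X)^+ w)``.  Voxels with zero residual
    variance and a nonzero effect are flagged with +/-inf; an all-zero
    contrast gives t = 0 everywhere.
    """
    if isinstance(weights, dict):
        w = result.design.condition_weights(weights)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != result.design.n_params:
            raise ValueError("contrast length does not match the regressor count")
    eff = result.betas @ w
    var = result.sigma2 * float(w @ result.xtx_pinv @ w)
    t = np.zeros_like(eff)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = var > 0
        t[pos] = eff[pos] / np.sqrt(var[pos])
        t[~pos] = np.where(eff[~pos] == 0, 0.0, np.sign(eff[~pos]) * np.inf)
    return t


def select_voxels(result: GLMResult, roi_rows: np.ndarray,
                  alpha: float = 0.01, correction_n: int | None = None,
                  contrast: dict[str, float] | None = None,
                  t_map: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Bonferroni-corrected one-tailed voxel selection within an ROI.

    Keeps ROI voxels whose selection-contrast t (default: mean physical shift
    > fixation) has one-tailed ``p < alpha / correction_n``.  ``correction_n``
    defaults to the ROI size; the pipeline passes the union size of all
    analyzed ROIs.  Returns ``(selected rows, retained fraction)``.
    """
    roi_rows = np.asarray(roi_rows)
    if roi_rows.size == 0:
        raise ValueError("empty ROI")
    if t_map is None:
        t_map = contrast_t(result, contrast or SELECTION_CONTRAST)
    if correction_n is None:
        correction_n = roi_rows.size
    t_roi = t_map[roi_rows]
    p = stats.t.sf(t_roi, result.df)
    keep = p < alpha / correction_n
    return roi_rows[keep], float(keep.mean())
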