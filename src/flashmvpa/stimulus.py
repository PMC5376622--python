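"""Flash Grab stimulus schedule and adjustment-task psychophysics.

The Flash Grab effect: a rotating sectored disc oscillates back and forth,
pausing briefly at each direction reversal.  A checkerboard flashed during the
pause is perceived as displaced in the direction of the *upcoming* motion, by
an amount that can exceed 10 degrees of rotation.  This module models the
frame-level stimulus timing (one flash per second in the motion-shift
conditions, 2 Hz flashes without motion in the physical-shift conditions) and
analyses the adjustment task that measures each participant's perceived shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: The six block conditions: clockwise/counter-clockwise motion-induced shift,
#: clockwise/counter-clockwise physical shift, motion alone, fixation alone.
CONDITIONS = ("CLW-M", "CCW-M", "CLW-S", "CCW-S", "M", "F")
MOTION_SHIFT_CONDITIONS = ("CLW-M", "CCW-M")
PHYSICAL_SHIFT_CONDITIONS = ("CLW-S", "CCW-S")


@dataclass(frozen=True)
class StimulusParams:
    """Geometry and timing of the oscillating-disc stimulus.

    Angles of the disc are in degrees of rotation; the display refresh drives
    all timing.  Defaults reproduce the scanner stimulus: 60 Hz refresh,
    2.30 deg rotation per frame, 60 deg nominal sweep between reversals,
    5-frame (~83 ms) stationary pause at every reversal, two reversals per
    second, checkerboard wedges centred on the four diagonal meridians.
    """

    refresh_rate: float = 60.0           # frames / s
    step: float = 2.30                   # deg rotation / frame
    sweep_extent: float = 60.0           # deg rotation between reversals (nominal)
    pause_frames: int = 5                # stationary frames at each reversal
    reversal_rate: float = 2.0           # reversals / s (governing constraint)
    flash_centers: tuple[float, ...] = (45.0, 135.0, 225.0, 315.0)
    disc_outer_radius: float = 8.5       # deg visual angle
    disc_inner_radius: float = 2.1       # deg visual angle
    first_sweep_deg: float = 45.0        # partial sweep before the first reversal

    def __post_init__(self) -> None:
        for name in ("refresh_rate", "step", "sweep_extent", "reversal_rate",
                     "disc_outer_radius", "disc_inner_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.pause_frames < 1:
            raise ValueError("pause_frames must be >= 1")
        if any(not (0 <= c < 360) for c in self.flash_centers):
            raise ValueError("flash_centers must lie in [0, 360)")

    @property
    def frames_per_half_cycle(self) -> int:
        """Frames from one reversal to the next, set by the reversal rate."""
        return int(round(self.refresh_rate / self.reversal_rate))

    @property
    def moving_frames_per_sweep(self) -> int:
        """Moving frames actually realized per sweep.

        The reversal rate is the governing constraint: each half-cycle is
        ``refresh_rate / reversal_rate`` frames of which ``pause_frames`` are
        stationary, so 25 moving frames (57.5 deg traversed) at the defaults.
        """
        n = self.frames_per_half_cycle - self.pause_frames
        if n < 1:
            raise ValueError("pause_frames leaves no moving frames per sweep")
        return n

    @property
    def pause_duration_s(self) -> float:
        """Stationary pause duration in seconds (~83 ms at the defaults)."""
        return self.pause_frames / self.refresh_rate


def nominal_sweep_frames(params: StimulusParams) -> int:
    """Moving frames implied by the nominal sweep extent alone.

    ``round(sweep_extent / step)`` = 26 at the defaults (59.8 deg traversed).
    The realized schedule trims this to :attr:`moving_frames_per_sweep` so
    that reversals occur at exactly ``reversal_rate`` per second.
    """
    return int(round(params.sweep_extent / params.step))


def build_frame_schedule(
    params: StimulusParams,
    condition: str,
    duration_s: float,
    rng: np.random.Generator | None = None,
    start_direction: int | None = None,
) -> pd.DataFrame:
    """Frame-by-frame stimulus table for one block of a condition.

    Parameters
    ----------
    condition
        One of ``CLW-M, CCW-M, CLW-S, CCW-S, M, F``.
    duration_s
        Block duration in seconds; must be a whole number of seconds.
    rng, start_direction
        The starting direction of motion is randomly assigned per run; pass
        either an explicit ``start_direction`` (+1 clockwise, -1
        counter-clockwise) or a generator to draw it.

    Returns
    -------
    DataFrame with columns ``frame``, ``time_s``, ``angle_deg`` (disc rotation
    relative to its start position), ``moving``, ``direction`` (+1/-1/0) and
    ``flash``.

    Notes
    -----
    Motion conditions: an initial partial sweep of ~``first_sweep_deg``
    followed by full sweeps, each half-cycle ending in a ``pause_frames``
    stationary pause at the reversal.  In motion-shift conditions the
    checkerboard is flashed during every pause that precedes motion in the
    named direction — exactly once per second.  Physical-shift conditions have
    no motion and flash at 2 Hz; ``M`` and ``F`` never flash.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if abs(duration_s - round(duration_s)) > 1e-9 or duration_s <= 0:
        raise ValueError("duration_s must be a positive whole number of seconds")

    n_frames = int(round(duration_s * params.refresh_rate))
    frames = np.arange(n_frames)
    angle = np.zeros(n_frames)
    moving = np.zeros(n_frames, dtype=bool)
    direction = np.zeros(n_frames, dtype=int)
    flash = np.zeros(n_frames, dtype=bool)

    has_motion = condition in ("CLW-M", "CCW-M", "M")
    half = params.frames_per_half_cycle
    pause = params.pause_frames

    if has_motion:
        if start_direction is None:
            rng = np.random.default_rng() if rng is None else rng
            start_direction = int(rng.choice([-1, 1]))
        if start_direction not in (-1, 1):
            raise ValueError("start_direction must be +1 or -1")
        first_moving = int(round(params.first_sweep_deg / params.step))
        full_moving = params.moving_frames_per_sweep
        # sweep index per frame; sweep 0 is the initial partial sweep
        a = 0.0
        f = 0
        sweep = 0
        while f < n_frames:
            n_move = first_moving if sweep == 0 else full_moving
            d = start_direction * (-1) ** sweep
            for _ in range(n_move):
                if f >= n_frames:
                    break
                a += d * params.step
                angle[f] = a
                moving[f] = True
                direction[f] = d
                f += 1
            # pause at the reversal; flash here if the *next* sweep moves in
            # the condition's direction (the Flash Grab pairs the flash with
            # the post-reversal motion direction)
            next_d = start_direction * (-1) ** (sweep + 1)
            want_flash = (
                (condition == "CLW-M" and next_d == 1)
                or (condition == "CCW-M" and next_d == -1)
            )
            for _ in range(pause):
                if f >= n_frames:
                    break
                angle[f] = a
                flash[f] = want_flash
                f += 1
            sweep += 1
    elif condition in PHYSICAL_SHIFT_CONDITIONS:
        # stationary disc, checkerboard flashed at 2 Hz in the same frame
        # slots the motion conditions use for their reversal pauses
        first_moving = int(round(params.first_sweep_deg / params.step))
        for k in range(int(2 * duration_s * params.reversal_rate)):
            start = first_moving + k * half
            flash[start : start + pause] = True
    # condition "F": nothing at all; "M" handled above with flash never set

    return pd.DataFrame(
        {
            "frame": frames,
            "time_s": frames / params.refresh_rate,
            "angle_deg": angle,
            "moving": moving,
            "direction": direction,
            "flash": flash,
        }
    )


def flash_count(schedule: pd.DataFrame) -> int:
    """Number of discrete flashes (contiguous runs of flash-on frames)."""
    on = schedule["flash"].to_numpy()
    starts = on & ~np.concatenate([[False], on[:-1]])
    return int(starts.sum())


# ---------------------------------------------------------------------------
# Psychophysics: adjustment task
# ---------------------------------------------------------------------------

@dataclass
class AdjustmentSession:
    """Three adjustment settings for one participant in one shift direction.

    ``condition`` is ``"CLW"`` or ``"CCW"``; ``adjustments`` are the final
    rotation offsets (degrees of rotation) at which the checkerboard appeared
    un-tilted, one per trial.  ``initial_offset`` records the random starting
    rotation (uniform in [-20, +20] deg) used to wash out response bias.
    """

    participant_id: str
    condition: str
    adjustments: tuple[float, float, float]
    initial_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.condition not in ("CLW", "CCW"):
            raise ValueError("condition must be 'CLW' or 'CCW'")
        if len(self.adjustments) != 3:
            raise ValueError("exactly 3 adjustments per (participant, condition)")


@dataclass
class EffectSize:
    """Per-participant motion-induced position shift, degrees of rotation.

    Stored signed (clockwise positive, counter-clockwise negative);
    magnitudes are used when comparing the two directions.
    """

    participant_id: str
    clw_shift: float
    ccw_shift: float

    @property
    def matched_shift_deg(self) -> float:
        """Direction-averaged magnitude, used to match the physical shift."""
        return (abs(self.clw_shift) + abs(self.ccw_shift)) / 2.0


def effect_size_from_adjustments(sessions: list[AdjustmentSession]) -> list[EffectSize]:
    """Average the three adjustments per condition into one effect size.

    Raises if any participant is missing one of the two directions.
    """
    by_pid: dict[str, dict[str, float]] = {}
    for s in sessions:
        by_pid.setdefault(s.participant_id, {})[s.condition] = float(
            np.mean(s.adjustments)
        )
    out = []
    for pid in sorted(by_pid):
        d = by_pid[pid]
        if set(d) != {"CLW", "CCW"}:
            missing = {"CLW", "CCW"} - set(d)
            raise ValueError(f"participant {pid}: missing condition(s) {missing}")
        out.append(EffectSize(pid, clw_shift=d["CLW"], ccw_shift=d["CCW"]))
    return out


def compare_directions(effects: list[EffectSize]) -> tuple[float, float]:
    """Paired t-test of |CLW| vs |CCW| shift magnitudes across participants.

    Returns ``(t, two_tailed_p)`` with ``df = n - 1``.
    """
    if len(effects) < 2:
        raise ValueError("need at least 2 participants for a paired t-test")
    clw = np.array([abs(e.clw_shift) for e in effects])
    ccw = np.array([abs(e.ccw_shift) for e in effects])
    d = clw - ccw
    if np.allclose(d, 0):
        return 0.0, 1.0
    res = stats.ttest_rel(clw, ccw)
    return float(res.statistic), float(res.pvalue)


def t_to_p(t: float, df: int, tail: str = "two") -> float:
    """p-value from a t statistic: ``tail`` is 'two', 'greater' or 'less'."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if tail == "two":
        return float(2.0 * stats.t.sf(abs(t), df))
    if tail == "greater":
        return float(stats.t.sf(t, df))
    if tail == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError("tail must be 'two', 'greater' or 'less'")
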