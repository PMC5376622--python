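"""Difference maps and within-ROI pattern correlation, the core statistic.

Subtracting the betas of the two motion-shift conditions (CLW-M - CCW-M)
cancels everything the two conditions share — identical flash positions and
identical background motion — leaving only the signature of the *perceived*
position shift.  The analogous physical-shift difference (CLW-S - CCW-S)
carries the signature of a real displacement.  An ROI that encodes perceived
position should show a positive voxel-wise Pearson correlation between the
two maps; correlations are Fisher z'-transformed for linear comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .glm import GLMResult

#: Fewer surviving voxels than this makes a correlation meaningless; such
#: ROIs/clusters are excluded from aggregation.
MIN_VOXELS = 3


@dataclass
class DifferenceMap:
    """Per-voxel beta difference beta(condA) - beta(condB) over chosen voxels."""

    roi: str
    voxel_rows: np.ndarray
    values: np.ndarray
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.voxel_rows) != len(self.values):
            raise ValueError("voxel list and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite difference values")


@dataclass
class CorrelationResult:
    """Pattern correlation between two difference maps within one ROI."""

    roi: str
    participant_id: str
    r: float
    z: float
    n_voxels: int
    valid: bool = True     # False when variance vanished or too few voxels


def difference_map(result: GLMResult, cond_a: str, cond_b: str,
                   voxel_rows: np.ndarray, roi: str = "") -> DifferenceMap:
    """Elementwise beta difference restricted to the selected voxels."""
    voxel_rows = np.asarray(voxel_rows)
    if voxel_rows.size == 0:
        raise ValueError("empty voxel selection")
    values = (result.condition_betas(cond_a) - result.condition_betas(cond_b))[voxel_rows]
    return DifferenceMap(roi=roi, voxel_rows=voxel_rows, values=values,
                         pair=(cond_a, cond_b))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z' = atanh(r); |r| >= 1 is clamped just inside with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlation at +/-1 clamped before Fisher transform")
        r = np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def correlate_maps(dm: DifferenceMap, ds: DifferenceMap,
                   participant_id: str = "") -> CorrelationResult:
    """Pearson r (and Fisher z') across voxels between two difference maps.

    The maps must cover the identical voxel list.  Zero variance in either
    map, or fewer than :data:`MIN_VOXELS` voxels, yields a flagged
    ``valid=False`` result (r and z set to NaN) instead of propagating NaNs.
    """
    if not np.array_equal(dm.voxel_rows, ds.voxel_rows):
        raise ValueError("difference maps cover different voxel lists")
    roi = dm.roi or ds.roi
    n = len(dm.values)
    if n < MIN_VOXELS or np.std(dm.values) == 0 or np.std(ds.values) == 0:
        return CorrelationResult(roi=roi, participant_id=participant_id,
                                 r=float("nan"), z=float("nan"),
                                 n_voxels=n, valid=False)
    r = float(np.corrcoef(dm.values, ds.values)[0, 1])
    return CorrelationResult(roi=roi, participant_id=participant_id,
                             r=r, z=fisher_z(r), n_voxels=n)


def correlation_table(results: list[CorrelationResult]):
    """Tabulate correlation results (participant, ROI, r, z, n_voxels)."""
    import pandas as pd

    return pd.DataFrame(
        [{"participant": c.participant_id, "roi": c.roi, "r": c.r, "z": c.z,
          "n_voxels": c.n_voxels, "valid": c.valid} for c in results]
    )
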