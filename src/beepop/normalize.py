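"""Two-stage normalization of the log-scale ratio matrix.

Stage one removes the arbitrary mixing ratio of each triplex run: for every
protein and block the mean of the observed channel values is subtracted, so
each fully observed triple sums to zero. Stage two puts the three isotope
labels on a common robust scale: within each label, values are centered by
their median and scaled by their median absolute deviation, computed across
all proteins (and, by default, pooled across blocks).

The MAD is used raw, without the 1.4826 normal-consistency constant; pass
``consistency=1.4826`` to rescale to a normal-sd-comparable unit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["block_center", "label_standardize", "DegenerateScaleError"]


class DegenerateScaleError(ValueError):
    """A label channel has zero median absolute deviation."""


def _check_ratio_matrix(matrix: pd.DataFrame) -> None:
    if not isinstance(matrix.columns, pd.MultiIndex) or matrix.columns.nlevels != 2:
        raise ValueError("expected (block_id, channel) MultiIndex columns")


def block_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract, per protein and block, the mean of the observed channels.

    A block with a single observed channel centers to exactly zero; fully
    missing blocks stay missing.
    """
    _check_ratio_matrix(matrix)
    out = matrix.copy()
    for block in matrix.columns.get_level_values(0).unique():
        sub = out[block]
        out[block] = sub.sub(sub.mean(axis=1), axis=0).to_numpy()
    return out


def label_standardize(
    matrix: pd.DataFrame,
    per_block: bool = False,
    consistency: float = 1.0,
) -> pd.DataFrame:
    """Center and scale each label channel by median and MAD across proteins.

    With ``per_block=False`` (default) one median/MAD per label is computed by
    pooling all blocks; ``per_block=True`` standardizes every (block, label)
    column separately. Raises :class:`DegenerateScaleError` when a channel has
    MAD zero. The applied medians and MADs are stored in ``result.attrs``.
    """
    _check_ratio_matrix(matrix)
    out = matrix.copy()
    medians: dict = {}
    mads: dict = {}
    if per_block:
        for col in matrix.columns:
            vals = matrix[col].to_numpy(float)
            med, mad = _robust_loc_scale(vals, f"{col[0]}/{col[1]}", consistency)
            out[col] = (matrix[col] - med) / mad
            medians[col], mads[col] = med, mad
    else:
        channels = matrix.columns.get_level_values(1).unique()
        for ch in channels:
            cols = matrix.columns[matrix.columns.get_level_values(1) == ch]
            vals = matrix[cols].to_numpy(float).ravel()
            med, mad = _robust_loc_scale(vals, str(ch), consistency)
            out[cols] = (matrix[cols] - med) / mad
            medians[ch], mads[ch] = med, mad
    out.attrs["label_median"] = medians
    out.attrs["label_mad"] = mads
    return out


def _robust_loc_scale(vals: np.ndarray, name: str, consistency: float) -> tuple[float, float]:
    obs = vals[np.isfinite(vals)]
    if obs.size == 0:
        raise DegenerateScaleError(f"label {name}: no observed values")
    med = float(np.median(obs))
    mad = float(np.median(np.abs(obs - med))) * consistency
    if mad == 0.0:
        raise DegenerateScaleError(f"label {name}: zero median absolute deviation")
    return med, mad
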