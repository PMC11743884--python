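"""Pairwise and third-order Dice overlap of binary voxel sets.

The pairwise coefficient ``2 |A∩B| / (|A|+|B|)`` and its three-set
generalization ``3 |A∩B∩C| / (|A|+|B|+|C|)`` quantify how much the
binarized connectivity profiles of two or three seed regions occupy the
same voxels.  Inputs are boolean volumes (or anything castable to one);
restricting to a tissue compartment (gray matter for profiles, white
matter for tract maps) is the caller's responsibility -- pass ``mask``
or pre-mask the arrays.
"""

from __future__ import annotations

import warnings

import numpy as np


class UndefinedDiceWarning(UserWarning):
    """All input sets are empty; the coefficient is undefined (NaN)."""


def _as_bool(volume: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    arr = np.asarray(volume)
    if arr.dtype != bool:
        if np.any(arr < 0):
            raise ValueError("binary volume contains negative values")
        arr = arr > 0
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != arr.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume shape {arr.shape}"
            )
        arr = arr & mask
    return arr


def dice_pair(
    a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Dice coefficient between two binary voxel sets.

    Returns ``2 |A∩B| / (|A|+|B|)``.  When both sets are empty the value is
    undefined: NaN is returned and :class:`UndefinedDiceWarning` is issued.
    """
    a = _as_bool(a, mask)
    b = _as_bool(b, mask)
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("Dice of two empty sets is undefined", UndefinedDiceWarning)
        return float("nan")
    return 2.0 * int((a & b).sum()) / denom


def dice_third_order(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Third-order Dice coefficient among three binary voxel sets.

    Returns ``3 |A∩B∩C| / (|A|+|B|+|C|)``, the single-number overlap of all
    three seed profiles.  NaN (with :class:`UndefinedDiceWarning`) when all
    three sets are empty.
    """
    a = _as_bool(a, mask)
    b = _as_bool(b, mask)
    c = _as_bool(c, mask)
    if not (a.shape == b.shape == c.shape):
        raise ValueError(
            f"volume shapes differ: {a.shape}, {b.shape}, {c.shape}"
        )
    denom = int(a.sum()) + int(b.sum()) + int(c.sum())
    if denom == 0:
        warnings.warn(
            "third-order Dice of three empty sets is undefined",
            UndefinedDiceWarning,
        )
        return float("nan")
    return 3.0 * int((a & b & c).sum()) / denom
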