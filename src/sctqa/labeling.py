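"""Ground-truth slice labels: per-slice MAE, saturation, corpus assembly.

The label of an axial slice is the pixel-to-pixel mean absolute HU error
between the ground-truth CT plane and the synthetic CT plane,

    MAE = (1/n) * sum_i |GT_i - sCT_i|,

computed over all n pixels of the slice.  Labels are capped ("saturated")
at the upper bound of the governing bin scheme so the open-ended high-MAE
interval is closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from sctqa.io_volumes import VolumePair

#: standard 12-bit CT range; guards against sentinel values
HU_MIN, HU_MAX = -1024.0, 3071.0

#: slices whose GT body fraction (pixels > -500 HU) falls below this are
#: excluded from training/evaluation by default: all-air slices carry
#: near-zero MAE and no anatomy.
DEFAULT_BODY_FRACTION = 0.02
BODY_THRESHOLD_HU = -500.0


@dataclass
class SliceSample:
    """One training/evaluation example: an sCT slice and its MAE label."""

    patient_id: str
    modality: str
    slice_index: int
    image: np.ndarray  # 2D HU grid (the sCT slice)
    mae_gt: float  # HU, >= 0, saturated when `saturated`
    saturated: bool = False


def slice_mae(gt_slice: np.ndarray, sct_slice: np.ndarray) -> float:
    """Mean absolute HU error between two same-shape 2D slices.

    Computed in float64 over all pixels.  Symmetric in its arguments and
    exactly ``|c|`` for a constant offset ``c``.
    """
    gt = np.asarray(gt_slice, dtype=np.float64)
    sct = np.asarray(sct_slice, dtype=np.float64)
    if gt.shape != sct.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {sct.shape}")
    if gt.size == 0:
        raise ValueError("empty slice")
    if not (np.isfinite(gt).all() and np.isfinite(sct).all()):
        raise ValueError("non-finite HU values in slice")
    return float(np.mean(np.abs(gt - sct)))


def saturate_mae(mae: float, upper: float) -> tuple[float, bool]:
    """Cap an MAE label at ``upper``; returns ``(value, clipped?)``.

    The boundary itself is not considered clipped; saturation is
    idempotent.
    """
    if upper <= 0:
        raise ValueError(f"saturation bound must be positive, got {upper}")
    if mae < 0:
        raise ValueError(f"MAE is nonnegative by construction, got {mae}")
    if mae > upper:
        return float(upper), True
    return float(mae), False


def clamp_hu(grid: np.ndarray, warn: bool = True) -> np.ndarray:
    """Clamp to the standard CT range [-1024, 3071] HU."""
    grid = np.asarray(grid, dtype=np.float64)
    out_of_range = (grid < HU_MIN) | (grid > HU_MAX)
    if out_of_range.any():
        if warn:
            warnings.warn(
                f"{int(out_of_range.sum())} voxels outside [{HU_MIN}, {HU_MAX}] "
                "HU were clamped",
                stacklevel=2,
            )
        grid = np.clip(grid, HU_MIN, HU_MAX)
    return grid


def default_include_rule(
    gt_slice: np.ndarray, min_body_fraction: float = DEFAULT_BODY_FRACTION
) -> bool:
    """Keep a slice when its GT body fraction (> -500 HU) is >= 2%."""
    body = np.mean(gt_slice > BODY_THRESHOLD_HU)
    return bool(body >= min_body_fraction)


def build_corpus(
    pairs: Iterable[VolumePair],
    saturation: float | None = None,
    include_rule: Callable[[np.ndarray], bool] | None = default_include_rule,
    body_mask: bool = False,
) -> list[SliceSample]:
    """Assemble the slice-sample corpus from registered volume pairs.

    One :class:`SliceSample` per retained axial slice, in deterministic
    order (patient, then slice index).  Labels are the per-slice MAE,
    saturated at ``saturation`` when given.  ``include_rule`` filters on
    the GT slice (pass ``None`` to keep every slice).  With
    ``body_mask=True`` the MAE is restricted to GT body pixels
    (> -500 HU); default is the plain all-pixel MAE.
    """
    from sctqa.binning import BinScheme  # local import, avoids cycle

    if isinstance(saturation, BinScheme):
        saturation = saturation.saturation
    samples: list[SliceSample] = []
    for pair in sorted(pairs, key=lambda p: p.patient_id):
        gt = clamp_hu(pair.gt, warn=False)
        sct = clamp_hu(pair.sct, warn=False)
        for i in range(pair.n_slices):
            gt_sl, sct_sl = gt[:, :, i], sct[:, :, i]
            if include_rule is not None and not include_rule(gt_sl):
                continue
            if body_mask:
                mask = gt_sl > BODY_THRESHOLD_HU
                if not mask.any():
                    continue
                mae = float(np.mean(np.abs(gt_sl[mask] - sct_sl[mask])))
            else:
                mae = slice_mae(gt_sl, sct_sl)
            sat_flag = False
            if saturation is not None:
                mae, sat_flag = saturate_mae(mae, saturation)
            samples.append(
                SliceSample(
                    patient_id=pair.patient_id,
                    modality=pair.modality,
                    slice_index=i,
                    image=pair.sct[:, :, i].astype(np.float64),
                    mae_gt=mae,
                    saturated=sat_flag,
                )
            )
    if not samples:
        raise ValueError(
            "empty corpus: every slice was filtered out "
            "(check the inclusion rule and the input volumes)"
        )
    return samples


def corpus_manifest(samples: Sequence[SliceSample]) -> pd.DataFrame:
    """Tabular corpus summary (no pixel data), deterministic row order."""
    rows = [
        {
            "patient_id": s.patient_id,
            "modality": s.modality,
            "slice_index": s.slice_index,
            "mae_gt": s.mae_gt,
            "saturated": s.saturated,
        }
        for s in samples
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["patient_id", "slice_index"], kind="stable").reset_index(
        drop=True
    )
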