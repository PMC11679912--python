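"""Head-like digital phantoms with exact per-slice MAE control.

Generates paired ground-truth CT / pseudo-synthetic-CT volumes at desk
scale: an elliptical soft-tissue body with a bone rim and randomized
air cavities (denser near the cranial/caudal ends, mimicking nasal
cavities, the high-error region of real head scans) on an air
background.  The "synthetic CT" is the ground truth plus an additive
zero-centered smooth error field, supported on body pixels and rescaled
per slice so that the slice MAE equals a requested target *exactly* —
which real sCT errors never allow, but which makes every downstream
stage testable against known truth.  Restricting the corruption to the
body keeps the corrupted volume inside the valid CT range (air stays at
-1000 HU) and mirrors where conversion errors actually live.

Two corruption styles are provided so modality experiments can be run in
miniature: "CBCT" adds a directional streak component on top of a
short-range random field, "MR" uses a long-range smooth bias field; the
two have clearly different spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from sctqa.io_volumes import Geometry, VolumePair, save_volume

HU_AIR, HU_SOFT, HU_BONE = -1000.0, 40.0, 700.0


@dataclass
class PhantomConfig:
    """Geometry, tissue HU values and corruption style of one phantom."""

    shape: tuple[int, int, int] = (32, 32, 20)
    hu_air: float = HU_AIR
    hu_soft: float = HU_SOFT
    hu_bone: float = HU_BONE
    corr_length_px: float = 2.0  # smooth-field correlation length
    modality_style: str = "CBCT"  # "CBCT" (streaks) or "MR" (smooth bias)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality_style not in ("CBCT", "MR"):
            raise ValueError(f"modality_style must be CBCT or MR, got {self.modality_style!r}")


def generate_gt(config: PhantomConfig) -> np.ndarray:
    """Ground-truth head phantom: soft-tissue ellipse, bone rim, cavities.

    Deterministic for a fixed config (seeded generator, no ambient
    randomness).  Rejects in-plane shapes smaller than 16x16.
    """
    h, w, n_slices = config.shape
    if h < 16 or w < 16:
        raise ValueError(f"in-plane shape too small (< 16x16): {(h, w)}")
    rng = np.random.default_rng(config.seed)
    vol = np.full(config.shape, config.hu_air, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.42 * h, 0.38 * w
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    body = r2 <= 1.0
    rim = (r2 <= 1.0) & (r2 >= 0.72)  # skull
    for i in range(n_slices):
        sl = vol[:, :, i]
        sl[body] = config.hu_soft
        sl[rim] = config.hu_bone
        # interior bone blob (vertebra/mandible-like), jittered per slice
        by = cy + rng.uniform(-0.12, 0.12) * h
        bx = cx + rng.uniform(-0.12, 0.12) * w
        br = rng.uniform(0.06, 0.10) * min(h, w)
        blob = ((yy - by) ** 2 + (xx - bx) ** 2) <= br**2
        sl[blob & body] = config.hu_bone
        # air cavities, more likely near the volume ends (nasal-cavity-like)
        end_frac = min(i, n_slices - 1 - i) / max(n_slices - 1, 1)
        p_cavity = 0.8 if end_frac < 0.25 else 0.25
        if rng.random() < p_cavity:
            n_cav = rng.integers(1, 3)
            for _ in range(n_cav):
                ky = cy + rng.uniform(-0.2, 0.2) * h
                kx = cx + rng.uniform(-0.2, 0.2) * w
                kr = rng.uniform(0.04, 0.08) * min(h, w)
                cav = ((yy - ky) ** 2 + (xx - kx) ** 2) <= kr**2
                sl[cav & body] = config.hu_air
    return vol


#: cap on |field| / mean(|field|); with air at -1000 HU this keeps the
#: corrupted volume inside [-1024, 3071] for targets up to ~130 HU
MAX_FIELD_RATIO = 8.0


def _error_field(
    shape: tuple[int, int],
    corr_length_px: float,
    style: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean error texture for one slice (unnormalized)."""
    h, w = shape
    base = gaussian_filter(rng.standard_normal((h, w)), corr_length_px)
    if style == "CBCT":
        # add a directional streak component (cone-beam-artifact flavor)
        angle = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        t = xx * np.cos(angle) + yy * np.sin(angle)
        freq = rng.uniform(0.4, 0.9)
        streaks = np.sin(2 * np.pi * freq * t / max(h, w) * 8 + rng.uniform(0, 2 * np.pi))
        fld = base + 0.7 * streaks
    else:  # MR: long-range smooth bias field
        fld = gaussian_filter(rng.standard_normal((h, w)), 4.0 * corr_length_px)
    fld = fld - fld.mean()
    return fld


def _unit_mae_field(
    fld: np.ndarray, mask: np.ndarray, max_ratio: float = MAX_FIELD_RATIO
) -> np.ndarray:
    """Normalize a field to mean(|.|) = 1 over the slice, supported on
    ``mask``, with peak magnitude capped at ``max_ratio``."""
    f = np.where(mask, fld, 0.0)
    if mask.any():
        f = np.where(mask, f - f[mask].mean(), 0.0)
    for _ in range(20):
        m = np.abs(f).mean()
        if m == 0:
            break
        s = f / m
        if np.abs(s).max() <= max_ratio + 1e-12:
            return s
        f = np.clip(s, -max_ratio, max_ratio)
    # degenerate texture: fall back to a +-1 pattern on the mask
    idx = np.flatnonzero(mask if mask.any() else np.ones(f.shape, bool))
    signs = np.ones(idx.size)
    signs[1::2] = -1.0
    s = np.zeros(f.size)
    s[idx] = signs * (f.size / idx.size)
    return s.reshape(f.shape)


def corrupt_to_target_mae(
    gt: np.ndarray,
    targets: Sequence[float],
    corr_length_px: float = 2.0,
    seed: int = 0,
    style: str = "CBCT",
) -> np.ndarray:
    """Additive corruption scaled so each slice MAE hits its target.

    The per-slice error field is zero-centered, supported on the body
    (GT > -500 HU) and normalized to ``mean(|field|) = 1`` over the whole
    slice, so adding ``target * field`` makes ``slice_mae(gt_i, sct_i)``
    equal ``targets[i]`` to floating-point precision.  A target of 0
    leaves the slice untouched.  Peak field magnitude is capped so the
    corrupted volume stays within the valid CT range.
    """
    gt = np.asarray(gt, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim != 1 or targets.size != gt.shape[2]:
        raise ValueError(
            f"need one target per axial slice: {targets.size} vs {gt.shape[2]}"
        )
    if (targets < 0).any():
        raise ValueError("per-slice MAE targets must be nonnegative")
    rng = np.random.default_rng(seed)
    sct = gt.copy()
    for i, target in enumerate(targets):
        fld = _error_field(gt.shape[:2], corr_length_px, style, rng)
        if target == 0:
            continue
        mask = gt[:, :, i] > -500.0
        unit = _unit_mae_field(fld, mask)
        if np.abs(unit).max() == 0:  # no texture at all: constant offset
            sct[:, :, i] += target
            continue
        sct[:, :, i] += target * unit
    return sct


def uniform_mae_sampler(lo: float = 0.0, hi: float = 100.0) -> Callable:
    """Per-slice MAE targets drawn uniformly on [lo, hi] HU."""

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(lo, hi, size=n)

    return sample


def level_mae_sampler(
    levels: Sequence[float] = (10.0, 35.0, 60.0, 85.0), jitter: float = 3.0
) -> Callable:
    """Per-slice MAE targets concentrated at a few separated levels.

    Levels are dealt in balanced proportions (then shuffled) with a small
    uniform jitter, so quartile binning on such a corpus recovers
    boundaries between the levels.
    """
    levels = np.asarray(levels, dtype=np.float64)

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        reps = int(np.ceil(n / levels.size))
        vals = np.tile(levels, reps)[:n]
        rng.shuffle(vals)
        out = vals + rng.uniform(-jitter, jitter, size=n)
        return np.clip(out, 0.0, None)

    return sample


def make_dataset(
    n_patients: int,
    config: PhantomConfig | None = None,
    mae_sampler: Callable | None = None,
    seed: int = 0,
    id_prefix: str = "phantom",
) -> tuple[list[VolumePair], pd.DataFrame]:
    """Generate a cohort of GT/sCT phantom pairs plus a truth manifest.

    Each patient gets its own anatomy (derived seed) and per-slice MAE
    targets from ``mae_sampler`` (default uniform on [0, 100] HU).  The
    manifest records every true slice MAE; the modality tag follows the
    config's corruption style.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    config = config or PhantomConfig()
    mae_sampler = mae_sampler or uniform_mae_sampler()
    rng = np.random.default_rng(seed)
    geometry = Geometry(spacing=config.spacing)
    pairs: list[VolumePair] = []
    rows = []
    for p in range(n_patients):
        pid = f"{id_prefix}_{p:03d}"
        anatomy_seed = int(rng.integers(0, 2**31 - 1))
        noise_seed = int(rng.integers(0, 2**31 - 1))
        pconf = PhantomConfig(
            shape=config.shape,
            hu_air=config.hu_air,
            hu_soft=config.hu_soft,
            hu_bone=config.hu_bone,
            corr_length_px=config.corr_length_px,
            modality_style=config.modality_style,
            spacing=config.spacing,
            seed=anatomy_seed,
        )
        gt = generate_gt(pconf)
        targets = mae_sampler(rng, config.shape[2])
        sct = corrupt_to_target_mae(
            gt, targets, config.corr_length_px, noise_seed, config.modality_style
        )
        pairs.append(
            VolumePair(
                patient_id=pid,
                modality=config.modality_style,
                gt=gt,
                sct=sct,
                geometry=geometry,
            )
        )
        for i, t in enumerate(targets):
            rows.append(
                {"patient_id": pid, "modality": config.modality_style,
                 "slice_index": i, "mae_true": float(t)}
            )
    manifest = pd.DataFrame(rows)
    return pairs, manifest


def write_dataset(
    pairs: Sequence[VolumePair],
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write NIfTI pairs (``<pid>_gt.nii.gz`` / ``<pid>_sct.nii.gz``) and
    the true-MAE manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        save_volume(pair.gt, pair.geometry, out_dir / f"{pair.patient_id}_gt.nii.gz")
        save_volume(pair.sct, pair.geometry, out_dir / f"{pair.patient_id}_sct.nii.gz")
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir
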