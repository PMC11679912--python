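"""MAE interval scheme: quartile bins, relaxed regression ranges.

The four classification bins (low, medium-low, medium-high, high MAE) are
delimited by the quartiles of the training-label distribution, which
balances the number of examples per class.  Each regressor's training
range is its classification bin widened by +-5 HU ("relaxation") so the
regression step can recover near-boundary misclassifications; the first
lower bound stays clamped at 0 and the last upper bound at the saturation
value that closes the open-ended high bin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

DEFAULT_RELAXATION_HU = 5.0


@dataclass
class BinScheme:
    """Classification boundaries + relaxed regression ranges, in HU.

    ``boundaries`` is the ascending list ``[0, q1, q2, q3, saturation]``
    for the default 4-class scheme.  Classification bins are half-open
    ``[b_k, b_{k+1})`` with the last bin closed at saturation.
    """

    boundaries: list[float]
    relaxation: float = DEFAULT_RELAXATION_HU
    regression_ranges: list[tuple[float, float]] | None = field(default=None)

    def __post_init__(self) -> None:
        b = list(map(float, self.boundaries))
        if len(b) < 3:
            raise ValueError("need at least 2 bins (3 boundaries)")
        if b[0] != 0:
            raise ValueError(f"first boundary must be 0, got {b[0]}")
        if any(lo >= hi for lo, hi in zip(b, b[1:])):
            raise ValueError(f"boundaries must be strictly increasing: {b}")
        self.boundaries = b

    @property
    def n_classes(self) -> int:
        return len(self.boundaries) - 1

    @property
    def saturation(self) -> float:
        return self.boundaries[-1]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "boundaries": self.boundaries,
            "relaxation": self.relaxation,
            "regression_ranges": (
                [list(r) for r in self.regression_ranges]
                if self.regression_ranges is not None
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinScheme":
        rr = d.get("regression_ranges")
        return cls(
            boundaries=list(d["boundaries"]),
            relaxation=float(d.get("relaxation", DEFAULT_RELAXATION_HU)),
            regression_ranges=[tuple(r) for r in rr] if rr is not None else None,
        )

    def save(self, path: str | Path) -> Path:
        """Write a JSON (.json) or YAML (.yaml/.yml) sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BinScheme":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)


def compute_classification_bins(
    mae_labels: Sequence[float],
    n_classes: int = 4,
    saturation: float | None = None,
    relaxation: float = DEFAULT_RELAXATION_HU,
) -> BinScheme:
    """Derive the classification bins from the label distribution.

    Interior boundaries are the ``k/n_classes`` quantiles of the labels
    (linear interpolation between order statistics) rounded to the nearest
    integer HU; the lower edge is 0 and the upper edge the saturation
    bound.  When ``saturation`` is omitted it defaults to the maximum
    observed label rounded up to the nearest 10 HU.

    Raises on a degenerate distribution whose rounded quantiles are not
    strictly increasing.
    """
    labels = np.asarray(mae_labels, dtype=np.float64)
    if labels.size < n_classes:
        raise ValueError(f"need at least {n_classes} labels, got {labels.size}")
    if (labels < 0).any():
        raise ValueError("MAE labels must be nonnegative")
    if saturation is None:
        saturation = float(np.ceil(labels.max() / 10.0) * 10.0)
        if saturation <= 0:
            raise ValueError("cannot infer a positive saturation bound")
    if labels.max() > saturation:
        raise ValueError(
            f"labels exceed the saturation bound {saturation}; saturate first"
        )
    qs = np.arange(1, n_classes) / n_classes
    interior = np.round(np.quantile(labels, qs, method="linear"))
    boundaries = [0.0, *interior.tolist(), float(saturation)]
    if any(lo >= hi for lo, hi in zip(boundaries, boundaries[1:])):
        raise ValueError(
            f"degenerate MAE distribution: rounded quantile boundaries "
            f"{boundaries} are not strictly increasing"
        )
    return BinScheme(boundaries=boundaries, relaxation=relaxation)


def derive_regression_ranges(scheme: BinScheme) -> BinScheme:
    """Fill the relaxed regression ranges of a scheme.

    ``range_k = [max(0, b_k - relaxation), min(saturation, b_{k+1} +
    relaxation)]`` — consecutive ranges overlap by twice the relaxation
    except at the clamped extremes.
    """
    b, r, sat = scheme.boundaries, scheme.relaxation, scheme.saturation
    widths = [hi - lo for lo, hi in zip(b, b[1:])]
    if r >= min(widths):
        warnings.warn(
            f"relaxation {r} HU is at least the smallest bin width "
            f"{min(widths)} HU; regression ranges will overlap heavily",
            stacklevel=2,
        )
    ranges = [
        (max(0.0, b[k] - r), min(sat, b[k + 1] + r)) for k in range(scheme.n_classes)
    ]
    return BinScheme(
        boundaries=list(b), relaxation=r, regression_ranges=ranges
    )


def assign_class(mae: float, scheme: BinScheme) -> int:
    """Classification bin of a (saturated) MAE value.

    Half-open convention: a value on a boundary belongs to the upper bin;
    the last bin is closed at saturation.
    """
    if not (0 <= mae <= scheme.saturation):
        raise ValueError(
            f"MAE {mae} outside [0, {scheme.saturation}]; saturate first"
        )
    b = scheme.boundaries
    for k in range(scheme.n_classes):
        if b[k] <= mae < b[k + 1]:
            return k
    return scheme.n_classes - 1  # mae == saturation


def regression_membership(mae: float, scheme: BinScheme) -> set[int]:
    """Indices of every regression range containing the value (closed
    intervals); defines the per-regressor training sets."""
    if scheme.regression_ranges is None:
        raise ValueError("regression ranges not derived; call derive_regression_ranges")
    if not (0 <= mae <= scheme.saturation):
        raise ValueError(f"MAE {mae} outside [0, {scheme.saturation}]")
    return {
        k
        for k, (lo, hi) in enumerate(scheme.regression_ranges)
        if lo <= mae <= hi
    }
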