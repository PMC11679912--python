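"""The two-step MAE prediction cascade.

A 4-way classifier first predicts the MAE *interval* of an axial sCT
slice; the slice is then routed to the regressor specific to that
interval, which produces the final MAE scalar.  Five estimators are
trained per pipeline (1 classifier + 4 regressors) but exactly two run
per slice at inference.  Each regressor is trained only on slices whose
ground-truth MAE falls inside its relaxed range, so a near-boundary
classification error can still be recovered downstream.

Training follows the reference recipe: cross-entropy for classification
(with the best epoch chosen by the *distance-weighted* accuracy, not the
loss), MSE for regression, L1+L2 penalties of 4e-4 on all weights,
learning rate 5e-5, mirroring + small-translation augmentation, and
patient-level 75/10/15 splits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import zoom as nd_zoom

from sctqa import nn
from sctqa.binning import BinScheme, assign_class, derive_regression_ranges, compute_classification_bins
from sctqa.io_volumes import Geometry, build_pmae_grid
from sctqa.labeling import SliceSample, saturate_mae


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessSpec:
    """Shared input pipeline: resample, HU-window, map to [0, 1].

    The default window [-1000, 2000] HU covers air through dental metal.
    """

    input_size: tuple[int, int] = (32, 32)
    hu_window: tuple[float, float] = (-1000.0, 2000.0)

    def to_dict(self) -> dict:
        return {"input_size": list(self.input_size), "hu_window": list(self.hu_window)}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(tuple(d["input_size"]), tuple(d["hu_window"]))

    @property
    def air_level(self) -> float:
        """Normalized intensity of air; used as the augmentation fill."""
        lo, hi = self.hu_window
        return float(np.clip((-1000.0 - lo) / (hi - lo), 0.0, 1.0))


def preprocess_slice(image: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    """Resample a 2D HU slice to the model input size and normalize.

    Values are clipped to the HU window and mapped linearly onto [0, 1].
    Rejects non-finite input.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected 2D slice, got {image.ndim}D")
    if not np.isfinite(image).all():
        raise ValueError("non-finite pixels in slice")
    h, w = spec.input_size
    if image.shape != (h, w):
        factors = (h / image.shape[0], w / image.shape[1])
        image = nd_zoom(image, factors, order=1, mode="nearest", grid_mode=True)
    lo, hi = spec.hu_window
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def preprocess_batch(
    images: Sequence[np.ndarray], spec: PreprocessSpec
) -> np.ndarray:
    """Stack preprocessed slices into an (N, 1, H, W) tensor."""
    return np.stack([preprocess_slice(im, spec) for im in images])[:, None, :, :]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyperparameters for one cascade training run.

    Defaults follow the reference recipe (lr 5e-5, L1=L2=4e-4,
    75/10/15 patient-level split); desk-scale runs with the tiny backbone
    typically raise the learning rate and shrink the translation range.
    """

    learning_rate: float = 5e-5
    l1_weight: float = 4e-4
    l2_weight: float = 4e-4
    max_epochs: int = 100
    batch_size: int = 32
    split_fractions: tuple[float, float, float] = (0.75, 0.10, 0.15)
    k_folds: int = 5
    seed: int = 0
    mirror: bool = True
    max_translation_px: int = 8
    backbone: str = "tiny"
    input_size: tuple[int, int] = (32, 32)
    hu_window: tuple[float, float] = (-1000.0, 2000.0)
    min_regression_samples: int = 20

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1: {self.split_fractions}")

    @property
    def preprocess(self) -> PreprocessSpec:
        return PreprocessSpec(tuple(self.input_size), tuple(self.hu_window))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def split_patients(
    patient_ids: Sequence[str],
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list[str], list[str], list[str]]:
    """Patient-level train/validation/test split.

    Splitting at patient granularity (never slice) avoids leakage of
    adjacent-slice anatomy between partitions.  Train and validation each
    receive at least one patient.
    """
    ids = sorted(set(patient_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = min(n_train, n - 1) if n > 1 else n
    train = ids[:n_train]
    val = ids[n_train : n_train + n_val]
    test = ids[n_train + n_val :]
    if not val:  # too few patients for three partitions: reuse train
        val = list(train)
    return train, val, test


def patient_kfold(
    patient_ids: Sequence[str], k: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """K folds at patient level; returns (train_ids, test_ids) per fold."""
    ids = sorted(set(patient_ids))
    if k < 2 or k > len(ids):
        raise ValueError(f"k={k} incompatible with {len(ids)} patients")
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    folds = np.array_split(ids, k)
    out = []
    for i in range(k):
        test = list(folds[i])
        train = [p for j, f in enumerate(folds) if j != i for p in f]
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def weighted_classification_score(
    true_classes: Sequence[int],
    predicted_classes: Sequence[int],
    n_classes: int,
) -> float:
    """Accuracy weighted by misclassification magnitude.

    ``1 - sum|c_pred - c_true| / (N * (n_classes - 1))``: 1 for a perfect
    prediction, 0 when every sample is misclassified by the maximal class
    distance.  A 1-class error therefore costs less than a 2- or 3-class
    error, which matches the recovery capability of the relaxed
    regression ranges.
    """
    t = np.asarray(true_classes, dtype=np.int64)
    p = np.asarray(predicted_classes, dtype=np.int64)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("need equal-length, nonempty class vectors")
    if (t < 0).any() or (t >= n_classes).any() or (p < 0).any() or (p >= n_classes).any():
        raise ValueError(f"class labels outside [0, {n_classes})")
    return float(1.0 - np.abs(p - t).sum() / (t.size * (n_classes - 1)))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class Estimator:
    """One trained network plus its task metadata.

    ``task`` is "classification" (probability vector output) or
    "regression" (single scalar; the network is trained on targets
    affinely mapped from ``target_range`` to [0, 1] and predictions are
    mapped back).
    """

    def __init__(
        self,
        task: str,
        backbone: str,
        input_size: tuple[int, int],
        out_dim: int,
        network: nn.Network,
        target_range: tuple[float, float] | None = None,
    ):
        if task not in ("classification", "regression"):
            raise ValueError(f"unknown task {task!r}")
        if task == "regression" and target_range is None:
            raise ValueError("regression estimator needs a target range")
        self.task = task
        self.backbone = backbone
        self.input_size = tuple(input_size)
        self.out_dim = out_dim
        self.network = network
        self.target_range = tuple(target_range) if target_range else None
        self.n_invocations = 0

    # -- inference --------------------------------------------------------
    def predict_probs(self, batch: np.ndarray) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("not a classifier")
        self.n_invocations += batch.shape[0]
        return nn.softmax(self.network.forward(batch))

    def predict_values(self, batch: np.ndarray) -> np.ndarray:
        if self.task != "regression":
            raise ValueError("not a regressor")
        self.n_invocations += batch.shape[0]
        lo, hi = self.target_range
        raw = self.network.forward(batch)[:, 0]
        return lo + raw * (hi - lo)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "task": self.task,
            "backbone": self.backbone,
            "input_size": list(self.input_size),
            "out_dim": self.out_dim,
            "target_range": list(self.target_range) if self.target_range else None,
        }
        np.savez(path, __meta__=np.bytes_(json.dumps(meta)), **self.network.get_state())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Estimator":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"missing estimator checkpoint: {path}")
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        net = nn.build_backbone(
            meta["backbone"], tuple(meta["input_size"]), meta["out_dim"], seed=0
        )
        net.set_state(state)
        return cls(
            task=meta["task"],
            backbone=meta["backbone"],
            input_size=tuple(meta["input_size"]),
            out_dim=meta["out_dim"],
            network=net,
            target_range=tuple(meta["target_range"]) if meta["target_range"] else None,
        )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_batch(
    batch: np.ndarray,
    rng: np.random.Generator,
    mirror: bool,
    max_translation_px: int,
    fill: float,
) -> np.ndarray:
    """Mirror + random translation on normalized (N,1,H,W) inputs.

    Translations pad with the normalized air level; the scalar label is
    unchanged (shifts are small and slices are surrounded by air).
    """
    out = batch.copy()
    n, _, h, w = out.shape
    if mirror:
        flip = rng.random(n) < 0.5
        out[flip] = out[flip, :, :, ::-1]
    t = max_translation_px
    if t > 0:
        for j in range(n):
            dy, dx = rng.integers(-t, t + 1, size=2)
            if dy == 0 and dx == 0:
                continue
            shifted = np.full((h, w), fill)
            ys0, ys1 = max(0, dy), min(h, h + dy)
            xs0, xs1 = max(0, dx), min(w, w + dx)
            shifted[ys0:ys1, xs0:xs1] = out[j, 0, ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
            out[j, 0] = shifted
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _corpus_arrays(
    samples: Sequence[SliceSample], spec: PreprocessSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(inputs, labels, patient ids) with inputs preprocessed once."""
    x = preprocess_batch([s.image for s in samples], spec)
    y = np.array([s.mae_gt for s in samples], dtype=np.float64)
    pid = np.array([s.patient_id for s in samples])
    return x, y, pid


def _train_network(
    net: nn.Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    task: str,
    cfg: TrainConfig,
    spec: PreprocessSpec,
    rng: np.random.Generator,
    n_classes: int = 0,
) -> list[dict]:
    """Shared epoch loop; selects and restores the best-epoch weights.

    Classification: best epoch maximizes the validation weighted score.
    Regression: best epoch minimizes validation MSE.
    """
    opt = nn.Adam(net, lr=cfg.learning_rate, l1=cfg.l1_weight, l2=cfg.l2_weight)
    n = x_train.shape[0]
    log: list[dict] = []
    best_state = net.get_state()
    best_metric = -np.inf
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = augment_batch(
                x_train[idx], rng, cfg.mirror, cfg.max_translation_px, spec.air_level
            )
            out = net.forward(xb)
            if task == "classification":
                loss, grad = nn.cross_entropy_loss(out, y_train[idx].astype(np.int64))
            else:
                loss, grad = nn.mse_loss(out, y_train[idx][:, None])
            net.backward(grad)
            opt.step()
            epoch_loss += loss + opt.penalty()
            n_batches += 1
        # validation metric (no augmentation)
        val_out = net.forward(x_val)
        if task == "classification":
            val_pred = val_out.argmax(axis=1)
            metric = weighted_classification_score(
                y_val.astype(np.int64), val_pred, n_classes
            )
            entry = {
                "epoch": epoch,
                "train_loss": epoch_loss / n_batches,
                "val_weighted_score": metric,
            }
        else:
            val_mse = float(np.mean((val_out[:, 0] - y_val) ** 2))
            metric = -val_mse
            entry = {
                "epoch": epoch,
                "train_loss": epoch_loss / n_batches,
                "val_mse": val_mse,
            }
        log.append(entry)
        if metric > best_metric:
            best_metric = metric
            best_state = net.get_state()
    net.set_state(best_state)
    return log


def train_classifier(
    corpus: Sequence[SliceSample],
    scheme: BinScheme,
    cfg: TrainConfig,
) -> tuple[Estimator, pd.DataFrame]:
    """Train the 4-way MAE-interval classifier.

    Cross-entropy with L1+L2 penalties; the returned checkpoint is the
    epoch with the *maximal validation weighted score*, not the minimal
    loss.  Raises when a class is absent from the training split.
    """
    spec = cfg.preprocess
    x, y_mae, pid = _corpus_arrays(corpus, spec)
    classes = np.array([assign_class(m, scheme) for m in y_mae], dtype=np.int64)
    train_ids, val_ids, _ = split_patients(pid, cfg.split_fractions, cfg.seed)
    tr = np.isin(pid, train_ids)
    va = np.isin(pid, val_ids)
    present = set(classes[tr].tolist())
    missing = sorted(set(range(scheme.n_classes)) - present)
    if missing:
        raise ValueError(
            f"classes {missing} absent from the training split; "
            "add patients or adjust the split seed"
        )
    rng = np.random.default_rng(cfg.seed)
    net = nn.build_backbone(cfg.backbone, spec.input_size, scheme.n_classes, cfg.seed)
    log = _train_network(
        net, x[tr], classes[tr], x[va], classes[va].astype(np.float64),
        "classification", cfg, spec, rng, n_classes=scheme.n_classes,
    )
    est = Estimator(
        "classification", cfg.backbone, spec.input_size, scheme.n_classes, net
    )
    return est, pd.DataFrame(log)


def train_regressors(
    corpus: Sequence[SliceSample],
    scheme: BinScheme,
    cfg: TrainConfig,
) -> tuple[list[Estimator], list[pd.DataFrame]]:
    """Train the four interval-specific MAE regressors.

    Regressor ``k`` sees only slices whose ground-truth MAE lies in the
    relaxed range ``regression_ranges[k]`` (closed interval).  Targets are
    affinely mapped to [0, 1] over that range for conditioning; the best
    epoch minimizes validation MSE.  Rejects an undersized training set,
    naming the bin.
    """
    if scheme.regression_ranges is None:
        raise ValueError("scheme has no regression ranges; derive them first")
    spec = cfg.preprocess
    x, y_mae, pid = _corpus_arrays(corpus, spec)
    train_ids, val_ids, _ = split_patients(pid, cfg.split_fractions, cfg.seed)
    tr_all = np.isin(pid, train_ids)
    va_all = np.isin(pid, val_ids)
    estimators: list[Estimator] = []
    logs: list[pd.DataFrame] = []
    for k, (lo, hi) in enumerate(scheme.regression_ranges):
        member = (y_mae >= lo) & (y_mae <= hi)
        tr = member & tr_all
        va = member & va_all
        n_tr = int(tr.sum())
        if n_tr < cfg.min_regression_samples:
            raise ValueError(
                f"regression bin {k} ([{lo}, {hi}] HU) has only {n_tr} training "
                f"samples (< {cfg.min_regression_samples})"
            )
        scaled = (y_mae - lo) / (hi - lo)
        # an empty validation subset falls back to training samples
        va_use = va if va.sum() > 0 else tr
        rng = np.random.default_rng(cfg.seed + 1 + k)
        net = nn.build_backbone(cfg.backbone, spec.input_size, 1, cfg.seed + 1 + k)
        log = _train_network(
            net, x[tr], scaled[tr], x[va_use], scaled[va_use],
            "regression", cfg, spec, rng,
        )
        estimators.append(
            Estimator(
                "regression", cfg.backbone, spec.input_size, 1, net,
                target_range=(lo, hi),
            )
        )
        logs.append(pd.DataFrame(log))
    return estimators, logs


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeModel:
    """Trained pipeline: bin scheme + classifier + 4 regressors."""

    scheme: BinScheme
    classifier: Estimator
    regressors: list[Estimator]
    preprocessing: PreprocessSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.regressors) != self.scheme.n_classes:
            raise ValueError(
                f"need {self.scheme.n_classes} regressors, got {len(self.regressors)}"
            )

    @property
    def n_estimators(self) -> int:
        return 1 + len(self.regressors)

    @property
    def total_invocations(self) -> int:
        return self.classifier.n_invocations + sum(
            r.n_invocations for r in self.regressors
        )

    def reset_invocations(self) -> None:
        self.classifier.n_invocations = 0
        for r in self.regressors:
            r.n_invocations = 0

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.scheme.save(directory / "scheme.json")
        (directory / "preprocess.json").write_text(
            json.dumps(self.preprocessing.to_dict(), indent=2)
        )
        (directory / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )
        self.classifier.save(directory / "classifier.npz")
        for k, reg in enumerate(self.regressors):
            reg.save(directory / f"regressor_{k}.npz")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "CascadeModel":
        directory = Path(directory)
        scheme = BinScheme.load(directory / "scheme.json")
        spec = PreprocessSpec.from_dict(
            json.loads((directory / "preprocess.json").read_text())
        )
        prov_path = directory / "provenance.json"
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        classifier = Estimator.load(directory / "classifier.npz")
        regressors = [
            Estimator.load(directory / f"regressor_{k}.npz")
            for k in range(scheme.n_classes)
        ]
        return cls(scheme, classifier, regressors, spec, prov)


def predict_slice(model: CascadeModel, image: np.ndarray) -> "PredictionRecord":
    """Predict the MAE of one axial sCT slice.

    Exactly two estimator invocations: classifier argmax (ties go to the
    lowest class index), then that class's regressor; the output is
    clipped to [0, saturation].
    """
    from sctqa.evaluation import PredictionRecord

    batch = preprocess_batch([image], model.preprocessing)
    probs = model.classifier.predict_probs(batch)[0]
    k = int(np.argmax(probs))  # np.argmax returns the lowest index on ties
    raw = float(model.regressors[k].predict_values(batch)[0])
    mae = float(np.clip(raw, 0.0, model.scheme.saturation))
    return PredictionRecord(
        patient_id="", modality="", slice_index=-1,
        class_predicted=k, mae_predicted=mae,
    )


def predict_volume(
    model: CascadeModel,
    sct: np.ndarray,
    geometry: Geometry | None = None,
    patient_id: str = "",
    modality: str = "",
) -> tuple[list["PredictionRecord"], np.ndarray]:
    """Predict every axial slice of an sCT; returns records + pMAE grid.

    Deterministic given a fixed model: inference involves no randomness.
    """
    sct = np.asarray(sct)
    if sct.ndim != 3:
        raise ValueError(f"expected 3D sCT, got {sct.ndim}D")
    records = []
    for i in range(sct.shape[2]):
        rec = predict_slice(model, sct[:, :, i])
        rec.patient_id = patient_id
        rec.modality = modality
        rec.slice_index = i
        records.append(rec)
    pmae = build_pmae_grid([r.mae_predicted for r in records], sct.shape)
    return records, pmae


def train_cascade(
    corpus: Sequence[SliceSample],
    cfg: TrainConfig,
    scheme: BinScheme | None = None,
) -> CascadeModel:
    """Train a complete pipeline (scheme derivation + 5 estimators).

    When no scheme is given, labels are saturated at the maximum observed
    value rounded up to 10 HU, quartile bins are computed from the
    (saturated) label distribution, and the relaxed regression ranges are
    derived.
    """
    if scheme is None:
        labels = np.array([s.mae_gt for s in corpus])
        scheme = compute_classification_bins(labels)
        scheme = derive_regression_ranges(scheme)
    elif scheme.regression_ranges is None:
        scheme = derive_regression_ranges(scheme)
    # honor the scheme's saturation on the labels
    corpus = [
        SliceSample(
            s.patient_id, s.modality, s.slice_index, s.image,
            *saturate_mae(s.mae_gt, scheme.saturation),
        )
        for s in corpus
    ]
    classifier, clf_log = train_classifier(corpus, scheme, cfg)
    regressors, reg_logs = train_regressors(corpus, scheme, cfg)
    model = CascadeModel(
        scheme=scheme,
        classifier=classifier,
        regressors=regressors,
        preprocessing=cfg.preprocess,
        provenance={"config_hash": cfg.config_hash(), "seed": cfg.seed},
    )
    model.training_logs = {"classifier": clf_log, "regressors": reg_logs}
    return model
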