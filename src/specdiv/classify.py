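"""Species classification: crown spectra extraction, train/test splitting,
SMOTE balancing, random-forest tuning and per-pixel mapping with a full
confusion-matrix accuracy report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .synthgen import NONFOREST, PIXEL_SIZE_M, Crown

logger = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """Feature vectors with labels, crown provenance and train/test tags."""

    samples: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) str or int
    crown_ids: np.ndarray  # (n,) provenance
    split: np.ndarray | None = None  # (n,) "train" | "test"

    def subset(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == tag
        return self.samples[m], self.labels[m]


@dataclass
class ClassificationMap:
    labels: np.ndarray  # (rows, cols) int, NONFOREST on masked pixels
    mask: np.ndarray  # (rows, cols) bool: True = forest/valid
    legend: dict[int, str]
    pixel_size_m: float = PIXEL_SIZE_M

    def area_km2(self) -> pd.Series:
        """Mapped area per class from the pixel histogram (1 px = 16 m^2)."""
        vals, counts = np.unique(self.labels[self.mask], return_counts=True)
        area = counts * self.pixel_size_m**2 / 1e6
        return pd.Series(area, index=[self.legend.get(int(v), str(v)) for v in vals])


@dataclass
class ConfusionReport:
    """Confusion matrix plus the derived accuracy scalars."""

    matrix: pd.DataFrame  # reference rows x predicted columns
    overall_accuracy: float  # percent
    kappa: float
    producers_accuracy: pd.Series  # percent per class
    users_accuracy: pd.Series  # percent per class
    oob_error: float | None = None  # percent

    @classmethod
    def from_labels(
        cls, reference: np.ndarray, predicted: np.ndarray, oob_error: float | None = None
    ) -> "ConfusionReport":
        reference = np.asarray(reference)
        predicted = np.asarray(predicted)
        if reference.size == 0:
            raise ValueError("empty label vectors")
        if reference.shape != predicted.shape:
            raise ValueError("label vectors must have equal length")
        classes = np.unique(np.concatenate([reference, predicted]))
        idx = {c: i for i, c in enumerate(classes)}
        m = np.zeros((len(classes), len(classes)), dtype=int)
        for r, p in zip(reference, predicted):
            m[idx[r], idx[p]] += 1
        matrix = pd.DataFrame(m, index=classes, columns=classes)
        return cls.from_matrix(matrix, oob_error=oob_error)

    @classmethod
    def from_matrix(
        cls, matrix: pd.DataFrame, oob_error: float | None = None
    ) -> "ConfusionReport":
        m = matrix.to_numpy(dtype=float)
        total = m.sum()
        diag = np.diag(m)
        p_o = diag.sum() / total
        row_tot = m.sum(axis=1)  # reference totals
        col_tot = m.sum(axis=0)  # predicted totals
        p_e = float(row_tot @ col_tot) / total**2
        kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            producers = np.where(row_tot > 0, diag / row_tot, np.nan) * 100.0
            users = np.where(col_tot > 0, diag / col_tot, np.nan) * 100.0
        return cls(
            matrix=matrix,
            overall_accuracy=float(p_o * 100.0),
            kappa=float(kappa),
            producers_accuracy=pd.Series(producers, index=matrix.index),
            users_accuracy=pd.Series(users, index=matrix.columns),
            oob_error=oob_error,
        )


def crown_footprint_pixels(
    crown: Crown, shape: tuple[int, int], pixel_size_m: float = PIXEL_SIZE_M
) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the pixels inside a crown disc."""
    r_px = crown.diameter_m / 2.0 / pixel_size_m
    cx, cy = crown.x_m / pixel_size_m, crown.y_m / pixel_size_m
    r0 = max(int(np.floor(cy - r_px)), 0)
    r1 = min(int(np.ceil(cy + r_px)) + 1, shape[0])
    c0 = max(int(np.floor(cx - r_px)), 0)
    c1 = min(int(np.ceil(cx + r_px)) + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return np.array([], int), np.array([], int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr + 0.5 - cy) ** 2 + (cc + 0.5 - cx) ** 2 <= r_px**2
    return rr[inside], cc[inside]


def extract_training_spectra(
    features: np.ndarray,
    mask: np.ndarray,
    crowns: list[Crown],
    min_pixels: int = 3,
    truth_map: np.ndarray | None = None,
) -> TrainingSet:
    """Collect one sample per valid pixel inside each crown footprint.

    ``features`` is a per-pixel feature stack ``(rows, cols, d)`` (e.g. MNF
    scores).  Crowns with fewer than ``min_pixels`` valid pixels are skipped
    with a warning.  When ``truth_map`` is given, footprint pixels whose
    rasterized truth label differs from the crown's species are dropped
    (overlapped crowns), mirroring pure-patch field sampling.
    """
    rows, cols, _ = features.shape
    xs, ys, labels, ids = [], [], [], []
    skipped = 0
    for i, crown in enumerate(crowns):
        rr, cc = crown_footprint_pixels(crown, (rows, cols))
        if rr.size:
            ok = mask[rr, cc]
            if truth_map is not None:
                ok &= truth_map[rr, cc] == crown.species
            rr, cc = rr[ok], cc[ok]
        if rr.size < min_pixels:
            skipped += 1
            continue
        xs.append(features[rr, cc])
        labels.append(np.full(rr.size, crown.species_id, dtype=object))
        ids.append(np.full(rr.size, i, dtype=int))
    if skipped:
        logger.warning("skipped %d crowns with < %d valid pixels", skipped, min_pixels)
    if not xs:
        raise ValueError("no crown overlaps any valid pixel")
    return TrainingSet(
        samples=np.vstack(xs),
        labels=np.concatenate(labels),
        crown_ids=np.concatenate(ids),
    )


def pool_rare_classes(ts: TrainingSet, min_crowns: int = 2, min_samples: int = 20,
                      others_label: str = "others") -> TrainingSet:
    """Pool classes with too few crowns or pixels into an ``others`` class,
    mirroring the treatment of infrequent species as one abundant class."""
    labels = ts.labels.copy()
    for lab in np.unique(labels):
        m = labels == lab
        if len(np.unique(ts.crown_ids[m])) < min_crowns or m.sum() < min_samples:
            labels[m] = others_label
    return TrainingSet(ts.samples, labels, ts.crown_ids, ts.split)


def split_train_test(
    ts: TrainingSet, train_fraction: float = 0.75, seed: int = 0
) -> TrainingSet:
    """Per-class random 75/25 split into disjoint train and test tags."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split = np.empty(len(ts.labels), dtype=object)
    for lab in np.unique(ts.labels):
        idx = np.flatnonzero(ts.labels == lab)
        if idx.size < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_train = max(int(round(train_fraction * idx.size)), 1)
        n_train = min(n_train, idx.size - 1)  # keep at least one test sample
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "test"
    return TrainingSet(ts.samples, ts.labels, ts.crown_ids, split)


def subsample_per_class(
    samples: np.ndarray, labels: np.ndarray, max_per_class: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly cap each class at ``max_per_class`` samples (keeps runtime
    bounded on large scenes; class balance is restored later by SMOTE)."""
    rng = np.random.default_rng(seed)
    keep = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size > max_per_class:
            idx = rng.choice(idx, size=max_per_class, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return samples[keep], labels[keep]


def smote_balance(
    samples: np.ndarray, labels: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class to the majority count with SMOTE.

    Synthetic points are convex combinations ``x + u (x_nn - x)``, u in
    [0, 1), of a sample and one of its k nearest same-class neighbors.
    ``k_neighbors`` is reduced (with a warning) for classes smaller than
    ``k + 1``.  Already balanced input is returned unchanged.
    """
    samples = np.asarray(samples, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    target = counts.max()
    if np.all(counts == target):
        return samples.copy(), labels.copy()
    rng = np.random.default_rng(seed)
    out_x, out_y = [samples], [labels]
    for cls, count in zip(classes, counts):
        need = target - count
        if need == 0:
            continue
        x = samples[labels == cls]
        if len(x) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 samples for SMOTE")
        k = min(k_neighbors, len(x) - 1)
        if k < k_neighbors:
            logger.warning("class %r: k_neighbors reduced to %d", cls, k)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
        _, nbr = nn.kneighbors(x)  # first neighbor is the point itself
        base = rng.integers(0, len(x), need)
        pick = nbr[base, rng.integers(1, k + 1, need)]
        u = rng.random(need)[:, None]
        out_x.append(x[base] + u * (x[pick] - x[base]))
        out_y.append(np.full(need, cls, dtype=labels.dtype))
    return np.vstack(out_x), np.concatenate(out_y)


@dataclass
class TunedForest:
    model: RandomForestClassifier
    mtry: int
    ntree: int
    oob_error: float  # percent
    classes_: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.classes_ = self.model.classes_

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)


def train_rf(
    samples: np.ndarray,
    labels: np.ndarray,
    mtry_grid: list[int] | None = None,
    ntree_grid: list[int] | None = None,
    seed: int = 0,
) -> TunedForest:
    """Grid-search (mtry, ntree) by out-of-bag accuracy and fit the forest.

    Ties resolve to the first grid combination; the chosen values and OOB
    error are logged and stored.
    """
    samples = np.asarray(samples, dtype=float)
    d = samples.shape[1]
    if mtry_grid is None:
        default = max(int(np.sqrt(d)), 1)
        mtry_grid = sorted({max(default // 2, 1), default, min(2 * default, d)})
    if ntree_grid is None:
        ntree_grid = [200, 500]
    if not mtry_grid or not ntree_grid:
        raise ValueError("empty hyperparameter grid")

    best = None
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            rf = RandomForestClassifier(
                n_estimators=ntree,
                max_features=min(mtry, d),
                oob_score=True,
                random_state=seed,
                n_jobs=1,
            )
            rf.fit(samples, labels)
            oob_acc = rf.oob_score_
            if best is None or oob_acc > best[0]:
                best = (oob_acc, mtry, ntree, rf)
    oob_acc, mtry, ntree, rf = best
    logger.info("RF tuned: mtry=%d ntree=%d OOB error=%.2f%%", mtry, ntree, (1 - oob_acc) * 100)
    return TunedForest(model=rf, mtry=mtry, ntree=ntree, oob_error=(1 - oob_acc) * 100.0)


def predict_map(
    classifier: TunedForest,
    features: np.ndarray,
    mask: np.ndarray,
    legend: dict[int, str] | None = None,
) -> ClassificationMap:
    """Label every unmasked pixel; masked pixels carry the non-forest code."""
    rows, cols, d = features.shape
    if d != classifier.model.n_features_in_:
        raise ValueError("feature dimension does not match the trained classifier")
    class_names = list(classifier.classes_)
    if legend is None:
        legend = {i: str(c) for i, c in enumerate(class_names)}
    name_to_code = {str(c): i for i, c in legend.items()}
    out = np.full((rows, cols), NONFOREST, dtype=np.int32)
    if mask.any():
        pred = classifier.predict(features[mask])
        out[mask] = np.array([name_to_code[str(p)] for p in pred], dtype=np.int32)
    return ClassificationMap(labels=out, mask=mask.copy(), legend=dict(legend))


def assess_accuracy(
    reference: np.ndarray, predicted: np.ndarray, oob_error: float | None = None
) -> ConfusionReport:
    """Confusion matrix with overall accuracy, Cohen's kappa and per-class
    producer's/user's accuracies (percent)."""
    return ConfusionReport.from_labels(reference, predicted, oob_error=oob_error)
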