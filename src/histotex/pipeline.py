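"""End-to-end classification pipeline and its evaluation metrics.

Flow: map an RGB image into four analysis spaces (entropy, LBP, R, B);
in every space extract 25 ACHLAC features and 16 co-occurrence features
(41 per space); cascade the spaces into one 164-long vector; standardize;
reduce to 7 dimensions with kernel PCA; classify with an SVM.  The abnormal
class is the positive class, normal the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import KernelPCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .glcm import glcm_feature_names as _glcm_names
from .glcm import glcm_feature_vector as _glcm_vector
from .hlac import achlac as _achlac
from .hlac import hlac as _hlac
from .masks import MaskSet, enumerate_masks, scale_masks
from .spaces import SPACE_NAMES, map_spaces

#: Label conventions: abnormal tissue is the positive class.
POSITIVE = "abnormal"
NEGATIVE = "normal"

HLAC_FAMILIES = ("hlac", "hlac_ext", "achlac")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the feature-extraction and classification stages.

    Defaults follow the method's reference setup: four spaces, 25 masks of
    order <= 2 in a 3 x 3 window, ACHLAC + 16 GLCM features per space
    (164 total), kernel PCA down to 7 dimensions, RBF-kernel SVM.
    """

    spaces: tuple[str, ...] = SPACE_NAMES
    max_order: int = 2
    mask_window: int = 3
    extended_radius: int | None = None  # odd radius; None = base 3x3 masks
    hlac_family: str = "achlac"
    include_glcm: bool = True
    entropy_window: int = 9
    glcm_distance: int = 1
    glcm_levels: int = 16
    kpca_components: int = 7
    kpca_kernel: str = "rbf"
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    seed: int = 0

    def __post_init__(self):
        if not self.spaces:
            raise ValueError("at least one space is required")
        if self.hlac_family not in HLAC_FAMILIES:
            raise ValueError(f"hlac_family must be one of {HLAC_FAMILIES}")

    def masks(self) -> MaskSet:
        base = enumerate_masks(self.max_order, self.mask_window)
        radius = self.extended_radius
        if self.hlac_family == "hlac_ext":
            radius = radius or 5
        if radius is not None:
            base = scale_masks(base, radius)
        return base


def feature_names(cfg: PipelineConfig) -> list[str]:
    """Deterministic column names: ``<space>/<family>/<slot>``."""
    masks = cfg.masks()
    names: list[str] = []
    for space in cfg.spaces:
        names += [f"{space}/{cfg.hlac_family}/{m}" for m in masks.names()]
        if cfg.include_glcm:
            names += [f"{space}/glcm/{g}" for g in _glcm_names()]
    return names


def _family_block(gray: np.ndarray, family: str, masks: MaskSet) -> np.ndarray:
    if family == "achlac":
        return _achlac(gray, masks)
    return _hlac(gray, masks)  # raw sums for hlac / hlac_ext


def extract_features(img: np.ndarray, cfg: PipelineConfig = PipelineConfig()) -> pd.Series:
    """Cascaded feature vector of one RGB image.

    Per space the HLAC-family block (25 values under the default masks) is
    followed by the 16 co-occurrence statistics; spaces are concatenated in
    configuration order.  Default length: 4 x (25 + 16) = 164.
    """
    maps = map_spaces(img, cfg.spaces, entropy_window=cfg.entropy_window)
    masks = cfg.masks()
    blocks = []
    for space in cfg.spaces:
        gray = maps[space]
        blocks.append(_family_block(gray, cfg.hlac_family, masks))
        if cfg.include_glcm:
            blocks.append(
                _glcm_vector(gray, distance=cfg.glcm_distance, levels=cfg.glcm_levels)
            )
    return pd.Series(np.concatenate(blocks), index=feature_names(cfg))


def extract_dataset(
    images: Sequence[np.ndarray], cfg: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Feature table (one row per image) with stable column names."""
    return pd.DataFrame([extract_features(img, cfg) for img in images])


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF bandwidth from the median pairwise Euclidean distance."""
    d = pairwise_distances(x)
    med = float(np.median(d[np.triu_indices_from(d, k=1)])) if len(x) > 1 else 0.0
    if med <= 0:
        return 1.0 / max(x.shape[1], 1)
    return 1.0 / (2.0 * med**2)


def _make_classifier(name: str, cfg: PipelineConfig):
    name = name.lower()
    if name == "svm":
        return SVC(kernel=cfg.svm_kernel, C=cfg.svm_c, random_state=cfg.seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=cfg.seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown classifier {name!r}")


class TexturePipeline:
    """Standardize -> kernel PCA -> classifier, fitted on labeled images.

    The scaler, the kernel-PCA projection and the classifier are all fitted
    on the training data only; given a fixed config seed the whole fit is
    deterministic.
    """

    def __init__(self, cfg: PipelineConfig = PipelineConfig(), classifier: str = "svm"):
        self.cfg = cfg
        self.classifier_name = classifier
        self._fitted = False

    # -- fitting ---------------------------------------------------------
    def fit_features(self, x: pd.DataFrame | np.ndarray, y: Sequence[str]) -> "TexturePipeline":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y)
        classes = set(y)
        if not {POSITIVE, NEGATIVE} <= classes:
            raise ValueError(
                f"training labels must include both {POSITIVE!r} and {NEGATIVE!r}"
            )
        n_comp = self.cfg.kpca_components
        if len(x) < n_comp:
            raise ValueError(f"need at least {n_comp} training samples")
        self.scaler_ = StandardScaler().fit(x)
        xs = self.scaler_.transform(x)
        gamma = _median_heuristic_gamma(xs) if self.cfg.kpca_kernel == "rbf" else None
        self.kpca_ = KernelPCA(
            n_components=n_comp,
            kernel=self.cfg.kpca_kernel,
            gamma=gamma,
            random_state=self.cfg.seed,
        ).fit(xs)
        xk = self.kpca_.transform(xs)
        self.clf_ = _make_classifier(self.classifier_name, self.cfg).fit(xk, y)
        self._fitted = True
        return self

    def fit(self, images: Sequence[np.ndarray], labels: Sequence[str]) -> "TexturePipeline":
        return self.fit_features(extract_dataset(images, self.cfg), labels)

    # -- inference -------------------------------------------------------
    def transform_features(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project feature vectors into the reduced KPCA space (7-D default)."""
        self._check_fitted()
        return self.kpca_.transform(self.scaler_.transform(np.asarray(x, dtype=np.float64)))

    def predict_features(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self.clf_.predict(self.transform_features(x))

    def predict(self, images: Sequence[np.ndarray]) -> np.ndarray:
        """One label per image, from {'normal', 'abnormal'}."""
        return self.predict_features(extract_dataset(images, self.cfg))

    def _check_fitted(self):
        if not self._fitted:
            raise RuntimeError("pipeline is not fitted; call fit() first")


# -- evaluation ----------------------------------------------------------

@dataclass(frozen=True)
class HybridMatrix:
    """Confusion counts with abnormal as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.fp + self.tn

    @property
    def c(self) -> int:
        return self.p + self.n


@dataclass(frozen=True)
class EvaluationMetrics:
    """Rates derived from the confusion counts.

    FPR + TNR = 1 and FNR + TPR = 1 whenever the corresponding class is
    present in the truth; a rate whose class is absent is NaN.
    """

    accuracy: float
    tpr: float
    tnr: float
    fpr: float
    fnr: float


def evaluate(
    predicted: Sequence[str], truth: Sequence[str]
) -> tuple[HybridMatrix, EvaluationMetrics]:
    """Confusion counts and rates for predicted vs true labels.

    accuracy = (TP + TN) / C, TPR = TP / P, TNR = TN / N, FPR = FP / N,
    FNR = FN / P.  If a class is absent from the truth the rates over that
    class are undefined and reported as NaN.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    tp = int(((predicted == POSITIVE) & (truth == POSITIVE)).sum())
    fn = int(((predicted == NEGATIVE) & (truth == POSITIVE)).sum())
    fp = int(((predicted == POSITIVE) & (truth == NEGATIVE)).sum())
    tn = int(((predicted == NEGATIVE) & (truth == NEGATIVE)).sum())
    hm = HybridMatrix(tp, fn, fp, tn)
    tpr = tp / hm.p if hm.p else float("nan")
    fnr = fn / hm.p if hm.p else float("nan")
    tnr = tn / hm.n if hm.n else float("nan")
    fpr = fp / hm.n if hm.n else float("nan")
    return hm, EvaluationMetrics((tp + tn) / hm.c, tpr, tnr, fpr, fnr)


# -- contrast experiments ------------------------------------------------

def run_contrast_experiment(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    variants: Sequence[str] = HLAC_FAMILIES,
    classifiers: Sequence[str] = ("svm",),
    cfg: PipelineConfig = PipelineConfig(),
    include_glcm: bool = False,
    test_size: float = 0.5,
) -> pd.DataFrame:
    """Compare HLAC feature families (and classifiers) on a held-out split.

    For every (variant, classifier) pair the pipeline is retrained on a
    stratified train split and evaluated on the complementary test split;
    the analysis-space maps are computed once per image and shared across
    variants.  Returns a table with columns variant, classifier, accuracy,
    tpr, tnr.
    """
    labels = np.asarray(labels)
    for v in variants:
        if v not in HLAC_FAMILIES:
            raise ValueError(f"unknown variant {v!r}")
    tables = {
        v: extract_dataset(
            images, replace(cfg, hlac_family=v, include_glcm=include_glcm)
        )
        for v in variants
    }
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, stratify=labels, random_state=cfg.seed
    )
    rows = []
    for v in variants:
        x = tables[v].to_numpy()
        for clf in classifiers:
            pipe = TexturePipeline(replace(cfg, hlac_family=v), classifier=clf)
            pipe.fit_features(x[train_idx], labels[train_idx])
            pred = pipe.predict_features(x[test_idx])
            _, met = evaluate(pred, labels[test_idx])
            rows.append(
                {
                    "variant": v,
                    "classifier": clf,
                    "accuracy": met.accuracy,
                    "tpr": met.tpr,
                    "tnr": met.tnr,
                }
            )
    return pd.DataFrame(rows)
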