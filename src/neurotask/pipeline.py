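"""One-vs-rest experiment orchestration and evaluation.

Multiclass mental-task recognition is cast as K one-class problems: for
each target class a DBN is trained unsupervised on that class's feature
vectors only, an anomaly detector (Isolation Forest by default; LOF or
elliptic envelope as comparators) is fitted on the DBN latent codes, and
at test time held-out target trials act as inliers while held-out trials
of every other class act as outliers.  Each (target, other) pair yields
a confusion-count row with accuracy, precision, recall, F1 and AUC —
``K * (K - 1)`` rows in total — plus a per-class mean-AUC summary.

Split protocol: 80% of the target class trains; the remaining 20% are
test inliers; an equal-fraction random 20% of each other class are test
outliers.  Min-max feature scaling is frozen on the target-class
training split only, so no test information (and no labels anywhere)
enters the fitted models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import dbn as dbn_mod
from . import detectors as det_mod
from .qtfd import CWKernelParams, FeatureScaler, trial_feature_matrix, DEFAULT_BAND_EDGES
from .signal_io import TrialSet

__all__ = [
    "SplitSpec",
    "Split",
    "DetectorConfig",
    "FeatureConfig",
    "ExperimentConfig",
    "ClassDetector",
    "PairMetrics",
    "EvaluationReport",
    "make_split",
    "confusion_metrics",
    "auc_score",
    "train_class_detector",
    "evaluate_pair",
    "run_experiment",
    "predict_class",
]


@dataclass
class SplitSpec:
    """Target class plus the train fraction (0.8 per the protocol)."""

    target_class: int
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class Split:
    """Index sets into the trial list of one TrialSet."""

    train_idx: np.ndarray
    test_inlier_idx: np.ndarray
    test_outlier_idx: dict[int, np.ndarray]


def make_split(trials: TrialSet, spec: SplitSpec) -> Split:
    """Disjoint target train/test indices plus per-other-class outlier pools."""
    labels = trials.labels
    classes = list(trials.classes)
    if spec.target_class not in classes:
        raise ValueError(f"class {spec.target_class} absent from the dataset")
    for c in classes:
        if (labels == c).sum() < 5:
            raise ValueError(f"class {c} has fewer than 5 trials")
    rng = np.random.default_rng(spec.seed)

    target_idx = np.flatnonzero(labels == spec.target_class)
    perm = rng.permutation(len(target_idx))
    n_train = int(round(spec.train_fraction * len(target_idx)))
    train_idx = np.sort(target_idx[perm[:n_train]])
    test_inlier_idx = np.sort(target_idx[perm[n_train:]])

    test_fraction = 1.0 - spec.train_fraction
    outliers = {}
    for c in classes:
        if c == spec.target_class:
            continue
        other_idx = np.flatnonzero(labels == c)
        n_out = max(1, int(round(test_fraction * len(other_idx))))
        chosen = rng.choice(other_idx, size=n_out, replace=False)
        outliers[int(c)] = np.sort(chosen)
    return Split(train_idx, test_inlier_idx, outliers)


def confusion_metrics(TP: int, FP: int, TN: int, FN: int
                      ) -> tuple[float, float, float, float]:
    """(accuracy, recall, precision, f1) from confusion counts.

    accuracy = (TP + TN) / (TP + FP + TN + FN); recall = TP / (TP + FN);
    precision = TP / (TP + FP); f1 = 2 TP / (2 TP + FP + FN).  A zero
    denominator returns 0 with a warning.
    """
    counts = (TP, FP, TN, FN)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts sum to zero")

    def _safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name} denominator is zero; returning 0",
                          RuntimeWarning, stacklevel=3)
            return 0.0
        return num / den

    accuracy = (TP + TN) / total
    recall = _safe(TP, TP + FN, "recall")
    precision = _safe(TP, TP + FP, "precision")
    f1 = _safe(2 * TP, 2 * TP + FP + FN, "f1")
    return accuracy, recall, precision, f1


def auc_score(scores: np.ndarray, is_outlier: np.ndarray) -> float:
    """Rank AUC: probability a random outlier's anomaly score exceeds a
    random inlier's, ties counted one half (Mann-Whitney statistic)."""
    is_outlier = np.asarray(is_outlier, dtype=bool)
    if is_outlier.all() or (~is_outlier).all():
        raise ValueError("need both inlier and outlier scores")
    return float(roc_auc_score(is_outlier, np.asarray(scores, dtype=float)))


@dataclass
class DetectorConfig:
    """Detector choice and its protocol hyperparameters."""

    kind: str = "if"  # {"if", "lof", "ee"}
    n_trees: int = 150
    psi: int = 256
    threshold: float = 0.5
    uncertain_band: float = 0.0
    n_neighbors: int = 35
    support_fraction: float = 0.9
    lof_threshold: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("if", "lof", "ee"):
            raise ValueError("detector kind must be 'if', 'lof' or 'ee'")


@dataclass
class FeatureConfig:
    """Time-frequency feature reduction settings (D = bands x time bins)."""

    kernel: CWKernelParams = field(default_factory=CWKernelParams)
    win_len: float = 1.0
    hop: float = 1.0
    band_edges: tuple = DEFAULT_BAND_EDGES
    n_time_bins: int = 5

    @property
    def n_features(self) -> int:
        return (len(self.band_edges) - 1) * self.n_time_bins


@dataclass
class ExperimentConfig:
    """Everything one experiment run needs, fully seeded."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    layer_sizes: tuple = dbn_mod.DEFAULT_LAYER_SIZES
    dbn: dbn_mod.TrainConfig = field(default_factory=dbn_mod.TrainConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    train_fraction: float = 0.8
    seed: int = 0

    def snapshot(self) -> dict:
        return asdict(self)


@dataclass
class ClassDetector:
    """Per-class fitted bundle: scaler -> DBN -> one-class detector.

    Everything inside was fitted on target-class trials only; no label is
    consumed by any fit routine.
    """

    target_class: int
    scaler: FeatureScaler
    dbn: dbn_mod.DBNModel
    config: DetectorConfig
    forest: det_mod.IsolationForestModel | None = None
    train_latent: np.ndarray | None = None

    def latent(self, raw_features: np.ndarray) -> np.ndarray:
        return dbn_mod.dbn_transform(self.dbn, self.scaler.transform(raw_features))

    def anomaly_scores(self, raw_features: np.ndarray) -> np.ndarray:
        """Higher = more anomalous, on each detector's native scale."""
        z = self.latent(raw_features)
        cfg = self.config
        if cfg.kind == "if":
            return det_mod.forest_scores(self.forest, z)
        if cfg.kind == "lof":
            return det_mod.lof_scores(self.train_latent, z, cfg.n_neighbors)
        return det_mod.ee_scores(self.train_latent, z, cfg.support_fraction,
                                 seed=cfg.seed)

    def is_anomaly(self, scores: np.ndarray) -> np.ndarray:
        cfg = self.config
        if cfg.kind == "if":
            return np.asarray(scores) > cfg.threshold
        if cfg.kind == "lof":
            return np.asarray(scores) > cfg.lof_threshold
        dim = self.dbn.layer_sizes[-1]
        return np.asarray(scores) > det_mod.ee_threshold(dim)


def train_class_detector(train_features: np.ndarray, detector_type: str = "if",
                         dbn_cfg: dbn_mod.TrainConfig | None = None,
                         det_cfg: DetectorConfig | None = None,
                         layer_sizes=dbn_mod.DEFAULT_LAYER_SIZES,
                         target_class: int = 0) -> ClassDetector:
    """Fit scaler, DBN and detector on one class's raw feature rows."""
    if det_cfg is None:
        det_cfg = DetectorConfig(kind=detector_type)
    if dbn_cfg is None:
        dbn_cfg = dbn_mod.TrainConfig()
    train_features = np.atleast_2d(train_features)
    if train_features.shape[1] != layer_sizes[0]:
        raise ValueError(
            f"feature width {train_features.shape[1]} does not match the DBN "
            f"input layer ({layer_sizes[0]})"
        )
    scaler = FeatureScaler().fit(train_features)
    scaled = scaler.transform(train_features)
    model = dbn_mod.train_dbn(scaled, layer_sizes, dbn_cfg)
    latent = dbn_mod.dbn_transform(model, scaled)

    det = ClassDetector(target_class, scaler, model, det_cfg,
                        train_latent=latent)
    if det_cfg.kind == "if":
        det.forest = det_mod.build_iforest(latent, det_cfg.n_trees,
                                           det_cfg.psi, det_cfg.seed)
    return det


@dataclass
class PairMetrics:
    """One (target, other) evaluation row mirroring the report table layout."""

    target_class: int
    other_class: int
    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float


def evaluate_pair(det: ClassDetector, inliers: np.ndarray,
                  outliers: np.ndarray, other_class: int = -1) -> PairMetrics:
    """Score inlier and outlier feature rows and tabulate one metric row.

    The positive class is target membership: a trial predicted *normal*
    is a predicted positive, and inliers are the actual positives.
    """
    inliers = np.atleast_2d(inliers)
    outliers = np.atleast_2d(outliers)
    if inliers.size == 0 or outliers.size == 0:
        raise ValueError("both inlier and outlier sets must be non-empty")
    s_in = det.anomaly_scores(inliers)
    s_out = det.anomaly_scores(outliers)
    anom_in = det.is_anomaly(s_in)
    anom_out = det.is_anomaly(s_out)

    TP = int((~anom_in).sum())   # inliers accepted
    FN = int(anom_in.sum())      # inliers rejected
    TN = int(anom_out.sum())     # outliers rejected
    FP = int((~anom_out).sum())  # outliers accepted
    accuracy, recall, precision, f1 = confusion_metrics(TP, FP, TN, FN)
    scores = np.concatenate([s_in, s_out])
    is_outlier = np.concatenate([np.zeros(len(s_in), bool),
                                 np.ones(len(s_out), bool)])
    return PairMetrics(det.target_class, other_class, TP, FP, TN, FN,
                       accuracy, precision, recall, f1,
                       auc_score(scores, is_outlier))


@dataclass
class EvaluationReport:
    """All pairwise rows plus per-class mean AUC and the config snapshot."""

    rows: list[PairMetrics]
    per_class_auc: dict[int, float]
    config: dict

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.csv`` (pair rows) and ``<prefix>.json`` (full report)."""
        self.to_dataframe().to_csv(f"{prefix}.csv", index=False)
        payload = {
            "pairs": [asdict(r) for r in self.rows],
            "per_class_auc": {str(k): v for k, v in self.per_class_auc.items()},
            "config": self.config,
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-stage seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def run_experiment(dataset: TrialSet, config: ExperimentConfig | None = None,
                   out_prefix: str | None = None,
                   raw_features: np.ndarray | None = None) -> EvaluationReport:
    """Full one-vs-rest pipeline on a labeled TrialSet.

    Raw (pre-scaling) trial features are computed once and shared across
    target classes — they are label-free, and per-class scaling is still
    fit on each target's training split only.  ``raw_features`` lets a
    caller reuse a precomputed matrix.
    """
    if config is None:
        config = ExperimentConfig()
    fc = config.features
    if raw_features is None:
        raw_features = trial_feature_matrix(
            dataset, fc.kernel, fc.win_len, fc.hop, fc.band_edges,
            fc.n_time_bins,
        )
    classes = [int(c) for c in dataset.classes]
    seeds = _stage_seeds(config.seed, 2 * len(classes))

    rows: list[PairMetrics] = []
    per_class_auc: dict[int, float] = {}
    for i, target in enumerate(classes):
        split = make_split(dataset, SplitSpec(target, config.train_fraction,
                                              seed=seeds[2 * i]))
        dbn_cfg = dbn_mod.TrainConfig(
            k_gibbs=config.dbn.k_gibbs,
            learning_rate=config.dbn.learning_rate,
            epochs=config.dbn.epochs,
            batch_size=config.dbn.batch_size,
            seed=seeds[2 * i + 1],
        )
        det_cfg = DetectorConfig(**{**asdict(config.detector),
                                    "seed": seeds[2 * i + 1]})
        det = train_class_detector(raw_features[split.train_idx],
                                   detector_type=det_cfg.kind,
                                   dbn_cfg=dbn_cfg, det_cfg=det_cfg,
                                   layer_sizes=config.layer_sizes,
                                   target_class=target)
        aucs = []
        for other, out_idx in split.test_outlier_idx.items():
            pm = evaluate_pair(det, raw_features[split.test_inlier_idx],
                               raw_features[out_idx], other_class=other)
            rows.append(pm)
            aucs.append(pm.auc)
        per_class_auc[target] = float(np.mean(aucs))

    report = EvaluationReport(rows, per_class_auc, config.snapshot())
    if out_prefix is not None:
        report.save(out_prefix)
    return report


def predict_class(bank: list[ClassDetector], x: np.ndarray) -> int:
    """Multiclass extension: the class whose detector scores ``x`` least
    anomalous wins; ties break toward the lowest class id.

    Note this aggregation goes beyond the pairwise one-vs-rest protocol
    the per-pair reports describe.
    """
    if not bank:
        raise ValueError("empty detector bank")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    order = sorted(bank, key=lambda d: d.target_class)
    scores = [float(d.anomaly_scores(x)[0]) for d in order]
    return order[int(np.argmin(scores))].target_class
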