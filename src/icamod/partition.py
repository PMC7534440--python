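"""Partitioning of independent components into hemi-modules.

Each continuous component column of S is converted into discrete gene sets:
genes with extreme positive standardized weights form the "a" hemi-module,
genes with extreme negative weights the "b" hemi-module, and the rest are
excluded (0 in the trivalued S_p matrix).  Components are first oriented so
their skewness is non-negative; the "a" hemi-module therefore comes from
the more highly skewed side.

Thresholds are stated in within-component standard-deviation units.  Two
partitioners are provided: a fixed symmetric threshold (default +-3 sd) and
a learned predictor that maps each component's shape (skewness, excess
kurtosis) to per-component asymmetric thresholds.  Different components
reach their best member recovery at different thresholds, so the learned
predictor typically yields more annotation-rich modules than any single
fixed cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .data_model import AnnotationSet, ValidationError
from .ica import Decomposition
from .synthetic import ComponentExample

log = logging.getLogger(__name__)

__all__ = [
    "PartitionedModules",
    "ThresholdModel",
    "orient_components",
    "fixed_threshold_partition",
    "fit_threshold_model",
    "model_partition",
]


@dataclass
class PartitionedModules:
    """Trivalued features x k matrix S_p plus the derived hemi-module sets.

    Entry +1 assigns a gene to the positive ("a") hemi-module of a
    component, -1 to the negative ("b") hemi-module, 0 excludes it.  Every
    component contributes exactly two hemi-module sets (possibly empty), so
    k components yield 2k hemi-modules.  Hemi ids are ordered block-wise
    (m1a..mka then m1b..mkb) to line up with the H = [S, -S] column order.
    """

    S_p: np.ndarray
    feature_ids: list[str]
    component_ids: list[str]
    thresholds_used: list[tuple[float, float]]

    def __post_init__(self) -> None:
        self.S_p = np.asarray(self.S_p)
        if not np.isin(self.S_p, (-1, 0, 1)).all():
            raise ValidationError("S_p entries must be in {-1, 0, +1}")
        if self.S_p.shape != (len(self.feature_ids), len(self.component_ids)):
            raise ValidationError("S_p shape does not match labels")
        if len(self.thresholds_used) != len(self.component_ids):
            raise ValidationError("one (t_pos, t_neg) pair required per component")

    @property
    def k(self) -> int:
        return len(self.component_ids)

    @property
    def hemi_ids(self) -> list[str]:
        return [f"{c}a" for c in self.component_ids] + [
            f"{c}b" for c in self.component_ids
        ]

    def hemi_masks(self) -> np.ndarray:
        """Boolean features x 2k membership matrix in hemi_ids order."""
        return np.concatenate([self.S_p == 1, self.S_p == -1], axis=1)

    def hemi_sets(self) -> dict[str, set[str]]:
        masks = self.hemi_masks()
        fids = np.asarray(self.feature_ids)
        return {
            h: set(fids[masks[:, j]]) for j, h in enumerate(self.hemi_ids)
        }

    def to_annotation_set(self) -> AnnotationSet:
        """Non-empty hemi-modules as Boolean gene sets (GMT-exportable)."""
        masks = self.hemi_masks()
        keep = masks.any(axis=0)
        return AnnotationSet(
            masks[:, keep],
            list(self.feature_ids),
            [h for h, k_ in zip(self.hemi_ids, keep) if k_],
        )


def _standardize_columns(S: np.ndarray) -> np.ndarray:
    sd = S.std(axis=0)
    sd[sd == 0] = 1.0
    return (S - S.mean(axis=0)) / sd


def orient_components(D: Decomposition) -> Decomposition:
    """Flip components (and their mixing rows) so every skewness is >= 0.

    The reconstruction S . A is unchanged; only the sign convention of each
    component is fixed so the "a" hemi-module is the more skewed side.
    """
    skew = stats.skew(D.S, axis=0)
    flip = skew < 0
    if (skew == 0).any():
        log.info("%d component(s) with exactly zero skewness left as-is", int((skew == 0).sum()))
    sign = np.where(flip, -1.0, 1.0)
    return Decomposition(
        S=D.S * sign[None, :],
        A=D.A * sign[:, None],
        k=D.k,
        seed=D.seed,
        converged=D.converged,
        n_iter=D.n_iter,
        feature_ids=list(D.feature_ids),
        sample_ids=list(D.sample_ids),
        mean=D.mean,
    )


def _partition(S: np.ndarray, t_pos: np.ndarray, t_neg: np.ndarray) -> np.ndarray:
    Z = _standardize_columns(S)
    S_p = np.zeros(S.shape, dtype=np.int8)
    S_p[Z >= t_pos[None, :]] = 1
    S_p[Z <= t_neg[None, :]] = -1
    return S_p


def fixed_threshold_partition(D: Decomposition, t: float = 3.0) -> PartitionedModules:
    """Assign genes with standardized weight >= t to "a", <= -t to "b"."""
    if t < 0:
        raise ValidationError("threshold must be >= 0")
    t_pos = np.full(D.k, float(t))
    t_neg = -t_pos
    return PartitionedModules(
        S_p=_partition(D.S, t_pos, t_neg),
        feature_ids=list(D.feature_ids),
        component_ids=D.component_ids,
        thresholds_used=[(float(t), -float(t))] * D.k,
    )


@dataclass
class ThresholdModel:
    """Learned map (skewness, excess kurtosis) -> (t_pos, t_neg).

    A small feed-forward network (2 inputs, one hidden layer of 8 tanh
    units, 2 outputs) regresses the member-recovery-optimal thresholds of
    simulated components on their shape statistics.  Inputs outside the
    training range are clamped to its boundary.
    """

    regressor: Pipeline
    feature_min: np.ndarray  # training-domain lower bound (skew, kurt)
    feature_max: np.ndarray
    n_examples: int
    seed: int
    loss: float

    def predict(self, skewness, kurtosis) -> tuple[np.ndarray, np.ndarray]:
        feats = np.column_stack(
            [np.atleast_1d(np.asarray(skewness, float)), np.atleast_1d(np.asarray(kurtosis, float))]
        )
        clipped = np.clip(feats, self.feature_min, self.feature_max)
        if (clipped != feats).any():
            log.warning(
                "%d component shape(s) outside the training domain; clamped",
                int((clipped != feats).any(axis=1).sum()),
            )
        pred = self.regressor.predict(clipped)
        pred = np.atleast_2d(pred)
        t_pos = np.maximum(pred[:, 0], 0.0)
        t_neg = np.minimum(pred[:, 1], 0.0)
        return t_pos, t_neg


_THRESHOLD_GRID = np.round(np.arange(0.5, 6.0 + 1e-9, 0.1), 10)


def _f1(n_true_pos: int, n_pred: int, n_true: int) -> float:
    if n_pred == 0 or n_true == 0 or n_true_pos == 0:
        return 0.0
    precision = n_true_pos / n_pred
    recall = n_true_pos / n_true
    return 2 * precision * recall / (precision + recall)


def _optimal_thresholds(example: ComponentExample) -> tuple[float, float]:
    """Grid-sweep (step 0.1 sd) the F1 of recovered vs planted members."""
    z = example.values
    z = (z - z.mean()) / z.std()
    best_pos, best_pos_f1 = 3.0, -1.0
    best_neg, best_neg_f1 = 3.0, -1.0
    pos_set = set(example.pos_members.tolist())
    neg_set = set(example.neg_members.tolist())
    for t in _THRESHOLD_GRID:
        pred_pos = np.flatnonzero(z >= t)
        f1p = _f1(len(pos_set.intersection(pred_pos)), pred_pos.size, len(pos_set))
        if f1p > best_pos_f1:
            best_pos, best_pos_f1 = float(t), f1p
        pred_neg = np.flatnonzero(z <= -t)
        f1n = _f1(len(neg_set.intersection(pred_neg)), pred_neg.size, len(neg_set))
        if f1n > best_neg_f1:
            best_neg, best_neg_f1 = float(t), f1n
    return best_pos, -best_neg


def fit_threshold_model(
    training: list[ComponentExample],
    seed: int = 0,
) -> ThresholdModel:
    """Fit the threshold predictor on simulated components with known members.

    Each training component is labelled with the (t_pos, t_neg) pair that
    maximizes the F1 of recovered vs planted members (independent sweeps of
    the positive and negative side, 0.1 sd grid); the network then regresses
    these labels on (skewness, excess kurtosis).  Seeded and reproducible.
    """
    if len(training) < 2:
        raise ValidationError("need at least two training components")
    feats = np.array(
        [
            (stats.skew(ex.values), stats.kurtosis(ex.values))
            for ex in training
        ]
    )
    if np.allclose(feats.std(axis=0), 0.0):
        raise ValidationError(
            "degenerate training set: all components share one shape point"
        )
    labels = np.array([_optimal_thresholds(ex) for ex in training])
    reg = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPRegressor(
                    hidden_layer_sizes=(8,),
                    activation="tanh",
                    solver="lbfgs",
                    max_iter=5000,
                    random_state=int(seed),
                ),
            ),
        ]
    )
    reg.fit(feats, labels)
    loss = float(np.mean((reg.predict(feats) - labels) ** 2))
    return ThresholdModel(
        regressor=reg,
        feature_min=feats.min(axis=0),
        feature_max=feats.max(axis=0),
        n_examples=len(training),
        seed=int(seed),
        loss=loss,
    )


def model_partition(D: Decomposition, M: ThresholdModel) -> PartitionedModules:
    """Partition with per-component thresholds predicted from shape.

    Components should be oriented first.  A non-finite prediction for a
    component falls back to the fixed +-3 rule with a warning.
    """
    Z = _standardize_columns(D.S)
    skew = stats.skew(Z, axis=0)
    kurt = stats.kurtosis(Z, axis=0)
    t_pos, t_neg = M.predict(skew, kurt)
    bad = ~(np.isfinite(t_pos) & np.isfinite(t_neg))
    if bad.any():
        log.warning(
            "non-finite threshold prediction for %d component(s); using +-3",
            int(bad.sum()),
        )
        t_pos = np.where(bad, 3.0, t_pos)
        t_neg = np.where(bad, -3.0, t_neg)
    return PartitionedModules(
        S_p=_partition(D.S, t_pos, t_neg),
        feature_ids=list(D.feature_ids),
        component_ids=D.component_ids,
        thresholds_used=[(float(p), float(n)) for p, n in zip(t_pos, t_neg)],
    )
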