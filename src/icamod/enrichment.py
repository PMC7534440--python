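"""Hypergeometric annotation enrichment of hemi-modules.

The enrichment matrix E has one row per hemi-module (2k rows, block order
m1a..mka then m1b..mkb) and one column per annotation.  Entries are signed
natural-log p-values: -log(p) for over-represented annotations (positive),
+log(p) for under-represented ones (negative).  An annotation is called
significant for a module set when the Simes global test over its 2k
over-representation p-values rejects; the count of significant annotations
is the module-quality metric used by the optimizer.  (The count deliberately
uses annotations, not modules-with->=1-annotation, which rewards splitting a
signal across several weaker components.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_model import AnnotationSet, ValidationError
from .partition import PartitionedModules

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentMatrix",
    "hypergeom_test",
    "hemi_annotation_pvalues",
    "build_E",
    "simes_pvalue",
    "simes_significant",
    "count_significant_annotations",
    "bh_qvalues",
]

_MIN_P = 1e-300  # floor before taking logs; keeps E finite


@dataclass
class EnrichmentMatrix:
    """Hemi-modules x annotations signed log p-value matrix."""

    values: np.ndarray
    hemi_ids: list[str]
    annotation_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.hemi_ids), len(self.annotation_ids)):
            raise ValidationError("E shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValidationError("E entries must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.hemi_ids, columns=self.annotation_ids
        )


def hypergeom_test(
    hemi: set[str], annotation: set[str], universe
) -> tuple[float, float]:
    """One-sided over/under-representation p-values for one pair of sets.

    Sampling |hemi| features without replacement from a universe containing
    |annotation| successes: p_over = P(overlap >= observed), p_under =
    P(overlap <= observed).  Both sets are restricted to the universe first.
    """
    universe = list(universe)
    M = len(universe)
    if M == 0:
        raise ValidationError("empty universe")
    uset = set(universe)
    hemi_u = set(hemi) & uset
    ann_u = set(annotation) & uset
    n_draw = len(hemi_u)
    if n_draw == 0:
        return 1.0, 1.0
    K = len(ann_u)
    obs = len(hemi_u & ann_u)
    p_over = float(hypergeom.sf(obs - 1, M, K, n_draw))
    p_under = float(hypergeom.cdf(obs, M, K, n_draw))
    return min(p_over, 1.0), min(p_under, 1.0)


def hemi_annotation_pvalues(
    P: PartitionedModules, B: AnnotationSet
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (p_over, p_under) arrays, shape (2k, n_annotations).

    Requires the partition and the annotation set to share one feature
    universe (same ids in the same order).
    """
    if list(P.feature_ids) != list(B.feature_ids):
        raise ValidationError(
            "partition and annotation set must share one feature universe"
        )
    masks = P.hemi_masks()  # features x 2k
    inc = B.incidence  # features x n_ann
    M = len(P.feature_ids)
    overlap = masks.T.astype(np.int64) @ inc.astype(np.int64)  # 2k x n_ann
    n_draw = masks.sum(axis=0).astype(np.int64)  # per hemi
    K = inc.sum(axis=0).astype(np.int64)  # per annotation
    Kg, ng = np.meshgrid(K, n_draw)
    p_over = hypergeom.sf(overlap - 1, M, Kg, ng)
    p_under = hypergeom.cdf(overlap, M, Kg, ng)
    empty = n_draw == 0
    p_over[empty, :] = 1.0
    p_under[empty, :] = 1.0
    return np.minimum(p_over, 1.0), np.minimum(p_under, 1.0)


def build_E(P: PartitionedModules, B: AnnotationSet) -> EnrichmentMatrix:
    """Signed log-p enrichment matrix over all hemi-module/annotation pairs.

    Entry = -log(p_over) when the annotation is over-represented
    (p_over <= p_under), +log(p_under) when under-represented; natural log.
    """
    p_over, p_under = hemi_annotation_pvalues(P, B)
    over = p_over <= p_under
    values = np.where(
        over,
        -np.log(np.maximum(p_over, _MIN_P)),
        np.log(np.maximum(p_under, _MIN_P)),
    )
    return EnrichmentMatrix(values, P.hemi_ids, list(B.annotation_ids))


def _validate_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return p


def simes_pvalue(p_values) -> float:
    """Simes global statistic min_i { n * p_(i) / i } over sorted p-values."""
    p = np.sort(_validate_pvalues(p_values))
    n = p.size
    return float(np.min(n * p / np.arange(1, n + 1)))


def simes_significant(p_values, alpha: float = 0.05) -> bool:
    """Simes global test: is at least one null in the set false at alpha?"""
    return simes_pvalue(p_values) <= alpha


def count_significant_annotations(
    P: PartitionedModules, B: AnnotationSet, alpha: float = 0.05
) -> int:
    """Number of annotations enriched in at least one hemi-module.

    Per annotation, the over-representation p-values across all 2k
    hemi-modules are aggregated with the Simes test at ``alpha``.
    Depletion contributes to E but not to this quality metric.
    """
    p_over, _ = hemi_annotation_pvalues(P, B)
    n = p_over.shape[0]
    ranks = np.arange(1, n + 1)
    sorted_p = np.sort(p_over, axis=0)
    simes = (n * sorted_p / ranks[:, None]).min(axis=0)
    return int((simes <= alpha).sum())


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = _validate_pvalues(p_values)
    return multipletests(p, method="fdr_bh")[1]
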