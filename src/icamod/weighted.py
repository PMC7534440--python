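"""Module-weighted annotations.

A Boolean annotation says whether a gene carries a term; a module-weighted
annotation says how strongly the term is predicted by the gene's module
membership.  The module definition matrix S is concatenated with its
negative, H = [S, -S], so each column of H carries per-gene weights for one
hemi-module in the same order as the rows of the enrichment matrix E.  The
product R = H . E then relates every gene to every annotation: annotations
enriched in modules a gene belongs to are boosted, annotations foreign to
its modules are diminished.  R is normalized per annotation (mean 0, sd 1
across genes); the un-normalized variant is kept for ranking annotations by
their strongest gene weight.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .data_model import ValidationError
from .enrichment import EnrichmentMatrix

log = logging.getLogger(__name__)

__all__ = [
    "WeightedAnnotationMatrix",
    "build_H",
    "build_R",
    "rank_annotations_by_max_weight",
    "word_position_bias",
    "DEFAULT_STOPWORDS",
]

DEFAULT_STOPWORDS = frozenset({"the", "for", "and", "of", "to", "via", "in"})


@dataclass
class WeightedAnnotationMatrix:
    """Features x annotations continuous relevance scores (the R matrix)."""

    values: np.ndarray
    feature_ids: list[str]
    annotation_ids: list[str]
    normalized: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.annotation_ids)):
            raise ValidationError("R shape does not match labels")
        if not np.isfinite(self.values).all():
            raise ValidationError("R entries must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.annotation_ids
        )


def build_H(S: np.ndarray) -> np.ndarray:
    """Unpartitioned hemi-module matrix H = [S, -S].

    Column order: the k "a" columns (S) then the k "b" columns (-S),
    matching the row order of :func:`icamod.enrichment.build_E`.
    Components should be oriented (skewness >= 0) first.
    """
    S = np.asarray(S, dtype=float)
    return np.concatenate([S, -S], axis=1)


def build_R(
    H: np.ndarray,
    E: EnrichmentMatrix,
    normalize: bool = True,
    feature_ids: list[str] | None = None,
) -> WeightedAnnotationMatrix:
    """Module-weighted annotation matrix R = H . E.

    ``normalize`` standardizes each annotation column across features
    (mean 0, sd 1).  Keep an un-normalized copy when ranking annotations by
    their most strongly associated gene.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[1] != E.values.shape[0]:
        raise ValidationError(
            f"H has {H.shape[1]} columns but E has {E.values.shape[0]} rows; "
            "column/row order must match (a-block then b-block)"
        )
    R = H @ E.values
    if normalize:
        sd = R.std(axis=0)
        sd[sd == 0] = 1.0
        R = (R - R.mean(axis=0)) / sd
    if feature_ids is None:
        feature_ids = [f"f{i + 1}" for i in range(H.shape[0])]
    return WeightedAnnotationMatrix(
        R, list(feature_ids), list(E.annotation_ids), normalized=normalize
    )


def rank_annotations_by_max_weight(
    R: WeightedAnnotationMatrix, n_top_features: int = 5
) -> pd.DataFrame:
    """Annotations ranked by the weight of their most strongly associated gene.

    Requires the un-normalized R (per-annotation standardization equalizes
    column scales and destroys the ranking signal).
    """
    if R.normalized:
        raise ValidationError("ranking requires the un-normalized R matrix")
    fids = np.asarray(R.feature_ids)
    max_w = R.values.max(axis=0)
    order = np.argsort(-max_w)
    rows = []
    for rank, j in enumerate(order, start=1):
        top_idx = np.argsort(-R.values[:, j])[:n_top_features]
        rows.append(
            {
                "annotation": R.annotation_ids[j],
                "rank": rank,
                "max_weight": max_w[j],
                "top_features": ",".join(fids[top_idx]),
            }
        )
    return pd.DataFrame(rows)


def _tokenize(name: str, min_word_len: int, stopwords) -> set[str]:
    words = re.split(r"[^0-9a-z]+", name.lower())
    return {w for w in words if len(w) >= min_word_len and w not in stopwords}


def word_position_bias(
    ranked_annotations,
    min_word_len: int = 3,
    stopwords=DEFAULT_STOPWORDS,
) -> pd.DataFrame:
    """Test each semantic word for bias toward the top or bottom of a ranking.

    ``ranked_annotations`` is a sequence of annotation names in rank order
    (best first) or the frame from :func:`rank_annotations_by_max_weight`.
    Per word, ranks of annotations containing it are compared with ranks of
    the rest (two-sided Mann-Whitney rank-sum).  ``bias`` is the rank-
    biserial correlation, positive = top-biased.
    """
    if isinstance(ranked_annotations, pd.DataFrame):
        names = ranked_annotations.sort_values("rank")["annotation"].tolist()
    else:
        names = list(ranked_annotations)
    if not names:
        raise ValidationError("empty ranking")
    tokens = [_tokenize(n, min_word_len, stopwords) for n in names]
    vocab = sorted(set().union(*tokens)) if tokens else []
    ranks = np.arange(1, len(names) + 1, dtype=float)
    rows = []
    for word in vocab:
        has = np.array([word in t for t in tokens])
        with_ranks, without_ranks = ranks[has], ranks[~has]
        if with_ranks.size == 0 or without_ranks.size == 0:
            rows.append({"word": word, "n_with": int(has.sum()), "bias": 0.0, "p": 1.0})
            continue
        u1, p = mannwhitneyu(with_ranks, without_ranks, alternative="two-sided")
        # rank-biserial: +1 when the word sits entirely at the top (low ranks)
        bias = 1.0 - 2.0 * u1 / (with_ranks.size * without_ranks.size)
        rows.append(
            {"word": word, "n_with": int(has.sum()), "bias": float(bias), "p": float(p)}
        )
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)
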