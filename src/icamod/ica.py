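"""Decomposition of an expression matrix into independent components.

A compendium X (features x samples) is modelled as X = S . A where the k
columns of S are statistically independent source signals (gene modules:
the relative inclusion of each gene in each module) and A holds the weight
of each module in each sample.  Sources are recovered with fixed-point
negentropy-maximizing ICA (FastICA, log-cosh contrast).  ICA converges from
a random start, so repeated runs differ slightly; :func:`multi_run` manages
seeded repeats and :func:`select_run` picks the run whose partitioned
modules are richest in significant annotations across one or more criterion
annotation sets (combined-rank rule).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .data_model import ExpressionMatrix, ValidationError, standardize

log = logging.getLogger(__name__)

__all__ = ["Decomposition", "decompose", "multi_run", "select_run", "combine_ranks"]


def combine_ranks(counts: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """Combined-rank run selection from a runs x criteria count matrix.

    Runs are ranked per criterion (rank 1 = highest count, competition
    ranking on ties); the combined rank is the row sum and the winner is
    its argmin, with ties resolved to the earliest run.
    """
    counts = np.atleast_2d(np.asarray(counts))
    ranks = np.column_stack(
        [rankdata(-counts[:, j], method="min") for j in range(counts.shape[1])]
    )
    combined = ranks.sum(axis=1)
    return int(np.argmin(combined)), ranks, combined


@dataclass
class Decomposition:
    """Paired S (features x k) and A (k x samples) with run metadata."""

    S: np.ndarray
    A: np.ndarray
    k: int
    seed: int
    converged: bool
    n_iter: int
    feature_ids: list[str]
    sample_ids: list[str]
    mean: np.ndarray | None = None  # per-sample mean removed before whitening

    def reconstruct(self) -> np.ndarray:
        """S . A plus the removed mean: approximates the decomposed input."""
        X = self.S @ self.A
        if self.mean is not None:
            X = X + self.mean[None, :]
        return X

    def __post_init__(self) -> None:
        if self.S.shape != (len(self.feature_ids), self.k):
            raise ValidationError("S shape does not match feature ids / k")
        if self.A.shape != (self.k, len(self.sample_ids)):
            raise ValidationError("A shape does not match k / sample ids")

    @property
    def component_ids(self) -> list[str]:
        return [f"m{i + 1}" for i in range(self.k)]

    def s_matrix(self) -> ExpressionMatrix:
        """S as a labelled matrix (features x components) for TSV export."""
        return ExpressionMatrix(self.S, self.feature_ids, self.component_ids)

    def a_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.A, self.component_ids, self.sample_ids)


def decompose(
    X: ExpressionMatrix,
    k: int,
    seed: int = 0,
    row_standardize: bool = True,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> Decomposition:
    """Extract k independent components from X.

    ``row_standardize`` standardizes every feature row first, balancing the
    compendium variance between genes with subtle and with large expression
    changes.  Deterministic given ``seed``; non-convergence within the
    iteration cap is reported via ``converged`` (the result is still
    returned).
    """
    if not 1 <= k <= min(X.n_features, X.n_samples):
        raise ValidationError(
            f"k={k} must be in [1, min(n_features, n_samples)="
            f"{min(X.n_features, X.n_samples)}]"
        )
    if row_standardize:
        X = standardize(X, axis="rows", policy="drop")
    ica = FastICA(
        n_components=k,
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
        random_state=int(seed),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(X.values)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            log.warning("ICA did not converge at k=%d (seed %d)", k, seed)
    A = ica.mixing_.T
    return Decomposition(
        S=S,
        A=A,
        k=k,
        seed=int(seed),
        converged=converged,
        n_iter=int(ica.n_iter_),
        feature_ids=list(X.feature_ids),
        sample_ids=list(X.sample_ids),
        mean=np.asarray(ica.mean_, dtype=float),
    )


def multi_run(
    X: ExpressionMatrix,
    k: int,
    n_runs: int,
    base_seed: int = 0,
    row_standardize: bool = True,
) -> list[Decomposition]:
    """n_runs seeded decompositions (seeds base_seed .. base_seed+n_runs-1)."""
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    return [
        decompose(X, k, seed=base_seed + i, row_standardize=row_standardize)
        for i in range(n_runs)
    ]


def select_run(
    runs: list[Decomposition],
    criteria: list,
    partition_cfg: dict | None = None,
    enrich_cfg: dict | None = None,
) -> tuple[int, pd.DataFrame]:
    """Pick the run with the best combined annotation-count rank.

    For every run and criterion annotation set, the partitioned modules are
    scored by the number of Simes-significant annotations; runs are ranked
    per criterion (rank 1 = most significant annotations) and the run with
    the smallest summed rank wins (ties go to the earliest run).
    """
    from .enrichment import count_significant_annotations
    from .partition import fixed_threshold_partition, model_partition, orient_components

    if not runs:
        raise ValidationError("need at least one run")
    if not criteria:
        raise ValidationError("need at least one criterion annotation set")
    partition_cfg = dict(partition_cfg or {})
    enrich_cfg = dict(enrich_cfg or {})
    alpha = float(enrich_cfg.get("alpha", 0.05))
    model = partition_cfg.get("model")
    threshold = float(partition_cfg.get("threshold", 3.0))

    counts = np.zeros((len(runs), len(criteria)), dtype=int)
    for i, run in enumerate(runs):
        oriented = orient_components(run)
        if model is not None:
            P = model_partition(oriented, model)
        else:
            P = fixed_threshold_partition(oriented, threshold)
        for j, B in enumerate(criteria):
            counts[i, j] = count_significant_annotations(P, B, alpha=alpha)
    best, ranks, combined = combine_ranks(counts)
    table = pd.DataFrame(
        {
            "run": range(len(runs)),
            "seed": [r.seed for r in runs],
            "converged": [r.converged for r in runs],
            **{f"count_{j}": counts[:, j] for j in range(len(criteria))},
            **{f"rank_{j}": ranks[:, j] for j in range(len(criteria))},
            "combined_rank": combined,
        }
    )
    return best, table
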