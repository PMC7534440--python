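"""Core typed matrices and readers/writers.

Two containers run through the whole pipeline:

* :class:`ExpressionMatrix` -- a labelled features x samples matrix of
  (log-scale) expression values or fold changes.  The same container holds
  module definition matrices (features x components) when they travel
  through TSV files.
* :class:`AnnotationSet` -- a Boolean features x annotations incidence
  matrix built from GMT gene sets.  GO terms, tissue terms, pathways and
  promoter/3'-UTR oligonucleotide "words" are all treated identically as
  Boolean annotations.

The package is ID-agnostic: feature ids may be probe sets or genes; any
mapping between the two is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "ExpressionMatrix",
    "AnnotationSet",
    "load_matrix",
    "save_matrix",
    "load_gene_sets",
    "save_gene_sets",
    "standardize",
]


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate ids, NaNs, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """Features x samples numeric matrix with row and column labels."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(i) for i in self.feature_ids]
        self.sample_ids = [str(i) for i in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "non-finite value at feature "
                f"{self.feature_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def transpose(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.T, self.sample_ids, self.feature_ids)


@dataclass
class AnnotationSet:
    """Boolean features x annotations incidence matrix (named gene sets)."""

    incidence: np.ndarray
    feature_ids: list[str]
    annotation_ids: list[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        self.feature_ids = [str(i) for i in self.feature_ids]
        self.annotation_ids = [str(i) for i in self.annotation_ids]
        if self.incidence.shape != (len(self.feature_ids), len(self.annotation_ids)):
            raise ValidationError("incidence shape does not match label lengths")
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.annotation_ids, "annotation ids")
        if self.incidence.shape[1] and not self.incidence.any(axis=0).all():
            empty = [
                a
                for a, nonzero in zip(self.annotation_ids, self.incidence.any(axis=0))
                if not nonzero
            ]
            raise ValidationError(f"annotations with no members: {empty[:5]}")

    @property
    def n_annotations(self) -> int:
        return self.incidence.shape[1]

    def members(self, annotation_id: str) -> set[str]:
        j = self.annotation_ids.index(annotation_id)
        mask = self.incidence[:, j]
        return {f for f, m in zip(self.feature_ids, mask) if m}

    def sizes(self) -> pd.Series:
        return pd.Series(
            self.incidence.sum(axis=0), index=self.annotation_ids, name="size"
        )


def load_matrix(path, orientation: str = "features_in_rows") -> ExpressionMatrix:
    """Read a labelled TSV matrix (header row + first label column).

    ``orientation`` says what the file's *rows* are; the returned matrix is
    always features x samples.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row ids {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate column ids {dup[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    X = ExpressionMatrix.from_frame(numeric)
    if orientation == "samples_in_rows":
        X = X.transpose()
    return X


def save_matrix(X: ExpressionMatrix, path) -> None:
    """Write the matrix in the same TSV dialect :func:`load_matrix` reads."""
    X.to_frame().to_csv(path, sep="\t", float_format="%.12g")


def load_gene_sets(path, universe: list[str]) -> AnnotationSet:
    """Read GMT gene sets, restricted to ``universe`` feature ids.

    Standard GMT: one set per line, ``name TAB description TAB member ...``.
    Sets with no surviving member after universe restriction are dropped
    with a warning.
    """
    universe = [str(u) for u in universe]
    index = {f: i for i, f in enumerate(universe)}
    names: list[str] = []
    descriptions: dict[str, str] = {}
    columns: list[np.ndarray] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name, desc, *members = fields
            col = np.zeros(len(universe), dtype=bool)
            for m in members:
                if m in index:
                    col[index[m]] = True
            if not col.any():
                log.warning(
                    "gene set %r has no members in the universe; dropped", name
                )
                continue
            if name in names:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            names.append(name)
            descriptions[name] = desc
            columns.append(col)
    if n_lines == 0:
        raise ParseError(f"{path}: empty GMT file")
    incidence = (
        np.column_stack(columns) if columns else np.zeros((len(universe), 0), bool)
    )
    return AnnotationSet(incidence, universe, names, descriptions)


def save_gene_sets(B: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for j, name in enumerate(B.annotation_ids):
            members = [f for f, m in zip(B.feature_ids, B.incidence[:, j]) if m]
            desc = B.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def standardize(
    X: ExpressionMatrix,
    axis: str = "columns",
    policy: str = "drop",
) -> ExpressionMatrix:
    """Center and scale each vector along ``axis`` to mean 0, population sd 1.

    ``axis='columns'`` standardizes each sample (the compendium convention);
    ``axis='rows'`` standardizes each feature (the ``row.norm`` convention
    that balances variance between genes with subtle and large changes).
    Zero-variance vectors are dropped with a warning (``policy='drop'``) or
    raise (``policy='fail'``).
    """
    if axis not in ("rows", "columns"):
        raise ValueError(f"unknown axis {axis!r}")
    if policy not in ("drop", "fail"):
        raise ValueError(f"unknown policy {policy!r}")
    values = X.values
    ax = 1 if axis == "rows" else 0
    sd = values.std(axis=ax)  # population sd (ddof=0)
    zero = sd == 0.0
    feature_ids, sample_ids = list(X.feature_ids), list(X.sample_ids)
    if zero.any():
        ids = np.array(feature_ids if axis == "rows" else sample_ids)[zero]
        if policy == "fail":
            raise ValidationError(
                f"zero-variance {axis[:-1]} vector(s): {ids.tolist()[:5]}"
            )
        log.warning("dropping %d zero-variance %s: %s", zero.sum(), axis, ids[:5])
        keep = ~zero
        if axis == "rows":
            values = values[keep, :]
            feature_ids = [f for f, k in zip(feature_ids, keep) if k]
        else:
            values = values[:, keep]
            sample_ids = [s for s, k in zip(sample_ids, keep) if k]
        sd = sd[keep]
    mean = values.mean(axis=ax)
    if axis == "rows":
        out = (values - mean[:, None]) / sd[:, None]
    else:
        out = (values - mean[None, :]) / sd[None, :]
    return ExpressionMatrix(out, feature_ids, sample_ids)
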