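"""Principal component analysis of taxonomic composition profiles.

Communities are compared in composition space: each library becomes a row of
relative abundances (viral-category counts divided by viral reads), rows are
column-centered, and PCA extracts the dominant axes of compositional
variation.  The input is plain proportions by default; a Hellinger transform
(square root of proportions), common for community data dominated by a few
categories, is available but off by default.

A deterministic eigenvector sign convention (the largest-magnitude loading of
each component is made positive) keeps score signs reproducible across runs
and library versions.  New samples — e.g. reference-site viromes — can be
projected into an existing ordination with the fitted centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .profiler import TaxonomicProfile


class OrdinationError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionMatrix:
    """Samples x categories relative-abundance matrix; rows sum to one."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            raise OrdinationError("composition values must be non-negative")
        sums = values.sum(axis=1)
        if (sums <= 0).any():
            bad = list(self.data.index[sums <= 0])
            raise OrdinationError(f"empty composition rows: {bad}")
        if not np.allclose(sums, 1.0, atol=1e-9):
            object.__setattr__(
                self, "data", self.data.div(self.data.sum(axis=1), axis=0)
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def categories(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CompositionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))


def to_proportions(profiles: Sequence[TaxonomicProfile]) -> CompositionMatrix:
    """Union-of-categories proportion matrix from per-library profiles.

    Each row divides the library's viral-category counts by its viral reads;
    ``unassigned`` reads are excluded (composition describes the identified
    viral fraction).  Categories absent from a library are structural zeros.
    """
    if not profiles:
        raise OrdinationError("no profiles given")
    ids = [p.library_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise OrdinationError(f"duplicate library ids in profiles: {ids}")
    for p in profiles:
        if p.viral_reads <= 0:
            raise OrdinationError(f"profile {p.library_id!r} has no viral reads")
    categories = sorted({c for p in profiles for c in p.viral_categories()})
    rows = {
        p.library_id: [p.counts.get(c, 0) / p.viral_reads for c in categories]
        for p in profiles
    }
    return CompositionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=categories)
    )


@dataclass(frozen=True)
class PcaModel:
    loadings: pd.DataFrame  # components x categories, orthonormal rows
    sample_scores: pd.DataFrame  # samples x components
    explained_variance_fractions: np.ndarray
    column_means: pd.Series
    hellinger: bool = False


def _as_frame(matrix: Union[CompositionMatrix, pd.DataFrame]) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, CompositionMatrix) else matrix


def pca_fit(
    matrix: Union[CompositionMatrix, pd.DataFrame],
    n_components: int = 2,
    hellinger: bool = False,
) -> PcaModel:
    """Column-centered PCA of a composition matrix.

    Components are covariance eigenvectors ordered by eigenvalue, with the
    deterministic sign convention.  A zero-variance matrix (all rows equal)
    yields all-zero scores and explained fractions.
    """
    df = _as_frame(matrix)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise OrdinationError("PCA needs at least 2 samples")
    max_k = min(n - 1, p)
    if not (1 <= n_components <= max_k):
        raise OrdinationError(
            f"n_components={n_components} out of range [1, {max_k}] "
            f"for a {n}x{p} matrix"
        )
    if hellinger:
        X = np.sqrt(X)
    means = X.mean(axis=0)
    Xc = X - means
    comp_index = [f"PC{i + 1}" for i in range(n_components)]

    if np.allclose(Xc, 0.0, atol=1e-12):
        loadings = np.eye(p)[:n_components]
        scores = np.zeros((n, n_components))
        fractions = np.zeros(n_components)
    else:
        model = PCA(n_components=n_components, svd_solver="full")
        scores = model.fit_transform(X)
        loadings = model.components_
        fractions = model.explained_variance_ratio_
        # sign convention: largest-|loading| entry of each component positive
        for i in range(n_components):
            j = int(np.argmax(np.abs(loadings[i])))
            if loadings[i, j] < 0:
                loadings[i] = -loadings[i]
                scores[:, i] = -scores[:, i]

    return PcaModel(
        loadings=pd.DataFrame(loadings, index=comp_index, columns=df.columns),
        sample_scores=pd.DataFrame(scores, index=df.index, columns=comp_index),
        explained_variance_fractions=np.asarray(fractions, dtype=float),
        column_means=pd.Series(means, index=df.columns),
        hellinger=hellinger,
    )


def project(
    model: PcaModel, matrix: Union[CompositionMatrix, pd.DataFrame]
) -> pd.DataFrame:
    """Project new samples into a fitted ordination.

    Categories unknown to the model are dropped with a warning; categories
    absent from the new data are zero-filled.  The model's own Hellinger
    setting and column means are applied before projection.
    """
    df = _as_frame(matrix)
    known = model.loadings.columns
    extra = [c for c in df.columns if c not in set(known)]
    if extra:
        warnings.warn(
            f"dropping {len(extra)} categor(ies) absent from the fitted model: "
            f"{extra}",
            stacklevel=2,
        )
    aligned = df.reindex(columns=known, fill_value=0.0).to_numpy(dtype=float)
    if model.hellinger:
        aligned = np.sqrt(aligned)
    centered = aligned - model.column_means.to_numpy()
    scores = centered @ model.loadings.to_numpy().T
    return pd.DataFrame(scores, index=df.index, columns=model.loadings.index)
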