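"""Aggregate hydrophobicity axis, correlations, clustering and plots.

The panel of empirical hydrophobicity scales is highly redundant; principal
component analysis of the z-scored scale columns yields a first component
that serves as a single "aggregate" hydrophobicity axis. Together with net
charge at intracellular pH this gives the 2D property space in which
transport receptors, cargos and nucleoporins segregate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA

from .ionization import DEFAULT_IONIZATION, DEFAULT_PH, IonizationModel
from .profiler import (
    NET_CHARGE,
    PropertyMatrix,
    PropertyVector,
    Subject,
    build_property_matrix,
)
from .scales import DEFAULT_REFERENCE_SCALE, ScaleRegistry, default_registry

AGGREGATE_HYDROPHOBICITY = "aggregate_hydrophobicity"

LINKAGE_METHODS = ("single", "complete", "average", "ward")


@dataclass(frozen=True)
class PCAResult:
    """Fitted principal components of the hydrophobicity columns.

    ``loadings`` has one orthonormal row per component over ``columns``;
    ``variance_fractions`` are non-increasing and sum to 1. ``col_means`` /
    ``col_stds`` are the raw-column statistics of the training matrix, so
    any new property vector can be placed on the training z-scale before
    projection. PC1 is sign-oriented so its loading on ``reference_scale``
    is positive (hydrophobic = high).
    """

    loadings: np.ndarray
    variance_fractions: np.ndarray
    columns: tuple[str, ...]
    col_means: pd.Series
    col_stds: pd.Series
    reference_scale: str

    @property
    def pc1_variance_fraction(self) -> float:
        return float(self.variance_fractions[0])

    def zscore_vector(self, vector: PropertyVector | Mapping[str, float]) -> np.ndarray:
        values = vector.values if isinstance(vector, PropertyVector) else vector
        missing = [c for c in self.columns if c not in values]
        if missing:
            raise ValueError("vector is missing column(s): " + ", ".join(missing))
        x = np.array([values[c] for c in self.columns], dtype=float)
        return (x - self.col_means.to_numpy()) / self.col_stds.to_numpy()

    def project(self, vector: PropertyVector | Mapping[str, float]) -> np.ndarray:
        """Scores of one subject on all components."""
        return self.loadings @ self.zscore_vector(vector)


def hydrophobicity_pca(
    matrix: PropertyMatrix,
    scales: ScaleRegistry | None = None,
    reference_scale: str = DEFAULT_REFERENCE_SCALE,
) -> PCAResult:
    """PCA of the hydrophobicity columns of a z-scored property matrix.

    The matrix must be in the ``zscored`` state (the scales have
    incommensurate units, so the analysis is of the correlation structure).
    Requires at least 3 rows.
    """
    if matrix.state != "zscored":
        raise ValueError(
            f"hydrophobicity PCA requires a zscored matrix, got '{matrix.state}'"
        )
    registry = scales if scales is not None else default_registry()
    columns = [c for c in registry.hydrophobicity_names if c in matrix.values.columns]
    if not columns:
        raise ValueError("matrix contains no hydrophobicity columns")
    if reference_scale not in columns:
        raise ValueError(
            f"reference scale '{reference_scale}' not among hydrophobicity columns"
        )
    sub = matrix.restrict(columns)
    if len(sub.values) < 3:
        raise ValueError("hydrophobicity PCA needs at least 3 rows")
    z = sub.values.to_numpy()
    pca = PCA(n_components=min(z.shape), svd_solver="full")
    pca.fit(z)
    loadings = pca.components_.copy()
    fractions = pca.explained_variance_ratio_.copy()
    ref_idx = columns.index(reference_scale)
    if loadings[0, ref_idx] < 0:
        loadings[0] = -loadings[0]
    return PCAResult(
        loadings=loadings,
        variance_fractions=fractions,
        columns=tuple(columns),
        col_means=sub.col_means.copy(),
        col_stds=sub.col_stds.copy(),
        reference_scale=reference_scale,
    )


def aggregate_hydrophobicity(
    vector: PropertyVector | Mapping[str, float], pca: PCAResult
) -> float:
    """Projection of a subject's hydrophobicity sub-vector onto PC1."""
    return float(pca.project(vector)[0])


def signed_squared_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """sign(r) * r^2 for the Pearson correlation of two columns."""
    ax = np.asarray(x, dtype=float)
    ay = np.asarray(y, dtype=float)
    if ax.shape != ay.shape or ax.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    if len(ax) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(ax) == 0.0 or np.std(ay) == 0.0:
        raise ValueError("zero-variance input column")
    r = float(np.corrcoef(ax, ay)[0, 1])
    return float(np.sign(r) * r * r)


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative clustering of matrix rows (Euclidean distance)."""

    linkage_matrix: np.ndarray
    leaf_order: tuple[str, ...]
    metric: str
    method: str

    def top_split(self, ids: Sequence[str]) -> tuple[set[str], set[set]]:
        """Partition of *ids* induced by cutting the top merge."""
        from scipy.cluster.hierarchy import fcluster

        assignments = fcluster(self.linkage_matrix, t=2, criterion="maxclust")
        left = {i for i, a in zip(ids, assignments) if a == 1}
        right = {i for i, a in zip(ids, assignments) if a == 2}
        return left, right


def cluster_rows(matrix: PropertyMatrix, method: str = "average") -> ClusterResult:
    """Hierarchical clustering of the rows of a z-scored property matrix."""
    if matrix.state != "zscored":
        raise ValueError(f"clustering requires a zscored matrix, got '{matrix.state}'")
    if len(matrix.values) < 2:
        raise ValueError("clustering needs at least 2 rows")
    if method not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}, got '{method}'")
    z = linkage(matrix.values.to_numpy(), method=method, metric="euclidean")
    order = leaves_list(z)
    ids = matrix.ids
    return ClusterResult(
        linkage_matrix=z,
        leaf_order=tuple(ids[i] for i in order),
        metric="euclidean",
        method=method,
    )


@dataclass(frozen=True)
class HeatmapExport:
    """Reordered numeric table plus the color-scale limits actually used."""

    table: pd.DataFrame
    vmin: float
    vmax: float
    image_path: str | None = None
    table_path: str | None = None


def export_heatmap(
    matrix: PropertyMatrix,
    cluster: ClusterResult | None = None,
    clip: float = 3.0,
    image_path: str | Path | None = None,
    table_path: str | Path | None = None,
) -> HeatmapExport:
    """Render the clustered property heat map and write the ordered table.

    Rows follow the dendrogram leaf order; the color scale is clipped at
    ``+-clip`` standard deviations (default 3), bright red above and bright
    green below the mean, matching the usual expression-style convention.
    """
    if matrix.state != "zscored":
        raise ValueError(f"heat map requires a zscored matrix, got '{matrix.state}'")
    if cluster is None:
        cluster = cluster_rows(matrix)
    ordered = matrix.values.loc[list(cluster.leaf_order)]
    vmin, vmax = -abs(clip), abs(clip)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import LinearSegmentedColormap

        cmap = LinearSegmentedColormap.from_list(
            "green_black_red", ["#00b000", "#000000", "#e00000"]
        )
        fig, ax = plt.subplots(
            figsize=(max(6.0, 0.25 * ordered.shape[1]), max(4.0, 0.18 * ordered.shape[0]))
        )
        im = ax.imshow(
            ordered.to_numpy(), aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax
        )
        ax.set_yticks(range(len(ordered.index)))
        ax.set_yticklabels(ordered.index, fontsize=6)
        ax.set_xticks(range(len(ordered.columns)))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
        fig.colorbar(im, ax=ax, label="z-score (clipped)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    if table_path is not None:
        out = ordered.copy()
        out.insert(0, "label", matrix.labels.loc[ordered.index])
        out.to_csv(table_path, sep="\t", index_label="id")
    return HeatmapExport(
        table=ordered,
        vmin=vmin,
        vmax=vmax,
        image_path=None if image_path is None else str(image_path),
        table_path=None if table_path is None else str(table_path),
    )


def property_space(
    subjects: Iterable[Subject],
    scales: ScaleRegistry | None = None,
    ionization: IonizationModel = DEFAULT_IONIZATION,
    ph: float = DEFAULT_PH,
    pca: PCAResult | None = None,
    reference_scale: str = DEFAULT_REFERENCE_SCALE,
) -> tuple[pd.DataFrame, PCAResult]:
    """The 2D reduced representation: net charge vs aggregate hydrophobicity.

    When *pca* is ``None`` the aggregate axis is fitted on the subjects
    themselves; otherwise their raw scale means are projected with the
    supplied (already fitted) axis. Returns the coordinate table (index id;
    columns label, net_charge, aggregate_hydrophobicity) and the PCA used.
    """
    registry = scales if scales is not None else default_registry()
    raw = build_property_matrix(subjects, registry, ionization, ph, normalize="raw")
    if pca is None:
        pca = hydrophobicity_pca(raw.zscore(), registry, reference_scale)
    scores = [
        aggregate_hydrophobicity(dict(raw.values.loc[i]), pca) for i in raw.ids
    ]
    df = pd.DataFrame(
        {
            "label": raw.labels,
            NET_CHARGE: raw.values[NET_CHARGE],
            AGGREGATE_HYDROPHOBICITY: scores,
        },
        index=pd.Index(raw.ids, name="id"),
    )
    return df, pca
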