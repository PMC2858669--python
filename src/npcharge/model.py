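"""Fitted property-space model of a protein collection.

:class:`PropertySpace` is the front door of the package: build it from
records (and optional complexes), call :meth:`PropertySpace.fit`, and read
the fitted aggregate-hydrophobicity axis, the 2D coordinates, regime
classifications and summary from the returned
:class:`PropertySpaceResults`. Electrostatic energy predictions hang off
the results via :meth:`PropertySpaceResults.energies`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .axes import (
    AGGREGATE_HYDROPHOBICITY,
    ClusterResult,
    HeatmapExport,
    PCAResult,
    aggregate_hydrophobicity,
    cluster_rows,
    export_heatmap,
    hydrophobicity_pca,
    signed_squared_correlation,
)
from .electrostatics import NPCModel, predict_particles
from .io import (
    ComplexManifest,
    ProteinRecord,
    load_complex_manifest,
    read_fasta,
    read_label_table,
)
from .ionization import DEFAULT_IONIZATION, DEFAULT_PH, IonizationModel
from .profiler import NET_CHARGE, PropertyMatrix, Subject, build_property_matrix
from .regimes import (
    RegimeThresholds,
    classify_table,
    compute_thresholds,
    predict_self_translocators,
    subject_molecular_weight,
)
from .scales import DEFAULT_REFERENCE_SCALE, ScaleRegistry, default_registry


class PropertySpace:
    """Charge/hydrophobicity model of a collection of proteins and complexes.

    Parameters
    ----------
    records : sequence of ProteinRecord
    complexes : sequence of ComplexManifest, optional
    scales : ScaleRegistry, optional
        Defaults to the bundled 27-scale + polarity registry.
    ionization : IonizationModel, optional
    ph : float
        pH at which net charges are reported (default 7.2, intracellular).
    background_labels : sequence of str
        Class labels whose subjects define the hydrophobicity threshold
        (their median). When no subject carries such a label the whole
        collection is used.
    reference_scale : str
        Hydrophobicity scale anchoring the sign of the aggregate axis.
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        complexes: Sequence[ComplexManifest] = (),
        *,
        scales: ScaleRegistry | None = None,
        ionization: IonizationModel = DEFAULT_IONIZATION,
        ph: float = DEFAULT_PH,
        background_labels: Sequence[str] = ("background",),
        reference_scale: str = DEFAULT_REFERENCE_SCALE,
    ):
        self.records = list(records)
        self.complexes = list(complexes)
        self.subjects: list[Subject] = self.records + self.complexes
        if not self.subjects:
            raise ValueError("need at least one record or complex")
        self.scales = scales if scales is not None else default_registry()
        self.ionization = ionization
        self.ph = ph
        self.background_labels = tuple(background_labels)
        self.reference_scale = reference_scale

    @classmethod
    def from_fasta(
        cls,
        fasta: str | Path,
        manifest: str | Path | None = None,
        labels: str | Path | None = None,
        **kwargs,
    ) -> "PropertySpace":
        """Build the model from a FASTA file (+ optional manifest/labels)."""
        label_map = read_label_table(labels) if labels else None
        records = read_fasta(fasta, labels=label_map)
        complexes = load_complex_manifest(manifest, records) if manifest else []
        return cls(records, complexes, **kwargs)

    def fit(self) -> "PropertySpaceResults":
        """Profile, z-score, fit the aggregate axis, and classify regimes."""
        raw = build_property_matrix(
            self.subjects, self.scales, self.ionization, self.ph, normalize="raw"
        )
        zscored = raw.zscore()
        pca = hydrophobicity_pca(zscored, self.scales, self.reference_scale)
        scores = [
            aggregate_hydrophobicity(dict(raw.values.loc[i]), pca) for i in raw.ids
        ]
        coords = pd.DataFrame(
            {
                "label": raw.labels,
                NET_CHARGE: raw.values[NET_CHARGE],
                AGGREGATE_HYDROPHOBICITY: scores,
            },
            index=pd.Index(raw.ids, name="id"),
        )
        background = coords[coords["label"].isin(self.background_labels)]
        if len(background) == 0:
            background = coords
        thresholds = compute_thresholds(background)
        coords = classify_table(coords, thresholds)
        coords["molecular_weight_da"] = [
            subject_molecular_weight(s) for s in self.subjects
        ]
        return PropertySpaceResults(
            model=self,
            raw_matrix=raw,
            zscored_matrix=zscored,
            pca=pca,
            coordinates=coords,
            thresholds=thresholds,
        )


@dataclass
class PropertySpaceResults:
    """Everything the fitted property-space model estimated."""

    model: PropertySpace
    raw_matrix: PropertyMatrix
    zscored_matrix: PropertyMatrix
    pca: PCAResult
    coordinates: pd.DataFrame
    thresholds: RegimeThresholds

    @property
    def pc1_variance_fraction(self) -> float:
        return self.pca.pc1_variance_fraction

    def polarity_correlation(self) -> float:
        """Signed r^2 between polarity and the aggregate hydrophobicity."""
        polarity_cols = self.model.scales.polarity_names
        if not polarity_cols:
            raise ValueError("registry has no polarity scale")
        return signed_squared_correlation(
            self.raw_matrix.values[polarity_cols[0]].to_numpy(),
            self.coordinates[AGGREGATE_HYDROPHOBICITY].to_numpy(),
        )

    def self_translocators(self, size_limit_da: float = 40_000.0) -> pd.DataFrame:
        """Subjects predicted to cross the pore without a receptor."""
        return predict_self_translocators(
            self.model.subjects, self.coordinates, self.thresholds, size_limit_da
        )

    def cluster(self, method: str = "average") -> ClusterResult:
        return cluster_rows(self.zscored_matrix, method=method)

    def plot_heatmap(
        self,
        image_path: str | Path | None = None,
        table_path: str | Path | None = None,
        clip: float = 3.0,
        method: str = "average",
    ) -> HeatmapExport:
        return export_heatmap(
            self.zscored_matrix,
            cluster=self.cluster(method),
            clip=clip,
            image_path=image_path,
            table_path=table_path,
        )

    def plot_space(self, path: str | Path) -> None:
        """Scatter of net charge vs aggregate hydrophobicity by class."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        for label, group in self.coordinates.groupby("label"):
            ax.scatter(
                group[AGGREGATE_HYDROPHOBICITY],
                group[NET_CHARGE],
                s=14,
                alpha=0.7,
                label=f"{label} (n={len(group)})",
            )
        ax.axhline(self.thresholds.charge_e, color="grey", lw=0.8, ls="--")
        ax.axvline(self.thresholds.hydrophobicity, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("aggregate hydrophobicity (PC1 score)")
        ax.set_ylabel(f"net charge at pH {self.model.ph} (e)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def energies(
        self,
        npc: NPCModel | None = None,
        t_delta_s_kbt: float | None = None,
    ) -> pd.DataFrame:
        """Electrostatic translocation energetics for every subject."""
        return predict_particles(
            self.model.subjects,
            npc,
            self.model.ionization,
            self.model.ph,
            t_delta_s_kbt,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        coords = self.coordinates
        lines = [
            "Property-space model of charge and hydrophobicity",
            "=" * 58,
            f"subjects               : {len(coords)} "
            f"({len(self.model.records)} proteins, {len(self.model.complexes)} complexes)",
            f"properties             : {len(self.raw_matrix.columns)} "
            f"({len(self.pca.columns)} hydrophobicity scales)",
            f"pH for net charge      : {self.model.ph}",
            f"PC1 variance fraction  : {self.pc1_variance_fraction:.3f}",
            f"PC2 variance fraction  : {float(self.pca.variance_fractions[1]):.3f}",
            f"charge threshold       : {self.thresholds.charge_e:+.1f} e",
            f"hydrophobicity thresh. : {self.thresholds.hydrophobicity:+.3f} (background median)",
            "",
            "per-class means (net charge e | aggregate hydrophobicity):",
        ]
        for label, group in coords.groupby("label"):
            lines.append(
                f"  {label:<18} n={len(group):<4} "
                f"{group[NET_CHARGE].mean():+9.2f} | "
                f"{group[AGGREGATE_HYDROPHOBICITY].mean():+7.3f}"
            )
        lines.append("")
        lines.append("regime counts:")
        for regime, n in coords["regime"].value_counts().items():
            lines.append(f"  {regime:<24} {n}")
        return "\n".join(lines)
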