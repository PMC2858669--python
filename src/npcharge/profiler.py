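"""Per-protein and per-complex physicochemical property profiles.

Every per-residue property is a composition statistic: the sum of the scale
value over the sequence divided by sequence length, so it is invariant under
residue reordering. Net charge is extensive (it scales with copy number in a
complex); per-residue means combine across complex members weighted by
copies x length, i.e. exactly the value of the concatenated sequence, while
each member chain keeps its own termini for the charge sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .io import ComplexManifest, ProteinRecord, validate_sequence
from .ionization import (
    DEFAULT_IONIZATION,
    DEFAULT_PH,
    IonizationModel,
    net_charge,
)
from .scales import ResidueScale, ScaleRegistry, default_registry

NET_CHARGE = "net_charge"
ISOELECTRIC_POINT = "isoelectric_point"

Subject = Union[ProteinRecord, ComplexManifest]

NORMALIZATION_STATES = ("raw", "centered", "zscored")


def scale_mean(sequence: str, scale: ResidueScale) -> float:
    """Mean of *scale* over the residues of *sequence* (scale units/residue)."""
    validate_sequence(sequence)
    return sum(scale.values[res] for res in sequence) / len(sequence)


def _complex_net_charge(
    manifest: ComplexManifest, ph: float, ionization: IonizationModel
) -> float:
    # Non-covalent assembly: every chain keeps both termini.
    return sum(
        count * net_charge(rec.sequence, ph, ionization)
        for rec, count in manifest.members
    )


def _complex_isoelectric_point(
    manifest: ComplexManifest,
    ionization: IonizationModel,
    tolerance: float = 1e-6,
    max_iter: int = 200,
) -> float:
    # Bisection on the summed (still strictly decreasing) charge curve.
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        q = _complex_net_charge(manifest, mid, ionization)
        if abs(q) < tolerance:
            return mid
        if q > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PropertyVector:
    """All properties of one subject, with extensivity flags.

    ``extensive[name]`` is true for totals that scale with copy count
    (net charge) and false for per-residue means and the isoelectric point.
    """

    subject_id: str
    values: Mapping[str, float]
    extensive: Mapping[str, bool]
    label: str = "unknown"

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def profile_protein(
    record: ProteinRecord,
    scales: ScaleRegistry | None = None,
    ionization: IonizationModel = DEFAULT_IONIZATION,
    ph: float = DEFAULT_PH,
) -> PropertyVector:
    """Property vector of a single chain: every registry scale mean, net
    charge at *ph* and isoelectric point."""
    from .ionization import isoelectric_point  # local to avoid cycle noise

    registry = scales if scales is not None else default_registry()
    values: dict[str, float] = {}
    extensive: dict[str, bool] = {}
    for scale in registry:
        values[scale.name] = scale_mean(record.sequence, scale)
        extensive[scale.name] = False
    values[NET_CHARGE] = net_charge(record.sequence, ph, ionization)
    extensive[NET_CHARGE] = True
    values[ISOELECTRIC_POINT] = isoelectric_point(record.sequence, ionization)
    extensive[ISOELECTRIC_POINT] = False
    return PropertyVector(
        subject_id=record.id, values=values, extensive=extensive, label=record.label
    )


def profile_complex(
    manifest: ComplexManifest,
    scales: ScaleRegistry | None = None,
    ionization: IonizationModel = DEFAULT_IONIZATION,
    ph: float = DEFAULT_PH,
) -> PropertyVector:
    """Property vector of a complex.

    Net charge is the copy-weighted sum of member charges; per-residue
    properties are copy-and-length-weighted means, identical to profiling
    the concatenation of all member chains.
    """
    registry = scales if scales is not None else default_registry()
    total_len = manifest.total_length
    values: dict[str, float] = {}
    extensive: dict[str, bool] = {}
    for scale in registry:
        weighted = sum(
            count * len(rec) * scale_mean(rec.sequence, scale)
            for rec, count in manifest.members
        )
        values[scale.name] = weighted / total_len
        extensive[scale.name] = False
    values[NET_CHARGE] = _complex_net_charge(manifest, ph, ionization)
    extensive[NET_CHARGE] = True
    values[ISOELECTRIC_POINT] = _complex_isoelectric_point(manifest, ionization)
    extensive[ISOELECTRIC_POINT] = False
    return PropertyVector(
        subject_id=manifest.name, values=values, extensive=extensive, label=manifest.label
    )


def profile_subject(
    subject: Subject,
    scales: ScaleRegistry | None = None,
    ionization: IonizationModel = DEFAULT_IONIZATION,
    ph: float = DEFAULT_PH,
) -> PropertyVector:
    if isinstance(subject, ComplexManifest):
        return profile_complex(subject, scales, ionization, ph)
    return profile_protein(subject, scales, ionization, ph)


@dataclass(frozen=True)
class PropertyMatrix:
    """Subjects x properties table with normalization metadata.

    ``state`` is one of ``raw``, ``centered``, ``zscored``. For the two
    normalized states, ``col_means``/``col_stds`` hold the statistics of the
    underlying raw columns (population standard deviation), so new vectors
    can be placed on the same scale.
    """

    values: pd.DataFrame
    labels: pd.Series
    state: str = "raw"
    col_means: pd.Series | None = None
    col_stds: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.state not in NORMALIZATION_STATES:
            raise ValueError(
                f"normalization state must be one of {NORMALIZATION_STATES}, "
                f"got '{self.state}'"
            )
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels must be indexed like the value rows")

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def center(self) -> "PropertyMatrix":
        if self.state != "raw":
            raise ValueError(f"can only center a raw matrix, got state '{self.state}'")
        if len(self.values) < 2:
            raise ValueError("centering needs at least 2 subjects")
        means = self.values.mean(axis=0)
        return PropertyMatrix(
            values=self.values - means,
            labels=self.labels,
            state="centered",
            col_means=means,
        )

    def zscore(self) -> "PropertyMatrix":
        if self.state != "raw":
            raise ValueError(f"can only z-score a raw matrix, got state '{self.state}'")
        if len(self.values) < 2:
            raise ValueError("z-scoring needs at least 2 subjects")
        means = self.values.mean(axis=0)
        stds = self.values.std(axis=0, ddof=0)
        zero = [c for c in self.values.columns if stds[c] == 0.0]
        if zero:
            raise ValueError(
                "zero-variance column(s) cannot be z-scored: " + ", ".join(zero)
            )
        return PropertyMatrix(
            values=(self.values - means) / stds,
            labels=self.labels,
            state="zscored",
            col_means=means,
            col_stds=stds,
        )

    def restrict(self, columns: Sequence[str]) -> "PropertyMatrix":
        """Column subset, keeping normalization metadata aligned."""
        missing = [c for c in columns if c not in self.values.columns]
        if missing:
            raise ValueError("unknown column(s): " + ", ".join(missing))
        return PropertyMatrix(
            values=self.values[list(columns)],
            labels=self.labels,
            state=self.state,
            col_means=None if self.col_means is None else self.col_means[list(columns)],
            col_stds=None if self.col_stds is None else self.col_stds[list(columns)],
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index_label="id")


def build_property_matrix(
    subjects: Iterable[Subject],
    scales: ScaleRegistry | None = None,
    ionization: IonizationModel = DEFAULT_IONIZATION,
    ph: float = DEFAULT_PH,
    normalize: str = "raw",
) -> PropertyMatrix:
    """Profile all subjects and assemble the property matrix.

    ``normalize``: ``raw`` keeps plain values; ``centered`` subtracts column
    means; ``zscored`` additionally divides by the column (population)
    standard deviation so every column has mean 0 and SD 1.
    """
    registry = scales if scales is not None else default_registry()
    vectors = [profile_subject(s, registry, ionization, ph) for s in subjects]
    if not vectors:
        raise ValueError("no subjects to profile")
    ids = [v.subject_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in property matrix")
    columns = list(vectors[0].values.keys())
    df = pd.DataFrame(
        [[v.values[c] for c in columns] for v in vectors], index=ids, columns=columns
    )
    labels = pd.Series([v.label for v in vectors], index=ids, name="label")
    matrix = PropertyMatrix(values=df, labels=labels, state="raw")
    if normalize == "raw":
        return matrix
    if normalize == "centered":
        return matrix.center()
    if normalize == "zscored":
        return matrix.zscore()
    raise ValueError(
        f"normalize must be one of {NORMALIZATION_STATES}, got '{normalize}'"
    )
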