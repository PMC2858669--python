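"""Residue-scale registry.

A :class:`ResidueScale` maps each of the 20 standard residues to a real
value. The bundled registry compiles 27 widely published per-residue
hydrophobicity scales plus the Grantham polarity scale; the TSV data file is
the single source of truth. Scales keep their published orientation (some
are hydrophilicity-oriented); orientation is immaterial to the principal
component analysis and the aggregate axis is sign-anchored to a reference
scale downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import STANDARD_RESIDUES

CATEGORIES = ("hydrophobicity", "polarity", "other")

#: Reference scale used to orient the aggregate hydrophobicity axis.
DEFAULT_REFERENCE_SCALE = "kyte_doolittle"


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue scale (hydrophobicity, polarity, or other)."""

    name: str
    category: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"scale '{self.name}': category must be one of {CATEGORIES}, "
                f"got '{self.category}'"
            )
        missing = sorted(set(STANDARD_RESIDUES) - set(self.values))
        if missing:
            raise ValueError(
                f"scale '{self.name}': missing residue(s) " + ", ".join(missing)
            )
        extra = sorted(set(self.values) - set(STANDARD_RESIDUES))
        if extra:
            raise ValueError(
                f"scale '{self.name}': unexpected residue key(s) " + ", ".join(extra)
            )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


class ScaleRegistry:
    """An ordered, name-unique collection of :class:`ResidueScale`.

    Equality ignores insertion order so registries loaded from reordered
    files compare equal.
    """

    def __init__(self, scales: Iterable[ResidueScale]):
        self._scales: dict[str, ResidueScale] = {}
        for scale in scales:
            if scale.name in self._scales:
                raise ValueError(f"duplicate scale name '{scale.name}'")
            self._scales[scale.name] = scale

    def __iter__(self):
        return iter(self._scales.values())

    def __len__(self) -> int:
        return len(self._scales)

    def __contains__(self, name: str) -> bool:
        return name in self._scales

    def __getitem__(self, name: str) -> ResidueScale:
        if name not in self._scales:
            raise KeyError(f"no scale named '{name}' in registry")
        return self._scales[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScaleRegistry):
            return NotImplemented
        if set(self._scales) != set(other._scales):
            return False
        return all(
            self._scales[n].category == other._scales[n].category
            and self._scales[n].values == other._scales[n].values
            for n in self._scales
        )

    def names(self, category: str | None = None) -> list[str]:
        """Scale names, optionally restricted to one category."""
        return [
            s.name for s in self._scales.values()
            if category is None or s.category == category
        ]

    @property
    def hydrophobicity_names(self) -> list[str]:
        return self.names("hydrophobicity")

    @property
    def polarity_names(self) -> list[str]:
        return self.names("polarity")


def load_scales(path: str | Path | None = None) -> ScaleRegistry:
    """Load a scale registry from a TSV file (default: bundled registry).

    Expected columns: ``name``, ``category``, then the 20 residue columns.
    Missing residues and duplicate names raise ``ValueError`` naming the
    offender.
    """
    if path is None:
        source = resources.files("npcharge.data") / "residue_scales.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"name", "category"}
    if not required.issubset(df.columns):
        raise ValueError("registry file must have 'name' and 'category' columns")
    residue_cols = [c for c in df.columns if c in set(STANDARD_RESIDUES)]
    scales = []
    for _, row in df.iterrows():
        missing = sorted(set(STANDARD_RESIDUES) - set(residue_cols))
        values = {r: float(row[r]) for r in residue_cols if pd.notna(row[r])}
        absent = sorted(set(STANDARD_RESIDUES) - set(values))
        if missing or absent:
            raise ValueError(
                f"scale '{row['name']}': missing residue(s) "
                + ", ".join(sorted(set(missing) | set(absent)))
            )
        scales.append(
            ResidueScale(name=str(row["name"]), category=str(row["category"]), values=values)
        )
    registry = ScaleRegistry(scales)
    return registry


def default_registry() -> ScaleRegistry:
    """The bundled registry: 27 hydrophobicity scales + Grantham polarity."""
    return load_scales(None)
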