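"""Presence-absence community matrices and species trait vectors.

The community matrix is the standard rows-are-species, columns-are-sites
binary incidence table of co-occurrence analysis.  Matrices are degenerate
(and rejected) when any species occurs nowhere or any site is empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


def _default_labels(prefix: str, k: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1}" for i in range(k))


@dataclass(frozen=True)
class CommunityMatrix:
    """Binary species x site incidence matrix with no empty rows or columns."""

    occupancy: np.ndarray
    species: tuple[str, ...] | None = None
    sites: tuple[str, ...] | None = None

    def __post_init__(self):
        occ = np.ascontiguousarray(np.asarray(self.occupancy), dtype=np.uint8)
        if occ.ndim != 2 or occ.size == 0:
            raise ValueError("occupancy must be a non-empty 2-d array")
        if not np.isin(np.asarray(self.occupancy), (0, 1)).all():
            raise ValueError("occupancy entries must all be 0 or 1")
        if (occ.sum(axis=1) == 0).any():
            raise ValueError("degenerate matrix: some species occurs at no site")
        if (occ.sum(axis=0) == 0).any():
            raise ValueError("degenerate matrix: some site holds no species")
        occ.setflags(write=False)
        object.__setattr__(self, "occupancy", occ)
        species = self.species or _default_labels("sp", occ.shape[0])
        sites = self.sites or _default_labels("site", occ.shape[1])
        if len(species) != occ.shape[0] or len(sites) != occ.shape[1]:
            raise ValueError("label lengths do not match matrix dimensions")
        object.__setattr__(self, "species", tuple(species))
        object.__setattr__(self, "sites", tuple(sites))

    @property
    def n_species(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_sites(self) -> int:
        return self.occupancy.shape[1]

    @property
    def row_sums(self) -> np.ndarray:
        """Species incidences (number of occupied sites per species)."""
        return self.occupancy.sum(axis=1, dtype=np.int64)

    @property
    def col_sums(self) -> np.ndarray:
        return self.occupancy.sum(axis=0, dtype=np.int64)

    @property
    def fill(self) -> float:
        return float(self.occupancy.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occupancy.astype(int),
                            index=list(self.species), columns=list(self.sites))

    def to_csv(self, path) -> None:
        """First column = species ids, header row = site ids, cells in {0,1}."""
        self.to_frame().to_csv(path, index_label="species")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CommunityMatrix":
        values = frame.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at species {frame.index[r]!r}, site {frame.columns[c]!r}"
            )
        return cls(values.astype(np.uint8),
                   species=tuple(map(str, frame.index)),
                   sites=tuple(map(str, frame.columns)))

    @classmethod
    def from_csv(cls, path) -> "CommunityMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass(frozen=True)
class TraitVector:
    """One continuous trait value per species, aligned to matrix rows."""

    values: np.ndarray
    species: tuple[str, ...] | None = None

    def __post_init__(self):
        vals = np.ascontiguousarray(np.asarray(self.values), dtype=np.float64)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("trait values must form a non-empty 1-d sequence")
        if not np.isfinite(vals).all():
            raise ValueError("trait values must be finite")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        species = self.species or _default_labels("sp", vals.size)
        if len(species) != vals.size:
            raise ValueError("species labels do not match trait vector length")
        object.__setattr__(self, "species", tuple(species))

    def __len__(self) -> int:
        return int(self.values.size)

    def with_values(self, values: Sequence[float]) -> "TraitVector":
        return TraitVector(np.asarray(values, dtype=float), species=self.species)

    def to_csv(self, path) -> None:
        pd.DataFrame({"species_id": list(self.species),
                      "trait_value": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TraitVector":
        frame = pd.read_csv(path)
        if list(frame.columns[:2]) != ["species_id", "trait_value"]:
            raise ValueError("trait CSV must have columns species_id, trait_value")
        return cls(frame["trait_value"].to_numpy(float),
                   species=tuple(map(str, frame["species_id"])))


def align_traits(matrix: CommunityMatrix, traits: TraitVector) -> TraitVector:
    """Check that ``traits`` matches ``matrix`` rows (by length; by id when both label)."""
    if len(traits) != matrix.n_species:
        raise ValueError(
            f"trait vector length {len(traits)} != species count {matrix.n_species}"
        )
    if set(traits.species) == set(matrix.species) and traits.species != matrix.species:
        order = [traits.species.index(s) for s in matrix.species]
        return TraitVector(traits.values[order], species=matrix.species)
    return traits
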