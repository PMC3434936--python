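"""Taxon-area matrices: binary area x species presence/absence data.

In a taxon-area analysis the geographic areas play the role of the taxa and
each species is one binary character (1 = the species occurs in the area).
The matrix is strictly binary: missing or polymorphic states are rejected at
construction, because the likelihood engine assumes fully observed tips and
the all-zero-column augmentation logic relies on absences being real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MatrixValidationError(ValueError):
    """Raised when a taxon-area matrix violates its invariants."""


def _check_unique_names(names: list[str], axis: str) -> None:
    if any(not isinstance(n, str) or n == "" for n in names):
        raise MatrixValidationError(f"{axis} names must be non-empty strings")
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise MatrixValidationError(f"duplicate {axis} name: {n!r}")
        seen.add(n)


@dataclass
class TaxonAreaMatrix:
    """Binary presence/absence matrix with named rows (areas) and columns
    (species).

    Parameters
    ----------
    area_names:
        Row labels, unique non-empty strings.
    species_names:
        Column labels, unique non-empty strings (typically Latin binomials).
    cells:
        Array-like of shape (n_areas, n_species) containing only 0 and 1.
    provenance:
        Free-text tag recording where the matrix came from.
    """

    area_names: list[str]
    species_names: list[str]
    cells: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.area_names = list(self.area_names)
        self.species_names = list(self.species_names)
        cells = np.asarray(self.cells)
        if cells.ndim != 2:
            raise MatrixValidationError("cells must be a 2-D array")
        if cells.shape != (len(self.area_names), len(self.species_names)):
            raise MatrixValidationError(
                f"cells shape {cells.shape} does not match "
                f"{len(self.area_names)} areas x {len(self.species_names)} species"
            )
        _check_unique_names(self.area_names, "area")
        _check_unique_names(self.species_names, "species")
        bad = ~np.isin(cells, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"non-binary state {cells[i, j]!r} at area {self.area_names[i]!r}, "
                f"character {j} ({self.species_names[j]!r}); only 0/1 are allowed"
            )
        self.cells = cells.astype(np.int8)

    # ------------------------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.area_names)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def row(self, area: str) -> np.ndarray:
        return self.cells[self.area_names.index(area)]

    def column(self, species: str) -> np.ndarray:
        return self.cells[:, self.species_names.index(species)]

    def row_sums(self) -> dict[str, int]:
        """Species presences per area (the species richness of each area)."""
        return dict(zip(self.area_names, self.cells.sum(axis=1).tolist()))

    def transpose(self) -> "TaxonAreaMatrix":
        """Swap the axes (species x areas files are read then transposed)."""
        return TaxonAreaMatrix(
            self.species_names, self.area_names, self.cells.T, self.provenance
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonAreaMatrix):
            return NotImplemented
        return (
            self.area_names == other.area_names
            and self.species_names == other.species_names
            and np.array_equal(self.cells, other.cells)
        )


def add_allzero_outgroup(
    matrix: TaxonAreaMatrix, name: str = "ROOT"
) -> TaxonAreaMatrix:
    """Append an artificial area containing no species, used to root the
    area tree (a hypothetical ancestral area holding none of the extant
    flora).

    The outgroup is an ordinary matrix row of zeros, so maximum likelihood
    and parsimony both treat rooting identically.
    """
    if name in matrix.area_names:
        raise MatrixValidationError(
            f"outgroup name {name!r} collides with an existing area"
        )
    cells = np.vstack([matrix.cells, np.zeros((1, matrix.n_species), dtype=np.int8)])
    return TaxonAreaMatrix(
        matrix.area_names + [name], list(matrix.species_names), cells,
        matrix.provenance,
    )
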