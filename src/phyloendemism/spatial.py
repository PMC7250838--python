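"""Gridded species occupancy and Human Footprint pressure surfaces.

The Human Footprint (HF) index scores each grid cell from 0 (no detectable
human pressure) to 50 (most modified) from a composite of built
environments, crop/pasture land, population density, night lights and
transport infrastructure. Cells are binned into five pressure categories
and given a linear human-pressure (HP) weight:

====================  ============  ======
category              HF interval   weight
====================  ============  ======
none                  exactly 0     1.0
low                   (0, 3)        0.8
moderate              [3, 6)        0.6
high                  [6, 12)       0.4
very_high             [12, 50]      0.2
====================  ============  ======

The half-open boundaries extend the integer anchor points (0; 1-2; 3-5;
6-11; 12-50) to the fractional values produced by block-mean upscaling; the
published cutoffs HF < 3, HF >= 6 and HF >= 12 all fall on interval
boundaries. A species' (or branch's) HP-weighted distribution is the sum of
the weights of its occupied cells; it replaces the raw cell count wherever
range size enters a metric.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "CATEGORY_WEIGHTS",
    "hp_weight",
    "hf_category",
    "PressureGrid",
    "OccupancyTable",
    "upscale_hf",
    "hp_weighted_distribution",
    "range_size",
    "cell_id",
]

CATEGORIES = ("none", "low", "moderate", "high", "very_high")
CATEGORY_WEIGHTS = {
    "none": 1.0,
    "low": 0.8,
    "moderate": 0.6,
    "high": 0.4,
    "very_high": 0.2,
}


def hf_category(hf: float) -> str:
    """Pressure category for an HF value in [0, 50]."""
    if not 0 <= hf <= 50:
        raise ValueError(f"HF value {hf} outside [0, 50]")
    if hf == 0:
        return "none"
    if hf < 3:
        return "low"
    if hf < 6:
        return "moderate"
    if hf < 12:
        return "high"
    return "very_high"


def hp_weight(hf: float) -> tuple[str, float]:
    """(category, HP weight) for an HF value; the weight is in {1, 0.8, 0.6, 0.4, 0.2}."""
    cat = hf_category(hf)
    return cat, CATEGORY_WEIGHTS[cat]


def cell_id(row: int, col: int) -> str:
    """Canonical id for a cell of a rectangular grid."""
    return f"r{row}c{col}"


class PressureGrid:
    """Per-cell Human Footprint values with derived categories and weights."""

    def __init__(self, hf: Mapping[str, float]):
        self._hf: dict[str, float] = {}
        self._category: dict[str, str] = {}
        self._weight: dict[str, float] = {}
        for cell, value in hf.items():
            cat, w = hp_weight(float(value))
            self._hf[str(cell)] = float(value)
            self._category[str(cell)] = cat
            self._weight[str(cell)] = w

    @classmethod
    def from_csv(cls, path: str | Path, cell_col: str = "cell_id", hf_col: str = "hf") -> "PressureGrid":
        df = pd.read_csv(path)
        return cls(dict(zip(df[cell_col].astype(str), df[hf_col].astype(float))))

    @property
    def cells(self) -> frozenset[str]:
        return frozenset(self._hf)

    def __len__(self) -> int:
        return len(self._hf)

    def __contains__(self, cell: str) -> bool:
        return cell in self._hf

    def hf(self, cell: str) -> float:
        return self._hf[cell]

    def category(self, cell: str) -> str:
        return self._category[cell]

    def weight(self, cell: str, strict: bool = False) -> float:
        """HP weight of a cell.

        Cells occupied by species but absent from the pressure surface are
        treated as unimpacted (weight 1.0) with a logged warning — the
        neutral choice, which degrades the weighted metrics toward their
        unweighted counterparts rather than inventing threat.
        """
        try:
            return self._weight[cell]
        except KeyError:
            if strict:
                raise KeyError(f"cell {cell!r} has no HF value") from None
            logger.warning(
                "cell %r has no HF value; assuming weight 1.0 (no pressure)", cell
            )
            return 1.0

    def cells_in_category(self, category: str) -> frozenset[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return frozenset(c for c, k in self._category.items() if k == category)

    def permuted(self, seed_or_rng) -> "PressureGrid":
        """A grid with the same HF multiset randomly reassigned to cells."""
        rng = (
            seed_or_rng
            if isinstance(seed_or_rng, np.random.Generator)
            else np.random.Generator(np.random.PCG64(seed_or_rng))
        )
        cells = sorted(self._hf)
        values = np.asarray([self._hf[c] for c in cells])
        return PressureGrid(dict(zip(cells, values[rng.permutation(len(cells))])))

    def to_frame(self) -> pd.DataFrame:
        cells = sorted(self._hf)
        return pd.DataFrame(
            {
                "cell_id": cells,
                "hf": [self._hf[c] for c in cells],
                "category": [self._category[c] for c in cells],
                "weight": [self._weight[c] for c in cells],
            }
        )


def upscale_hf(fine: np.ndarray, block: int) -> PressureGrid:
    """Block-mean a fine HF raster onto a coarse analysis grid.

    ``fine`` is a 2-D array with ``nan`` marking missing (e.g. marine)
    cells. Each ``block x block`` window becomes one coarse cell whose HF is
    the arithmetic mean of the non-missing fine values it covers; windows
    with no data are absent from the result. Coarse cells are keyed
    ``r{i}c{j}`` by block position.
    """
    arr = np.asarray(fine, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("fine raster must be a non-empty 2-D array")
    if block < 1:
        raise ValueError("block factor must be >= 1")
    n_r = -(-arr.shape[0] // block)
    n_c = -(-arr.shape[1] // block)
    out: dict[str, float] = {}
    for i in range(n_r):
        for j in range(n_c):
            window = arr[i * block : (i + 1) * block, j * block : (j + 1) * block]
            if np.isnan(window).all():
                continue
            out[cell_id(i, j)] = float(np.nanmean(window))
    return PressureGrid(out)


class OccupancyTable:
    """Sparse binary species x grid-cell incidence.

    Duplicate (species, cell) pairs collapse; every species occupies at
    least one cell; range size is the number of distinct occupied cells.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        by_species: dict[str, set[str]] = {}
        by_cell: dict[str, set[str]] = {}
        for sp, cell in pairs:
            sp, cell = str(sp), str(cell)
            by_species.setdefault(sp, set()).add(cell)
            by_cell.setdefault(cell, set()).add(sp)
        if not by_species:
            raise ValueError("occupancy table is empty")
        self._by_species = {s: frozenset(c) for s, c in by_species.items()}
        self._by_cell = {c: frozenset(s) for c, s in by_cell.items()}

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "OccupancyTable":
        return cls((sp, c) for sp, cells in mapping.items() for c in cells)

    @classmethod
    def from_long_csv(
        cls, path: str | Path, species_col: str = "species", cell_col: str = "cell_id"
    ) -> "OccupancyTable":
        df = pd.read_csv(path)
        return cls(zip(df[species_col].astype(str), df[cell_col].astype(str)))

    @classmethod
    def from_wide_csv(cls, path: str | Path) -> "OccupancyTable":
        """Read a presence/absence matrix: rows = species, columns = cells."""
        df = pd.read_csv(path, index_col=0)
        pairs = [
            (str(sp), str(cell))
            for sp in df.index
            for cell in df.columns[df.loc[sp].astype(float).to_numpy() > 0]
        ]
        return cls(pairs)

    # -- queries ---------------------------------------------------------

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._by_species)

    @property
    def cells(self) -> frozenset[str]:
        return frozenset(self._by_cell)

    def cells_of(self, species: str) -> frozenset[str]:
        try:
            return self._by_species[species]
        except KeyError:
            raise KeyError(f"unknown species {species!r}") from None

    def species_in(self, cell: str) -> frozenset[str]:
        try:
            return self._by_cell[cell]
        except KeyError:
            raise KeyError(f"unknown cell {cell!r}") from None

    def range_size(self, species: str) -> int:
        return len(self.cells_of(species))

    def restrict_species(self, keep: Iterable[str]) -> "OccupancyTable":
        keep_set = set(keep) & self.species
        if not keep_set:
            raise ValueError("restriction removes every species")
        return OccupancyTable(
            (sp, c) for sp in keep_set for c in self._by_species[sp]
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (sp, c)
            for sp in sorted(self._by_species)
            for c in sorted(self._by_species[sp])
        ]
        return pd.DataFrame(rows, columns=["species", "cell_id"])

    def __len__(self) -> int:
        return sum(len(c) for c in self._by_species.values())


def hp_weighted_distribution(cells: Iterable[str], grid: PressureGrid) -> float:
    """Sum of HP weights over a set of cells.

    This is the HP-weighted distribution score of a species or branch: it
    lies between 0.2x and 1x the plain cell count.
    """
    cell_list = list(cells)
    if not cell_list:
        raise ValueError("cell set is empty")
    return float(sum(grid.weight(c) for c in set(cell_list)))


def range_size(species: str, occ: OccupancyTable) -> int:
    """Number of distinct grid cells occupied by a species."""
    return occ.range_size(species)
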