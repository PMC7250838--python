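"""Per-cell and per-species diversity metrics.

Spatial (per grid cell) metrics
    PD          summed branch lengths of the cell's species subtree
                (one species -> its terminal branch only)
    residual PD OLS residuals of PD regressed on species richness
    WE          weighted endemism: sum of 1/range over resident species
    EDR         fair-proportion evolutionary distinctiveness divided by
                range size, summed over resident species
    PE          phylogenetic endemism: each branch's length divided equally
                among the cells its descendants occupy
    HIPE        human-impacted PE: each branch's length apportioned to its
                cells in proportion to their HP weights

Species-level metrics
    TE          terminal endemism: TBL / range size
    HITE        human-impacted TE: TBL / HP-weighted distribution

PE, HIPE and EDR are additive partitions of the mapped tree's PD: summed
over all cells each returns the total branch length shared by the tree and
the occupancy data. HIPE reduces exactly to PE when all cells carry the
same HP weight, and a species' HITE/TE ratio is bounded in [1, 5] because
weights live in [0.2, 1].

All per-cell maps are returned as named pandas Series indexed by cell id;
species tables as DataFrames indexed by species.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phylo import Phylogeny, TreeDistribution
from .spatial import OccupancyTable, PressureGrid, hp_weighted_distribution

logger = logging.getLogger(__name__)

__all__ = [
    "mapped_species",
    "richness",
    "grid_pd",
    "residual_pd",
    "weighted_endemism",
    "edr",
    "pe",
    "hipe",
    "hipe_pe_ratio",
    "clade_contribution",
    "cumulative_capture",
    "te",
    "hite",
    "species_scores",
    "aggregate_over_trees",
    "forest_cell_metric",
]


def mapped_species(tree: Phylogeny, occ: OccupancyTable) -> frozenset[str]:
    """Species present in both the phylogeny and the occupancy data.

    Spatial metrics are computed on this intersection; names found on only
    one side are reported through the module logger and dropped.
    """
    common = tree.tips & occ.species
    dropped = (tree.tips | occ.species) - common
    if dropped:
        logger.info(
            "%d species lack either phylogenetic or spatial data and are "
            "excluded: %s",
            len(dropped),
            sorted(dropped)[:10],
        )
    if not common:
        raise ValueError("tree and occupancy share no species")
    return frozenset(common)


def _series(values: Mapping[str, float], name: str) -> pd.Series:
    s = pd.Series(values, dtype=float, name=name)
    return s.sort_index()


def richness(occ: OccupancyTable, species: Iterable[str] | None = None) -> pd.Series:
    """Species count per cell, optionally restricted to a species subset."""
    keep = occ.species if species is None else frozenset(species)
    vals = {
        c: len(occ.species_in(c) & keep)
        for c in occ.cells
        if occ.species_in(c) & keep
    }
    return _series(vals, "richness")


def grid_pd(tree: Phylogeny, occ: OccupancyTable) -> pd.Series:
    """Per-cell PD: branch lengths of the subtree spanning the cell's
    species (root path included); a single-species cell scores that
    species' terminal branch length."""
    common = mapped_species(tree, occ)
    out: dict[str, float] = {}
    for cell in occ.cells:
        sp = occ.species_in(cell) & common
        if sp:
            out[cell] = tree.subtree_pd(sp)
    return _series(out, "pd")


def residual_pd(pd_map: pd.Series, richness_map: pd.Series) -> pd.Series:
    """OLS residuals of PD on richness across cells.

    Positive residuals flag cells holding more evolutionary history than
    their species count predicts. Residuals sum to zero.
    """
    if set(pd_map.index) != set(richness_map.index):
        raise ValueError("PD and richness maps must cover the same cells")
    if len(pd_map) < 3:
        raise ValueError("need at least 3 cells for a residual map")
    x = richness_map.loc[pd_map.index].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("richness is constant; regression is singular")
    fit = sm.OLS(pd_map.to_numpy(dtype=float), sm.add_constant(x)).fit()
    return pd.Series(fit.resid, index=pd_map.index, name="residual_pd").sort_index()


def weighted_endemism(occ: OccupancyTable) -> pd.Series:
    """Range-size-weighted richness: each species contributes 1/range to
    every cell it occupies (and hence exactly 1 in total)."""
    out: dict[str, float] = {c: 0.0 for c in occ.cells}
    for sp in occ.species:
        share = 1.0 / occ.range_size(sp)
        for c in occ.cells_of(sp):
            out[c] += share
    return _series(out, "we")


def edr(tree: Phylogeny, occ: OccupancyTable) -> pd.Series:
    """Evolutionary distinctiveness rarity: each species' fair-proportion
    ED divided equally among its occupied cells.

    ED is computed on the tree pruned to the mapped species, so each
    branch's length is split only among descendants that have spatial data
    and the map partitions the mapped PD exactly.
    """
    common = mapped_species(tree, occ)
    sub = tree if common == tree.tips else tree.prune(tree.tips - common)
    ed = sub.fair_proportion()
    out: dict[str, float] = {}
    for sp, ed_s in ed.items():
        share = ed_s / occ.range_size(sp)
        for c in occ.cells_of(sp):
            out[c] = out.get(c, 0.0) + share
    return _series(out, "edr")


def _branch_cells(
    tree: Phylogeny, occ: OccupancyTable, common: frozenset[str]
) -> list[tuple[float, frozenset[str]]]:
    """(length, occupied-cell set) per branch, skipping branches none of
    whose descendants have spatial data."""
    out = []
    for br in tree.branch_table():
        mapped = br.tips & common
        if not mapped:
            continue
        cells: set[str] = set()
        for sp in mapped:
            cells |= occ.cells_of(sp)
        out.append((br.length, frozenset(cells)))
    return out


def pe(tree: Phylogeny, occ: OccupancyTable) -> pd.Series:
    """Phylogenetic endemism: each branch's length divided equally across
    all cells in which any of its descendants occur."""
    common = mapped_species(tree, occ)
    out: dict[str, float] = {}
    for length, cells in _branch_cells(tree, occ, common):
        share = length / len(cells)
        for c in cells:
            out[c] = out.get(c, 0.0) + share
    return _series(out, "pe")


def hipe(tree: Phylogeny, occ: OccupancyTable, grid: PressureGrid) -> pd.Series:
    """Human-impacted phylogenetic endemism.

    Each branch's length is apportioned across its occupied cells in
    proportion to each cell's HP weight, i.e. cell ``c`` receives
    ``length * w(c) / sum of w over the branch's cells``. Cells under low
    pressure therefore absorb PD from shared branches, while branches
    wholly confined to high-pressure cells keep their PD there.
    """
    common = mapped_species(tree, occ)
    out: dict[str, float] = {}
    for length, cells in _branch_cells(tree, occ, common):
        weights = {c: grid.weight(c) for c in cells}
        total_w = sum(weights.values())
        for c, w in weights.items():
            out[c] = out.get(c, 0.0) + length * w / total_w
    return _series(out, "hipe")


def hipe_pe_ratio(
    hipe_map: pd.Series,
    pe_map: pd.Series,
    grid: PressureGrid,
    extreme: str,
) -> pd.Series:
    """HIPE/PE ratio restricted to cells at a pressure extreme.

    ``extreme`` is ``"very_high"`` or ``"none"``. Very-high-pressure cells
    can only lose PD under the HP reweighting, so their ratio is <= 1 and a
    ratio near 1 marks endemic PD trapped entirely under heavy pressure;
    zero-pressure cells can only gain, so their ratio is >= 1.
    """
    if extreme not in ("very_high", "none"):
        raise ValueError("extreme must be 'very_high' or 'none'")
    cells = grid.cells_in_category(extreme) & set(pe_map.index)
    out: dict[str, float] = {}
    for c in cells:
        if pe_map[c] == 0:
            logger.warning("cell %r has PE = 0; omitted from ratio map", c)
            continue
        out[c] = float(hipe_map.get(c, 0.0) / pe_map[c])
    return _series(out, f"hipe_pe_ratio_{extreme}")


def clade_contribution(maps: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Per-cell proportional contribution of each clade to a summed metric.

    ``maps`` gives one per-cell map per clade (absent cells count as 0).
    Rows are cells with a positive total; each row sums to 1.
    """
    if not maps:
        raise ValueError("no clade maps given")
    df = pd.DataFrame(maps).fillna(0.0).sort_index()
    totals = df.sum(axis=1)
    df = df.loc[totals > 0]
    return df.div(totals[totals > 0], axis=0)


def _ranked_cells(values: pd.Series) -> list[str]:
    # descending value, ties broken by ascending cell id, for reproducibility
    return sorted(values.index, key=lambda c: (-values[c], c))


def cumulative_capture(
    cell_map: pd.Series, fractions: Sequence[float]
) -> pd.Series:
    """Assign each cell to the smallest cumulative-share band covering it.

    Cells are ranked by value (descending; ties by cell id); walking down
    the ranking, a cell joins band ``f`` for the smallest requested
    fraction ``f`` that is not yet covered when the cell is reached, i.e.
    the cell is needed to reach cumulative share ``f``. Cells reached only
    after every requested fraction is already covered are returned as NaN.
    """
    fr = sorted(float(f) for f in fractions)
    if not fr or fr[0] <= 0 or fr[-1] > 1:
        raise ValueError("fractions must lie in (0, 1]")
    total = float(cell_map.sum())
    if total <= 0:
        raise ValueError("cell map has no positive mass")
    out: dict[str, float] = {}
    running = 0.0
    for c in _ranked_cells(cell_map):
        band = next((f for f in fr if running < f - 1e-12), np.nan)
        out[c] = band
        running += float(cell_map[c]) / total
    return _series(out, "cumulative_band")


def te(tree: Phylogeny, occ: OccupancyTable) -> pd.Series:
    """Terminal endemism: TBL x 1/range, per species.

    TBLs come from the full input tree (before intersecting with the
    spatial data); species without occupancy are omitted from the result.
    """
    tbl = tree.terminal_branch_lengths()
    common = mapped_species(tree, occ)
    return _series({s: tbl[s] / occ.range_size(s) for s in common}, "te")


def hite(tree: Phylogeny, occ: OccupancyTable, grid: PressureGrid) -> pd.Series:
    """Human-impacted terminal endemism: TBL x 1/(HP-weighted distribution).

    Replacing the cell count with the HP-weighted distribution inflates the
    score of species whose ranges sit under heavy human pressure; HITE is
    always >= TE and at most 5x TE.
    """
    tbl = tree.terminal_branch_lengths()
    common = mapped_species(tree, occ)
    return _series(
        {
            s: tbl[s] / hp_weighted_distribution(occ.cells_of(s), grid)
            for s in common
        },
        "hite",
    )


def species_scores(
    tree: Phylogeny,
    occ: OccupancyTable,
    grid: PressureGrid,
    attributes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-species prioritisation table.

    Columns: tbl, range, hp_weighted_range, te, hite and hite_rank (1 =
    highest HITE; ties broken by species name). ``attributes`` (indexed by
    species, e.g. clade or IUCN category columns) is joined if given.
    """
    tbl = tree.terminal_branch_lengths()
    common = mapped_species(tree, occ)
    rows = []
    for s in sorted(common):
        hp_range = hp_weighted_distribution(occ.cells_of(s), grid)
        rows.append(
            {
                "species": s,
                "tbl": tbl[s],
                "range": occ.range_size(s),
                "hp_weighted_range": hp_range,
                "te": tbl[s] / occ.range_size(s),
                "hite": tbl[s] / hp_range,
            }
        )
    df = pd.DataFrame(rows).set_index("species")
    order = sorted(df.index, key=lambda s: (-df.loc[s, "hite"], s))
    df["hite_rank"] = pd.Series(
        {s: i + 1 for i, s in enumerate(order)}, dtype=int
    )
    if attributes is not None:
        df = df.join(attributes, how="left")
    return df


def aggregate_over_trees(
    trees: TreeDistribution | Sequence[Phylogeny],
    metric_fn: Callable[[Phylogeny], pd.Series],
    min_presence: float = 0.5,
) -> pd.DataFrame:
    """Median (plus min/max) of a per-cell or per-species metric across a
    tree distribution.

    ``metric_fn`` maps one tree to a Series. A key contributes no value for
    trees where it is absent; keys present in fewer than ``min_presence``
    of the trees are dropped with a logged warning. The median of an even
    count is the midpoint of the central pair.
    """
    if len(trees) == 0:
        raise ValueError("empty tree distribution")
    per_tree = [metric_fn(t) for t in trees]
    df = pd.DataFrame(per_tree).T  # keys x trees
    n = df.notna().sum(axis=1)
    flagged = df.index[n < min_presence * len(trees)]
    if len(flagged):
        logger.warning(
            "%d keys present in < %.0f%% of trees dropped from the "
            "aggregate: %s",
            len(flagged),
            100 * min_presence,
            list(flagged[:10]),
        )
    df = df.drop(index=flagged)
    out = pd.DataFrame(
        {
            "median": df.median(axis=1),
            "min": df.min(axis=1),
            "max": df.max(axis=1),
            "n_trees": df.notna().sum(axis=1).astype(int),
        }
    )
    return out.sort_index()


def forest_cell_metric(
    forest: Sequence[Phylogeny],
    metric_fn: Callable[[Phylogeny], pd.Series],
) -> pd.Series:
    """Sum a per-cell metric over the independent trees of a forest.

    Paraphyletic groups (e.g. 'reptiles' = lepidosaurs + turtles +
    crocodilians without birds) are handled as separate trees whose
    per-cell metrics add; no connecting branches between the trees are
    fabricated, so the summed PD is conservative.
    """
    if not forest:
        raise ValueError("empty forest")
    acc: pd.Series | None = None
    name = None
    for tree in forest:
        s = metric_fn(tree)
        name = s.name
        acc = s if acc is None else acc.add(s, fill_value=0.0)
    acc.name = name
    return acc.sort_index()
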