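"""Randomisation tests and extinction-scenario PD loss.

Two null models are provided:

* a pressure-randomisation null for the spatial overlap between
  high-endemism cells and high human pressure — observed Human Footprint
  values are permuted across the occupied-cell universe (sampling without
  replacement preserves the empirical HF distribution) and the overlap of
  the fixed top-fraction cells with HF >= 6 is recomputed per replicate;

* a stratified random-extinction null for PD loss — each replicate drops,
  within every stratum (e.g. taxonomic order), a uniformly random species
  set of the same size as the observed threatened set there, and records
  the drop in total PD.

PD loss itself is total PD minus the total PD of the pruned tree; because
pruning merges emptied internal edges, the loss of a species set always
covers at least the set's summed terminal branch lengths, plus any internal
branches left with no surviving descendants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import Phylogeny, TreeDistribution
from .spatial import PressureGrid

__all__ = [
    "NullDistribution",
    "top_cells",
    "pressure_overlap",
    "randomize_pressure_null",
    "pd_loss",
    "random_extinction_null",
    "scenario_loss_range",
]


@dataclass
class NullDistribution:
    """Replicate values of a randomisation test, with the observed value."""

    values: np.ndarray
    observed: float
    seed: int
    reps: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.reps:
            raise ValueError("replicate count does not match request")

    def summary(self) -> dict:
        """Observed value, null mean/sd and empirical quantiles."""
        q = np.quantile(self.values, [0.025, 0.5, 0.975])
        return {
            "observed": float(self.observed),
            "null_mean": float(self.values.mean()),
            "null_sd": float(self.values.std(ddof=1)) if self.reps > 1 else 0.0,
            "null_q025": float(q[0]),
            "null_median": float(q[1]),
            "null_q975": float(q[2]),
            "prop_null_ge_observed": float(
                np.mean(self.values >= self.observed)
            ),
            "reps": int(self.reps),
            "seed": int(self.seed),
        }


def top_cells(cell_map: pd.Series, fraction: float) -> set[str]:
    """The highest-value ``ceil(fraction * n)`` cells of a metric map.

    Ties are broken by ascending cell id so the selection is reproducible.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if len(cell_map) == 0:
        raise ValueError("empty cell map")
    k = int(np.ceil(fraction * len(cell_map)))
    ranked = sorted(cell_map.index, key=lambda c: (-cell_map[c], c))
    return set(ranked[:k])


def pressure_overlap(cells: Iterable[str], grid: PressureGrid) -> dict:
    """Pressure composition of a cell set.

    Returns the proportion of cells under high or very high pressure
    (HF >= 6), under low pressure in the broad sense (HF < 3), and the full
    per-category breakdown (which sums to 1).
    """
    cell_list = sorted(set(cells))
    if not cell_list:
        raise ValueError("cell set is empty")
    missing = [c for c in cell_list if c not in grid]
    if missing:
        raise KeyError(f"cells not in pressure grid: {missing[:5]}")
    cats = [grid.category(c) for c in cell_list]
    n = len(cats)
    by_cat = {k: cats.count(k) / n for k in
              ("none", "low", "moderate", "high", "very_high")}
    return {
        "hf_ge6": by_cat["high"] + by_cat["very_high"],
        "hf_lt3": by_cat["none"] + by_cat["low"],
        "by_category": by_cat,
        "n_cells": n,
    }


def randomize_pressure_null(
    cell_map: pd.Series,
    grid: PressureGrid,
    fraction: float,
    reps: int,
    seed: int,
) -> NullDistribution:
    """Null for the overlap of top-value cells with high pressure.

    The observed statistic is the HF >= 6 share among the top ``fraction``
    of cells of ``cell_map``. Each replicate permutes the observed HF
    values across all cells of ``grid`` (pass a grid restricted to the
    occupied universe) and recomputes that share for the same top cells.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    chosen = top_cells(cell_map, fraction)
    observed = pressure_overlap(chosen, grid)["hf_ge6"]
    rng = np.random.Generator(np.random.PCG64(seed))
    values = np.empty(reps)
    for i in range(reps):
        values[i] = pressure_overlap(chosen, grid.permuted(rng))["hf_ge6"]
    return NullDistribution(values=values, observed=observed, seed=seed, reps=reps)


def _as_forest(tree_or_forest) -> list[Phylogeny]:
    if isinstance(tree_or_forest, Phylogeny):
        return [tree_or_forest]
    return list(tree_or_forest)


def pd_loss(tree_or_forest, drop: Iterable[str]) -> float:
    """Reduction in total PD when a species set goes extinct.

    For a forest the loss is summed over trees, each tree losing its own
    members of the set. Dropping every tip of a tree is an error; the loss
    is bounded below by the summed TBLs of the dropped species and above by
    total PD.
    """
    drop_set = set(drop)
    if not drop_set:
        return 0.0
    forest = _as_forest(tree_or_forest)
    all_tips: set[str] = set()
    for t in forest:
        all_tips |= t.tips
    unknown = drop_set - all_tips
    if unknown:
        raise KeyError(f"species not in any tree: {sorted(unknown)[:5]}")
    loss = 0.0
    for t in forest:
        local = drop_set & t.tips
        if not local:
            continue
        if local == t.tips:
            raise ValueError("scenario drops every tip of a tree")
        loss += t.total_pd() - t.prune(local).total_pd()
    return float(loss)


def random_extinction_null(
    tree_or_forest,
    observed_drop: Iterable[str],
    strata: Mapping[str, str] | None,
    reps: int,
    seed: int,
) -> NullDistribution:
    """Stratified random-extinction null for PD loss.

    ``strata`` maps each candidate species to a stratum label (e.g. its
    order); ``None`` puts every tip in one stratum. Each replicate draws,
    within every stratum, a uniform random species set of the same size as
    the observed threatened set in that stratum, and records the resulting
    PD loss. The observed loss is attached for comparison.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    forest = _as_forest(tree_or_forest)
    tips: set[str] = set()
    for t in forest:
        tips |= t.tips
    observed = set(observed_drop)
    if strata is None:
        strata = {s: "all" for s in tips}
    pools: dict[str, list[str]] = {}
    for sp, st in strata.items():
        pools.setdefault(str(st), []).append(sp)
    for st in pools:
        pools[st].sort()
    counts: dict[str, int] = {st: 0 for st in pools}
    stratum_of = {sp: str(st) for sp, st in strata.items()}
    for sp in observed:
        if sp not in stratum_of:
            raise ValueError(f"observed species {sp!r} has no stratum")
        counts[stratum_of[sp]] += 1
    for st, k in counts.items():
        if k > len(pools[st]):
            raise ValueError(
                f"stratum {st!r} holds {len(pools[st])} candidates but "
                f"{k} observed extinctions"
            )
    observed_loss = pd_loss(forest, observed)
    rng = np.random.Generator(np.random.PCG64(seed))
    values = np.empty(reps)
    for i in range(reps):
        drawn: set[str] = set()
        for st, k in counts.items():
            if k:
                drawn |= set(rng.choice(pools[st], size=k, replace=False))
        values[i] = pd_loss(forest, drawn)
    return NullDistribution(
        values=values, observed=observed_loss, seed=seed, reps=reps
    )


def scenario_loss_range(
    trees: TreeDistribution | Sequence[Phylogeny] | Phylogeny,
    candidates: Iterable[str],
    mode: str,
    reps: int = 1,
    seed: int = 0,
) -> dict:
    """PD-loss range for data-deficiency scenarios over a tree distribution.

    Candidate species are the unassessed / Data Deficient pool. Modes:

    * ``single_min`` — per tree, the smallest loss over single-candidate
      extinctions (the best case: only one candidate is truly at risk);
    * ``random_subset`` — per tree and replicate, a uniformly sized
      (1..n) then uniformly chosen candidate subset goes extinct;
    * ``all`` — every candidate goes extinct.

    Returns min / median / max (plus count) over the collected losses.
    Candidates absent from a given tree are ignored for that tree.
    """
    if mode not in ("single_min", "random_subset", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    tree_list = [trees] if isinstance(trees, Phylogeny) else list(trees)
    cand = sorted(set(candidates))
    if not cand:
        raise ValueError("empty candidate set")
    rng = np.random.Generator(np.random.PCG64(seed))
    losses: list[float] = []
    for t in tree_list:
        local = [s for s in cand if s in t.tips]
        if not local:
            continue
        if mode == "single_min":
            losses.append(min(pd_loss(t, {s}) for s in local))
        elif mode == "all":
            losses.append(pd_loss(t, local))
        else:
            for _ in range(reps):
                k = int(rng.integers(1, len(local) + 1))
                subset = rng.choice(local, size=k, replace=False)
                losses.append(pd_loss(t, set(subset)))
    if not losses:
        raise ValueError("no candidate occurs in any tree")
    arr = np.asarray(losses)
    return {
        "min": float(arr.min()),
        "median": float(np.median(arr)),
        "max": float(arr.max()),
        "n": int(arr.size),
        "mode": mode,
    }
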