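"""Do high-endemism cells coincide with high human pressure?

Selects the top 10% of cells by phylogenetic endemism and compares their
overlap with high/very-high pressure (HF >= 6) against a null in which the
observed HF values are permuted across the occupied cells.
"""

from phyloendemism import (
    PressureGrid,
    SimulationConfig,
    pe,
    pressure_overlap,
    randomize_pressure_null,
    simulate_dataset,
    top_cells,
)

tree, occ, grid = simulate_dataset(SimulationConfig(seed=7))
pe_map = pe(tree, occ)
universe = PressureGrid({c: grid.hf(c) for c in pe_map.index})

observed = pressure_overlap(top_cells(pe_map, 0.1), universe)
print(f"high-PE cells under HF >= 6: {observed['hf_ge6']:.1%}")

null = randomize_pressure_null(pe_map, universe, fraction=0.1,
                               reps=1000, seed=7)
s = null.summary()
print(f"null mean {s['null_mean']:.1%}  (95% interval "
      f"{s['null_q025']:.1%} - {s['null_q975']:.1%}, {s['reps']} reps)")
print(f"share of null replicates >= observed: {s['prop_null_ge_observed']:.3f}")
print(
    "\nBecause this synthetic Human Footprint surface is generated\n"
    "independently of the ranges, the observed overlap should sit inside\n"
    "the null interval; with real data, an observed value above the upper\n"
    "quantile indicates endemism hotspots disproportionately under pressure."
)
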