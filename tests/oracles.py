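"""Independent brute-force reference implementations used only by tests.

Everything here works directly on Newick text via dendropy's tree objects
and explicit loops over edges / cells / paths, sharing no code with the
package's own implementations.
"""

from __future__ import annotations

import dendropy


def edges_of(newick: str) -> list[tuple[float, frozenset[str]]]:
    """(length, descendant tip set) for every non-root edge."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    out = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        tips = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        out.append((float(nd.edge.length), tips))
    return out


def total_pd(newick: str) -> float:
    return sum(length for length, _ in edges_of(newick))


def terminal_branch_lengths(newick: str) -> dict[str, float]:
    return {
        next(iter(tips)): length
        for length, tips in edges_of(newick)
        if len(tips) == 1
    }


def subtree_pd(newick: str, species: set[str]) -> float:
    if len(species) == 1:
        return terminal_branch_lengths(newick)[next(iter(species))]
    return sum(length for length, tips in edges_of(newick) if tips & species)


def fair_proportion(newick: str) -> dict[str, float]:
    ed: dict[str, float] = {}
    for length, tips in edges_of(newick):
        for sp in tips:
            ed[sp] = ed.get(sp, 0.0) + length / len(tips)
    return ed


def pd_loss(newick: str, drop: set[str]) -> float:
    """Length of every edge all of whose descendants go extinct."""
    return sum(length for length, tips in edges_of(newick) if tips <= drop)


def hp_weight(hf: float) -> float:
    # independent restatement of the published interval table
    if hf == 0:
        return 1.0
    if hf < 3:
        return 0.8
    if hf < 6:
        return 0.6
    if hf < 12:
        return 0.4
    return 0.2


def grid_pd(newick: str, occ: dict[str, set[str]]) -> dict[str, float]:
    tree_tips = {next(iter(t)) for _, t in edges_of(newick) if len(t) == 1}
    cells: set[str] = set()
    for c in occ.values():
        cells |= c
    out = {}
    for cell in cells:
        sp = {s for s, cc in occ.items() if cell in cc} & tree_tips
        if sp:
            out[cell] = subtree_pd(newick, sp)
    return out


def pe(newick: str, occ: dict[str, set[str]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for length, tips in edges_of(newick):
        mapped = tips & set(occ)
        if not mapped:
            continue
        cells: set[str] = set()
        for sp in mapped:
            cells |= occ[sp]
        for c in cells:
            out[c] = out.get(c, 0.0) + length / len(cells)
    return out


def hipe(
    newick: str, occ: dict[str, set[str]], hf: dict[str, float]
) -> dict[str, float]:
    out: dict[str, float] = {}
    for length, tips in edges_of(newick):
        mapped = tips & set(occ)
        if not mapped:
            continue
        cells: set[str] = set()
        for sp in mapped:
            cells |= occ[sp]
        total_w = sum(hp_weight(hf[c]) for c in cells)
        for c in cells:
            out[c] = out.get(c, 0.0) + length * hp_weight(hf[c]) / total_w
    return out


def te(newick: str, occ: dict[str, set[str]]) -> dict[str, float]:
    tbl = terminal_branch_lengths(newick)
    return {s: tbl[s] / len(occ[s]) for s in occ if s in tbl}


def hite(
    newick: str, occ: dict[str, set[str]], hf: dict[str, float]
) -> dict[str, float]:
    tbl = terminal_branch_lengths(newick)
    return {
        s: tbl[s] / sum(hp_weight(hf[c]) for c in occ[s])
        for s in occ
        if s in tbl
    }
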