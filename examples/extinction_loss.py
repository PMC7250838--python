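"""PD at risk from phylogenetically clumped extinctions.

Simulates a 100-species tree whose threatened quarter carries full
phylogenetic signal (relatives share fate), then compares the PD lost if
all threatened species go extinct with a stratified random-extinction null
(same number of extinctions within each root clade). Also shows the
data-deficiency scenario range machinery.
"""

from phyloendemism import (
    pd_loss,
    random_extinction_null,
    scenario_loss_range,
    simulate_threat,
    simulate_tree,
)

tree = simulate_tree(100, 0.02, seed=1)
threat = simulate_threat(tree, prevalence=0.25, signal=1.0, seed=1)

labels = {n: lab for lab, n in tree.tip_nodes().items()}
strata = {}
for i, kid in enumerate(tree.children(tree.root)):
    stack = [kid]
    while stack:
        n = stack.pop()
        kids = tree.children(n)
        if not kids:
            strata[labels[n]] = f"clade{i}"
        stack.extend(kids)

print(f"total PD: {tree.total_pd():.0f} MY; "
      f"{len(threat)} of {tree.n_tips} species threatened")
print(f"observed loss if all threatened go extinct: "
      f"{pd_loss(tree, threat):.0f} MY")

null = random_extinction_null(tree, threat, strata, reps=100, seed=1)
s = null.summary()
print(f"stratified random-extinction null: mean {s['null_mean']:.0f} MY "
      f"(95% interval {s['null_q025']:.0f} - {s['null_q975']:.0f})")

candidates = sorted(threat)[:5]  # pretend these five are Data Deficient
for mode in ("single_min", "random_subset", "all"):
    out = scenario_loss_range(tree, candidates, mode, reps=50, seed=2)
    print(f"scenario {mode:<13}: loss {out['min']:.1f} - {out['max']:.1f} MY "
          f"(median {out['median']:.1f}, n = {out['n']})")

print(
    "\nWhen threat clusters on the tree, whole clades — terminal branches\n"
    "plus the internal branches only they carry — are at risk together, so\n"
    "the observed loss typically exceeds the null mean. The scenario modes\n"
    "bracket the loss from data-deficient species: best case one extinction\n"
    "(the shortest-branch candidate), worst case all of them."
)
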