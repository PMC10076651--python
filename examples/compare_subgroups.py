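"""Do two subgroups share the same symptom network?

Simulates two respondent groups — the second carries one extra
cross-construct edge — and runs the permutation network comparison test.
M is the maximum edge-weight difference between the groups' networks
(structure invariance); S is the difference in global strength (overall
connectivity); both p-values come from re-estimating the networks under
permuted group labels.
"""

from symptomnet import compare_networks
from symptomnet.simulate import GeneratorConfig, simulate_dataset


def make_group(seed, extra_edge=False):
    bridges = [(0, 4, 0.25)]
    if extra_edge:
        bridges.append((2, 6, 0.3))
    cfg = GeneratorConfig(
        n_respondents=500,
        blocks=[("A", 4, 0.25), ("B", 4, 0.25)],
        bridge_edges=bridges,
        item_levels=[4] * 8,
        seed=seed,
    )
    table, _ = simulate_dataset(cfg)
    return table.keyed()

group_a = make_group(seed=1)
group_b = make_group(seed=2, extra_edge=True)

# n_perm = 1000 keeps the smallest achievable Holm-corrected edge p-value
# below 0.05 (with 28 edges and add-one p-values, 200 permutations cannot
# localize any single edge)
result = compare_networks(group_a, group_b, n_perm=1000, seed=5, n_lambda=20)
print(result.summary())

flagged = result.edge_tests().query("p_holm < 0.05")
print(f"\nedges differing after Holm correction: {len(flagged)}")
if len(flagged):
    print(flagged.to_string(index=False))
print(
    "\nA small M p-value says at least one conditional association differs "
    "between the groups; the Holm-corrected per-edge tests localize it."
)
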