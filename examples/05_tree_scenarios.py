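"""Classify gene-family trees against the ohnolog co-option scenarios.

After two rounds of whole-genome duplication a family holds up to four
ohnologs. If venom function arose once, the SV tips form a single clade
(one bipartition of the unrooted tree separates them); scattered SV clades
indicate repeated, independent recruitment.
"""

from venomkit import classify_ohnolog_scenario, parse_labeled_tree, sv_monophyletic
from venomkit.simulate import ScenarioTreeConfig, generate_scenario_tree

for scenario in ("single_copy_cooption", "independent_diversification"):
    newick = generate_scenario_tree(
        ScenarioTreeConfig(seed=2, scenario=scenario, n_sv=4, n_nv=4)
    )
    tree = parse_labeled_tree(newick)
    print(f"simulated under : {scenario}")
    print(f"  newick        : {newick}")
    print(f"  SV monophyly  : {sv_monophyletic(tree)}")
    print(f"  classified as : {classify_ohnolog_scenario(tree)}\n")

# A hand-written tree with a single SV tip is undetermined: one tip is
# trivially monophyletic, so it cannot distinguish the scenarios.
single = parse_labeled_tree("((sv1|habu|SV,nv1|habu|NV),(nv2|cobra|NV,nv3|cobra|NV));")
print(f"single SV tip   : {classify_ohnolog_scenario(single)}")
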