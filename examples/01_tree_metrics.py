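"""Basic extent-of-evolution metrics on a small gene tree.

Builds a three-leaf rooted tree with branch lengths in substitutions per
site and prints its total length (all evolution since the root), each
leaf's root-to-tip distance (per-lineage evolution) and a patristic
distance (evolution separating two sequences).
"""

import evorate as ev

tree = ev.read_newick("((Arabidopsis:0.012,Brassica:0.019):0.004,Oryza:0.031);")

total = ev.tree_total_length(tree)
print(f"total tree length: {total:.4f} substitutions/site")
print("  = the whole extent of molecular evolution captured by the tree")

for leaf, d in sorted(ev.root_to_tip(tree).items()):
    print(f"root-to-tip {leaf}: {d:.4f} substitutions/site")
print("  = evolution each lineage accumulated since the common ancestor")

d = ev.patristic_distance(tree, "Arabidopsis", "Oryza")
print(f"patristic Arabidopsis-Oryza: {d:.4f} substitutions/site")
print("  = evolution separating the two sequences through their ancestor")

rerooted = ev.root_at_outgroup(tree, {"Oryza"})
print(f"total length after rerooting on Oryza: {ev.tree_total_length(rerooted):.4f}")
print("  = unchanged: rerooting never creates or destroys branch length")
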