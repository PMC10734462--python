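"""Concatenated ribosomal-protein phylogeny of a simulated cohort.

Thirteen ribosomal proteins are extracted by homology, aligned per marker,
gap-masked (columns > 70% gaps dropped), concatenated, and summarized into
a neighbor-joining tree with bootstrap supports from column resampling.
"""

from ferroscan import align_marker, extract_markers, mask_and_concat, nj_tree
from ferroscan.simulate import SimulationConfig, simulate_cohort

sim = simulate_cohort(SimulationConfig(seed=17, n_per_group=3))
marker_set = extract_markers(sim.genomes, sim.catalog)
print(f"markers retained: {len(marker_set.markers)} "
      f"({', '.join(marker_set.markers[:5])}, ...)")

blocks = {m: align_marker(marker_set.sequences[m]) for m in marker_set.markers}
masked = mask_and_concat(blocks, [g.genome_id for g in sim.genomes])
print(f"concatenated alignment: {len(masked.genome_ids)} genomes x "
      f"{masked.length} columns")

tree = nj_tree(masked, bootstraps=200, seed=4)
clades = {}
for gid, grp in sim.truth.group_of.items():
    clades.setdefault(grp, []).append(gid)
for grp, tips in sorted(clades.items()):
    mono = tree.is_monophyletic(tips)
    support = tree.clade_support(tips)
    print(f"  {grp}: monophyletic={mono}, bootstrap support={support}")
print()
print("All four planted clades should be recovered as monophyletic with")
print("high support; the Newick string below can be loaded in any viewer.")
print(tree.newick()[:120] + "...")
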