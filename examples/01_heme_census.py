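"""Census of heme-binding motifs (CXXCH / CX3CH / CX4CH) in protein sequences.

Each motif anchors one covalently bound heme of a c-type cytochrome, so the
per-protein count separates monoheme proteins (e.g. the Cyc2 iron oxidase)
from multiheme cytochromes such as the decaheme MtoA.
"""

from ferroscan import scan_protein
from ferroscan.hemes import profile_protein

examples = {
    "monoheme (Cyc2-like)": "MAKLCAACHKEQGTRVLA",
    "two spaced variants": "MDCAAACHLERTCAAAACHWQ",
    "decaheme (MtoA-like)": "M" + "CAACHAALKE" * 10,
}

for name, seq in examples.items():
    hits = scan_protein(seq)
    prof = profile_protein("p", seq)
    classes = ", ".join(f"{h.motif_class}@{h.start}" for h in hits)
    print(f"{name}: {prof.total_hemes} hemes (category {prof.category})")
    print(f"  motifs: {classes}")

print()
print(
    "Counts are non-overlapping by a leftmost-start greedy rule - two heme"
)
print("attachments cannot share a cysteine, so nested matches collapse to one.")
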