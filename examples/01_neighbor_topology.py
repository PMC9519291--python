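"""Anatomical context sets on the FDI primary-dentition graph.

For each context size K the neighbors of a tooth are: its two within-arch
neighbors (K=2, crossing the midline), plus the facing tooth in the opposing
arch (K=3), plus the facing tooth's own two within-arch neighbors (K=5).
"""

from cariesctx import arch_order, neighbor_set

print("upper arch:", " ".join(str(p) for p in arch_order("upper")))
print("lower arch:", " ".join(str(p) for p in arch_order("lower")))
print()

for tooth in ("51", "64", "85"):
    for k in (2, 3, 5):
        nbs = ", ".join(str(p) for p in neighbor_set(tooth, k))
        print(f"tooth {tooth}, K={k}: [{nbs}]")
    print()

print(
    "Tooth 51's sets are the canonical worked example; tooth 85 sits at the\n"
    "arch end, so its missing distal neighbor is omitted and the lists are\n"
    "shorter than K."
)
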