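"""Call and classify events from a hand-written segregation matrix.

Six SNP markers on one chromosome, four spores: a 3:1 tract (gene
conversion on one chromatid) far from a crossover-style phase change.
"""

import numpy as np

from meiomap import MarkerMap, Tetrad, build_profile
from meiomap.calling import call_raw_events, group_events
from meiomap.classify import classify_group
from meiomap.core import P1, P2

S, Y = P1, P2  # the two parental allele codes
markers = MarkerMap({"chrS": np.array([1000, 3000, 5000, 7000, 9000, 11000])})
matrix = np.array(
    [
        #  conversion at marker 1 (spore 2 carries S on a Y background),
        #  crossover between markers 4 and 5 (spores 0 and 3 switch)
        [S, S, S, S, S, Y],
        [S, S, S, S, S, S],
        [Y, S, Y, Y, Y, Y],
        [Y, Y, Y, Y, Y, S],
    ],
    dtype=np.int8,
)

tetrad = Tetrad("demo", {"chrS": matrix})
profile = build_profile(tetrad, "chrS", markers)
print("Per-marker segregation:", " ".join(profile.classes))

events = call_raw_events(profile, matrix)
for e in events:
    print(
        f"{e.kind:9s} at {e.start}-{e.end} bp on chromatids "
        f"{sorted(e.chromatids)} ({e.flank_relation or 'breakpoint'})"
    )

for group in group_events(events, gap=5000):
    label = classify_group(group)
    print(
        f"Group spanning {group.span[0]}-{group.span[1]} bp -> class {label}"
    )
print("E1 = simple noncrossover conversion; E2 = simple crossover.")
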