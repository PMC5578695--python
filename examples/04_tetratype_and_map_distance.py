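"""Fluorescent-spore tetratype scoring and Perkins map distances.

Tetrads carrying RFP and CFP markers in repulsion are typed as parental
ditype / tetratype / nonparental ditype; the tetratype fraction tracks
crossing over in the marked interval and the Perkins formula converts
tetrad counts into a genetic map distance.
"""

from meiomap.assays import (
    TetradTypeCounts,
    percent_tetratype,
    perkins_distance,
    tetratype_phenotype,
    type_fluorescent_tetrad,
)

R, C, RC, NONE = (True, False), (False, True), (True, True), (False, False)
observed = [(R, R, C, C), (R, C, RC, NONE), (R, R, C, C), (R, C, RC, NONE)]
for spores in observed[:2]:
    print("Tetrad", spores, "->", type_fluorescent_tetrad(spores))

wt = TetradTypeCounts(pd=158, tt=92, npd=0)  # ~36.7% TT, wild-type-like
null = TetradTypeCounts(pd=210, tt=40, npd=0)  # ~16% TT, resolvase null
allele = TetradTypeCounts(pd=195, tt=55, npd=0)

print(f"\n%TT wild type {percent_tetratype(wt):.1f}, null "
      f"{percent_tetratype(null):.1f}, test allele "
      f"{percent_tetratype(allele):.1f}")
call = tetratype_phenotype(allele, wt, null)
print(f"Phenotype vs both controls (chi-square, p<0.01): {call}")

dist = perkins_distance(TetradTypeCounts(pd=48, tt=50, npd=2))
print(f"\nPerkins distance for PD=48 TT=50 NPD=2: "
      f"{dist.cm:.1f} +/- {dist.se:.1f} cM")
print("(cM = 100 x (TT/2 + 3 NPD)/n; NPDs carry the double-crossover "
      "correction)")
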