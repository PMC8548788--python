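"""Range analysis of the L9(3^4) extraction-optimisation experiment.

Reads the packaged nine-run orthogonal design (solid-liquid ratio, solvent
concentration, extraction time, column temperature; three levels each) and
computes the level means k, ranges R and best level per factor.
"""

from herbqc import load_fixture
from herbqc.doe import best_levels, from_frame, range_analysis, rank_factors

design = from_frame(load_fixture("table2_orthogonal"))
ra = range_analysis(design)

print("level means k (rows k1..k3 per factor):")
print(ra.k.round(3).to_string())
print("\nrange R per factor (raw):")
print(ra.r.round(3).to_string())
print("\nfactor importance:", " > ".join(rank_factors(ra)))
print("\nbest level per factor:")
print(best_levels(ra).to_string())
print("\nA large R means the factor moves the extraction yield strongly; "
      "the best levels reproduce the selected working conditions "
      "(70% solvent, 30 min, 1:30, 35 C).")
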