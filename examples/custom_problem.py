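"""Build and validate a decision problem of your own.

Constructs a random but valid three-alternative problem, checks the matrix
against the criteria, renders the red/amber/green view of the performance
levels, and scores it — the same pipeline the packaged study runs, on
arbitrary criteria and level ladders.
"""

from mcda import rag_render, score_alternatives, validate_matrix
from mcda.synthetic import random_instance

criteria, matrix, values = random_instance(
    n_alternatives=3, n_criteria=4, n_levels=3, seed=5
)

report = validate_matrix(matrix, criteria)
print("matrix valid:", report.ok)

tags = rag_render(matrix, criteria)
print("\nRAG view (red = worst level, green = best):")
header = "            " + "".join(f"{c.id:>8}" for c in criteria)
print(header)
for alt in matrix.alternatives:
    row = "".join(f"{tags[(alt, c.id)]:>8}" for c in criteria)
    print(f"{alt:12s}{row}")

table = score_alternatives(matrix, criteria, values)
print("\nweighted totals:")
for alt in matrix.alternatives:
    print(f"  {alt}: {float(table.totals[alt]):.1f}  ({table.rank_labels[alt]})")
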