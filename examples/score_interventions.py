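"""Score and rank the four packaged intervention types.

Loads the packaged criteria, performance matrices and group preference
values, computes both scoring models, and prints the totals and ranks.  The
unweighted model sums 1/2/3 level codes (max 30); the weighted model sums
elicited part-worth values (max 100), so the two can disagree on ordering —
here they break the Written Communication / Face-to-Face tie.
"""

from mcda import fixtures
from mcda.aggregation import criterion_summary, score_alternatives

criteria = fixtures.study_criteria()
values = fixtures.study_values()

unweighted = score_alternatives(fixtures.study_matrix("unweighted"), criteria)
weighted = score_alternatives(fixtures.study_matrix("weighted"), criteria, values)

print("Intervention type        unweighted (/30)  weighted (/100)")
for alt in fixtures.ALTERNATIVES:
    print(
        f"{alt:24s} {unweighted.totals[alt]:>4} {unweighted.rank_labels[alt]:>12}"
        f"  {str(weighted.totals[alt]):>6} {weighted.rank_labels[alt]:>8}"
    )

print("\nCriterion weights, most to least important:")
for cid, weight in criterion_summary(values, criteria):
    print(f"  {cid:16s} {weight:5.1f}%")
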