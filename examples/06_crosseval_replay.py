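"""Replay a cross-evaluation from precomputed hub-simulation scores.

Useful when hub-simulation score tables come from elsewhere: the
cross-evaluation matrix, recurrence counts and back-evaluation are
recomputed from the score cells alone.  Here we use the shipped reference
fixture (synthetic placeholder CUIs).
"""

from pathlib import Path

from hetepath import back_evaluate, cross_evaluate
from hetepath.hubs import load_hub_scores

fixture = Path(__file__).resolve().parent.parent / "tests" / "data" / "hub_scores_fixture.tsv"
hub_results = load_hub_scores(fixture)

table = cross_evaluate(hub_results, threshold=0.2)
print("candidate recurrence and mean score across hub simulations:")
for cand in table.scores.index:
    print(f"  {cand}: recurrence={table.recurrence[cand]} "
          f"mean={table.mean_score[cand]:.4f}")

count, passed = back_evaluate("C9200005", hub_results, threshold=0.2)
print(f"\nback-evaluation of C9200005 (an antihistamine): {count} hub(s) passed")
for hub, score in passed:
    print(f"  {hub}  {score:.3f}")
# The back-evaluated antihistamine passes in exactly five hub simulations,
# listed in descending score order (0.585 down to 0.369, mean 0.4394).
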