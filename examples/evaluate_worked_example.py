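"""Verify daily migration predictions against trap catches (Koshi, May 2021).

Loads the packaged month of daily predictions and pheromone-trap catches for
the Koshi site, classifies every day as hit (H), fail (F) or excluded (-)
for the 3-day and 5-day evaluation windows, and prints the hitting ratio
hits / (hits + fails). A positive prediction is a hit when a catch occurs
within the window starting at the predicted arrival; a prediction-free day is
a hit when it is catch-free, unless it is shadowed by a recent positive
prediction (then it is excluded).
"""

from mothflight.data import load_example_catches, load_example_predictions
from mothflight.evaluation import classify_days, site_hitting_ratio

preds = load_example_predictions("koshi")
catches = load_example_catches("koshi")

for L in (3, 5):
    cls = classify_days(preds, catches, L, site="koshi")
    marks = "".join(c.mark for c in cls)
    hits = sum(1 for c in cls if c.category == "hit")
    fails = sum(1 for c in cls if c.category == "fail")
    print(f"{L}-day window: {marks}")
    print(f"  hits {hits} / evaluated {hits + fails}  ->  "
          f"hitting ratio {site_hitting_ratio(cls):.2f}")
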