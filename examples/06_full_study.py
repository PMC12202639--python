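"""Full seat-angle study: 5 whole-chair recline conditions end to end.

Generates a synthetic condition series (pressure migrating from cushion to
backrest as the chair reclines, plus internal spinal responses), analyzes
every condition, and prints the trend table that relates surface metrics
to internal responses.
"""

import json
import tempfile
from pathlib import Path

import ergoseat as es

config = {
    "conditions": {"kind": "whole_chair_flip",
                   "angles": [0, 10, 20, 30, 40],
                   "synthetic": {"seed": 7}},
    "partitions": {"cushion_split_row": 14, "backrest_l1_row": 24},
}

with tempfile.TemporaryDirectory() as td:
    report = es.run_pipeline(config, Path(td) / "out")

print(f"{'angle':>6} {'hip p_max':>10} {'waist p_max':>12} {'hip comfort':>14} {'waist comfort':>14}")
for block in report["conditions"]:
    print(f"{block['angle']:>6.0f} {block['regions']['hip']['p_max']:>10.2f} "
          f"{block['regions']['waist']['p_max']:>12.2f} "
          f"{block['comfort']['hip']:>14} {block['comfort']['waist']:>14}")

print("\nrank correlation of hip surface metrics vs internal responses:")
print(json.dumps(report["trend_matrix"]["hip"], indent=1))
# As recline grows, cushion load falls (hip drops below its ideal window)
# and backrest load rises (waist exceeds 4-8 kPa): the classification flags
# exactly the trade-off that bounds the comfortable recline range. The
# rank correlations show which surface metric tracks which internal
# response across conditions.
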