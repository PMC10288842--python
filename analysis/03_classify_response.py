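"""Classify the volumetric response of each interim phantom against the
baseline MTV measured in step 02: relative MTV change, PR/SD/PD label
(-73% / +63% bounds, boundaries to SD), responder flag.

Writes results/response.csv.
"""

import json
from pathlib import Path

import pandas as pd

from netmtv import classify_response, is_responder, percent_change

res = Path("results")
meas = json.loads((res / "mtv_measurements.json").read_text())
mtv_b = meas["scans"]["baseline"]["total_mtv_ml"]

rows = []
for tag, block in meas["scans"].items():
    if tag == "baseline":
        continue
    pct = percent_change(mtv_b, block["total_mtv_ml"])
    cls = classify_response(pct)
    rows.append(
        {
            "scan": tag,
            "baseline_mtv_ml": mtv_b,
            "interim_mtv_ml": block["total_mtv_ml"],
            "pct_change": pct,
            "class": cls.value,
            "responder": is_responder(cls),
        }
    )
    print(f"{tag}: {pct:+.1f}% -> {cls.value} ({'responder' if is_responder(cls) else 'non-responder'})")

pd.DataFrame(rows).to_csv(res / "response.csv", index=False)
print(f"wrote {res}/response.csv")
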