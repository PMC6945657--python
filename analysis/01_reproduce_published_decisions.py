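"""Reproduce the published commissioning decisions from the printed tables.

No simulation here: the bundled tables (the gamma passing rates a full
Monte-Carlo linac simulation produced against measured golden beam data)
are pushed through the package's decision rules, and every published
outcome is re-derived:

* Pearson trend r for the competing initial energies at 6 and 10 MV,
* the initial-energy selections (6.26 over 5.40 MeV; 10.5 over 10.7 MeV),
* the three serial-stage argmax picks per nominal energy,
* the cross-depth head-to-head that overturned the 10 MV stage-1 pick.

Writes results/published_decisions.{json,csv}.
"""

import json
from pathlib import Path

import pandas as pd

from linactune import select_energy
from linactune.tables import (
    depth_comparison_from_table,
    load_table,
    stage_from_table,
    trend_from_table,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

records = []
report = {}

print("== Pearson trends (average uncertainty vs 1%/1mm rate) ==")
for tid in (1, 2, 8, 9):
    t = trend_from_table(tid)
    print(f"table {tid:2d}  {t.candidate_label:>9}: r = {t.pearson_r:+.2f}, "
          f"final 1%/1mm = {t.final_rate_1_1:.1f}%")
    report[f"table{tid}_pearson_r"] = round(t.pearson_r, 2)
    records.append({"table": tid, "quantity": "pearson_r",
                    "value": round(t.pearson_r, 2)})

print("\n== Initial-energy selections ==")
for label, pair in (("6MV", (1, 2)), ("10MV", (8, 9))):
    sel = select_energy([trend_from_table(t) for t in pair])
    print(f"{label}: selected {sel.chosen_label} "
          f"(qualifiers: {[t.candidate_label for t in sel.qualifiers]})")
    report[f"{label}_selected_energy"] = sel.chosen_energy
    records.append({"table": pair, "quantity": "selected_energy_mev",
                    "value": sel.chosen_energy})

print("\n== Serial optimization stages (best-depth 1%/1mm argmax) ==")
for tid in (5, 6, 7, 12, 14, 15):
    st = stage_from_table(tid)
    print(f"table {tid:2d}  {st.parameter_name:>16}: chose {st.chosen_value:g} "
          f"at {st.chosen_rate:.1f}%")
    report[f"table{tid}_chosen"] = st.chosen_value
    report[f"table{tid}_rate"] = st.chosen_rate
    records.append({"table": tid, "quantity": f"argmax_{st.parameter_name}",
                    "value": st.chosen_value})

print("\n== Cross-depth safeguard (10 MV energy FWHM) ==")
cmp13 = depth_comparison_from_table(13)
print(f"{cmp13.label_a} wins {cmp13.wins_a} of {len(cmp13.rates_a)} depths "
      f"over {cmp13.label_b} -> winner {cmp13.winner}")
print("This overturns the table-12 argmax (0.140 MeV): the 0.120 MeV energy "
      "FWHM is the better configuration depth-by-depth, and its final tuned "
      "rate (81.4%) beats 0.140 MeV's (78.9%).")
report["table13_wins_0p120"] = cmp13.wins_a

(OUT / "published_decisions.json").write_text(json.dumps(report, indent=2) + "\n")
pd.DataFrame(records).to_csv(OUT / "published_decisions.csv", index=False)
print(f"\nwrote {OUT/'published_decisions.json'} and .csv")
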