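#!/usr/bin/env python
"""Optimum IMS cutoffs for the three-class pacing response.

For each pacing tool, takes the captured paced beats (LAT <= 0), runs the
generalized-Youden multi-class threshold search on the scores and
ground-truth labels, and compares the recovered pair with the published
cutoffs (c_low = 78.4%, c_high = 88.9%).
"""

import json
import subprocess
import sys
from pathlib import Path

from hisims import BeatClass, filter_captured, optimize_thresholds
from hisims.io import read_scores
from hisims.synthetic_ecg import CAPTURED_PACED_CLASSES

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    if not (RESULTS / "scores_his_lead.csv").exists():
        subprocess.check_call([sys.executable,
                               str(Path(__file__).parent
                                   / "01_simulate_and_score.py")])
    out = {}
    for preset in ("his_lead", "catheter"):
        results = read_scores(RESULTS / f"scores_{preset}.csv")
        paced = [r for r in results
                 if r.true_class is not BeatClass.INTRINSIC]
        captured = [r for r in filter_captured(paced)
                    if r.true_class in CAPTURED_PACED_CLASSES]
        ts = optimize_thresholds([r.global_ims_pct for r in captured],
                                 [r.true_class for r in captured])
        out[preset] = {"c_low_pct": ts.c_low_pct,
                       "c_high_pct": ts.c_high_pct,
                       "n_captured": len(captured)}
        print(f"{preset:9s}: c_low = {ts.c_low_pct:5.1f}%  "
              f"c_high = {ts.c_high_pct:5.1f}%   "
              f"(published 78.4% / 88.9%, n = {len(captured)})")

    (RESULTS / "thresholds.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
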