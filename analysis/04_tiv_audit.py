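"""Step 4 — audit the classifier's reliance on total intracranial volume.

Splits the test subjects into TIV tertiles (per-sex recall and balanced
accuracy per tertile), locates the KDE overlap interval R_tiv at the 20%
density threshold, and extracts the balanced correctly-classified subset.
Artifacts: tertiles.csv, rtiv.json.
"""

import json
from pathlib import Path

import pandas as pd

from brainsexmap.pipeline import run_stage, validate_config

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = validate_config(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    run_stage("tiv-audit", cfg, out)
    print(pd.read_csv(out / "tertiles.csv").round(3).to_string(index=False))
    rtiv = json.loads((out / "rtiv.json").read_text())
    if rtiv.get("empty"):
        print("no density overlap between the sexes at this threshold")
    else:
        print(f"R_tiv = [{rtiv['lo']:.0f}, {rtiv['hi']:.0f}] ml "
              f"(threshold {rtiv['density_threshold']}, bandwidths "
              f"F={rtiv['bandwidth_f']:.1f} / M={rtiv['bandwidth_m']:.1f} ml)")
        print(f"balanced correctly-classified subset: "
              f"{len(rtiv['balanced_subset'])} subjects")


if __name__ == "__main__":
    main()
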