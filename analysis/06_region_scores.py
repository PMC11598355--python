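"""Step 6 — score atlas regions on the sex differences map.

For each toy-atlas region: the saliency score (fraction of voxels with
normalised saliency > 0.1), mean saliency, the across-regions min-max
normalised mean, and the weighted score that ranks the regions. The planted
effect regions (1-3 in the demo config) should top the ranking.
Artifacts: region_scores.csv, topk.json.
"""

import json
from pathlib import Path

import pandas as pd

from brainsexmap.pipeline import run_stage, validate_config

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = validate_config(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    run_stage("score", cfg, out)
    table = pd.read_csv(out / "region_scores.csv")
    print(table.round(3).to_string(index=False))
    topk = json.loads((out / "topk.json").read_text())
    print(f"top {topk['k']} regions by weighted saliency score:")
    for r in topk["regions"]:
        print(f"  {r['name']}: {r['weighted_score']:.3f}")


if __name__ == "__main__":
    main()
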