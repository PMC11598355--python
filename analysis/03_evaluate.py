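"""Step 3 — evaluate on the held-out test split.

Reports global accuracy, balanced accuracy, precision/recall/F1 and AUC with
Male as the positive class, plus the same metrics per site, field strength,
and age bin. Artifacts: predictions.csv, metrics.json.
"""

import json
from pathlib import Path

from brainsexmap.pipeline import run_stage, validate_config

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = validate_config(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    run_stage("evaluate", cfg, out)
    report = json.loads((out / "metrics.json").read_text())
    g = report["global"]
    print(f"test n={g['n']}: accuracy={g['accuracy']:.3f} "
          f"balanced={g['balanced_accuracy']:.3f} auc={g['auc_roc']:.3f}")
    for variable, groups in report["subgroups"].items():
        for label, m in groups.items():
            print(f"  {variable}={label}: n={m['n']} "
                  f"balanced={m['balanced_accuracy']:.3f}")


if __name__ == "__main__":
    main()
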