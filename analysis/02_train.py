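"""Step 2 — train the sex classifier.

Trains the compact SFCN (Adam, binary cross-entropy, initial lr 0.01,
reduce-on-plateau, 50%/15-degree rotation augmentation) on the z-scored
training split and keeps the epoch with the lowest validation loss.
Artifacts: checkpoint.npz, history.json.
"""

import json
from pathlib import Path

from brainsexmap.pipeline import run_stage, validate_config

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = validate_config(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    run_stage("train", cfg, out)
    history = json.loads((out / "history.json").read_text())
    for h in history["history"]:
        print(f"epoch {h['epoch']:2d} lr={h['lr']:.4g} "
              f"train={h['train_loss']:.4f} val={h['val_loss']:.4f}")
    print(f"selected epoch (lowest validation loss): "
          f"{history['selected_epoch']}")


if __name__ == "__main__":
    main()
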