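"""Step 5 — gradient saliency maps and the composite sex differences map.

Computes one gradient class-saliency map per correctly classified test
subject (single backward pass, min-max normalised within the brain mask),
averages them per sex, and builds the composite map from the TIV-balanced
subset. Artifacts: saliency/, saliency_female.nii.gz, saliency_male.nii.gz,
sex_differences_map.nii.gz.
"""

from pathlib import Path

import numpy as np

from brainsexmap.pipeline import run_stage, validate_config
from brainsexmap.volume import Volume

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = validate_config(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    run_stage("saliency", cfg, out)
    comp = Volume.from_nifti(out / "sex_differences_map.nii.gz")
    nz = comp.data[comp.data > 0]
    print(f"sex differences map: {comp.shape} grid, "
          f"{nz.size} nonzero voxels, "
          f"in-brain saliency mean {nz.mean():.3f} / max {nz.max():.3f}")
    for name in ("saliency_female.nii.gz", "saliency_male.nii.gz"):
        if (out / name).exists():
            m = Volume.from_nifti(out / name)
            print(f"  {name}: mean in-brain saliency "
                  f"{np.mean(m.data[m.data > 0]):.3f}")


if __name__ == "__main__":
    main()
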