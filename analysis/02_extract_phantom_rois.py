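#!/usr/bin/env python
"""Build a synthetic imaging phantom and extract its ROI table.

Exercises the voxel-level path: tissue-fraction arithmetic, GM-threshold
masking, tract-probability weighting and bilateral averaging, then checks
the planted per-ROI means are recovered (they are exact on the noiseless
phantom; a second noisy phantom shows the sampling error).
"""


import numpy as np

from noddinorms.volumes import (PhantomConfig, extract_roi_table,
                                generate_phantom_volumes, save_volume_set)

from paths import RESULTS, SCRATCH


def main() -> None:
    cfg = PhantomConfig(seed=1)
    volumes, spec = generate_phantom_volumes(cfg)
    save_volume_set(volumes, spec, SCRATCH / "phantom_volumes")
    table = extract_roi_table(volumes, spec)
    table["planted"] = [cfg.mean_for(r.roi_name, r.metric)
                        for r in table.itertuples()]
    table["abs_error"] = (table["value"] - table["planted"]).abs()
    table.drop(columns="participant_id").to_csv(
        RESULTS / "phantom_roi_means.csv", index=False, float_format="%.12g")
    print(f"noiseless phantom: max |error| = {table['abs_error'].max():.2e} "
          "(planted means recovered exactly)")

    noisy, spec_n = generate_phantom_volumes(PhantomConfig(seed=1, noise_sd=0.02))
    noisy_table = extract_roi_table(noisy, spec_n)
    err = np.abs(noisy_table["value"].to_numpy() - table["planted"].to_numpy())
    print(f"noisy phantom (voxel SD 0.02): max ROI-mean |error| = {err.max():.4f}")


if __name__ == "__main__":
    main()
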