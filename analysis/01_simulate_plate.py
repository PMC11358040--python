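#!/usr/bin/env python
"""Generate the default synthetic screen plate and triage assays.

Writes the raw plate (manifest + per-well per-frame .dat files) under
scratch/plate/ and the planted-truth tables under results/.  The plate
holds 12 library compounds in four chemotypes (CX1 strong/fast
dimerizers ... CX4 inactive), duplicate monomer controls, triplicate
dimer controls and duplicate matched buffers.
"""

from pathlib import Path

import numpy as np

from trsaxs.synth import simulate_screen_plate, simulate_triage_assays, write_plate

SEED = 42
ROOT = Path(__file__).resolve().parents[1]


def main():
    plate = simulate_screen_plate(seed=SEED)
    manifest = write_plate(plate, ROOT / "scratch" / "plate")
    assays = simulate_triage_assays(seed=SEED)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    plate.truth.to_csv(out / "planted_truth.csv", index=False)
    assays.truth.to_csv(out / "planted_triage_truth.csv", index=False)

    n_frames = sum(len(s) for s in plate.series.values())
    print(f"wrote {manifest}")
    print(f"{len(plate.series)} wells, {n_frames} frames "
          f"({len(plate.truth)} compounds, 5 controls, 2 buffers)")
    print(f"planted conversion rates span "
          f"{plate.truth[plate.truth.k_true > 0].k_true.min():.2f}-"
          f"{plate.truth.k_true.max():.2f} s^-1")
    n_path = (assays.truth["pathological"] != "").sum()
    print(f"planted pathological melt curves: {n_path}/{len(assays.truth)}")


if __name__ == "__main__":
    main()
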