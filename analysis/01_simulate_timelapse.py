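#!/usr/bin/env python
"""Simulate the three benchmark movies of the retrofusion assay.

Renders noiseless three-channel time-lapses (one frame per 180 s, 121
frames covering 0-360 min) for:

* ``dimerizer``       — protease on, partial retrofusion (the control arm);
* ``no_dimerizer``    — protease off: the EL signal should stay flat;
* ``retro_attenuated``— protease on, retrofusion rate halved (a lipid/pH
  perturbation modelled purely as slower retrofusion).

Ground-truth tables land in results/simulated/<condition>/; the image
stacks themselves (large, binary) go to scratch/simulated/<condition>/.
"""

import math
import sys
from pathlib import Path

import tifffile

from retroquant.kinetics import KineticParams
from retroquant.synthetic import AcquisitionParams, generate_geometry, generate_timelapse

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "simulated"
SCRATCH = ROOT / "scratch" / "simulated"
SEED = 11

CONDITIONS = {
    "dimerizer": KineticParams(
        rho=2.0, phi_dynamic=0.7, k_cleave=0.004, k_retro=0.004, half_life_h=24.0
    ),
    "no_dimerizer": KineticParams(
        rho=2.0, phi_dynamic=0.7, k_cleave=0.0, k_retro=0.004, half_life_h=math.inf
    ),
    "retro_attenuated": KineticParams(
        rho=2.0, phi_dynamic=0.7, k_cleave=0.004, k_retro=0.002, half_life_h=24.0
    ),
}


def main() -> int:
    geom = generate_geometry(3, SEED, image_shape=(256, 256))
    acq = AcquisitionParams(n_frames=121)
    for name, kinetics in CONDITIONS.items():
        outdir = RESULTS / name
        outdir.mkdir(parents=True, exist_ok=True)
        stackdir = SCRATCH / name
        stackdir.mkdir(parents=True, exist_ok=True)
        stack, truth = generate_timelapse(geom, kinetics, acq)
        tifffile.imwrite(
            stackdir / "stack.tif", stack, photometric="minisblack",
            metadata={"axes": "TCYX"},
        )
        (outdir / "ground_truth_pools.csv").write_text(truth.pools_csv())
        (outdir / "ground_truth_intensities.csv").write_text(truth.intensities_csv())
        final = truth.pools["EL_observable"].iloc[-1]
        print(f"{name}: {stack.shape[0]} frames, true EL signal at 6 h = {final:.3f}")
    print(f"wrote stacks under {SCRATCH}, ground truth under {RESULTS}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
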