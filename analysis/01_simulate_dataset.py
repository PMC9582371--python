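#!/usr/bin/env python
"""Generate the synthetic food self-control cohort.

Writes a BIDS-like dataset (events, motion, BOLD, masks, ground truth) for
a 20-subject cohort on the 20^3 grid with the full 50-stimulus task and
343-volume runs. BOLD volumes are bulky, so the dataset goes under
scratch/ by default; downstream scripts read it from there.
"""

import argparse
import time
from pathlib import Path

from selfcontrol_fmri import simulate
from selfcontrol_fmri.config import SimConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("scratch/dataset"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--subjects", type=int, default=20)
    parser.add_argument("--small", action="store_true",
                        help="16 stimuli, 130 volumes, 12^3 grid")
    args = parser.parse_args()

    kw = dict(n_subjects=args.subjects, frac_sc=0.25, seed=args.seed)
    if args.small:
        kw.update(n_stimuli=16, n_volumes_per_run=130, grid_shape=(12, 12, 12))
    config = SimConfig(**kw)

    t0 = time.perf_counter()
    truth = simulate.generate_dataset(config, args.out, overwrite=True)
    n_sc = sum(1 for c in truth.classes.values() if c == "SC")
    print(f"wrote {config.n_subjects} subjects ({n_sc} SC-truth, "
          f"{config.n_subjects - n_sc} NSC-truth) to {args.out} "
          f"in {time.perf_counter() - t0:.1f}s")
    print(f"grid {config.grid_shape}, {config.n_volumes_per_run} volumes/run, "
          f"{config.n_stimuli} stimuli, TR {config.tr}s")
    print("ground-truth amplitudes per group/region:",
          truth.amplitudes)


if __name__ == "__main__":
    main()
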