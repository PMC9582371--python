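#!/usr/bin/env python
"""Statistical calibration experiments and the peak-voxel circularity demo.

Runs the simulation experiments that characterize the pipeline: group
recovery of the vmPFC goal-value amplitude with white-matter null
calibration, the circular peak-voxel selection experiment (rejection rates
of peak vs mean extraction on a guaranteed-null region), FDR control, PPI
coupling recovery, and the deconvolution round trip. Writes
results/verification.json.
"""

import argparse
import json
from pathlib import Path

from selfcontrol_fmri import experiments as ex


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path,
                        default=Path("results/verification.json"))
    args = parser.parse_args()

    out = {
        "classification_closure": ex.classification_closure(seed=args.seed),
        "ols_oracle": ex.ols_oracle_check(seed=args.seed),
        "orthogonalization_order": ex.orthogonalization_order_check(
            seed=args.seed),
        "recovery": ex.recovery_experiment(seed=args.seed),
        "circularity": ex.circularity_experiment(seed=args.seed),
        "fdr": ex.fdr_calibration(seed=args.seed),
        "ppi": ex.ppi_recovery(seed=args.seed),
        "ppi_null": ex.ppi_recovery(seed=args.seed, null=True),
        "deconvolution": ex.deconvolution_roundtrip(),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2, default=float))

    circ = out["circularity"]
    print(f"circular peak selection on null white matter rejects in "
          f"{circ['peak_rejection_rate']:.0%} of simulations "
          f"(mean spurious effect {circ['peak_mean_effect']:.2f}); "
          f"mean-over-mask stays nominal at "
          f"{circ['mean_rejection_rate']:.1%}")
    rec = out["recovery"]
    print(f"goal-value amplitude recovered (p<.001) in "
          f"{rec['significant_fraction']:.0%} of 30-subject groups; "
          f"white-matter voxelwise FPR {rec['white_matter_fpr']:.3f}")
    print(f"FDR at q=.05: empirical {out['fdr']['empirical_fdr']:.3f}")
    print(f"PPI coupling sign recovered in "
          f"{out['ppi']['sign_recovery_rate']:.0%} of simulations; "
          f"null rejection rate {out['ppi_null']['rejection_rate']:.2f}")
    print(f"deconvolution round-trip error "
          f"{out['deconvolution']['relative_error']:.3f}")
    print(f"details in {args.out}")


if __name__ == "__main__":
    main()
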