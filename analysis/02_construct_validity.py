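#!/usr/bin/env python
"""Construct validity of the simulated badge data against ground truth.

Computes the raw dyad-second classification metrics, sweeps the three
cleaning strategies over their parameter grids, and reports the combined
recommended pipeline (interpolate 75 s, then delete events < 55 s).
Writes sweep curves and the validation report under results/.
"""

import argparse
import json
from pathlib import Path

from rfidcontacts.preprocessing import (
    DEFAULT_CLOSURE_GRID,
    DEFAULT_CUTOFF_GRID,
    ProcessingConfig,
    sweep,
)
from rfidcontacts.validation import validate
from rfidcontacts.synthetic import make_world


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    world = make_world(master_seed=args.seed)
    report = validate(world.observed, world.truth, ProcessingConfig.recommended())
    (args.out / "construct_validity.json").write_text(report.to_json() + "\n")
    print(report.to_text())

    helpful = []
    for strategy, grid in (
        ("min_duration", DEFAULT_CUTOFF_GRID),
        ("interpolate", DEFAULT_CUTOFF_GRID),
        ("triadic_closure", DEFAULT_CLOSURE_GRID),
    ):
        result = sweep(strategy, grid, world.observed, world.truth)
        result.to_frame().to_csv(args.out / f"sweep_{strategy}.csv", index=False)
        gain = result.optimum_score - result.scores[0]
        if gain > 0:
            helpful.append(strategy)
        print(
            f"{strategy:>16}: optimum at {result.optimum_value:>3} "
            f"(accuracy {result.optimum_score:.4f}, {gain:+.4f} vs unprocessed)"
        )
    print(f"strategies improving accuracy on this world: {', '.join(helpful) or 'none'}")
    print(
        "note: the interpolation optimum sits near the upper tail of the flicker "
        "gap distribution (~3x its mean), not at the mean itself"
    )


if __name__ == "__main__":
    main()
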