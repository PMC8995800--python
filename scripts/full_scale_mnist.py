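#!/usr/bin/env python
"""Full-scale MNIST sweeps with the published session counts (CPU-hours).

Requires local MNIST IDX files (train-images-idx3-ubyte etc.); nothing is
downloaded.  Runs the two dense-network protocols at their published scale:

* disorganized: width-512 twin-hidden network, 20 epochs, 100 sessions,
  diagonal masking at evaluation over a reduction grid;
* developmental: width-512 one-hidden network, 10 and 50 epochs, 100
  sessions, diagonal / gaussian / random windows.

Expect several CPU-hours per sweep at these session counts; trim --sessions
for a faster pass.
"""

import argparse
from pathlib import Path

from szlab.data import load_mnist
from szlab.experiments import run_developmental_sweep, run_disorganized_sweep, write_summary
from szlab.zoo import config_a, config_b, schedule_ab, WindowSpec


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, required=True, help="directory with MNIST IDX files")
    parser.add_argument("--out", type=Path, default=Path("results/mnist"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--sessions", type=int, default=100)
    parser.add_argument("--protocol", choices=["disorganized", "developmental"],
                        default="disorganized")
    args = parser.parse_args()

    train_ds, test_ds = load_mnist(args.data)
    reductions = [0.0, 0.2, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]

    if args.protocol == "disorganized":
        sweep = run_disorganized_sweep(
            config_b(width=512), train_ds, test_ds, reductions,
            sessions=args.sessions, base_seed=args.seed,
            schedule=schedule_ab(epochs=20), family="diagonal",
        )
        sweeps = [sweep]
    else:
        sweeps = [
            run_developmental_sweep(
                config_a(width=512, window=WindowSpec(family, 0.0)),
                train_ds, test_ds, reductions,
                sessions=args.sessions, base_seed=args.seed,
                schedule=schedule_ab(epochs=epochs), family=family,
            )
            for family in ("diagonal", "gaussian", "random")
            for epochs in (10, 50)
        ]

    long_path, means_path = write_summary(sweeps, args.out)
    print(f"wrote {long_path} and {means_path}")


if __name__ == "__main__":
    main()
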