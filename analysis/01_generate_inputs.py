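#!/usr/bin/env python
"""Generate the full synthetic input set for the reconstruction pipeline.

One seed provisions everything downstream: the compartmentalised template
model (with planted essential genes, a sterol-auxotrophy branch and an
NGAM drain), its leaky and gap-severed variants, an orthology table with
DIOPT scores, a synonym/identifier fixture, an uncompartmentalised second
network with a gene-compartment table, and a probe-level expression table
with planted regulation directions.
"""

import argparse
from pathlib import Path

from gmnforge.synth import generate_all


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--outdir", type=Path, default=Path("results/inputs"))
    args = parser.parse_args()
    paths = generate_all(args.seed, args.outdir)
    print(f"generated {len(paths)} fixture files under {args.outdir}:")
    for key, path in sorted(paths.items()):
        print(f"  {key:24s} {path}")


if __name__ == "__main__":
    main()
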