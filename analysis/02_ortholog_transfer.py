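#!/usr/bin/env python
"""Build the orthology-transferred draft model.

Treats the template's genes as source-organism genes, filters the
orthology table by DIOPT score (max-score ties kept, >9 orthologs dropped
as unspecific), rewrites every GPR, removes reactions with no orthology
evidence at all, and reports the per-gene disposition.
"""

import argparse
from pathlib import Path

from gmnforge.io import read_model, write_model
from gmnforge.ortho import OrthologyTable, filter_orthologs, translate_gprs
import pandas as pd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/inputs"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    template = read_model(args.indir / "template.json")
    table = OrthologyTable(pd.read_csv(args.indir / "orthology.tsv", sep="\t"))
    mapping = filter_orthologs(table, template.genes)
    draft, report = translate_gprs(template, mapping)

    args.outdir.mkdir(parents=True, exist_ok=True)
    write_model(draft, args.outdir / "draft_model.json")
    report.to_csv(args.outdir / "ortholog_dispositions.tsv", sep="\t", index=False)

    counts = report["disposition"].value_counts()
    print(f"template: {len(template.reactions)} reactions, {len(template.genes)} genes")
    print(f"draft:    {len(draft.reactions)} reactions, {len(draft.genes)} genes")
    print(f"removed (no orthology evidence): {report.attrs['removed_reactions']}")
    for disposition, n in counts.items():
        print(f"  {disposition}: {n} source genes")


if __name__ == "__main__":
    main()
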