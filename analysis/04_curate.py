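#!/usr/bin/env python
"""Metabolite- and reaction-centric curation.

Resolves planted synonymous metabolites through the identifier
dictionaries (merging unambiguous pairs, flagging ties for review),
deduplicates reactions on the currency-free compartment-insensitive
canonical form, and repairs the planted ATP-generating cycle located by
the leak test.
"""

import argparse
from pathlib import Path

import pandas as pd

from gmnforge.curation import (
    apply_synonym_merge,
    build_identifier_dictionary,
    find_duplicate_reactions,
    find_synonyms,
    merge_duplicates,
    read_xref_table,
)
from gmnforge.fluxsim import fba
from gmnforge.io import read_model, write_model
from gmnforge.leak import localize_leak, test_leaks


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/inputs"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    # --- synonym resolution on the identifier fixture
    syn_model = read_model(args.indir / "synonym_model.json")
    xref = read_xref_table(args.indir / "metabolite_xrefs.tsv")
    report = find_synonyms(build_identifier_dictionary(syn_model, xref))
    merged = apply_synonym_merge(syn_model, report)
    pd.DataFrame(report.merged, columns=["kept", "removed", "shared_ids"]).to_csv(
        args.outdir / "synonyms_merged.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"ambiguous_group": [";".join(sorted(g)) for g in report.ambiguous]}
    ).to_csv(args.outdir / "synonyms_ambiguous.tsv", sep="\t", index=False)
    print(f"synonyms: merged {len(report.merged)} pairs, "
          f"flagged {len(report.ambiguous)} ambiguous group(s) for review")
    print(f"  metabolites {len(syn_model.metabolites)} -> {len(merged.metabolites)}")

    # --- duplicate screen on the merged reconstruction
    model = read_model(args.outdir / "merged_model.json")
    groups = find_duplicate_reactions(model, ignore_compartments=True)
    deduped = merge_duplicates(model, groups)
    print(f"duplicates: {len(groups)} group(s); "
          f"reactions {len(model.reactions)} -> {len(deduped.reactions)}; "
          f"genes preserved: {model.genes == deduped.genes}")

    # --- energy-leak repair on the planted leaky variant
    leaky = read_model(args.indir / "leaky.json")
    leak_rows = []
    for leak in test_leaks(leaky):
        status = "LEAK" if leak.leaking else "ok"
        pairs = ""
        if leak.leaking:
            leak = localize_leak(leaky, leak)
            pairs = ";".join("|".join(p) for p in leak.culprit_pairs)
            # repair: drop one member of the first single-culprit hit
            culprit = leak.culprit_singles[0]
            del leaky.reactions[culprit]
            print(f"leak[{leak.metabolite}]: flux {leak.dissipation_flux:g}, "
                  f"removed {culprit}")
        leak_rows.append({"metabolite": leak.metabolite, "status": status,
                          "dissipation_flux": leak.dissipation_flux,
                          "culprit_pairs": pairs})
    pd.DataFrame(leak_rows).to_csv(args.outdir / "leak_report.tsv", sep="\t", index=False)
    residual = [l for l in test_leaks(leaky) if l.leaking]
    growth = fba(leaky).objective_value
    print(f"after repair: {len(residual)} residual leak(s), growth {growth:.3f}")
    write_model(leaky, args.outdir / "repaired_model.json")


if __name__ == "__main__":
    main()
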