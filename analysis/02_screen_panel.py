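#!/usr/bin/env python
"""Screen the simulated candidates through the five-criterion II-SNP filter.

Criteria: exclusion list, frequency spectrum (bi-allelic in [0.4, 0.6],
multi-allelic MAF > 0.01), Ho > 0.4, HWE and pairwise linkage equilibrium
at Bonferroni-adjusted levels, and >= 10 Mb spacing per chromosome.
Writes the audit table and the surviving locus list.
"""

import pathlib

import pandas as pd

from forensnp import selection, vcfio

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    cohort = vcfio.read_vcf(OUT / "cohort.vcf")
    result = selection.apply_selection(
        cohort, selection.SelectionCriteria(), seed=SEED,
        hwe_reps=20_000, ld_reps=4_000,
    )
    result.audit.to_csv(OUT / "selection_audit.tsv", sep="\t", index=False)
    pd.DataFrame({"locus": result.selected_ids}).to_csv(
        OUT / "selected_loci.tsv", sep="\t", index=False
    )
    n_fail = (~result.audit["selected"]).sum()
    print(f"selected {len(result.selected_ids)}/{cohort.n_loci} candidates")
    if n_fail:
        failed = result.audit[~result.audit["selected"]]
        for crit in selection.CRITERIA:
            n = (failed[crit] == "fail").sum()
            if n:
                print(f"  {n} dropped by the {crit} criterion")
    print(f"wrote selection_audit.tsv, selected_loci.tsv to {OUT}")


if __name__ == "__main__":
    main()
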