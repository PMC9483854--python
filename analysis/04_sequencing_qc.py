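#!/usr/bin/env python
"""Sequencing-performance metrics of the simulated MPS run.

Depth of coverage (DoC), heterozygote allele coverage ratio (ACR) and
noise level (NL) per locus, with the casework flags: calls below 20x
depth and loci with mean ACR below the 0.66 reference value.
"""

import pathlib

from forensnp import qc, vcfio

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = vcfio.read_vcf(OUT / "cohort.vcf")
    counts = vcfio.read_read_counts(OUT / "read_counts.tsv")
    report = qc.qc_summary(counts, cohort)
    per_locus = report.pop("per_locus")
    merged = (
        per_locus["doc"]
        .merge(per_locus["acr"], on="locus", how="left")
        .merge(per_locus["nl"], on="locus", how="left")
    )
    merged.to_csv(OUT / "sequencing_qc.tsv", sep="\t", index=False)

    print(f"panel mean DoC: {report['doc_mean']:.0f}x "
          f"(locus means {per_locus['doc']['doc_mean'].min():.0f}x"
          f"-{per_locus['doc']['doc_mean'].max():.0f}x)")
    print(f"panel mean ACR: {report['acr_mean']:.4f}")
    print(f"panel mean NL:  {report['nl_mean']:.4f}")
    print(f"calls below 20x: {report['n_low_depth_calls']}")
    print(f"loci with ACR < 0.66: {len(report['low_acr_loci'])}")
    print(f"wrote sequencing_qc.tsv to {OUT}")


if __name__ == "__main__":
    main()
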