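#!/usr/bin/env python
"""Per-locus forensic parameters and panel cumulatives for the screened set.

Computes Ho, He, PIC, PM, PD, PE and the HWE exact-test p-value per locus,
then the cumulative match probability (CPM), cumulative power of
discrimination and combined power of exclusion (CPE) in log10 space.
"""

import json
import pathlib

import pandas as pd

from forensnp import panel_metrics, vcfio
from forensnp.locus_stats import compute_locus_stats, round_report

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    cohort = vcfio.read_vcf(OUT / "cohort.vcf")
    keep = pd.read_csv(OUT / "selected_loci.tsv", sep="\t")["locus"].tolist()
    panel = cohort.subset_loci(keep)

    stats = compute_locus_stats(panel, hwe_reps=20_000, seed=SEED)
    stats.to_csv(OUT / "locus_stats.tsv", sep="\t", index=False)
    summary = panel_metrics.summarize_panel(stats)
    (OUT / "panel_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n"
    )

    m = summary.means
    print(f"{summary.n_loci} loci; means: "
          f"Ho {round_report(m['ho'])}, He {round_report(m['he'])}, "
          f"PIC {round_report(m['pic'])}, PD {round_report(m['pd'])}, "
          f"PE {round_report(m['pe'])}")
    print(f"cumulative PM: {summary.cumulative_pm.sci()} "
          f"(log10 {summary.cumulative_pm.log10:.2f})")
    print(f"cumulative PD: {summary.cumulative_pd}")
    print(f"combined PE:   {summary.cumulative_pe}")
    print(f"wrote locus_stats.tsv, panel_summary.json to {OUT}")


if __name__ == "__main__":
    main()
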