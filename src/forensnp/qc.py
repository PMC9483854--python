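"""Amplicon MPS sequencing-performance metrics: DoC, ACR, NL.

* DoC (depth of coverage): total reads per call, summarised per locus as
  mean +/- population standard deviation across samples.
* ACR (allele coverage ratio): for each heterozygous call with both allele
  counts positive, the lower of the two genotype-allele read counts over
  the higher; locus value is the mean over such calls.  Calls where one
  genotype allele received zero reads are excluded and counted as
  dropouts.
* NL (noise level): per call, reads on alleles outside the called genotype
  (including off-target reads) divided by total reads; locus value is the
  mean over calls with positive depth.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, ReadCountTable, ValidationError


class MissingLocusError(ValidationError):
    """A locus required for a QC metric is absent from the count table."""


def _merged(counts: ReadCountTable, gm: GenotypeMatrix) -> pd.DataFrame:
    """Count rows annotated with the called genotype of each (sample, locus)."""
    geno_rows = []
    for j, locus in enumerate(gm.panel):
        for i, s in enumerate(gm.samples):
            a, b = gm.calls[i, j]
            if a < 0:
                continue
            geno_rows.append(
                (s, locus.id, locus.alleles[a], locus.alleles[b], a != b)
            )
    geno = pd.DataFrame(
        geno_rows, columns=["sample", "locus", "allele1", "allele2", "het"]
    )
    merged = counts.table.merge(geno, on=["sample", "locus"], how="inner")
    merged["in_genotype"] = (merged["allele"] == merged["allele1"]) | (
        merged["allele"] == merged["allele2"]
    )
    return merged


def doc_per_locus(
    counts: ReadCountTable, panel_ids: list[str] | None = None
) -> pd.DataFrame:
    """Mean and population SD of total reads per sample at each locus."""
    totals = counts.totals()
    if panel_ids is not None:
        present = set(totals["locus"])
        absent = [l for l in panel_ids if l not in present]
        if absent:
            raise MissingLocusError(f"loci absent from count table: {absent}")
    out = (
        totals.groupby("locus", sort=False)["reads"]
        .agg(doc_mean="mean", doc_sd=lambda x: float(np.std(x)), n_samples="size")
        .reset_index()
    )
    out["low_coverage"] = out["doc_mean"] == 0
    return out


def acr_per_locus(counts: ReadCountTable, gm: GenotypeMatrix) -> pd.DataFrame:
    """Mean heterozygote allele coverage ratio (lower/higher reads) per locus."""
    merged = _merged(counts, gm)
    het = merged[merged["het"] & merged["in_genotype"]]
    rows = []
    for locus_id, grp in het.groupby("locus", sort=False):
        wide = grp.pivot_table(
            index="sample", columns="allele", values="reads", aggfunc="sum"
        )
        pair = wide.to_numpy(dtype=float)
        lo = np.nanmin(pair, axis=1)
        hi = np.nanmax(pair, axis=1)
        usable = lo > 0
        n_dropout = int(np.sum(~usable))
        if not np.any(usable):
            warnings.warn(
                f"locus {locus_id}: no heterozygote with both alleles covered",
                stacklevel=2,
            )
            acr = np.nan
        else:
            acr = float(np.mean(lo[usable] / hi[usable]))
        rows.append((locus_id, acr, int(usable.sum()), n_dropout))
    return pd.DataFrame(
        rows, columns=["locus", "acr_mean", "n_het_calls", "n_dropouts"]
    )


def nl_per_locus(counts: ReadCountTable, gm: GenotypeMatrix) -> pd.DataFrame:
    """Mean off-genotype read fraction per locus."""
    merged = _merged(counts, gm)
    merged["geno"] = merged["reads"].where(merged["in_genotype"], 0)
    per_call = (
        merged.groupby(["sample", "locus"], sort=False)[["reads", "geno"]]
        .sum()
        .rename(columns={"reads": "total"})
        .reset_index()
    )
    nonzero = per_call[per_call["total"] > 0].copy()
    n_skipped = len(per_call) - len(nonzero)
    nonzero["nl"] = 1.0 - nonzero["geno"] / nonzero["total"]
    out = (
        nonzero.groupby("locus", sort=False)["nl"]
        .agg(nl_mean="mean", n_calls="size")
        .reset_index()
    )
    out.attrs["n_zero_depth_calls"] = n_skipped
    return out


def qc_summary(
    counts: ReadCountTable,
    gm: GenotypeMatrix,
    doc_floor: float = 20.0,
    acr_floor: float = 0.66,
) -> dict:
    """Panel-level QC report.

    Returns panel means of DoC/ACR/NL, the calls whose total depth falls
    below ``doc_floor`` (forensic casework threshold, default 20x) and the
    loci whose mean ACR falls below ``acr_floor`` (default 0.66, a
    commonly cited heterozygote-balance reference value).
    """
    doc = doc_per_locus(counts, gm.panel.ids)
    acr = acr_per_locus(counts, gm)
    nl = nl_per_locus(counts, gm)
    totals = counts.totals()
    low_depth = totals[totals["reads"] < doc_floor]
    low_acr = acr[acr["acr_mean"] < acr_floor]
    return {
        "doc_mean": float(doc["doc_mean"].mean()),
        "acr_mean": float(acr["acr_mean"].mean(skipna=True)),
        "nl_mean": float(nl["nl_mean"].mean()),
        "n_low_depth_calls": int(len(low_depth)),
        "low_depth_calls": low_depth[["sample", "locus"]].to_dict("records"),
        "low_acr_loci": low_acr["locus"].tolist(),
        "per_locus": {
            "doc": doc,
            "acr": acr,
            "nl": nl,
        },
    }
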