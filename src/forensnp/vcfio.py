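"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as VCF v4.2 (GT only, contigs declared, 1-based
positions); allele-frequency panels and per-allele read counts travel as
UTF-8 tab-separated tables.  Phase in GT fields is ignored on input —
every downstream statistic treats genotypes as unordered allele pairs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .types import (
    MISSING,
    FrequencyPanel,
    GenotypeMatrix,
    Locus,
    ReadCountTable,
    ValidationError,
)

CONTIG_LENGTH = 260_000_000


class FormatError(ValidationError):
    """Malformed input file."""


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a genotype matrix as VCF v4.2.

    Records are emitted in (chromosome, position) order; REF is the
    panel's first allele at each locus.  Phase is not written (``/``).
    """
    panel = matrix.panel.sorted_by_position()
    order = [matrix.panel.index_of(l.id) for l in panel]
    header = pysam.VariantHeader()
    header.add_meta("source", "forensnp")
    for c in sorted({l.chrom for l in panel}, key=lambda s: (len(s), s)):
        header.contigs.add(c, length=CONTIG_LENGTH)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, locus in zip(order, panel):
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,  # pysam is 0-based internally
                alleles=tuple(locus.alleles)
                if locus.n_alleles > 1
                else (locus.alleles[0], "."),
                id=locus.id,
            )
            for i, s in enumerate(matrix.samples):
                a, b = matrix.calls[i, j]
                if a == MISSING or b == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (int(a), int(b))
                rec.samples[s].phased = False
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a genotype matrix.

    ``./.`` becomes a missing call; phased and unphased separators are
    treated identically; multi-allelic ALT lists are supported.  Panel
    allele frequencies are estimated from the calls themselves (uniform
    for all-missing loci).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alleles = tuple(a for a in rec.alleles if a != ".")
            if not alleles:
                raise FormatError(f"record {rec.id or rec.pos}: no alleles")
            col = np.full((len(samples), 2), MISSING, dtype=np.int16)
            for i, s in enumerate(samples):
                if "GT" not in rec.samples[s]:
                    raise FormatError(
                        f"sample {s}, locus {rec.id or rec.pos}: no GT field"
                    )
                gt = rec.samples[s]["GT"]
                if gt is None or all(a is None for a in gt):
                    continue
                if len(gt) != 2 or any(a is None for a in gt):
                    raise FormatError(
                        f"sample {s}, locus {rec.id or rec.pos}: "
                        f"non-diploid genotype {gt}"
                    )
                col[i] = sorted(gt)
            called = col[col[:, 0] != MISSING]
            if called.size:
                counts = np.bincount(called.reshape(-1), minlength=len(alleles))
                freqs = counts / counts.sum()
            else:
                freqs = np.full(len(alleles), 1.0 / len(alleles))
            loci.append(
                Locus(
                    id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    alleles=alleles,
                    freqs=freqs,
                )
            )
            columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0, 2), dtype=np.int16)
    )
    return GenotypeMatrix(samples, FrequencyPanel(loci), calls)


# ---------------------------------------------------------------------------
# TSV tables

FREQ_COLUMNS = ["locus", "chromosome", "position", "allele", "frequency"]


def write_frequency_table(panel: FrequencyPanel, path: str | os.PathLike) -> None:
    rows = []
    for locus in panel:
        for a, f in zip(locus.alleles, locus.freqs):
            rows.append((locus.id, locus.chrom, locus.pos, a, repr(float(f))))
    pd.DataFrame(rows, columns=FREQ_COLUMNS).to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str | os.PathLike) -> FrequencyPanel:
    """Read a long-format allele-frequency TSV into a panel.

    Per-locus frequencies are renormalised only when their sum deviates
    from 1 by less than 1e-6; larger deviations raise a validation error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"frequency table lacks columns {missing}")
    loci = []
    for locus_id, grp in df.groupby("locus", sort=False):
        freqs = grp["frequency"].to_numpy(dtype=float)
        if np.any(freqs < 0):
            raise FormatError(f"locus {locus_id}: negative frequency")
        total = freqs.sum()
        if abs(total - 1.0) > 1e-6:
            raise FormatError(
                f"locus {locus_id}: frequencies sum to {total:.8f}"
            )
        freqs = freqs / total
        loci.append(
            Locus(
                id=str(locus_id),
                chrom=str(grp["chromosome"].iloc[0]),
                pos=int(grp["position"].iloc[0]),
                alleles=tuple(grp["allele"].astype(str)),
                freqs=freqs,
            )
        )
    return FrequencyPanel(loci)


def write_read_counts(counts: ReadCountTable, path: str | os.PathLike) -> None:
    counts.table.to_csv(path, sep="\t", index=False)


def read_read_counts(path: str | os.PathLike) -> ReadCountTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ReadCountTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"read-count table lacks columns {missing}")
    if (df["reads"] < 0).any():
        raise FormatError("negative read counts")
    return ReadCountTable(df)
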