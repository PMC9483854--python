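"""Core containers shared by every pipeline stage.

The pipeline operates on three in-memory structures:

* :class:`FrequencyPanel` — the marker panel: per-locus coordinates, allele
  symbols and population allele frequencies.
* :class:`GenotypeMatrix` — samples × loci unordered diploid genotypes,
  stored as allele *indices* into the panel's allele lists (-1 = missing).
* :class:`ReadCountTable` — long-format per (sample, locus, allele) read
  counts from an amplicon MPS run, with ``*`` reserved for off-target reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved allele symbol for reads that map to the amplicon but to none of
#: the panel alleles.
OFFTARGET = "*"

MISSING = -1


class ValidationError(ValueError):
    """Raised when an input structure violates a container invariant."""


@dataclass(frozen=True)
class Locus:
    """One marker: identifier, genomic coordinate, alleles and frequencies.

    Coordinates are 1-based; ``alleles`` is an ordered list whose first
    element is treated as REF when the locus is written to VCF.
    """

    id: str
    chrom: str
    pos: int
    alleles: tuple[str, ...]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if len(self.alleles) != freqs.size:
            raise ValidationError(
                f"locus {self.id}: {len(self.alleles)} alleles but "
                f"{freqs.size} frequencies"
            )
        if freqs.size == 0:
            raise ValidationError(f"locus {self.id}: no alleles")
        if np.any(freqs < 0):
            raise ValidationError(f"locus {self.id}: negative frequency")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"locus {self.id}: frequencies sum to {freqs.sum():.12f}, not 1"
            )
        if self.pos < 1:
            raise ValidationError(f"locus {self.id}: position must be 1-based")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class FrequencyPanel:
    """Ordered collection of loci with unique (chromosome, position)."""

    loci: list[Locus]

    def __post_init__(self) -> None:
        coords = {(l.chrom, l.pos) for l in self.loci}
        if len(coords) != len(self.loci):
            raise ValidationError("duplicate (chromosome, position) in panel")
        ids = {l.id for l in self.loci}
        if len(ids) != len(self.loci):
            raise ValidationError("duplicate locus identifiers in panel")

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, i: int) -> Locus:
        return self.loci[i]

    @property
    def ids(self) -> list[str]:
        return [l.id for l in self.loci]

    def index_of(self, locus_id: str) -> int:
        for i, l in enumerate(self.loci):
            if l.id == locus_id:
                return i
        raise KeyError(locus_id)

    def subset(self, ids: list[str]) -> "FrequencyPanel":
        keep = set(ids)
        return FrequencyPanel([l for l in self.loci if l.id in keep])

    def sorted_by_position(self) -> "FrequencyPanel":
        def key(l: Locus):
            c = l.chrom.removeprefix("chr")
            return (int(c) if c.isdigit() else 99, c, l.pos)

        return FrequencyPanel(sorted(self.loci, key=key))


@dataclass
class GenotypeMatrix:
    """Unordered diploid genotypes for ``samples`` × ``panel.loci``.

    ``calls[i, j]`` is the sorted pair of allele indices of sample *i* at
    locus *j*; ``(-1, -1)`` marks a missing call.  Phase is never stored.
    """

    samples: list[str]
    panel: FrequencyPanel
    calls: np.ndarray  # (n_samples, n_loci, 2) int16

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.samples), len(self.panel), 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.panel)} loci"
            )
        for j, locus in enumerate(self.panel):
            col = self.calls[:, j, :]
            called = col[col != MISSING]
            if called.size and called.max() >= locus.n_alleles:
                raise ValidationError(
                    f"locus {locus.id}: allele index {called.max()} out of range"
                )
        # enforce unordered representation
        self.calls = np.sort(self.calls, axis=2)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.panel)

    def missing_mask(self) -> np.ndarray:
        """(n_samples, n_loci) boolean; True where the call is missing."""
        return np.any(self.calls == MISSING, axis=2)

    def het_mask(self) -> np.ndarray:
        """(n_samples, n_loci) boolean; True for heterozygous calls."""
        return (self.calls[:, :, 0] != self.calls[:, :, 1]) & ~self.missing_mask()

    def locus_calls(self, j: int) -> np.ndarray:
        """Non-missing calls at locus *j*, shape (n_typed, 2)."""
        col = self.calls[:, j, :]
        return col[~np.any(col == MISSING, axis=1)]

    def subset_loci(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.panel.index_of(i) for i in ids]
        return GenotypeMatrix(
            list(self.samples), self.panel.subset(ids), self.calls[:, idx, :]
        )

    def concat_samples(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if self.panel.ids != other.panel.ids:
            raise ValidationError("panels differ; cannot concatenate samples")
        return GenotypeMatrix(
            list(self.samples) + list(other.samples),
            self.panel,
            np.concatenate([self.calls, other.calls], axis=0),
        )


@dataclass
class ReadCountTable:
    """Long-format per-allele read counts: sample, locus, allele, reads."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample", "locus", "allele", "reads")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"read-count table lacks columns {missing}")
        if (self.table["reads"] < 0).any():
            raise ValidationError("negative read counts")
        self.table = self.table.reset_index(drop=True)

    def totals(self) -> pd.DataFrame:
        """Total reads (genotype alleles + off-target) per (sample, locus)."""
        return (
            self.table.groupby(["sample", "locus"], sort=False)["reads"]
            .sum()
            .reset_index()
        )

    def for_locus(self, locus_id: str) -> pd.DataFrame:
        return self.table[self.table["locus"] == locus_id]
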