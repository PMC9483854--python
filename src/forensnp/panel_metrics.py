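"""Panel-level cumulative forensic measures.

The headline numbers of a forensic identification panel are far below
float-decimal printing defaults (a 111-locus cumulative match probability is
~1e-51), so every product here is accumulated in log10 space and reported
both as a float (when representable) and in scientific "m.mmmE-ee" /
"1-m.mmE-ee" notation mirroring forensic reporting conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LogProduct:
    """A probability held as log10 with a display helper."""

    log10: float

    @property
    def value(self) -> float:
        return 10.0**self.log10

    def sci(self, digits: int = 3) -> str:
        if np.isinf(self.log10):
            return "0"
        exp = int(np.floor(self.log10))
        mant = 10.0 ** (self.log10 - exp)
        mant = round(mant, digits)
        if mant >= 10.0:  # rounding pushed the mantissa over a decade
            mant /= 10.0
            exp += 1
        return f"{mant:.{digits}f}E{exp:+d}"


@dataclass
class PanelSummary:
    """Cumulative and summary forensic measures for a marker panel."""

    n_loci: int
    cumulative_pm: LogProduct
    cumulative_pe_complement: LogProduct  # prod(1 - PE_i)
    means: dict[str, float] = field(default_factory=dict)
    minima: dict[str, tuple[str, float]] = field(default_factory=dict)
    maxima: dict[str, tuple[str, float]] = field(default_factory=dict)

    @property
    def cumulative_pd(self) -> str:
        return f"1-{self.cumulative_pm.sci()}"

    @property
    def cumulative_pe(self) -> str:
        return f"1-{self.cumulative_pe_complement.sci()}"

    def to_dict(self) -> dict:
        return {
            "n_loci": self.n_loci,
            "cumulative_pm": self.cumulative_pm.sci(),
            "cumulative_pm_log10": self.cumulative_pm.log10,
            "cumulative_pd": self.cumulative_pd,
            "cumulative_pe": self.cumulative_pe,
            "cumulative_pe_complement_log10": self.cumulative_pe_complement.log10,
            "means": self.means,
            "minima": self.minima,
            "maxima": self.maxima,
        }


def cumulative_pm(pm_values) -> LogProduct:
    """Cumulative match probability: product of per-locus PMs (log10 space)."""
    pm = np.asarray(list(pm_values), dtype=float)
    if np.any((pm < 0) | (pm > 1)):
        raise ValueError("PM values must lie in (0, 1]")
    if np.any(pm == 0):
        warnings.warn("PM of 0 encountered; cumulative PM is exactly 0", stacklevel=2)
        return LogProduct(-np.inf)
    return LogProduct(float(np.sum(np.log10(pm))))


def cumulative_pe(pe_values) -> LogProduct:
    """Combined power of exclusion, returned as the complement prod(1-PE_i).

    The combined PE itself is ``1 - complement``; keeping the complement in
    log10 space avoids underflow for panels where it is ~1e-12.
    """
    pe = np.asarray(list(pe_values), dtype=float)
    if np.any((pe < 0) | (pe >= 1)):
        raise ValueError("PE values must lie in [0, 1)")
    return LogProduct(float(np.sum(np.log10(1.0 - pe))))


def summarize_panel(stats: pd.DataFrame) -> PanelSummary:
    """Panel summary from a per-locus statistics table.

    Expects the columns produced by
    :func:`forensnp.locus_stats.compute_locus_stats` (locus, ho, he, pic,
    pm, pd, pe).  Means are reported at full precision; report rounding is
    left to the writer.
    """
    if len(stats) == 0:
        raise ValueError("need at least one locus")
    measures = ["ho", "he", "pic", "pm", "pd", "pe"]
    means = {m: float(stats[m].mean()) for m in measures}
    minima = {}
    maxima = {}
    for m in measures:
        i_min = int(stats[m].idxmin())
        i_max = int(stats[m].idxmax())
        minima[m] = (str(stats.loc[i_min, "locus"]), float(stats.loc[i_min, m]))
        maxima[m] = (str(stats.loc[i_max, "locus"]), float(stats.loc[i_max, m]))
    return PanelSummary(
        n_loci=len(stats),
        cumulative_pm=cumulative_pm(stats["pm"]),
        cumulative_pe_complement=cumulative_pe(stats["pe"]),
        means=means,
        minima=minima,
        maxima=maxima,
    )
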