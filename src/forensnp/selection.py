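"""Five-criterion individual-identification SNP screening.

Candidate loci are filtered, with a per-locus audit trail, by:

1. a user-supplied exclusion list (stands in for the disease-association
   database screen, which is a curation step rather than a computation),
2. frequency spectrum — bi-allelic allele frequencies inside a window
   (default [0.4, 0.6]); multi-allelic minor-allele frequency above a
   floor (default 0.01),
3. observed heterozygosity above a floor (default 0.4),
4. Hardy–Weinberg equilibrium at a Bonferroni-adjusted level over the loci
   entering the test,
5. pairwise genotypic linkage equilibrium at a Bonferroni-adjusted level
   over the pairs tested (the lower-Ho locus of a significant pair is
   dropped),
6. physical spacing — at most one locus per ``min_spacing`` window on a
   chromosome, resolved greedily left-to-right in favour of higher Ho.

Cheap deterministic filters run before the permutation tests, so the
multiple-testing burden matches the loci that actually reach each test.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locus_stats import (
    allele_frequencies,
    bonferroni_threshold,
    hwe_exact_test,
    ld_exact_test,
    observed_heterozygosity,
)
from .types import FrequencyPanel, GenotypeMatrix, ValidationError

CRITERIA = ["excluded", "frequency", "ho", "hwe", "ld", "spacing"]


@dataclass
class SelectionCriteria:
    """Thresholds of the screening pipeline."""

    hwe_alpha: float = 0.05  # Bonferroni-adjusted internally
    ld_alpha: float = 0.05  # Bonferroni-adjusted internally
    min_spacing: int = 10_000_000  # bp
    biallelic_freq_window: tuple[float, float] = (0.4, 0.6)
    multiallelic_min_maf: float = 0.01
    min_ho: float = 0.4
    exclusion_list: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        lo, hi = self.biallelic_freq_window
        if not 0 <= lo <= hi <= 1:
            raise ValidationError("biallelic_freq_window outside [0, 1]")
        if self.min_spacing <= 0:
            raise ValidationError("min_spacing must be positive")
        self.exclusion_list = frozenset(self.exclusion_list)


@dataclass
class SelectionResult:
    """Selected loci plus the per-locus audit trail."""

    selected: GenotypeMatrix
    audit: pd.DataFrame

    @property
    def selected_ids(self) -> list[str]:
        return self.selected.panel.ids


def _locus_seed(seed: int, *names: str) -> int:
    h = seed & 0x7FFFFFFF
    for name in sorted(names):
        h ^= zlib.crc32(name.encode())
    return h & 0x7FFFFFFF


def apply_selection(
    gm: GenotypeMatrix,
    criteria: SelectionCriteria,
    seed: int = 0,
    hwe_reps: int = 100_000,
    ld_reps: int = 10_000,
) -> SelectionResult:
    """Run the full screening pipeline over candidate loci.

    Permutation-test seeds derive from ``seed`` and the locus identifiers,
    so p-values do not depend on which other candidates are present and
    the filter is idempotent.
    """
    panel = gm.panel
    for locus in panel:
        if locus.pos < 1 or not locus.chrom:
            raise ValidationError(f"locus {locus.id}: missing coordinates")
    ids = panel.ids
    audit = pd.DataFrame(
        {"locus": ids, **{c: "-" for c in CRITERIA}},
    )
    audit["failing_value"] = np.nan
    audit = audit.set_index("locus")

    info: dict[str, dict] = {}
    for j, locus in enumerate(panel):
        calls = gm.locus_calls(j)
        info[locus.id] = {
            "freqs": allele_frequencies(calls, locus.n_alleles),
            "ho": observed_heterozygosity(calls),
            "calls": calls,
            "locus": locus,
            "j": j,
        }

    alive = list(ids)

    # 1. exclusion list
    for lid in list(alive):
        if lid in criteria.exclusion_list:
            audit.loc[lid, "excluded"] = "fail"
            alive.remove(lid)
        else:
            audit.loc[lid, "excluded"] = "pass"

    # 2. frequency window / MAF floor
    lo, hi = criteria.biallelic_freq_window
    for lid in list(alive):
        freqs = info[lid]["freqs"]
        observed = freqs[freqs > 0]
        if info[lid]["locus"].n_alleles == 2:
            ok = bool(np.all((freqs >= lo) & (freqs <= hi)))
            failing = float(freqs.min())
        else:
            maf = float(observed.min()) if observed.size > 1 else 0.0
            ok = maf > criteria.multiallelic_min_maf
            failing = maf
        if ok:
            audit.loc[lid, "frequency"] = "pass"
        else:
            audit.loc[lid, "frequency"] = "fail"
            audit.loc[lid, "failing_value"] = failing
            alive.remove(lid)

    # 3. observed heterozygosity floor
    for lid in list(alive):
        ho = info[lid]["ho"]
        if ho > criteria.min_ho:
            audit.loc[lid, "ho"] = "pass"
        else:
            audit.loc[lid, "ho"] = "fail"
            audit.loc[lid, "failing_value"] = ho
            alive.remove(lid)

    # 4. HWE at Bonferroni-adjusted alpha over the loci entering the test
    if alive:
        thr = bonferroni_threshold(criteria.hwe_alpha, len(alive))
        for lid in list(alive):
            p = hwe_exact_test(
                info[lid]["calls"],
                mc_reps=hwe_reps,
                seed=_locus_seed(seed, lid),
            )
            if p >= thr:
                audit.loc[lid, "hwe"] = "pass"
            else:
                audit.loc[lid, "hwe"] = "fail"
                audit.loc[lid, "failing_value"] = p
                alive.remove(lid)

    # 5. pairwise LD; drop the lower-Ho locus of each significant pair
    if len(alive) > 1:
        pairs = [
            (alive[i], alive[j])
            for i in range(len(alive))
            for j in range(i + 1, len(alive))
        ]
        thr = bonferroni_threshold(criteria.ld_alpha, len(pairs))
        # any pair reaching this many exceedances cannot be significant at thr
        stop_hits = max(10, int(np.ceil(thr * (ld_reps + 1))) + 1)
        dropped: set[str] = set()
        for lid in alive:
            audit.loc[lid, "ld"] = "pass"
        for l1, l2 in pairs:
            if l1 in dropped or l2 in dropped:
                continue
            p = ld_exact_test(
                info[l1]["calls"],
                info[l2]["calls"],
                mc_reps=ld_reps,
                seed=_locus_seed(seed, l1, l2),
                early_stop_hits=stop_hits,
            )
            if p < thr:
                victim = min(
                    (l1, l2),
                    key=lambda lid: (info[lid]["ho"], -info[lid]["locus"].pos),
                )
                audit.loc[victim, "ld"] = "fail"
                audit.loc[victim, "failing_value"] = p
                dropped.add(victim)
        alive = [lid for lid in alive if lid not in dropped]

    # 6. spacing, greedy left-to-right per chromosome, keep higher Ho
    for lid in alive:
        audit.loc[lid, "spacing"] = "pass"
    by_chrom: dict[str, list[str]] = {}
    for lid in alive:
        by_chrom.setdefault(info[lid]["locus"].chrom, []).append(lid)
    survivors: set[str] = set()
    for chrom, lids in by_chrom.items():
        lids = sorted(lids, key=lambda l: info[l]["locus"].pos)
        kept: list[str] = []
        for lid in lids:
            alive_here = True
            while kept and alive_here:
                prev = kept[-1]
                gap = info[lid]["locus"].pos - info[prev]["locus"].pos
                if gap >= criteria.min_spacing:
                    break
                # drop the lower-Ho locus; ties favour the earlier position
                if info[lid]["ho"] > info[prev]["ho"]:
                    audit.loc[prev, "spacing"] = "fail"
                    audit.loc[prev, "failing_value"] = gap
                    kept.pop()  # re-check the newcomer against earlier keeps
                else:
                    audit.loc[lid, "spacing"] = "fail"
                    audit.loc[lid, "failing_value"] = gap
                    alive_here = False
            if alive_here:
                kept.append(lid)
        survivors.update(kept)
    alive = [lid for lid in alive if lid in survivors]

    audit["selected"] = [lid in alive for lid in ids]
    selected = (
        gm.subset_loci(alive)
        if alive
        else GenotypeMatrix(
            list(gm.samples),
            FrequencyPanel([]),
            np.empty((gm.n_samples, 0, 2), dtype=np.int16),
        )
    )
    return SelectionResult(selected, audit.reset_index())
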