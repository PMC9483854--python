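"""Between-population comparison: Nei's DA, Weir–Cockerham FST, NJ, PCA.

* ``nei_da`` — Nei et al.'s DA distance, 1 - mean over loci of the sum of
  sqrt(x_a * y_a) over the union of the two populations' alleles.
* ``weir_cockerham_fst`` — the genotype-based theta estimator with variance
  components summed over loci and alleles (ratio of sums); negative
  estimates are reported as computed.
* ``nj_tree`` — Saitou–Nei neighbor joining with deterministic label-order
  tie-breaking; negative branch lengths are clamped to zero with the
  deficit transferred to the sibling edge, and the tree is emitted as
  Newick rooted at the last join.
* ``pca_individuals`` — individual-level PCA on centred allele-dosage
  columns (one allele per locus dropped to remove frequency closure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .locus_stats import allele_frequencies
from .types import FrequencyPanel, GenotypeMatrix, ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix over labelled populations."""

    labels: list[str]
    matrix: np.ndarray = field(repr=False)
    metric: str = "DA"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape inconsistent with labels")
        if np.any(np.abs(np.diag(m)) > 1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(np.abs(m - m.T) > 1e-12):
            raise ValidationError("distance matrix must be symmetric")
        self.matrix = (m + m.T) / 2.0


def population_frequencies(gm: GenotypeMatrix) -> FrequencyPanel:
    """Panel with allele frequencies estimated from a genotype matrix."""
    from .types import Locus

    loci = []
    for j, locus in enumerate(gm.panel):
        freqs = allele_frequencies(gm.locus_calls(j), locus.n_alleles)
        loci.append(Locus(locus.id, locus.chrom, locus.pos, locus.alleles, freqs))
    return FrequencyPanel(loci)


def nei_da(freqs_x: FrequencyPanel, freqs_y: FrequencyPanel) -> float:
    """Nei's DA distance between two populations' allele-frequency tables."""
    by_id_y = {l.id: l for l in freqs_y}
    shared = [l for l in freqs_x if l.id in by_id_y]
    if not shared:
        raise ValidationError("no shared loci between the frequency tables")
    total = 0.0
    for lx in shared:
        ly = by_id_y[lx.id]
        alleles = list(dict.fromkeys(list(lx.alleles) + list(ly.alleles)))
        x = np.array([lx.freqs[lx.alleles.index(a)] if a in lx.alleles else 0.0
                      for a in alleles])
        y = np.array([ly.freqs[ly.alleles.index(a)] if a in ly.alleles else 0.0
                      for a in alleles])
        total += float(np.sum(np.sqrt(x * y)))
    return 1.0 - total / len(shared)


def _locus_components(
    matrices: list[GenotypeMatrix], j: int
) -> tuple[float, float, float]:
    """Weir–Cockerham variance components (a, b, c) for locus *j*, summed
    over alleles."""
    per_pop = []
    k = matrices[0].panel[j].n_alleles
    for gm in matrices:
        calls = gm.calls[:, j, :]
        calls = calls[~np.any(calls < 0, axis=1)]
        if calls.shape[0] == 0:
            continue
        n_i = calls.shape[0]
        p_i = np.bincount(calls.reshape(-1), minlength=k) / (2 * n_i)
        het = calls[:, 0] != calls[:, 1]
        h_i = np.zeros(k)
        for a in range(k):
            h_i[a] = np.mean(het & np.any(calls == a, axis=1))
        per_pop.append((n_i, p_i, h_i))
    r = len(per_pop)
    if r < 2:
        return 0.0, 0.0, 0.0
    n = np.array([x[0] for x in per_pop], dtype=float)
    p = np.stack([x[1] for x in per_pop])  # (r, k)
    h = np.stack([x[2] for x in per_pop])
    nbar = n.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for al in range(k):
        pbar = float(np.sum(n * p[:, al]) / (r * nbar))
        if pbar == 0.0 or pbar == 1.0:
            continue
        s2 = float(np.sum(n * (p[:, al] - pbar) ** 2) / ((r - 1) * nbar))
        hbar = float(np.sum(n * h[:, al]) / (r * nbar))
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a_sum += (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1))
        b_sum += (nbar / (nbar - 1)) * (
            inner - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c_sum += hbar / 2.0
    return a_sum, b_sum, c_sum


def weir_cockerham_fst(matrices: list[GenotypeMatrix]) -> float:
    """Multi-allelic Weir–Cockerham theta over two or more populations.

    Variance components are summed over loci and alleles before the ratio
    is taken; loci monomorphic across all populations contribute nothing.
    """
    if len(matrices) < 2:
        raise ValidationError("need at least two populations")
    ids = matrices[0].panel.ids
    for gm in matrices[1:]:
        if gm.panel.ids != ids:
            raise ValidationError("populations must share the same loci")
    for gm in matrices:
        if gm.n_samples < 2:
            raise ValidationError("each population needs >= 2 individuals")
    a_tot = denom = 0.0
    for j in range(len(ids)):
        a, b, c = _locus_components(matrices, j)
        a_tot += a
        denom += a + b + c
    if denom == 0.0:
        raise ValidationError("no polymorphic loci; FST undefined")
    return a_tot / denom


def pairwise_fst(geno_x: GenotypeMatrix, geno_y: GenotypeMatrix) -> float:
    """Weir–Cockerham theta between two populations."""
    return weir_cockerham_fst([geno_x, geno_y])


def distance_matrix_da(pops: dict[str, FrequencyPanel]) -> DistanceMatrix:
    """All-pairs Nei DA matrix from per-population frequency tables."""
    labels = list(pops)
    m = np.zeros((len(labels), len(labels)))
    for i, x in enumerate(labels):
        for j2 in range(i + 1, len(labels)):
            d = nei_da(pops[x], pops[labels[j2]])
            m[i, j2] = m[j2, i] = d
    return DistanceMatrix(labels, m, "DA")


def distance_matrix_fst(pops: dict[str, GenotypeMatrix]) -> DistanceMatrix:
    """All-pairs Weir–Cockerham theta matrix from genotype matrices."""
    labels = list(pops)
    m = np.zeros((len(labels), len(labels)))
    for i, x in enumerate(labels):
        for j2 in range(i + 1, len(labels)):
            d = pairwise_fst(pops[x], pops[labels[j2]])
            m[i, j2] = m[j2, i] = d
    return DistanceMatrix(labels, m, "FST")


# ---------------------------------------------------------------------------
# Neighbor joining


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{child.newick()}:{bl:.10g}" for child, bl in self.children
        )
        return f"({inner})"

    def min_leaf(self) -> str:
        if not self.children:
            return self.label
        return min(c.min_leaf() for c, _ in self.children)


def nj_tree(dist: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns a Newick string with branch
    lengths, exact on additive matrices."""
    n = len(dist.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 populations")
    d = dist.matrix.astype(float).copy()
    nodes: list[_Node] = [_Node(lbl) for lbl in dist.labels]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        best = None  # (Q, label_i, label_j, ai, aj)
        for ii in range(r):
            for jj in range(ii + 1, r):
                q = (r - 2) * sub[ii, jj] - R[ii] - R[jj]
                li = nodes[active[ii]].min_leaf()
                lj = nodes[active[jj]].min_leaf()
                key = (q, *sorted((li, lj)))
                if best is None or key < best[0]:
                    best = (key, ii, jj)
        _, ii, jj = best
        dij = sub[ii, jj]
        li = dij / 2.0 + (R[ii] - R[jj]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        u = _Node(None, [(nodes[active[ii]], li), (nodes[active[jj]], lj)])
        new_d = np.zeros(d.shape[0])
        for kk in range(r):
            if kk in (ii, jj):
                continue
            new_d[active[kk]] = (sub[ii, kk] + sub[jj, kk] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d
        d[:-1, -1] = new_d
        nodes.append(u)
        u_idx = d.shape[0] - 1
        active = [a for k2, a in enumerate(active) if k2 not in (ii, jj)]
        active.append(u_idx)

    # last join: attach the remaining three clusters to one root node with
    # the three-point formulas
    i, j, k = active
    la = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lb = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lc = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    root = _Node(
        None,
        [
            (nodes[i], max(la, 0.0)),
            (nodes[j], max(lb, 0.0)),
            (nodes[k], max(lc, 0.0)),
        ],
    )
    return root.newick() + ";"


# ---------------------------------------------------------------------------
# PCA


def pca_individuals(
    matrices: list[GenotypeMatrix], n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Individual-level PCA on allele dosages.

    Individuals from all populations are stacked; per locus, the dosage
    (0/1/2) of every allele but the last is used as a feature.  Columns are
    centred (constant columns dropped) and decomposed by SVD.  Returns the
    coordinates, the explained-variance fractions, and one population label
    per individual.
    """
    from sklearn.decomposition import PCA

    ids = matrices[0].panel.ids
    for gm in matrices[1:]:
        if gm.panel.ids != ids:
            raise ValidationError("populations must share the same loci")
    blocks = []
    labels: list[str] = []
    for p_idx, gm in enumerate(matrices):
        cols = []
        for j, locus in enumerate(gm.panel):
            calls = gm.calls[:, j, :]
            for a in range(locus.n_alleles - 1):
                dosage = np.sum(calls == a, axis=1).astype(float)
                dosage[np.any(calls < 0, axis=1)] = np.nan
                cols.append(dosage)
        blocks.append(np.column_stack(cols))
        labels.extend([f"pop{p_idx}"] * gm.n_samples)
    x = np.vstack(blocks)
    # mean-impute missing dosages so they are neutral after centring
    col_means = np.nanmean(x, axis=0)
    nan_idx = np.where(np.isnan(x))
    x[nan_idx] = np.take(col_means, nan_idx[1])
    keep = x.std(axis=0) > 0
    if not np.any(keep):
        raise ValidationError("all dosage columns constant; PCA undefined")
    x = x[:, keep]
    if x.shape[0] <= n_components:
        raise ValidationError("need more individuals than components")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    return coords, pca.explained_variance_ratio_, labels
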