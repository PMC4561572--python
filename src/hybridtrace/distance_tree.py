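"""Nei (1972) standard genetic distance, neighbor-joining, locus bootstrap.

The distance is D = -ln( Jxy / sqrt(Jx * Jy) ) with J-terms averaged
arithmetically across loci; populations missing a locus are handled by
pairwise locus deletion.  The NJ implementation is deterministic: Q-matrix
ties break to the lowest (row, col) index pair, and a negative branch
length is clamped to zero with the excess transferred to its sister branch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeDataset
from .popgen_stats import AlleleFrequencyTable, allele_frequencies

__all__ = [
    "PhyloTree",
    "nei_standard_distance",
    "nei_distance_matrix",
    "nj_tree",
    "bootstrap_support",
]


# ---------------------------------------------------------------------------
# Nei's standard distance
# ---------------------------------------------------------------------------

def nei_standard_distance(
    freqs: AlleleFrequencyTable, pop_a: str, pop_b: str, loci=None
) -> float:
    """Nei's standard D between two populations over a locus subset.

    Only loci scored in *both* populations enter the averages (pairwise
    deletion); no common scored locus is an error.  Disjoint allele sets
    at every common locus give D = +inf.
    """
    loci = list(freqs.loci if loci is None else loci)
    jxy = jx = jy = 0.0
    used = 0
    for locus in loci:
        if freqs.is_empty(pop_a, locus) or freqs.is_empty(pop_b, locus):
            continue
        pa = freqs.freq(pop_a, locus)
        pb = freqs.freq(pop_b, locus)
        jxy += sum(p * pb.get(a, 0.0) for a, p in pa.items())
        jx += sum(p * p for p in pa.values())
        jy += sum(p * p for p in pb.values())
        used += 1
    if used == 0:
        raise ValueError(f"no common scored locus between {pop_a!r} and {pop_b!r}")
    jxy, jx, jy = jxy / used, jx / used, jy / used
    if jxy == 0.0:
        return math.inf
    return max(0.0, -math.log(jxy / math.sqrt(jx * jy)))


def _identity_tensor(freqs: AlleleFrequencyTable, populations: list[str]):
    """Per-locus gene-identity matrices J[l, x, y] = sum_a pX(a) pY(a).

    NaN marks (locus, pair) cells where either population is unscored.
    """
    P, L = len(populations), len(freqs.loci)
    J = np.full((L, P, P), np.nan)
    for l, locus in enumerate(freqs.loci):
        vecs = []
        union = freqs.allele_union(locus, populations)
        index = {a: k for k, a in enumerate(union)}
        for pop in populations:
            if freqs.is_empty(pop, locus):
                vecs.append(None)
                continue
            v = np.zeros(len(union))
            for a, f in freqs.freq(pop, locus).items():
                v[index[a]] = f
            vecs.append(v)
        for x in range(P):
            if vecs[x] is None:
                continue
            for y in range(x, P):
                if vecs[y] is None:
                    continue
                J[l, x, y] = J[l, y, x] = float(vecs[x] @ vecs[y])
    return J


def _nei_from_identity(J: np.ndarray) -> np.ndarray:
    """Distance matrix from the per-locus identity tensor (loci subset
    already applied), honouring pairwise deletion."""
    valid = np.isfinite(J)  # (L, P, P)
    cnt = valid.sum(axis=0)
    if (np.diag(cnt) == 0).any():
        bad = int(np.argmin(np.diag(cnt)))
        raise ValueError(f"population index {bad} unscored at every resampled locus")
    with np.errstate(invalid="ignore", divide="ignore"):
        jbar_xy = np.nansum(J, axis=0) / cnt
    diag = np.einsum("lxx->lx", J)  # (L, P)
    # per-pair mean of each population's own identity over the pair's loci
    jbar_x = np.einsum("lx,lxy->xy", np.nan_to_num(diag), valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        jbar_x = jbar_x / cnt
    jbar_y = jbar_x.T
    if (cnt == 0).any():
        raise ValueError("a population pair shares no scored locus")
    with np.errstate(divide="ignore", invalid="ignore"):
        D = -np.log(jbar_xy / np.sqrt(jbar_x * jbar_y))
    D[jbar_xy == 0.0] = np.inf
    D = np.maximum(D, 0.0)
    np.fill_diagonal(D, 0.0)
    return D


def nei_distance_matrix(
    freqs: AlleleFrequencyTable, populations: list[str] | None = None, loci=None
) -> tuple[list[str], np.ndarray]:
    """All-pairs Nei D. Returns (labels, symmetric matrix)."""
    pops = list(freqs.populations if populations is None else populations)
    J = _identity_tensor(freqs, pops)
    if loci is not None:
        idx = [freqs.loci.index(l) for l in loci]
        J = J[idx]
    return pops, _nei_from_identity(J)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    name: str | None = None
    length: float = 0.0
    children: list = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree over population labels (rooted representation at a
    trifurcating internal node). ``supports`` maps canonical bipartitions
    (frozenset of the side not containing the reference leaf) to bootstrap
    support in [0, 1]."""

    root: _Node
    labels: list[str]
    supports: dict[frozenset, float] | None = None
    n_bootstrap_dropped: int = 0

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the canonical frozenset of leaf
        names on the side away from the reference (first) leaf."""
        all_leaves = set(self.labels)
        ref = sorted(all_leaves)[0]
        out: set[frozenset] = set()
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            side = set(node.leaves())
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset(side))
        return out

    def to_newick(self, include_support: bool = True) -> str:
        all_leaves = set(self.labels)
        ref = sorted(all_leaves)[0]

        def fmt(node: _Node) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and self.supports is not None:
                side = set(node.leaves())
                key = frozenset(all_leaves - side if ref in side else side)
                if key in self.supports:
                    label = f"{self.supports[key]:.3f}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def nj_tree(labels: list[str], dm: np.ndarray) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Requires >= 3 populations and finite entries; infinite distances must
    be resolved upstream (pairwise locus deletion).  Deterministic: ties in
    the Q criterion resolve to the lowest (row, col) pair; the final three
    branches solve the three-point formulas, clamped at zero.
    """
    dm = np.asarray(dm, dtype=float)
    n = len(labels)
    if dm.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dm, dm.T, equal_nan=True):
        raise ValueError("distance matrix is not symmetric")
    if not np.isfinite(dm).all():
        raise ValueError(
            "infinite distance entries: exclude unscored loci pairwise before NJ"
        )
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 populations")

    nodes = [_Node(name=lab) for lab in labels]
    d = dm.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qq = np.full((m, m), np.inf)
        qq[iu] = q[iu]
        i, j = np.unravel_index(int(np.argmin(qq)), qq.shape)  # lowest (row,col) on ties
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            li, lj = 0.0, d[i, j]
        elif lj < 0:
            li, lj = d[i, j], 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        new = _Node(children=[ni, nj_])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = np.maximum(dk[keep], 0.0)
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        d = d2

    # final trifurcation: three-point formulas
    a, b, c = nodes
    la = max(0.0, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    lb = max(0.0, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    lc = max(0.0, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    a.length, b.length, c.length = la, lb, lc
    root = _Node(children=[a, b, c])
    return PhyloTree(root=root, labels=list(labels))


def bootstrap_support(
    dataset: GenotypeDataset,
    grouping: str = "site_species",
    n_reps: int = 1000,
    seed: int | None = None,
    loci: list[str] | None = None,
) -> PhyloTree:
    """NJ tree with bipartition supports from a loci-resampling bootstrap.

    Each replicate resamples loci with replacement, recomputes Nei
    distances and the NJ tree; support is the fraction of completed
    replicates containing each original-tree bipartition.  Replicates
    yielding an unusable distance matrix (e.g. an infinite entry) are
    dropped and counted; >1% dropped raises a warning.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    freqs = allele_frequencies(dataset, grouping=grouping)
    pops = list(freqs.populations)
    locus_list = list(freqs.loci if loci is None else loci)
    J = _identity_tensor(freqs, pops)
    idx_all = np.array([freqs.loci.index(l) for l in locus_list])

    base = nj_tree(pops, _nei_from_identity(J[idx_all]))
    target = base.bipartitions()
    hits = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    dropped = 0
    completed = 0
    for _ in range(n_reps):
        pick = rng.choice(idx_all, size=len(idx_all), replace=True)
        try:
            D = _nei_from_identity(J[pick])
            if not np.isfinite(D).all():
                raise ValueError("infinite distance in replicate")
            rep = nj_tree(pops, D)
        except ValueError:
            dropped += 1
            continue
        completed += 1
        rep_bps = rep.bipartitions()
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
    if completed == 0:
        raise ValueError("every bootstrap replicate was dropped")
    if dropped > 0.01 * n_reps:
        warnings.warn(f"{dropped}/{n_reps} bootstrap replicates dropped")
    base.supports = {bp: hits[bp] / completed for bp in target}
    base.n_bootstrap_dropped = dropped
    return base
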