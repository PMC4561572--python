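"""Supervised genotype-class classification and hybridization/migration rates.

Each sampled fly is assigned posterior probabilities over five ancestry
classes relative to its natal host taxon:

====================  =====================================================
pure_natal            both gametes from the natal taxon's gene pool
pure_non_natal        both gametes from the other taxon (a migrant genotype)
f1                    one gamete from each taxon (first-generation hybrid)
backcross_natal       F1 x pure natal (one natal gamete, one mixed gamete)
backcross_non_natal   F1 x pure non-natal
====================  =====================================================

Reference allele frequencies for the two taxa come from the sampled
populations themselves (per sympatric site pair by default, poolable),
Dirichlet-smoothed over the union allele set so every observed allele has
strictly positive probability in both gene pools.  This is a fixed-
frequency empirical-Bayes classifier: per-locus class likelihoods are
multiplied across scored loci (log domain) and combined with a migration
prior nu, P(pure_natal) = 1 - nu and nu/4 for each remaining class.

Per-generation rates follow from the class calls in a host sample S:
hybridization rate = #F1 / |S|; migration into S's taxon =
(#pure_non_natal + #F1 / 2) / |S|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

CLASSES = ("pure_natal", "pure_non_natal", "f1", "backcross_natal", "backcross_non_natal")

__all__ = ["CLASSES", "AncestryClassModel", "class_genotype_probability",
           "classify", "estimate_rates"]


def _gametes(cls: str, pa: dict, pb: dict) -> tuple[dict, dict]:
    mix = {a: 0.5 * (pa.get(a, 0.0) + pb.get(a, 0.0)) for a in set(pa) | set(pb)}
    return {
        "pure_natal": (pa, pa),
        "pure_non_natal": (pb, pb),
        "f1": (pa, pb),
        "backcross_natal": (pa, mix),
        "backcross_non_natal": (pb, mix),
    }[cls]


def class_genotype_probability(
    genotype: tuple[int, int], pa: dict, pb: dict, cls: str
) -> float:
    """Probability of an unordered diploid genotype under an ancestry class.

    ``pa`` is the natal-taxon and ``pb`` the non-natal-taxon allele
    frequency map at the locus, both strictly positive on the union allele
    set (Dirichlet smoothing applied upstream).  For gamete distributions
    q1, q2 and alleles x != y the genotype probability is
    q1(x)q2(y) + q1(y)q2(x); for x == y it is q1(x)q2(x).
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    x, y = genotype
    union = set(pa) | set(pb)
    if x not in union or y not in union:
        raise ValueError(
            f"allele {x if x not in union else y} absent from the union allele "
            "set: smoothing was not applied upstream"
        )
    q1, q2 = _gametes(cls, pa, pb)
    if x == y:
        return q1.get(x, 0.0) * q2.get(x, 0.0)
    return q1.get(x, 0.0) * q2.get(y, 0.0) + q1.get(y, 0.0) * q2.get(x, 0.0)


@dataclass
class AncestryClassModel:
    """Reference frequencies and prior for the five-class model.

    ``ref_counts`` maps (reference key, locus index) -> allele count dict,
    where a reference key is (pair id, species) or ("pooled", species).
    Smoothing happens at lookup over the per-locus union allele set.
    """

    ref_counts: dict
    unions: list[list[int]]  # per locus, sorted union allele set
    nu: float = 0.05
    lam: float | None = None  # None -> 1/K per locus

    def __post_init__(self) -> None:
        if not 0.0 < self.nu < 1.0:
            raise ValueError("migration prior nu must be in (0, 1)")

    def priors(self) -> np.ndarray:
        return np.array([1.0 - self.nu] + [self.nu / 4.0] * 4)

    def smoothed(self, key, locus_idx: int, minus: tuple[int, int] | None = None) -> dict:
        counts = dict(self.ref_counts.get((key, locus_idx), {}))
        if minus is not None and minus[0] != MISSING:
            for a in minus:
                counts[a] = counts.get(a, 0) - 1
                if counts[a] < 0:
                    raise ValueError("leave-one-out removed an allele not in the reference")
        union = self.unions[locus_idx]
        K = len(union)
        lam = (1.0 / K) if self.lam is None else self.lam
        n2 = sum(counts.values())
        denom = n2 + lam * K
        return {a: (counts.get(a, 0) + lam) / denom for a in union}


def _build_model(
    dataset: GenotypeDataset, nu: float, lam: float | None, pooled: bool
) -> tuple[AncestryClassModel, list[str]]:
    taxa = sorted(set(dataset.species_labels))
    if len(taxa) != 2:
        raise ValueError(f"classification needs exactly 2 taxa, got {taxa}")
    L = dataset.n_loci
    ref_counts: dict = {}
    for i in range(dataset.n_individuals):
        key = ("pooled" if pooled else dataset.pair_of(dataset.site_labels[i]),
               dataset.species_labels[i])
        for j in range(L):
            a1, a2 = dataset.calls[i, j]
            if a1 == MISSING:
                continue
            c = ref_counts.setdefault((key, j), {})
            c[int(a1)] = c.get(int(a1), 0) + 1
            c[int(a2)] = c.get(int(a2), 0) + 1
    unions = []
    for j in range(L):
        alleles = dataset.calls[:, j, :].reshape(-1)
        unions.append(sorted(int(a) for a in np.unique(alleles[alleles != MISSING])))
    return AncestryClassModel(ref_counts=ref_counts, unions=unions, nu=nu, lam=lam), taxa


def classify(
    dataset: GenotypeDataset,
    nu: float = 0.05,
    lam: float | None = None,
    pooled_references: bool = False,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Posterior ancestry-class probabilities for every individual.

    Returns a table with one row per individual: natal site/taxon, the five
    posteriors (summing to 1), the argmax class (ties resolve to the
    earliest class in ``CLASSES``, i.e. toward pure_natal), and locus
    counts.  Individuals missing every locus get NaN posteriors and
    assigned class ``"unclassified"``.

    With ``leave_one_out`` the individual's own alleles are removed from
    its natal reference counts before smoothing, removing the bias of an
    individual supporting its own assignment.
    """
    model, taxa = _build_model(dataset, nu, lam, pooled_references)
    other = {taxa[0]: taxa[1], taxa[1]: taxa[0]}
    priors = model.priors()
    log_priors = np.log(priors)

    rows = []
    for i, iid in enumerate(dataset.individuals):
        natal = dataset.species_labels[i]
        refkey = "pooled" if pooled_references else dataset.pair_of(dataset.site_labels[i])
        loglik = np.zeros(5)
        n_used = 0
        for j in range(dataset.n_loci):
            g = (int(dataset.calls[i, j, 0]), int(dataset.calls[i, j, 1]))
            if g[0] == MISSING:
                continue
            pa = model.smoothed((refkey, natal), j, minus=g if leave_one_out else None)
            pb = model.smoothed((refkey, other[natal]), j)
            for c, cls in enumerate(CLASSES):
                loglik[c] += np.log(class_genotype_probability(g, pa, pb, cls))
            n_used += 1
        if n_used == 0:
            rows.append([iid, dataset.site_labels[i], natal] + [np.nan] * 5
                        + ["unclassified", 0, dataset.n_loci])
            continue
        logpost = log_priors + loglik
        logpost -= logpost.max()
        post = np.exp(logpost)
        post /= post.sum()
        assigned = CLASSES[int(np.argmax(post))]  # first max -> pure_natal on ties
        rows.append([iid, dataset.site_labels[i], natal] + post.tolist()
                    + [assigned, n_used, dataset.n_loci - n_used])

    return pd.DataFrame(
        rows,
        columns=["individual", "site", "natal_taxon", *CLASSES,
                 "assigned", "n_loci_used", "n_loci_missing"],
    )


def estimate_rates(posteriors: pd.DataFrame) -> pd.DataFrame:
    """Per-generation hybridization and migration rates from class calls.

    For each natal-taxon sample S (classified individuals only):
    hybridization = #F1 / |S|; migration into S's taxon =
    (#pure_non_natal + #F1 / 2) / |S|.
    """
    df = posteriors[posteriors["assigned"] != "unclassified"]
    out = []
    for taxon, grp in df.groupby("natal_taxon", sort=True):
        n = len(grp)
        if n == 0:
            raise ValueError(f"empty classified sample for taxon {taxon!r}")
        n_f1 = int((grp["assigned"] == "f1").sum())
        n_mig = int((grp["assigned"] == "pure_non_natal").sum())
        n_bx = int(grp["assigned"].str.startswith("backcross").sum())
        out.append({
            "natal_taxon": taxon,
            "n": n,
            "n_f1": n_f1,
            "n_migrant": n_mig,
            "n_backcross": n_bx,
            "hybridization_rate": n_f1 / n,
            "migration_rate": (n_mig + 0.5 * n_f1) / n,
        })
    if not out:
        raise ValueError("no classified individuals")
    return pd.DataFrame(out)
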