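"""Allele frequencies, heterozygosity and inbreeding coefficients.

Frequencies are maximum-likelihood counts/(2n) by default; Dirichlet
smoothing over the union allele set of both taxa is available for the
genotype-class classifier, which needs strictly positive reference
frequencies.  The inbreeding coefficient is f = 1 - Ho/He with the
unbiased (2n/(2n-1)) expected-heterozygosity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

__all__ = [
    "AlleleFrequencyTable",
    "PopulationSummary",
    "allele_frequencies",
    "heterozygosity_and_f",
]


@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) allele -> frequency with sample sizes.

    ``counts`` holds the raw scored-allele counts (2 per genotyped diploid);
    ``freqs`` the (possibly smoothed) frequencies.  A (population, locus)
    cell with no scored individuals is *empty*: present in ``n_genotyped``
    with n = 0 and absent from ``freqs`` — it is never zero-filled.
    """

    populations: list[str]
    loci: list[str]
    counts: dict = field(repr=False)
    n_genotyped: dict = field(repr=False)
    freqs: dict = field(repr=False)
    smoothing: str = "none"

    def freq(self, pop: str, locus: str) -> dict[int, float]:
        key = (pop, locus)
        if key not in self.freqs:
            raise KeyError(f"no scored individuals for population {pop!r} at {locus!r}")
        return self.freqs[key]

    def is_empty(self, pop: str, locus: str) -> bool:
        return self.n_genotyped.get((pop, locus), 0) == 0

    def allele_union(self, locus: str, populations=None) -> list[int]:
        pops = self.populations if populations is None else populations
        out: set[int] = set()
        for p in pops:
            out.update(self.freqs.get((p, locus), {}))
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        """Long format: population, locus, allele, frequency, n."""
        rows = []
        for (pop, locus), f in self.freqs.items():
            n = self.n_genotyped[(pop, locus)]
            for allele, freq in sorted(f.items()):
                rows.append((pop, locus, allele, freq, n))
        return pd.DataFrame(rows, columns=["population", "locus", "allele", "frequency", "n"])


def _group_indices(dataset: GenotypeDataset, grouping: str) -> dict[str, np.ndarray]:
    labels = dataset.population_labels(grouping)
    out: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, []).append(i)
    return {k: np.asarray(v) for k, v in out.items()}


def allele_frequencies(
    dataset: GenotypeDataset,
    grouping: str = "site_species",
    smoothing: str = "none",
    lam: float | None = None,
) -> AlleleFrequencyTable:
    """Tabulate allele frequencies per population under a grouping.

    Parameters
    ----------
    grouping
        ``"site"``, ``"species"`` or ``"site_species"``.
    smoothing
        ``"none"`` -> ML frequencies count/(2n).  ``"dirichlet"`` ->
        posterior mean (count + lam)/(2n + lam*K) over the union allele set
        observed across *all* populations at the locus (so both taxa share
        one support); default lam = 1/K.
    """
    if smoothing not in ("none", "dirichlet"):
        raise ValueError(f"unknown smoothing {smoothing!r}")
    groups = _group_indices(dataset, grouping)
    loci = dataset.locus_names
    counts: dict = {}
    n_genotyped: dict = {}
    for pop, idx in groups.items():
        sub = dataset.calls[idx]  # (m, L, 2)
        for j, locus in enumerate(loci):
            alleles = sub[:, j, :].reshape(-1)
            alleles = alleles[alleles != MISSING]
            vals, cts = np.unique(alleles, return_counts=True)
            counts[(pop, locus)] = dict(zip(vals.tolist(), cts.tolist()))
            n_genotyped[(pop, locus)] = int(len(alleles) // 2)

    freqs: dict = {}
    for (pop, locus), c in counts.items():
        n2 = 2 * n_genotyped[(pop, locus)]
        if n2 == 0:
            continue  # empty cell, never zero-filled
        if smoothing == "none":
            freqs[(pop, locus)] = {a: k / n2 for a, k in c.items()}
        else:
            union = sorted(
                {a for (p2, l2), c2 in counts.items() if l2 == locus for a in c2}
            )
            K = len(union)
            l_ = (1.0 / K) if lam is None else float(lam)
            denom = n2 + l_ * K
            freqs[(pop, locus)] = {a: (c.get(a, 0) + l_) / denom for a in union}

    return AlleleFrequencyTable(
        populations=list(groups),
        loci=list(loci),
        counts=counts,
        n_genotyped=n_genotyped,
        freqs=freqs,
        smoothing=smoothing if smoothing == "none" else f"dirichlet({lam if lam is not None else '1/K'})",
    )


@dataclass
class PopulationSummary:
    """Ho, unbiased He and f per (population, locus), plus per-population
    mean and SD of f across the loci where f is defined (He > 0)."""

    per_locus: pd.DataFrame  # population, locus, n, Ho, He, f
    per_population: pd.DataFrame  # population, mean_f, sd_f, n_loci_defined


def heterozygosity_and_f(
    dataset: GenotypeDataset, grouping: str = "site_species"
) -> PopulationSummary:
    """Observed/expected heterozygosity and inbreeding coefficient.

    Ho = het count / n genotyped; He = (2n/(2n-1)) (1 - sum p^2);
    f = 1 - Ho/He, undefined (NaN) at monomorphic loci (He = 0) and
    excluded from the per-population mean.
    """
    groups = _group_indices(dataset, grouping)
    rows = []
    for pop, idx in groups.items():
        sub = dataset.calls[idx]
        for j, locus in enumerate(dataset.locus_names):
            g = sub[:, j, :]
            scored = g[:, 0] != MISSING
            n = int(scored.sum())
            if n == 0:
                rows.append((pop, locus, 0, np.nan, np.nan, np.nan))
                continue
            g = g[scored]
            ho = float((g[:, 0] != g[:, 1]).mean())
            alleles = g.reshape(-1)
            _, cts = np.unique(alleles, return_counts=True)
            p = cts / (2 * n)
            he_ml = 1.0 - float((p ** 2).sum())
            he = (2 * n / (2 * n - 1)) * he_ml if n > 0 and 2 * n > 1 else np.nan
            f = 1.0 - ho / he if he and he > 0 else np.nan
            rows.append((pop, locus, n, ho, he, f))
    per_locus = pd.DataFrame(rows, columns=["population", "locus", "n", "Ho", "He", "f"])
    agg = (
        per_locus.dropna(subset=["f"])
        .groupby("population")["f"]
        .agg(mean_f="mean", sd_f="std", n_loci_defined="count")
        .reindex(list(groups))
        .reset_index()
    )
    return PopulationSummary(per_locus=per_locus, per_population=agg)
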