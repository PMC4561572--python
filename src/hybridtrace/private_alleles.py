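"""Private-allele accounting between two taxa.

An allele is *private* to a taxon when it is observed (frequency > 0) in at
least one of that taxon's populations and in none of the other taxon's;
presence/absence only, no minimum-frequency filter.  The module also
tallies how many populations carry each allele (k = 1, 2, ...), flags
two-population alleles whose two carriers form a sympatric cross-taxon
pair, tests the private-allele split between taxa with a goodness-of-fit
chi-square, and computes null expectations for sympatric rare-allele
sharing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popgen_stats import AlleleFrequencyTable

__all__ = [
    "PrivateAlleleReport",
    "find_private_alleles",
    "private_proportion_chisq",
    "rare_shared_expectation",
]


def _default_taxon(pop: str) -> str:
    return pop.rsplit("_", 1)[1] if "_" in pop else pop


def _default_pair(pop: str) -> str:
    return pop.rsplit("_", 1)[0] if "_" in pop else pop


@dataclass
class PrivateAlleleReport:
    """Per allele x locus carrier lists with privacy flags and summaries."""

    records: pd.DataFrame       # locus, allele, k, carriers, status, sympatric_pair
    taxa: tuple[str, str]
    n_private: dict             # taxon -> count, plus "total"
    k_counts: dict              # k -> number of alleles carried by exactly k pops
    n_two_pop: int
    n_two_pop_sympatric_cross_taxon: int

    def summary(self) -> str:
        a, b = self.taxa
        lines = [
            f"total private alleles: {self.n_private['total']}",
            f"  private to {a}: {self.n_private[a]}",
            f"  private to {b}: {self.n_private[b]}",
            f"alleles in exactly 1 population: {self.k_counts.get(1, 0)}",
            f"alleles in exactly 2 populations: {self.n_two_pop}",
            f"  of which sympatric cross-taxon pairs: {self.n_two_pop_sympatric_cross_taxon}",
        ]
        return "\n".join(lines)


def find_private_alleles(
    freqs: AlleleFrequencyTable,
    taxon_of=None,
    pair_of=None,
) -> PrivateAlleleReport:
    """Classify every observed allele as private to one taxon or shared.

    ``taxon_of`` / ``pair_of`` map a population label to its taxon and
    paired-site id; by default the label is split as ``site_taxon`` on the
    last underscore.  Two populations form a sympatric cross-taxon pair
    when they share a pair id but differ in taxon.
    """
    taxon_of = taxon_of or _default_taxon
    pair_of = pair_of or _default_pair
    taxa = sorted({taxon_of(p) for p in freqs.populations})
    if len(taxa) != 2:
        raise ValueError(f"expected exactly 2 taxa, got {taxa}")

    rows = []
    k_counts: dict[int, int] = {}
    n_private = {taxa[0]: 0, taxa[1]: 0}
    n_two = n_two_symp = 0
    for locus in freqs.loci:
        carriers: dict[int, list[str]] = {}
        for pop in freqs.populations:
            if freqs.is_empty(pop, locus):
                continue
            for allele, f in freqs.freq(pop, locus).items():
                if f > 0:
                    carriers.setdefault(allele, []).append(pop)
        for allele in sorted(carriers):
            pops = carriers[allele]
            k = len(pops)
            k_counts[k] = k_counts.get(k, 0) + 1
            carrier_taxa = {taxon_of(p) for p in pops}
            if len(carrier_taxa) == 1:
                status = f"private_{carrier_taxa.pop()}"
                n_private[status.removeprefix("private_")] += 1
            else:
                status = "shared"
            sympatric = False
            if k == 2:
                n_two += 1
                p1, p2 = pops
                sympatric = (pair_of(p1) == pair_of(p2)
                             and taxon_of(p1) != taxon_of(p2))
                n_two_symp += sympatric
            rows.append((locus, allele, k, tuple(sorted(pops)), status, sympatric))

    records = pd.DataFrame(
        rows, columns=["locus", "allele", "k", "carriers", "status", "sympatric_pair"]
    )
    n_private["total"] = n_private[taxa[0]] + n_private[taxa[1]]
    return PrivateAlleleReport(
        records=records, taxa=(taxa[0], taxa[1]), n_private=n_private,
        k_counts=k_counts, n_two_pop=n_two,
        n_two_pop_sympatric_cross_taxon=n_two_symp,
    )


def private_proportion_chisq(count_a: int, count_b: int) -> dict:
    """Goodness-of-fit chi-square of a private-allele split against a 50:50
    expectation (df = 1, no continuity correction)."""
    if count_a < 0 or count_b < 0 or count_a + count_b == 0:
        raise ValueError("counts must be nonnegative and not both zero")
    res = stats.chisquare([count_a, count_b])
    return {"chi2": float(res.statistic), "df": 1, "p": float(res.pvalue)}


def rare_shared_expectation(
    n_two_pop_alleles: int,
    n_pops: int,
    n_sympatric_pairs: int,
    mode: str = "combinatorial",
    seed: int | None = None,
    reps: int = 100_000,
) -> float:
    """Null expected number of two-population alleles whose carriers form a
    sympatric cross-taxon pair, under random placement.

    Modes
    -----
    ``"combinatorial"``
        (n_sympatric_pairs / C(n_pops, 2)) * n_two_pop_alleles — each allele
        lands on a uniform unordered population pair.
    ``"paper"``
        n_sympatric_pairs / (n_pops * (n_pops - 1)) * n_two_pop_alleles —
        ordered-pair denominator; exactly half the combinatorial value.
    ``"montecarlo"``
        Simulate ``reps`` placements of the alleles on uniform unordered
        pairs and average the sympatric hit count.
    """
    if n_pops < 2 or n_sympatric_pairs < 0 or n_two_pop_alleles < 0:
        raise ValueError("invalid counts")
    if n_sympatric_pairs > n_pops // 2:
        raise ValueError("more sympatric pairs than disjoint pairs available")
    if mode == "paper":
        return n_sympatric_pairs / (n_pops * (n_pops - 1)) * n_two_pop_alleles
    if mode == "combinatorial":
        return n_sympatric_pairs / math.comb(n_pops, 2) * n_two_pop_alleles
    if mode == "montecarlo":
        rng = np.random.default_rng(seed)
        n_pairs = math.comb(n_pops, 2)
        # label the first n_sympatric_pairs pair-indices as sympatric: a
        # uniform draw over pair indices makes the identity of pairs moot
        draws = rng.integers(0, n_pairs, size=(reps, n_two_pop_alleles))
        hits = (draws < n_sympatric_pairs).sum(axis=1)
        return float(hits.mean())
    raise ValueError(f"unknown mode {mode!r}")
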