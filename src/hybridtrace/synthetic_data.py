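"""Two-taxon, multi-site microsatellite simulator.

Emulates the study design the analysis modules assume: two sibling taxa
sampled at nine paired (sympatric) sites along a geographic transect, 19
microsatellites on five linkage groups, strong divergence without fixed
differences, private alleles arising by sampling, an introgression cline
toward a focal site at a tunable subset of loci, and injected F1 /
migrant / backcross individuals at stated per-generation rates.

Divergence follows the Balding-Nichols model: per locus an ancestral
frequency vector p ~ Dirichlet(1, ..., 1) over a shared allele set, and
each taxon's frequencies ~ Dirichlet(p (1-F)/F) independently, so F is
interpretable as the between-taxon FST.  At introgressed loci the
taxon-A frequencies at site s are mixed toward taxon B with weight
alpha_s = alpha_max * exp(-d_s / lambda_km), d_s the great-circle distance
to the focal site.  Genotypes are drawn under Hardy-Weinberg from the
site x taxon frequencies; hybrid classes use the same gamete model as the
classifier (one gamete per parental pool, backcross gametes mixed 50:50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, Locus

__all__ = [
    "SimulationConfig", "SimFrequencies", "default_geography",
    "simulate_frequencies", "sample_dataset", "simulate_dataset", "realized_fst",
]

_TAXA = ("pom", "zeph")  # taxon A (cline recipient) and taxon B


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults are the emulated design itself."""

    n_loci: int = 19
    alleles_per_locus: int = 8
    divergence: float = 0.15            # Balding-Nichols F (between-taxon FST)
    n_sites: int = 9
    n_per_population: int = 30
    introgressed_locus_fraction: float = 7 / 19
    cline_alpha_max: float = 0.4        # mixing weight at the focal site
    cline_lambda_km: float = 150.0      # exponential decay length of the cline
    rate_f1: float = 0.0
    rate_migrant: float = 0.0
    rate_backcross: float = 0.0
    missing_rate: float = 0.02          # per-call missingness
    site_spacing_km: float = 40.0       # sites on a line; focal at one end
    symmetric_cline: bool = False       # also mix taxon B toward A
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence < 1.0:
            raise ValueError("divergence F must be in (0, 1)")
        if not 0.0 <= self.cline_alpha_max <= 1.0:
            raise ValueError("cline_alpha_max must be in [0, 1]")
        rates = (self.rate_f1, self.rate_migrant, self.rate_backcross)
        if any(r < 0 or r > 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("class rates must lie in [0, 1] and sum to < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def sites(self) -> list[str]:
        return [f"s{k + 1}" for k in range(self.n_sites)]

    @property
    def focal_site(self) -> str:
        return self.sites[-1]


def default_geography(config: SimulationConfig) -> pd.DataFrame:
    """Paired sites on an east-west line at the configured spacing, focal
    site at one end; both taxa share each site (pair = site)."""
    lat = 46.0
    km_per_deg_lon = 111.195 * math.cos(math.radians(lat))
    rows = []
    for k, s in enumerate(config.sites):
        rows.append({"site": s, "lat": lat,
                     "lon": -122.0 + k * config.site_spacing_km / km_per_deg_lon,
                     "pair": s, "species": "both"})
    return pd.DataFrame(rows).set_index("site", drop=False)


@dataclass
class SimFrequencies:
    """Generated frequencies plus the ground truth needed by recovery tests."""

    config: SimulationConfig
    allele_labels: np.ndarray    # (L, A) fragment lengths
    ancestral: np.ndarray        # (L, A)
    taxon_freqs: np.ndarray      # (2, L, A) base frequencies per taxon
    site_freqs: np.ndarray       # (S, 2, L, A) after cline mixing
    introgressed: np.ndarray     # (L,) bool
    alpha: np.ndarray            # (S,) mixing weight toward the other taxon
    distance_km: np.ndarray      # (S,) distance to the focal site
    loci: list[Locus] = field(default_factory=list)


def simulate_frequencies(
    config: SimulationConfig,
    geography: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> SimFrequencies:
    """Draw ancestral, taxon and site-level allele frequencies."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    geography = default_geography(config) if geography is None else geography
    L, A, S = config.n_loci, config.alleles_per_locus, config.n_sites
    F = config.divergence

    labels = np.empty((L, A), dtype=np.int64)
    for l in range(L):
        start = 100 + 20 * (l % 40)
        labels[l] = start + 2 * np.arange(A)

    ancestral = rng.dirichlet(np.ones(A), size=L)
    scale = (1.0 - F) / F
    taxon = np.empty((2, L, A))
    for t in range(2):
        for l in range(L):
            taxon[t, l] = rng.dirichlet(np.maximum(ancestral[l] * scale, 1e-9))

    n_intro = round(config.introgressed_locus_fraction * L)
    intro = np.zeros(L, dtype=bool)
    intro[rng.choice(L, size=n_intro, replace=False)] = True

    from .clinal_tests import geo_distance  # local import avoids a cycle at import time
    focal = geography.loc[config.focal_site]
    dist = np.array([
        geo_distance(geography.loc[s, "lat"], geography.loc[s, "lon"],
                     focal["lat"], focal["lon"])
        for s in config.sites
    ])
    alpha = config.cline_alpha_max * np.exp(-dist / config.cline_lambda_km)

    site = np.empty((S, 2, L, A))
    site[:, 0] = taxon[0]
    site[:, 1] = taxon[1]
    for s in range(S):
        a = alpha[s]
        site[s, 0, intro] = (1 - a) * taxon[0, intro] + a * taxon[1, intro]
        if config.symmetric_cline:
            site[s, 1, intro] = (1 - a) * taxon[1, intro] + a * taxon[0, intro]

    loci = [Locus(f"p{l + 1}", linkage_group=(l % 5) + 1) for l in range(L)]
    return SimFrequencies(
        config=config, allele_labels=labels, ancestral=ancestral,
        taxon_freqs=taxon, site_freqs=site, introgressed=intro,
        alpha=alpha, distance_km=dist, loci=loci,
    )


def _draw_gametes(freq: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """m haploid gametes from per-locus frequencies (L, A) -> (m, L) indices."""
    cum = np.cumsum(freq, axis=1)
    u = rng.random((m, freq.shape[0]))
    return np.minimum((u[:, :, None] > cum[None, :, :]).sum(axis=2),
                      freq.shape[1] - 1)


def sample_dataset(
    freqs: SimFrequencies,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Draw diploid genotypes for every site x taxon population.

    Each individual's true class is drawn from (pure, f1, migrant,
    backcross) at the configured rates; returns the dataset and a truth
    table (individual, site, natal taxon, true class).
    """
    config = freqs.config
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.n_loci
    class_names = ("pure_natal", "f1", "pure_non_natal", "backcross_natal")
    probs = np.array([
        1.0 - config.rate_f1 - config.rate_migrant - config.rate_backcross,
        config.rate_f1, config.rate_migrant, config.rate_backcross,
    ])

    individuals, sites_l, species_l, rows, truth = [], [], [], [], []
    for s_idx, site in enumerate(config.sites):
        for t_idx, taxon in enumerate(_TAXA):
            m = config.n_per_population
            own = freqs.site_freqs[s_idx, t_idx]
            other = freqs.site_freqs[s_idx, 1 - t_idx]
            mix = 0.5 * (own + other)
            classes = rng.choice(4, size=m, p=probs)
            g1 = np.empty((m, L), dtype=np.int64)
            g2 = np.empty((m, L), dtype=np.int64)
            for c, (f1_, f2_) in enumerate(
                [(own, own), (own, other), (other, other), (own, mix)]
            ):
                sel = classes == c
                k = int(sel.sum())
                if k == 0:
                    continue
                g1[sel] = _draw_gametes(f1_, k, rng)
                g2[sel] = _draw_gametes(f2_, k, rng)
            a1 = freqs.allele_labels[np.arange(L)[None, :], g1]
            a2 = freqs.allele_labels[np.arange(L)[None, :], g2]
            calls = np.stack([a1, a2], axis=2)
            if config.missing_rate > 0:
                miss = rng.random((m, L)) < config.missing_rate
                calls[miss] = 0
            for i in range(m):
                iid = f"{site}_{taxon}_{i + 1}"
                individuals.append(iid)
                sites_l.append(site)
                species_l.append(taxon)
                rows.append(calls[i])
                truth.append((iid, site, taxon, class_names[classes[i]]))

    dataset = GenotypeDataset(
        individuals=individuals, loci=list(freqs.loci),
        calls=np.stack(rows), site_labels=sites_l, species_labels=species_l,
    )
    truth_df = pd.DataFrame(truth, columns=["individual", "site", "natal_taxon",
                                            "true_class"])
    return dataset, truth_df


def simulate_dataset(
    config: SimulationConfig, geography: pd.DataFrame | None = None
) -> tuple[GenotypeDataset, pd.DataFrame, pd.DataFrame, SimFrequencies]:
    """One-call convenience: (dataset, truth, geography, frequencies)."""
    rng = np.random.default_rng(config.seed)
    geography = default_geography(config) if geography is None else geography
    freqs = simulate_frequencies(config, geography, rng)
    dataset, truth = sample_dataset(freqs, rng)
    return dataset, truth, geography, freqs


def realized_fst(taxon_freqs: np.ndarray) -> float:
    """Hudson-style FST between the two taxa, 1 - Hw/Hb with the H-terms
    averaged across loci (ratio of averages); taxon_freqs is (2, L, A)."""
    pa, pb = taxon_freqs[0], taxon_freqs[1]
    hw = 0.5 * ((1 - (pa ** 2).sum(axis=1)) + (1 - (pb ** 2).sum(axis=1)))
    hb = 1 - (pa * pb).sum(axis=1)
    return float(1.0 - hw.mean() / hb.mean())
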