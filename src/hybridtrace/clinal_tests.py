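"""Clinal-introgression tests: paired-site divergence, permutation-calibrated
regression toward a focal site, climate-covariate correlations, and
Mantel / partial Mantel tests.

The per-locus divergence between the two taxa at a paired site is the
total-variation distance between their allele-frequency vectors,
0.5 * sum_a |pA(a) - pB(a)|, bounded in [0, 1]; the site-level statistic is
its mean over the loci scored in both populations.  The cline statistic is
the Pearson r of that divergence on great-circle distance to a focal site,
calibrated by a one-tailed Monte Carlo null that randomly reassigns
individuals among sites *within* each taxon (per-site sample sizes
preserved) and asks how often a positive r at least as large arises by
chance: p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset
from .popgen_stats import allele_frequencies

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "freq_difference", "geo_distance", "PairedSiteDivergence",
    "paired_site_divergence", "cline_regression", "ClineTestResult",
    "permutation_pvalue", "covariate_correlation", "mantel", "partial_mantel",
]


def freq_difference(pa: dict, pb: dict) -> float:
    """Total-variation distance between two allele-frequency maps, in [0,1]."""
    union = set(pa) | set(pb)
    return 0.5 * sum(abs(pa.get(a, 0.0) - pb.get(a, 0.0)) for a in union)


def geo_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in km (decimal degrees in)."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = math.radians(lat2 - lat1), math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


# ---------------------------------------------------------------------------
# Paired-site divergence
# ---------------------------------------------------------------------------

@dataclass
class PairedSiteDivergence:
    """Per paired site: per-locus and mean taxon divergence, distance to the
    focal site, and optional climate covariates."""

    sites: list[str]
    per_locus: pd.DataFrame        # sites x loci, NaN where a locus is unscored
    mean: pd.Series                # mean over the scored loci at each site
    distance_km: pd.Series
    n_loci_scored: pd.Series
    covariates: pd.DataFrame | None = None


def _focal_coords(geography: pd.DataFrame, focal_site) -> tuple[float, float]:
    if isinstance(focal_site, str):
        if focal_site not in geography.index:
            raise KeyError(f"focal site {focal_site!r} not in geography table")
        row = geography.loc[focal_site]
        return float(row["lat"]), float(row["lon"])
    lat, lon = focal_site
    return float(lat), float(lon)


def paired_site_divergence(
    dataset: GenotypeDataset, geography: pd.DataFrame, focal_site
) -> PairedSiteDivergence:
    """Between-taxon divergence at every site where both taxa were sampled.

    ``focal_site`` is a site id in the geography table or a (lat, lon)
    tuple.  Loci unscored in either population at a site are excluded from
    that site's mean (their count is reported in ``n_loci_scored``).
    """
    taxa = sorted(set(dataset.species_labels))
    if len(taxa) != 2:
        raise ValueError(f"need exactly 2 taxa, got {taxa}")
    freqs = allele_frequencies(dataset, grouping="site_species")
    sites = [s for s in geography.index
             if all(f"{s}_{t}" in freqs.populations for t in taxa)]
    if not sites:
        raise ValueError("no site has both taxa sampled")
    flat, flon = _focal_coords(geography, focal_site)

    mat = np.full((len(sites), len(freqs.loci)), np.nan)
    for i, s in enumerate(sites):
        pa, pb = f"{s}_{taxa[0]}", f"{s}_{taxa[1]}"
        for j, locus in enumerate(freqs.loci):
            if freqs.is_empty(pa, locus) or freqs.is_empty(pb, locus):
                continue
            mat[i, j] = freq_difference(freqs.freq(pa, locus), freqs.freq(pb, locus))
    per_locus = pd.DataFrame(mat, index=sites, columns=freqs.loci)
    dist = pd.Series(
        [geo_distance(geography.loc[s, "lat"], geography.loc[s, "lon"], flat, flon)
         for s in sites], index=sites, name="distance_km")
    cov_cols = [c for c in ("precip_jul_oct", "tmax_jul", "tmin_jan")
                if c in geography.columns]
    covariates = geography.loc[sites, cov_cols] if cov_cols else None
    return PairedSiteDivergence(
        sites=sites,
        per_locus=per_locus,
        mean=per_locus.mean(axis=1, skipna=True).rename("mean_difference"),
        distance_km=dist,
        n_loci_scored=per_locus.notna().sum(axis=1).rename("n_loci"),
        covariates=covariates,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0 or len(x) < 3:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _masked_pearson_cols(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of x against each column of Y, ignoring NaN rows per column."""
    M = np.isfinite(Y)
    Y0 = np.where(M, Y, 0.0)
    n = M.sum(axis=0)
    sx = x @ M
    sy = Y0.sum(axis=0)
    sxx = (x ** 2) @ M
    syy = (Y0 ** 2).sum(axis=0)
    sxy = x @ Y0
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt((n * sxx - sx ** 2) * (n * syy - sy ** 2))
        r = num / den
    r[n < 3] = np.nan
    return r


def cline_regression(div: PairedSiteDivergence) -> tuple[float, pd.Series]:
    """Pearson r of divergence on distance-to-focal: overall and per locus.

    Zero variance in either variable gives NaN (reported missing).
    """
    if len(div.sites) < 3:
        raise ValueError("cline regression needs >= 3 paired sites")
    x = div.distance_km.to_numpy()
    overall = _pearson(x, div.mean.to_numpy())
    per_locus = pd.Series(
        _masked_pearson_cols(x, div.per_locus.to_numpy()),
        index=div.per_locus.columns, name="r",
    )
    return overall, per_locus


def covariate_correlation(div: PairedSiteDivergence, covariate: str) -> float:
    """Pearson r of the mean divergence on a climate covariate."""
    if div.covariates is None or covariate not in div.covariates.columns:
        raise KeyError(f"covariate {covariate!r} not present for these sites")
    return _pearson(div.covariates[covariate].to_numpy(), div.mean.to_numpy())


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

@dataclass
class ClineTestResult:
    """Observed cline r with one-tailed Monte Carlo p, per locus and overall."""

    table: pd.DataFrame  # locus, linkage_group, r, p
    overall_r: float
    overall_p: float
    n_perm: int
    seed: int | None


def _encode_counts(dataset: GenotypeDataset) -> np.ndarray:
    """Per-individual allele-dosage tensor (n, L, Amax); rows sum to 2 at
    scored loci and 0 at missing ones, so denominators fall out of sums."""
    n, L = dataset.n_individuals, dataset.n_loci
    maps = []
    for j in range(L):
        alleles = dataset.calls[:, j, :].reshape(-1)
        maps.append({int(a): k for k, a in
                     enumerate(np.unique(alleles[alleles != MISSING]))})
    amax = max((len(m) for m in maps), default=1)
    X = np.zeros((n, L, max(amax, 1)))
    for j, m in enumerate(maps):
        for i in range(n):
            a1, a2 = dataset.calls[i, j]
            if a1 == MISSING:
                continue
            X[i, j, m[int(a1)]] += 1
            X[i, j, m[int(a2)]] += 1
    return X


def _stats_from_counts(counts: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """counts: (2, S, L, A) allele-dosage sums; x: (S,) distances."""
    denom = counts.sum(axis=-1)  # (2, S, L)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = counts / denom[..., None]
    scored = (denom[0] > 0) & (denom[1] > 0)  # (S, L)
    diff = 0.5 * np.abs(f[0] - f[1]).sum(axis=-1)  # (S, L)
    diff = np.where(scored, diff, np.nan)
    with np.errstate(invalid="ignore"):
        mean_diff = np.nanmean(diff, axis=1)
    overall = _pearson(x, mean_diff)
    per_locus = _masked_pearson_cols(x, diff)
    return overall, per_locus


def permutation_pvalue(
    dataset: GenotypeDataset,
    geography: pd.DataFrame,
    focal_site,
    n_perm: int = 9999,
    seed: int | None = None,
) -> ClineTestResult:
    """One-tailed permutation test of the cline regression.

    Each of ``n_perm`` permutations randomly reassigns individuals among
    the paired sites within their own taxon (per-site sample sizes
    preserved), recomputes per-site frequencies, per-pair total-variation
    divergences and the Pearson r on distance-to-focal, and the p-value is
    (1 + #{r_perm >= r_obs}) / (1 + n_perm), per locus and for the
    across-loci mean.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    taxa = sorted(set(dataset.species_labels))
    if len(taxa) != 2:
        raise ValueError(f"need exactly 2 taxa, got {taxa}")
    sites = [s for s in geography.index
             if all(any(sl == s and sp == t for sl, sp in
                        zip(dataset.site_labels, dataset.species_labels))
                    for t in taxa)]
    if len(sites) < 3:
        raise ValueError("permutation test needs >= 3 paired sites with both taxa")
    site_rank = {s: k for k, s in enumerate(sites)}
    keep = [i for i in range(dataset.n_individuals)
            if dataset.site_labels[i] in site_rank]
    ds = dataset.subset(keep) if len(keep) < dataset.n_individuals else dataset

    # sort individuals by (taxon, site) so group sums are segment sums
    order = sorted(range(ds.n_individuals),
                   key=lambda i: (taxa.index(ds.species_labels[i]),
                                  site_rank[ds.site_labels[i]]))
    X = _encode_counts(ds)[order]
    n, L, A = X.shape
    X2 = X.reshape(n, L * A)
    group_keys = [(taxa.index(ds.species_labels[order[i]]),
                   site_rank[ds.site_labels[order[i]]]) for i in range(n)]
    starts, seen = [], None
    for i, k in enumerate(group_keys):
        if k != seen:
            starts.append(i)
            seen = k
    S = len(sites)
    assert len(starts) == 2 * S, "each taxon must be sampled at every paired site"
    starts = np.asarray(starts)
    n_a = sum(1 for k in group_keys if k[0] == 0)  # taxon-A block size

    flat, flon = _focal_coords(geography, focal_site)
    x = np.array([geo_distance(geography.loc[s, "lat"], geography.loc[s, "lon"],
                               flat, flon) for s in sites])

    def stat(Xp: np.ndarray) -> tuple[float, np.ndarray]:
        counts = np.add.reduceat(Xp, starts, axis=0).reshape(2, S, L, A)
        return _stats_from_counts(counts, x)

    obs_overall, obs_locus = stat(X2)
    rng = np.random.default_rng(seed)
    exceed_overall = 0
    exceed_locus = np.zeros(L)
    idx = np.arange(n)
    for _ in range(n_perm):
        perm = idx.copy()
        perm[:n_a] = rng.permutation(n_a)
        perm[n_a:] = n_a + rng.permutation(n - n_a)
        p_overall, p_locus = stat(X2[perm])
        if not np.isnan(p_overall) and p_overall >= obs_overall:
            exceed_overall += 1
        with np.errstate(invalid="ignore"):
            exceed_locus += (p_locus >= obs_locus) & np.isfinite(p_locus)

    p_over = (1 + exceed_overall) / (1 + n_perm)
    p_loci = (1 + exceed_locus) / (1 + n_perm)
    p_loci = np.where(np.isfinite(obs_locus), p_loci, np.nan)
    table = pd.DataFrame({
        "locus": ds.locus_names,
        "linkage_group": [loc.linkage_group for loc in ds.loci],
        "r": obs_locus,
        "p": p_loci,
    })
    return ClineTestResult(table=table, overall_r=obs_overall, overall_p=p_over,
                           n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _check_dm(dm: np.ndarray, name: str) -> np.ndarray:
    dm = np.asarray(dm, float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.allclose(dm, dm.T):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(dm), 0.0):
        raise ValueError(f"{name} has a nonzero diagonal")
    return dm


def mantel(
    dma: np.ndarray, dmb: np.ndarray, n_perm: int = 9999, seed: int | None = None,
    labels_a=None, labels_b=None,
) -> tuple[float, float]:
    """Mantel test: Pearson r of upper-triangle entries, one-tailed p from
    jointly permuting the row/column labels of the first matrix."""
    if labels_a is not None and labels_b is not None and list(labels_a) != list(labels_b):
        raise ValueError("distance-matrix labels do not match")
    A = _check_dm(dma, "dmA")
    B = _check_dm(dmb, "dmB")
    if A.shape != B.shape:
        raise ValueError("distance matrices differ in size")
    iu = np.triu_indices(A.shape[0], k=1)
    va, vb = A[iu], B[iu]
    r_obs = _pearson(va, vb)
    if np.isnan(r_obs):
        return np.nan, np.nan
    rng = np.random.default_rng(seed)
    m = A.shape[0]
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(m)
        rp = _pearson(A[np.ix_(p, p)][iu], vb)
        if rp >= r_obs:
            exceed += 1
    return r_obs, (1 + exceed) / (1 + n_perm)


def partial_mantel(
    dma: np.ndarray, dmb: np.ndarray, dmc: np.ndarray,
    n_perm: int = 9999, seed: int | None = None,
) -> tuple[float, float]:
    """Partial Mantel (Smouse-Long-Sokal): correlate the residual matrices
    of A and B after linear regression on C; permute the labels of A's
    residual matrix for the one-tailed null."""
    A = _check_dm(dma, "dmA")
    B = _check_dm(dmb, "dmB")
    C = _check_dm(dmc, "dmC")
    if not (A.shape == B.shape == C.shape):
        raise ValueError("distance matrices differ in size")
    m = A.shape[0]
    iu = np.triu_indices(m, k=1)

    def residual_matrix(M: np.ndarray) -> np.ndarray:
        vc = C[iu]
        vm = M[iu]
        if vc.std() == 0:
            return M - vm.mean()
        slope, intercept = np.polyfit(vc, vm, 1)
        R = M - (intercept + slope * C)
        np.fill_diagonal(R, 0.0)
        return R

    RA, RB = residual_matrix(A), residual_matrix(B)
    va, vb = RA[iu], RB[iu]
    if va.std() < 1e-12 or vb.std() < 1e-12:
        return 0.0, 1.0  # a matrix fully explained by C: nothing left to correlate
    r_obs = _pearson(va, vb)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(m)
        rp = _pearson(RA[np.ix_(p, p)][iu], vb)
        if rp >= r_obs:
            exceed += 1
    return r_obs, (1 + exceed) / (1 + n_perm)
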