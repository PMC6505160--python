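"""Diversity and differentiation statistics.

Observed heterozygosity (Ho), Nei–Chesser within-population gene
diversity (Hs), Weir–Cockerham Fst (θ) as a ratio of variance-component
sums over loci, a distance-based AMOVA with a permutation test, PCA on
mean-imputed centred dosages, and a Mantel test of isolation by distance
with haversine geographic distances.

All statistics treat missing genotypes by per-locus exclusion; every
stochastic procedure takes an explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# diversity

@dataclass
class DiversityResult:
    """Per-population (and overall) Ho/Hs summary, Table-2 style."""

    table: pd.DataFrame  # population, n, missing_pct, ho, hs

    def row(self, population: str) -> pd.Series:
        return self.table.set_index("population").loc[population]


def _locus_stats(dos: np.ndarray):
    """Per-locus n_called, alt frequency and het proportion for a group's
    accession × marker dosage block."""
    called = dos != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dos, 0).sum(axis=0) / (2 * np.maximum(n, 1))
        ho = (dos == 1).sum(axis=0) / np.maximum(n, 1)
    return n, p, ho


def observed_heterozygosity(gm: GenotypeMatrix, rows: np.ndarray | None = None) -> float:
    """Mean over loci of the proportion of heterozygotes among called
    individuals; loci with zero calls in the group are excluded."""
    dos = gm.dosage if rows is None else gm.dosage[rows]
    n, _, ho = _locus_stats(dos)
    valid = n >= 1
    return float(ho[valid].mean()) if valid.any() else float("nan")


def gene_diversity_hs(gm: GenotypeMatrix, rows: np.ndarray | None = None) -> float:
    """Nei–Chesser unbiased within-population gene diversity.

    Per locus with n called individuals, alt frequency p and observed het
    proportion Ho:  Hs = n/(n-1) · (1 - p² - (1-p)² - Ho/(2n)),
    averaged over loci with n >= 2.
    """
    dos = gm.dosage if rows is None else gm.dosage[rows]
    n, p, ho = _locus_stats(dos)
    valid = n >= 2
    n, p, ho = n[valid], p[valid], ho[valid]
    if len(n) == 0:
        return float("nan")
    hs = n / (n - 1) * (1 - p**2 - (1 - p) ** 2 - ho / (2 * n))
    return float(hs.mean())


def diversity_table(gm: GenotypeMatrix, popmap: PopulationMap) -> DiversityResult:
    """Ho/Hs per subpopulation plus two whole-collection rows: "Total"
    treats the collection as one population; "Mean over pops" averages the
    per-population values (the two conventions for a pooled row)."""
    popmap.validate_against(gm)
    lookup = {a: i for i, a in enumerate(gm.accession_ids)}
    rows_out = []
    groups = popmap.groups(gm.accession_ids)
    all_rows = np.array(
        [lookup[a] for ids in groups.values() for a in ids], dtype=np.intp
    )
    miss = gm.dosage == MISSING
    rows_out.append(
        {
            "population": "Total",
            "n": len(all_rows),
            "missing_pct": 100 * float(miss[all_rows].mean()),
            "ho": observed_heterozygosity(gm, all_rows),
            "hs": gene_diversity_hs(gm, all_rows),
        }
    )
    per_pop = []
    for label, ids in groups.items():
        rows = np.array([lookup[a] for a in ids], dtype=np.intp)
        rec = {
            "population": label,
            "n": len(ids),
            "missing_pct": 100 * float(miss[rows].mean()),
            "ho": observed_heterozygosity(gm, rows),
            "hs": gene_diversity_hs(gm, rows),
        }
        per_pop.append(rec)
        rows_out.append(rec)
    mean_row = {
        "population": "Mean over pops",
        "n": len(all_rows),
        "missing_pct": float(np.mean([r["missing_pct"] for r in per_pop])),
        "ho": float(np.mean([r["ho"] for r in per_pop])),
        "hs": float(np.mean([r["hs"] for r in per_pop])),
    }
    rows_out.append(mean_row)
    return DiversityResult(table=pd.DataFrame(rows_out))


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst

def wc_components(
    gm: GenotypeMatrix, group_rows: list[np.ndarray]
) -> pd.DataFrame:
    """Per-locus Weir–Cockerham variance components a, b, c for r groups.

    With sample sizes n_i, alt frequencies p_i and het proportions h_i:

        n̄  = Σ n_i / r
        n_c = (r·n̄ − Σ n_i²/(r·n̄)) / (r − 1)
        p̄  = Σ n_i p_i / (r·n̄)
        s² = Σ n_i (p_i − p̄)² / ((r − 1)·n̄)
        h̄  = Σ n_i h_i / (r·n̄)
        a = (n̄/n_c) [s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄ − 1)]
        b = (n̄/(n̄−1)) [p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
        c = h̄/2

    Loci where any group has no calls, or n̄ ≤ 1, or n_c = 0 are returned
    as NaN (excluded from both sums of the θ ratio).
    """
    r = len(group_rows)
    n_mat, p_mat, h_mat = [], [], []
    for rows in group_rows:
        n, p, h = _locus_stats(gm.dosage[rows])
        n_mat.append(n)
        p_mat.append(p)
        h_mat.append(h)
    n_i = np.array(n_mat, dtype=float)  # r × loci
    p_i = np.array(p_mat)
    h_i = np.array(h_mat)

    nbar = n_i.sum(axis=0) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    bad = (n_i == 0).any(axis=0) | (nbar <= 1) | ~np.isfinite(nc) | (nc == 0)
    a, b, c = (np.where(bad, np.nan, x) for x in (a, b, c))
    return pd.DataFrame({"a": a, "b": b, "c": c})


def theta_from_components(comp: pd.DataFrame) -> float:
    """θ = Σ a / Σ (a+b+c) over loci with defined components; NaN when the
    denominator is zero (no variation)."""
    a = comp["a"].to_numpy()
    tot = (comp["a"] + comp["b"] + comp["c"]).to_numpy()
    ok = np.isfinite(tot)
    denom = tot[ok].sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


@dataclass
class FstResult:
    pairs: pd.DataFrame  # pop_a, pop_b, theta, ci_low, ci_high
    components: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def matrix(self) -> pd.DataFrame:
        pops = sorted(set(self.pairs["pop_a"]) | set(self.pairs["pop_b"]))
        m = pd.DataFrame(np.nan, index=pops, columns=pops)
        for rec in self.pairs.itertuples():
            m.loc[rec.pop_a, rec.pop_b] = rec.theta
            m.loc[rec.pop_b, rec.pop_a] = rec.theta
        np.fill_diagonal(m.values, 0.0)
        return m


def pairwise_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    n_boot: int = 1000,
    seed: int | None = None,
) -> FstResult:
    """Weir–Cockerham θ for every population pair, as a ratio of sums over
    loci, with an optional locus-bootstrap percentile CI (n_boot > 0)."""
    popmap.validate_against(gm)
    lookup = {a: i for i, a in enumerate(gm.accession_ids)}
    groups = {
        lab: np.array([lookup[a] for a in ids], dtype=np.intp)
        for lab, ids in popmap.groups(gm.accession_ids).items()
    }
    labels = sorted(groups)
    rng = np.random.default_rng(seed)
    rows, components = [], {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            comp = wc_components(gm, [groups[la], groups[lb]])
            theta = theta_from_components(comp)
            ci = (float("nan"), float("nan"))
            if n_boot > 0 and np.isfinite(theta):
                ok = comp.dropna()
                thetas = []
                for _ in range(n_boot):
                    bs = ok.iloc[rng.integers(0, len(ok), len(ok))]
                    thetas.append(theta_from_components(bs))
                ci = tuple(np.percentile(thetas, [2.5, 97.5]))
            rows.append((la, lb, theta, *ci))
            components[(la, lb)] = comp
    return FstResult(
        pairs=pd.DataFrame(
            rows, columns=["pop_a", "pop_b", "theta", "ci_low", "ci_high"]
        ),
        components=components,
    )


# ---------------------------------------------------------------------------
# AMOVA

@dataclass
class AmovaResult:
    ssd_total: float
    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    percent_among: float
    p_value: float
    n_permutations: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among_populations", "within_populations", "total"],
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "SSD": [self.ssd_among, self.ssd_within, self.ssd_total],
                "variance_component": [
                    self.sigma2_among, self.sigma2_within,
                    self.sigma2_among + self.sigma2_within,
                ],
                "percent": [self.percent_among, 100 - self.percent_among, 100.0],
            }
        )


def squared_distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Missing-scaled squared Euclidean distance between accessions:
    δ²_ij = Σ_l (d_il − d_jl)² · L / L_ij over loci called in both, where
    L is the locus count and L_ij the shared-call count."""
    d = gm.dosage.astype(float)
    called = gm.dosage != MISSING
    d[~called] = 0.0
    L = gm.n_markers
    # Σ (x−y)² over shared loci = x·x + y·y − 2x·y restricted to shared calls
    sq = d**2
    shared = called.astype(float) @ called.T.astype(float)
    cross = d @ d.T
    sq_shared = sq @ called.T.astype(float)
    delta2 = sq_shared + sq_shared.T - 2 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        delta2 = delta2 * (L / shared)
    delta2[shared == 0] = np.nan
    np.fill_diagonal(delta2, 0.0)
    return delta2


def _amova_ssd(delta2: np.ndarray, group_rows: list[np.ndarray]):
    n = delta2.shape[0]
    iu = np.triu_indices(n, k=1)
    ssd_total = float(delta2[iu].sum() / n)
    ssd_within = 0.0
    for rows in group_rows:
        sub = delta2[np.ix_(rows, rows)]
        iuk = np.triu_indices(len(rows), k=1)
        ssd_within += float(sub[iuk].sum() / len(rows))
    return ssd_total, ssd_total - ssd_within, ssd_within


def _phi_from_ssd(ssd_among, ssd_within, sizes):
    n = int(sum(sizes))
    k = len(sizes)
    n0 = (n - sum(s**2 for s in sizes) / n) / (k - 1)
    sigma_w = ssd_within / (n - k)
    sigma_a = (ssd_among / (k - 1) - sigma_w) / n0
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else float("nan")
    return sigma_a, sigma_w, phi


def amova(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """One-level distance-based AMOVA on dosage vectors.

    Partitions the missing-scaled squared-Euclidean distance variance
    among and within populations; Φ_ST = σ²_a/(σ²_a+σ²_w); significance
    by permuting individuals among groups with group sizes fixed, with
    the add-one rule p = (1 + #{Φ_perm >= Φ_obs})/(1 + n_permutations).
    """
    popmap.validate_against(gm)
    lookup = {a: i for i, a in enumerate(gm.accession_ids)}
    groups = popmap.groups(gm.accession_ids)
    if len(groups) < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    group_rows = [
        np.array([lookup[a] for a in ids], dtype=np.intp)
        for ids in groups.values()
    ]
    sizes = [len(r) for r in group_rows]
    for lab, s in zip(groups, sizes):
        if s == 1:
            logger.warning("AMOVA group %s has a single individual", lab)
    n = int(sum(sizes))
    k = len(sizes)
    if n < k + 1:
        raise ValueError("AMOVA needs N >= K+1 individuals")

    delta2 = squared_distance_matrix(gm)
    all_rows = np.concatenate(group_rows)
    delta2 = delta2[np.ix_(all_rows, all_rows)]
    offsets = np.cumsum([0, *sizes])
    rel_rows = [np.arange(offsets[i], offsets[i + 1]) for i in range(k)]

    ssd_total, ssd_among, ssd_within = _amova_ssd(delta2, rel_rows)
    sigma_a, sigma_w, phi = _phi_from_ssd(ssd_among, ssd_within, sizes)
    denom = sigma_a + sigma_w
    percent = 100 * sigma_a / denom if denom != 0 else float("nan")

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        prow = [perm[r] for r in rel_rows]
        _, sa, sw = _amova_ssd(delta2, prow)
        _, _, phi_p = _phi_from_ssd(sa, sw, sizes)
        if np.isfinite(phi_p) and np.isfinite(phi) and phi_p >= phi:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return AmovaResult(
        ssd_total=ssd_total, ssd_among=ssd_among, ssd_within=ssd_within,
        df_among=k - 1, df_within=n - k,
        sigma2_among=sigma_a, sigma2_within=sigma_w,
        phi_st=phi, percent_among=percent,
        p_value=p, n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# PCA and isolation by distance

def pca(gm: GenotypeMatrix, n_components: int = 10):
    """PCA of the dosage matrix: per-marker mean imputation of missing
    calls, column centring (no variance scaling), SVD.

    Returns (scores DataFrame indexed by accession, percent variance per
    component over the full spectrum).
    """
    if gm.n_accessions < 2:
        raise ValueError("PCA needs >= 2 accessions")
    x = gm.dosage.astype(float)
    mask = gm.dosage == MISSING
    n_called = (~mask).sum(axis=0)
    col_sum = np.where(mask, 0.0, x).sum(axis=0)
    col_mean = np.where(n_called > 0, col_sum / np.maximum(n_called, 1), 0.0)
    x[mask] = np.take(col_mean, np.where(mask)[1])
    x -= x.mean(axis=0)
    if not x.any():
        raise ValueError("zero-variance matrix")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pct = 100 * s**2 / (s**2).sum()
    n_components = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components],
        index=gm.accession_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, pct[:n_components]


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance_matrix(coords: pd.DataFrame) -> np.ndarray:
    """Pairwise haversine distances (km) from a lat/lon DataFrame."""
    lat = coords["lat"].to_numpy(float)
    lon = coords["lon"].to_numpy(float)
    n = len(lat)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return out


def allele_sharing_distance(gm: GenotypeMatrix) -> np.ndarray:
    """1 − allele-sharing similarity: mean |d_i − d_j| / 2 over shared
    loci.  The default genetic distance for the isolation-by-distance
    test."""
    n = gm.n_accessions
    out = np.zeros((n, n))
    d = gm.dosage
    for i in range(n):
        for j in range(i + 1, n):
            shared = (d[i] != MISSING) & (d[j] != MISSING)
            if shared.sum() == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            val = np.abs(d[i, shared].astype(float) - d[j, shared]).mean() / 2
            out[i, j] = out[j, i] = val
    return out


def mantel_ibd(
    genetic_distance: np.ndarray,
    coordinates: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between genetic and haversine geographic
    distance: Pearson r of the strictly-lower-triangle vectors, one-sided
    upper p by permuting accession order of the genetic matrix."""
    g = np.asarray(genetic_distance, dtype=float)
    n = g.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs >= 3 accessions")
    if g.shape != (n, n) or not np.allclose(g, g.T, equal_nan=True):
        raise ValueError("genetic distance must be square symmetric")
    geo = geographic_distance_matrix(coordinates)
    il = np.tril_indices(n, k=-1)
    gv, ev = g[il], geo[il]
    r = float(np.corrcoef(gv, ev)[0, 1])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        rp = float(np.corrcoef(g[np.ix_(perm, perm)][il], ev)[0, 1])
        if rp >= r:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return r, p
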