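"""Two-locus linkage disequilibrium from unphased genotypes.

r² is computed from maximum-likelihood haplotype frequencies obtained by
an EM over the double-heterozygote phase ambiguity, on pairwise-complete
observations — the convention of the standard unphased-genotype LD
workflow.  Genome-wide decay is summarised by least-squares fitting of
the Hill–Weir drift expectation

    E(r²) = [(10+C) / ((2+C)(11+C))] ·
            [1 + ((3+C)(12+12C+C²)) / (n (2+C)(11+C))],   C = ρ·d,

with n the number of sampled chromosomes, and the decay distance is the
point where the fitted curve falls to a baseline r² (0.1 by default).
The local profile averages r² between SNPs of consecutive sequencing
units, keyed to the left cut site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize

from .io import MISSING, GenotypeMatrix
from .rad import SequencingUnit

logger = logging.getLogger(__name__)


class HapFreqs(NamedTuple):
    pAB: float
    pAb: float
    paB: float
    pab: float
    n: int  # pairwise-complete individuals
    loglik: float


def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3×3 joint genotype counts over pairwise-complete individuals."""
    mask = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[mask].astype(np.intp), g2[mask].astype(np.intp)
    return np.bincount(3 * a + b, minlength=9).reshape(3, 3)


def _loglik(counts: np.ndarray, pAB: float, pAb: float, paB: float, pab: float) -> float:
    """Observed-data log-likelihood of the 3×3 genotype table under
    Hardy–Weinberg random union of haplotypes."""
    h = np.array([[pab, paB], [pAb, pAB]])  # h[a1][a2], allele 1 = alt
    ll = 0.0
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0:
                continue
            p = 0.0
            # sum over unordered haplotype pairs producing genotype (i, j)
            for x1 in range(2):
                for y1 in range(2):
                    x2, y2 = i - x1, j - y1
                    if x2 in (0, 1) and y2 in (0, 1):
                        p += h[x1][y1] * h[x2][y2]
            ll += c * np.log(max(p, 1e-300))
    return float(ll)


def em_haplotype_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
    return_trace: bool = False,
):
    """ML haplotype frequencies (pAB, pAb, paB, pab) by EM.

    A is the alt allele at locus 1, B at locus 2.  Initialised at linkage
    equilibrium; the E-step splits double-heterozygote counts by the odds
    of coupling vs repulsion phase (degenerate 0/0 odds split equally);
    iterates until max |Δfreq| < tol.  Returns ``None`` if either locus is
    monomorphic in the pairwise-complete subset.

    The two-locus likelihood can be bimodal in the coupling frequency, so
    the EM is run from three starts — linkage equilibrium plus the two
    phase extremes — and the highest-likelihood solution is kept.  With
    ``return_trace`` also returns the per-iteration observed-data
    log-likelihood of the best run (non-decreasing by the EM property).
    """
    c = _pair_counts(np.asarray(g1), np.asarray(g2))
    n = int(c.sum())
    if n == 0:
        return None
    pA = (2 * c[2, :].sum() + c[1, :].sum()) / (2 * n)
    pB = (2 * c[:, 2].sum() + c[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None

    # haplotype counts contributed by phase-unambiguous genotypes
    n_dh = c[1, 1]
    base_AB = 2 * c[2, 2] + c[2, 1] + c[1, 2]
    base_Ab = 2 * c[2, 0] + c[2, 1] + c[1, 0]
    base_aB = 2 * c[0, 2] + c[0, 1] + c[1, 2]
    base_ab = 2 * c[0, 0] + c[0, 1] + c[1, 0]
    total = 2.0 * n

    def run(pAB0: float):
        pAB = pAB0
        pAb, paB, pab = pA - pAB, pB - pAB, 1 - pA - pB + pAB
        trace = [_loglik(c, pAB, pAb, paB, pab)] if return_trace else None
        for _ in range(max_iter):
            coupling = pAB * pab
            repulsion = pAb * paB
            frac = 0.5 if coupling + repulsion == 0 else coupling / (coupling + repulsion)
            new = (
                (base_AB + n_dh * frac) / total,
                (base_Ab + n_dh * (1 - frac)) / total,
                (base_aB + n_dh * (1 - frac)) / total,
                (base_ab + n_dh * frac) / total,
            )
            delta = max(abs(a - b) for a, b in zip(new, (pAB, pAb, paB, pab)))
            pAB, pAb, paB, pab = new
            if return_trace:
                trace.append(_loglik(c, pAB, pAb, paB, pab))
            if delta < tol:
                break
        final_ll = trace[-1] if return_trace else _loglik(c, pAB, pAb, paB, pab)
        return HapFreqs(pAB, pAb, paB, pab, n, final_ll), trace

    if n_dh == 0:  # no double heterozygotes: haplotypes fully determined
        freqs = (base_AB / total, base_Ab / total, base_aB / total, base_ab / total)
        result = HapFreqs(*freqs, n, _loglik(c, *freqs))
        return (result, [result.loglik]) if return_trace else result

    lo, hi = max(0.0, pA + pB - 1), min(pA, pB)
    eps = 1e-6 * (hi - lo)
    starts = {pA * pB, lo + eps, hi - eps}
    best, best_trace = None, None
    for s in starts:
        result, trace = run(min(max(s, lo), hi))
        if best is None or result.loglik > best.loglik:
            best, best_trace = result, trace
    return (best, best_trace) if return_trace else best


def r2_from_freqs(freqs: HapFreqs) -> float:
    pA = freqs.pAB + freqs.pAb
    pB = freqs.pAB + freqs.paB
    d = freqs.pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return np.nan
    return float(np.clip(d * d / denom, 0.0, 1.0))


def r2_pair(g1: np.ndarray, g2: np.ndarray, method: str = "em") -> float:
    """Pairwise r² between two dosage vectors.

    ``method="em"`` (default): from EM haplotype frequencies.
    ``method="composite"``: squared Pearson correlation of dosages
    (composite LD, no phase model).  NaN when either locus is monomorphic
    in the pairwise-complete subset.
    """
    if method == "composite":
        g1, g2 = np.asarray(g1), np.asarray(g2)
        mask = (g1 != MISSING) & (g2 != MISSING)
        a, b = g1[mask].astype(float), g2[mask].astype(float)
        if len(a) < 2 or a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1] ** 2)
    freqs = em_haplotype_freqs(g1, g2)
    if freqs is None:
        return np.nan
    return r2_from_freqs(freqs)


def windowed_ld(
    gm: GenotypeMatrix, window_bp: int = 1_000_000, method: str = "em"
) -> pd.DataFrame:
    """r² for every intra-chromosome marker pair within ``window_bp``.

    Returns a table (chrom, pos_i, pos_j, distance_bp, r2, n) with
    undefined pairs (monomorphic in the complete subset) dropped; their
    count is logged and stored in ``df.attrs["n_undefined"]``.
    """
    chroms, pos = gm.chromosomes, gm.positions
    records = []
    n_undef = 0
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                dist = int(p[b] - p[a])
                if dist <= 0:
                    continue
                if dist > window_bp:
                    break
                g1, g2 = gm.dosage[:, idx[a]], gm.dosage[:, idx[b]]
                r2 = r2_pair(g1, g2, method=method)
                if np.isnan(r2):
                    n_undef += 1
                    continue
                n = int(np.sum((g1 != MISSING) & (g2 != MISSING)))
                records.append((chrom, int(p[a]), int(p[b]), dist, r2, n))
    df = pd.DataFrame(
        records, columns=["chrom", "pos_i", "pos_j", "distance_bp", "r2", "n"]
    )
    df.attrs["n_undefined"] = n_undef
    if n_undef:
        logger.info("windowed_ld: %d undefined pairs skipped", n_undef)
    return df


# ---------------------------------------------------------------------------
# Hill–Weir decay

def hill_weir_expected_r2(distance_bp, rho: float, n: int):
    """Drift expectation of r² at recombination scale C = rho·distance for
    a sample of n chromosomes."""
    c = rho * np.asarray(distance_bp, dtype=float)
    first = (10 + c) / ((2 + c) * (11 + c))
    second = 1 + ((3 + c) * (12 + 12 * c + c * c)) / (n * (2 + c) * (11 + c))
    return first * second


@dataclass
class DecayFit:
    rho: float  # per-bp recombination-scale parameter
    n: int  # chromosomes in the expectation
    baseline: float
    decay_distance_bp: float | None  # None = curve never reaches baseline
    n_pairs: int

    def expected_r2(self, distance_bp):
        return hill_weir_expected_r2(distance_bp, self.rho, self.n)


def fit_decay(
    pairs: pd.DataFrame,
    n: int,
    baseline: float = 0.1,
    binned: bool = False,
    bin_width_bp: int = 1000,
) -> DecayFit:
    """Least-squares fit of ρ in the Hill–Weir expectation to a (distance,
    r²) cloud, then the decay distance where the fitted curve crosses the
    baseline (bisection, 1-bp tolerance).

    ``binned=True`` fits to per-bin mean r² (distance bins of
    ``bin_width_bp``) instead of raw pairs — the common plotting
    convention; raw-pair fitting is the default.
    """
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 pairs to fit, got {len(pairs)}")
    if n < 2:
        raise ValueError("n must be >= 2 chromosomes")
    d = pairs["distance_bp"].to_numpy(float)
    y = pairs["r2"].to_numpy(float)
    if binned:
        bins = (d // bin_width_bp).astype(int)
        grouped = pd.DataFrame({"bin": bins, "d": d, "r2": y}).groupby("bin")
        d = grouped["d"].mean().to_numpy()
        y = grouped["r2"].mean().to_numpy()

    def sse(log10_rho: float) -> float:
        resid = y - hill_weir_expected_r2(d, 10.0 ** log10_rho, n)
        return float(resid @ resid)

    # coarse log-scale scan keeps the 1-D refinement off flat shoulders
    grid = np.linspace(-10, 0, 41)
    start = grid[int(np.argmin([sse(g) for g in grid]))]
    res = optimize.minimize_scalar(
        sse, bounds=(start - 1.0, start + 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"decay fit failed to converge: {res}")
    rho = float(10.0 ** res.x)

    d_max = float(d.max())
    lo, hi = 1.0, 10.0 * d_max
    f = lambda x: float(hill_weir_expected_r2(x, rho, n) - baseline)
    if hill_weir_expected_r2(0.0, rho, n) <= baseline:
        decay = 0.0
    elif f(hi) > 0:
        decay = None  # curve never reaches the baseline within range
    else:
        decay = float(optimize.brentq(f, lo, hi, xtol=1.0))
    return DecayFit(rho=rho, n=n, baseline=baseline,
                    decay_distance_bp=decay, n_pairs=len(pairs))


def default_sample_chromosomes(pairs: pd.DataFrame) -> int:
    """n for the Hill–Weir expectation: twice the median pairwise-complete
    individual count, fixed before fitting."""
    return int(2 * np.median(pairs["n"].to_numpy()))


# ---------------------------------------------------------------------------
# local LD between consecutive sequencing units

@dataclass
class LocalLDProfile:
    records: pd.DataFrame  # chrom, left_cut_pos, mean_r2, n_snp_pairs
    tallies: pd.DataFrame  # per-chrom + Total: n_ge_baseline, n_lt_baseline, pct
    baseline: float


def local_ld_profile(
    gm: GenotypeMatrix,
    units: list[SequencingUnit],
    baseline: float = 0.1,
    method: str = "em",
) -> LocalLDProfile:
    """Mean r² between the SNPs of each pair of consecutive sequencing
    units on a chromosome, keyed to the left unit's cut position, with
    per-chromosome tallies of means >= baseline vs < baseline.

    Consecutive pairs in which no r² is defined are excluded from the
    tallies (and logged).
    """
    from .reporting import proportion_report

    by_chrom: dict[str, list[SequencingUnit]] = {}
    for u in units:
        by_chrom.setdefault(u.chromosome, []).append(u)
    rows = []
    n_excluded = 0
    for chrom, ulist in sorted(by_chrom.items()):
        ulist = sorted(ulist, key=lambda u: u.cut_site.motif_start)
        for left, right in zip(ulist, ulist[1:]):
            vals = [
                r2
                for i in left.snp_indices
                for j in right.snp_indices
                if not np.isnan(
                    r2 := r2_pair(gm.dosage[:, i], gm.dosage[:, j], method=method)
                )
            ]
            if not vals:
                n_excluded += 1
                continue
            rows.append(
                (chrom, left.cut_site.motif_start, float(np.mean(vals)), len(vals))
            )
    records = pd.DataFrame(
        rows, columns=["chrom", "left_cut_pos", "mean_r2", "n_snp_pairs"]
    )
    if n_excluded:
        logger.info("local_ld_profile: %d unit pairs had no defined r2", n_excluded)

    tally_rows = []
    for chrom, sub in records.groupby("chrom", sort=True):
        ge = int((sub["mean_r2"] >= baseline).sum())
        lt = int((sub["mean_r2"] < baseline).sum())
        tally_rows.append((chrom, ge, lt))
    total_ge = sum(r[1] for r in tally_rows)
    total_lt = sum(r[2] for r in tally_rows)
    tally_rows.append(("Total", total_ge, total_lt))
    tallies = pd.DataFrame(
        tally_rows, columns=["chrom", "n_ge_baseline", "n_lt_baseline"]
    )
    tallies["pct_ge_baseline"] = [
        proportion_report(ge, ge + lt) if ge + lt else np.nan
        for ge, lt in zip(tallies["n_ge_baseline"], tallies["n_lt_baseline"])
    ]
    records.attrs["n_excluded"] = n_excluded
    return LocalLDProfile(records=records, tallies=tallies, baseline=baseline)
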