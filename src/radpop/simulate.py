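"""Synthetic data with the statistical structure the pipeline assumes.

Four generators, all fully deterministic under an explicit seed:

* structured/admixed genotypes — Balding–Nichols population allele
  frequencies around an ancestral frequency (Beta with dispersion set by
  the differentiation parameter F) and Dirichlet individual ancestry,
  the test bed for Fst/AMOVA/PCA/Hs;
* LD genotypes — gametes built as mosaics of a finite founder-haplotype
  pool with distance-dependent founder switching, producing monotone
  distance decay of r² (a phenomenological model: the fitted decay
  parameter is not analytically tied to the switch rate);
* a toy genome — FASTA with planted restriction-motif sites,
  gene-annotation GFF3 enriched in euchromatic arms, and a pericentromeric
  heterochromatin BED, with ground truth returned for oracle tests;
* geographic coordinates on a north–south transect so that isolation by
  distance holds by construction.

Defaults emulate the study conditions this package targets: a ~99-
accession, 3-ancestral-population wild-tomato-like collection with a few
percent missing genotypes and LD decaying over tens of kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MarkerInfo, PopulationMap
from .rad import digest_sequence


@dataclass
class SimParams:
    """Generator settings; ``seed`` is mandatory (no silent clock seeding)."""

    seed: int
    K: int = 3  # ancestral populations
    F: float = 0.15  # Balding–Nichols differentiation
    n_per_pop: int = 33
    n_loci: int = 2000
    admixture_alpha: float | np.ndarray = 0.0  # 0 → unadmixed one-hot ancestry
    founder_haplotypes: int = 30
    switch_rate_per_bp: float = 1e-5
    marker_spacing_bp: float = 2000.0
    missing_rate: float = 0.06
    n_chromosomes: int = 1
    chromosome_length: int = 5_000_000

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_per_pop < 1 or self.n_loci < 1:
            raise ValueError("K, n_per_pop, n_loci must be positive")
        if not 0 <= self.F < 1:
            raise ValueError("F must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _positions(rng: np.random.Generator, n_loci: int, mean_spacing: float) -> np.ndarray:
    gaps = np.maximum(1, rng.exponential(mean_spacing, n_loci).astype(np.int64))
    return np.cumsum(gaps)


def _alleles(rng: np.random.Generator, n_loci: int) -> list[tuple[str, str]]:
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, n_loci)
    alt = (ref + rng.integers(1, 4, n_loci)) % 4
    return list(zip(bases[ref], bases[alt]))


def _apply_missing(rng, dosage: np.ndarray, rate: float) -> np.ndarray:
    if rate > 0:
        mask = rng.random(dosage.shape) < rate
        dosage = np.where(mask, -1, dosage)
    return dosage.astype(np.int8)


def simulate_structured_population(
    params: SimParams,
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Balding–Nichols structured genotypes with optional admixture.

    Ancestral frequency p_l ~ Uniform(0.05, 0.95); population frequency
    p_kl ~ Beta(p_l(1−F)/F, (1−p_l)(1−F)/F) (F = 0 collapses to
    p_kl = p_l exactly); ancestry q_i one-hot per home population when
    ``admixture_alpha == 0``, else Dirichlet(alpha); genotype ~
    Binomial(2, Σ_k q_ik p_kl); missing mask Bernoulli(missing_rate).

    Returns (GenotypeMatrix, PopulationMap with true ancestry, the true
    allele-frequency table: rows loci, columns ancestral + per-pop).
    """
    rng = np.random.default_rng(params.seed)
    K, L = params.K, params.n_loci
    p_anc = rng.uniform(0.05, 0.95, L)
    if params.F < 1e-12:  # Beta shapes overflow; the limit is exact panmixia
        p_pop = np.tile(p_anc, (K, 1))
    else:
        shape1 = p_anc * (1 - params.F) / params.F
        shape2 = (1 - p_anc) * (1 - params.F) / params.F
        p_pop = rng.beta(shape1, shape2, size=(K, L))

    n = K * params.n_per_pop
    home = np.repeat(np.arange(K), params.n_per_pop)
    alpha = params.admixture_alpha
    if np.all(np.asarray(alpha) == 0):
        q = np.zeros((n, K))
        q[np.arange(n), home] = 1.0
        labels = [f"POP{h + 1}" for h in home]
    else:
        alpha_vec = np.full(K, float(alpha)) if np.ndim(alpha) == 0 else np.asarray(alpha, float)
        q = rng.dirichlet(alpha_vec, size=n)
        labels = [f"POP{int(np.argmax(qi)) + 1}" for qi in q]

    p_ind = q @ p_pop  # n × L expected allele frequency per individual
    dosage = rng.binomial(2, p_ind)
    dosage = _apply_missing(rng, dosage, params.missing_rate)

    positions = _positions(rng, L, params.marker_spacing_bp)
    alleles = _alleles(rng, L)
    markers = [
        MarkerInfo("sim01", int(pos), ref, alt)
        for pos, (ref, alt) in zip(positions, alleles)
    ]
    ids = [f"ACC{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(ids, markers, dosage)
    ancestry = pd.DataFrame(q, index=ids, columns=[f"POP{k + 1}" for k in range(K)])
    popmap = PopulationMap(labels=dict(zip(ids, labels)), ancestry=ancestry)
    truth = pd.DataFrame(
        {"ancestral": p_anc, **{f"POP{k + 1}": p_pop[k] for k in range(K)}}
    )
    return gm, popmap, truth


def simulate_ld_genotypes(params: SimParams) -> GenotypeMatrix:
    """Founder-mosaic genotypes with distance-decaying LD.

    Per population, ``founder_haplotypes`` (M) haplotypes are drawn
    site-wise from the population frequencies; each gamete copies one
    founder and switches to a random founder between adjacent markers
    with probability 1 − exp(−c·spacing).  LD comes from the finite pool
    (background level ~1/M) plus local founder persistence, so mean r²
    decays with distance at a rate growing with c.
    """
    if params.founder_haplotypes < 2:
        raise ValueError("need >= 2 founder haplotypes")
    if params.switch_rate_per_bp <= 0:
        raise ValueError("switch rate must be > 0")
    rng = np.random.default_rng(params.seed)
    K, L, M = params.K, params.n_loci, params.founder_haplotypes
    positions = _positions(rng, L, params.marker_spacing_bp)
    spacing = np.diff(positions)
    p_switch = 1 - np.exp(-params.switch_rate_per_bp * spacing)

    p_anc = rng.uniform(0.05, 0.95, L)
    if params.F < 1e-12:
        p_pop = np.tile(p_anc, (K, 1))
    else:
        p_pop = rng.beta(
            p_anc * (1 - params.F) / params.F,
            (1 - p_anc) * (1 - params.F) / params.F,
            size=(K, L),
        )

    rows = []
    for k in range(K):
        founders = (rng.random((M, L)) < p_pop[k]).astype(np.int8)
        n_gam = 2 * params.n_per_pop
        # vectorised mosaic: founder index per gamete per locus
        idx = np.empty((n_gam, L), dtype=np.int64)
        idx[:, 0] = rng.integers(0, M, n_gam)
        switches = rng.random((n_gam, L - 1)) < p_switch
        draws = rng.integers(0, M, (n_gam, L - 1))
        for j in range(1, L):
            idx[:, j] = np.where(switches[:, j - 1], draws[:, j - 1], idx[:, j - 1])
        gametes = founders[idx, np.arange(L)]
        rows.append(gametes[0::2] + gametes[1::2])
    dosage = np.concatenate(rows, axis=0)
    dosage = _apply_missing(rng, dosage, params.missing_rate)
    alleles = _alleles(rng, L)
    markers = [
        MarkerInfo("sim01", int(pos), ref, alt)
        for pos, (ref, alt) in zip(positions, alleles)
    ]
    ids = [f"ACC{i + 1:04d}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(ids, markers, dosage)


@dataclass
class GenomeFixture:
    fasta_path: Path
    gff_path: Path
    het_bed_path: Path
    sites: list  # ground-truth CutSites from a scan of the final sequence
    genes: list[tuple[str, int, int, str]]
    heterochromatin: list[tuple[str, int, int]]
    sequences: dict[str, str]


def simulate_genome_fixture(
    out_dir: str | Path,
    seed: int,
    chromosome_lengths: dict[str, int] | None = None,
    motif: str = "CTGCAG",
    sites_per_chrom: int = 40,
    genes_per_chrom: int = 30,
    het_fraction: float = 0.3,
    gene_eu_enrichment: float = 4.0,
    gene_length: int = 2000,
) -> GenomeFixture:
    """Toy genome for digestion/classification/overlap tests.

    Each chromosome gets a central heterochromatin block covering
    ``het_fraction`` of its length, a random ACGT background with
    ``sites_per_chrom`` planted motif copies, and genes placed with
    euchromatin:heterochromatin density ratio ``gene_eu_enrichment``.
    The returned site list is the ground truth from an independent scan
    of the final sequence (so chance background occurrences are
    included).  Writes FASTA, GFF3 and BED3 under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chromosome_lengths = chromosome_lengths or {"chr01": 200_000, "chr02": 150_000}

    sequences: dict[str, str] = {}
    het: list[tuple[str, int, int]] = []
    genes: list[tuple[str, int, int, str]] = []
    all_sites = []
    gene_no = 0
    for chrom, length in chromosome_lengths.items():
        seq = rng.choice(list("ACGT"), size=length)
        # plant motifs at distinct non-overlapping positions
        starts = rng.choice(
            np.arange(0, length - len(motif), len(motif)),
            size=min(sites_per_chrom, (length - len(motif)) // len(motif)),
            replace=False,
        )
        for s in starts:
            seq[s : s + len(motif)] = list(motif)
        text = "".join(seq)
        sequences[chrom] = text
        all_sites.extend(digest_sequence(text, motif, chrom))

        h0 = int(length * (0.5 - het_fraction / 2)) + 1
        h1 = int(length * (0.5 + het_fraction / 2))
        het.append((chrom, h0, h1))

        # density ratio via rejection: heterochromatic placements accepted
        # with probability 1/enrichment
        placed = 0
        while placed < genes_per_chrom:
            start = int(rng.integers(1, length - gene_length))
            end = start + gene_length - 1
            in_het = h0 <= start <= h1
            if in_het and rng.random() > 1.0 / gene_eu_enrichment:
                continue
            gene_no += 1
            genes.append((chrom, start, end, f"gene{gene_no:04d}"))
            placed += 1

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom, text in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(text), 80):
                fh.write(text[i : i + 80] + "\n")
    gff_path = out_dir / "genes.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, gid in sorted(genes):
            fh.write(
                f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n"
            )
    het_bed_path = out_dir / "heterochromatin.bed"
    with open(het_bed_path, "w") as fh:
        for chrom, start, end in het:
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")
    return GenomeFixture(
        fasta_path=fasta_path, gff_path=gff_path, het_bed_path=het_bed_path,
        sites=all_sites, genes=sorted(genes), heterochromatin=het,
        sequences=sequences,
    )


def simulate_coordinates(
    popmap: PopulationMap,
    seed: int,
    centroid_spacing_deg: float = 3.0,
    jitter_deg: float = 0.3,
    base_lat: float = 0.0,
    lon: float = -78.0,
) -> pd.DataFrame:
    """Geographic coordinates on a north–south transect.

    Population centroids are spaced ``centroid_spacing_deg`` apart in
    latitude (southwards, mimicking an Andean coastal transect);
    individuals get Gaussian jitter.  Centroid separation grows with the
    label index, so genetic and geographic distance correlate by
    construction.  Also attaches the frame to ``popmap.coordinates``.
    """
    rng = np.random.default_rng(seed)
    labels = sorted(set(popmap.labels.values()))
    centroid = {
        lab: (base_lat - i * centroid_spacing_deg, lon) for i, lab in enumerate(labels)
    }
    rows = []
    for acc, lab in popmap.labels.items():
        lat0, lon0 = centroid[lab]
        rows.append(
            (acc, lat0 + rng.normal(0, jitter_deg), lon0 + rng.normal(0, jitter_deg))
        )
    df = pd.DataFrame(rows, columns=["accession", "lat", "lon"]).set_index("accession")
    popmap.coordinates = df
    return df
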