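"""In-silico restriction digestion and sequencing-unit construction.

A reduced-representation (RAD) library sequences short reads anchored at
restriction-enzyme cut sites.  For a palindromic motif such as PstI's
CTGCAG a forward-strand scan finds every site.  A *sequencing unit* is the
region around one cut site captured by single-end reads — with the default
read span of 93 bp per side the unit covers 186 bp — and it groups the
SNPs used for redundancy pruning and local-LD profiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, MarkerInfo

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class CutSite:
    chromosome: str
    motif_start: int  # 1-based position of the first motif base
    region_class: str | None = None  # "euchromatin" | "heterochromatin"

    def __post_init__(self) -> None:
        if self.motif_start < 1:
            raise ValueError("motif_start must be >= 1")


@dataclass
class SequencingUnit:
    """A cut-site-anchored interval holding >= 1 SNP."""

    unit_id: int
    chromosome: str
    cut_site: CutSite
    interval: tuple[int, int]  # 1-based inclusive; clipped at chromosome start
    snp_indices: list[int] = field(default_factory=list)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def digest_sequence(seq: str, motif: str, chromosome: str = "seq") -> list[CutSite]:
    """All forward-strand motif occurrences (overlaps included), 1-based."""
    _check_motif(motif)
    seq = seq.upper()
    sites = []
    start = seq.find(motif)
    while start != -1:
        sites.append(CutSite(chromosome, start + 1))
        start = seq.find(motif, start + 1)
    return sites


def digest_genome(fasta_path: str | Path, motif: str = "CTGCAG") -> list[CutSite]:
    """Scan every sequence of a FASTA for the restriction motif.

    Ambiguity codes (N etc.) never match.  For palindromic motifs (CTGCAG
    equals its own reverse complement) the forward scan is complete.
    """
    from pyfaidx import Fasta

    _check_motif(motif)
    sites: list[CutSite] = []
    with Fasta(str(fasta_path), as_raw=True) as fa:
        for name in fa.keys():
            sites.extend(digest_sequence(str(fa[name][:]), motif, name))
    return sites


def _check_motif(motif: str) -> None:
    if not motif:
        raise ValueError("empty motif")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over A/C/G/T, got {motif!r}")


def classify_sites(
    sites: list[CutSite], annotation: GenomeAnnotation
) -> tuple[list[CutSite], dict[str, int]]:
    """Assign each site to euchromatin or heterochromatin in place.

    A site is heterochromatic iff its motif start lies inside a merged
    heterochromatin interval (1-based inclusive).  Chromosomes without a
    heterochromatin track default to euchromatin with a warning (e.g. the
    unanchored chromosome 0, which has no genetic-map assignment).
    """
    het = annotation.het_by_chrom()
    warned: set[str] = set()
    counts = {"euchromatin": 0, "heterochromatin": 0}
    for site in sites:
        ivs = het.get(site.chromosome)
        if ivs is None:
            if site.chromosome not in warned and annotation.heterochromatin:
                logger.warning(
                    "chromosome %s absent from heterochromatin track; "
                    "classifying euchromatic", site.chromosome,
                )
                warned.add(site.chromosome)
            site.region_class = "euchromatin"
        else:
            inside = np.any(
                (ivs[:, 0] <= site.motif_start) & (site.motif_start <= ivs[:, 1])
            )
            site.region_class = "heterochromatin" if inside else "euchromatin"
        counts[site.region_class] += 1
    return sites, counts


def build_units(
    sites: list[CutSite],
    markers: list[MarkerInfo],
    read_span: int = 93,
) -> tuple[list[SequencingUnit], list[int]]:
    """Group SNPs into cut-site-anchored sequencing units.

    Each SNP is assigned to the nearest cut site whose candidate interval
    [motif_start - read_span, motif_start + read_span] contains it; on a
    distance tie the left (lower-position) site wins.  Only sites with at
    least one assigned SNP become units.  ``unit_id`` is written back into
    each assigned :class:`MarkerInfo`; indices of SNPs falling outside
    every interval are returned for reporting.

    Returns (units sorted by chromosome then cut position, unassigned
    marker indices).
    """
    if read_span <= 0:
        raise ValueError("read_span must be positive")
    by_chrom: dict[str, list[CutSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chromosome, []).append(s)
    site_pos = {
        c: np.array(sorted(s.motif_start for s in v), dtype=np.int64)
        for c, v in by_chrom.items()
    }

    assigned: dict[tuple[str, int], list[int]] = {}
    unassigned: list[int] = []
    for idx, m in enumerate(markers):
        pos_arr = site_pos.get(m.chromosome)
        if pos_arr is None or len(pos_arr) == 0:
            unassigned.append(idx)
            continue
        k = int(np.searchsorted(pos_arr, m.position))
        best: int | None = None
        best_dist = read_span + 1
        for cand in (k - 1, k):  # nearest candidates; left first for the tie rule
            if 0 <= cand < len(pos_arr):
                d = abs(int(pos_arr[cand]) - m.position)
                if d <= read_span and d < best_dist:
                    best, best_dist = int(pos_arr[cand]), d
        if best is None:
            unassigned.append(idx)
        else:
            assigned.setdefault((m.chromosome, best), []).append(idx)

    units: list[SequencingUnit] = []
    for uid, (chrom, pos) in enumerate(sorted(assigned)):
        snp_idx = sorted(assigned[(chrom, pos)], key=lambda i: markers[i].position)
        unit = SequencingUnit(
            unit_id=uid,
            chromosome=chrom,
            cut_site=CutSite(chrom, pos),
            interval=(max(1, pos - read_span), pos + read_span),
            snp_indices=snp_idx,
        )
        for i in snp_idx:
            markers[i].unit_id = uid
        units.append(unit)
    if unassigned:
        logger.info("%d SNPs fall outside every sequencing unit", len(unassigned))
    return units, unassigned


def overlap_report(
    units: list[SequencingUnit],
    markers: list[MarkerInfo],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Per-chromosome marker/gene overlap summary.

    Columns: snps, genes_in_sequenced_regions (gene interval intersects
    >= 1 unit interval), genes_with_snps (gene contains >= 1 SNP),
    snps_in_gene_regions (SNP position inside >= 1 gene).  A "Total" row
    sums the chromosomes.
    """
    from intervaltree import IntervalTree

    unit_trees: dict[str, IntervalTree] = {}
    for u in units:
        unit_trees.setdefault(u.chromosome, IntervalTree()).addi(
            u.interval[0], u.interval[1] + 1
        )
    gene_trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _gid in annotation.genes:
        gene_trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)

    chroms = sorted(
        {m.chromosome for m in markers}
        | {u.chromosome for u in units}
        | {g[0] for g in annotation.genes}
    )
    rows = []
    for chrom in chroms:
        snps = [m for m in markers if m.chromosome == chrom]
        n_snps = len(snps)
        utree = unit_trees.get(chrom)
        gtree = gene_trees.get(chrom)
        genes_here = [g for g in annotation.genes if g[0] == chrom]
        genes_seq = sum(
            1 for _, s, e, _gid in genes_here if utree and utree.overlap(s, e + 1)
        )
        genes_snp = sum(
            1
            for _, s, e, _gid in genes_here
            if any(s <= m.position <= e for m in snps)
        )
        snps_gene = sum(1 for m in snps if gtree and gtree.overlap(m.position, m.position + 1))
        rows.append(
            {
                "chrom": chrom,
                "snps": n_snps,
                "genes_in_sequenced_regions": genes_seq,
                "genes_with_snps": genes_snp,
                "snps_in_gene_regions": snps_gene,
            }
        )
    df = pd.DataFrame(rows)
    total = df.drop(columns="chrom").sum()
    total["chrom"] = "Total"
    return pd.concat([df, total.to_frame().T], ignore_index=True)[
        ["chrom", "snps", "genes_in_sequenced_regions", "genes_with_snps",
         "snps_in_gene_regions"]
    ]


def write_sites_bed(sites: list[CutSite], motif_len: int, path: str | Path) -> None:
    """Cut sites as BED (0-based half-open on write)."""
    with open(path, "w") as fh:
        for s in sites:
            cls = s.region_class or "."
            fh.write(f"{s.chromosome}\t{s.motif_start - 1}\t"
                     f"{s.motif_start - 1 + motif_len}\t{cls}\n")


def units_table(units: list[SequencingUnit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "chrom": [u.chromosome for u in units],
            "cut_pos": [u.cut_site.motif_start for u in units],
            "start": [u.interval[0] for u in units],
            "end": [u.interval[1] for u in units],
            "n_snps": [len(u.snp_indices) for u in units],
        }
    )
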