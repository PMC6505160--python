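"""Headline ratios, summary-table writers and the pipeline orchestrator.

Percentages follow the printed-table style: 100·num/den rounded half-up
to two decimals, always re-derivable from the integer counts written in
the same file.  ``run_pipeline`` chains the stages in the analysis
order — digestion → units → presence/MAF filters → redundancy pruning →
diversity/differentiation → LD — writing tab-separated tables, a
machine-readable config echo and a log, deterministically for a given
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .filtering import FilterConfig, filter_markers, missingness_report, prune_redundant
from .io import read_annotation, read_genotypes, read_popmap
from .popgen import allele_sharing_distance, amova, diversity_table, mantel_ibd, pairwise_fst, pca

logger = logging.getLogger(__name__)


def proportion_report(numerator: int, denominator: int, label: str | None = None) -> float:
    """100·numerator/denominator, rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    val = float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    if label:
        logger.info("%s: %.2f%% (%d of %d)", label, val, numerator, denominator)
    return val


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    genotypes: str
    out_dir: str
    popmap: str | None = None
    fasta: str | None = None
    gff: str | None = None
    het_bed: str | None = None
    motif: str = "CTGCAG"
    read_span: int = 93
    min_presence_fraction: float = 75 / 99
    min_maf: float = 0.05
    prune: bool = True
    ld_window_bp: int = 1_000_000
    ld_baseline: float = 0.1
    n_permutations: int = 999
    n_boot: int = 0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extras"}
        d["version"] = __version__
        return d


def run_pipeline(config: RunConfig) -> Path:
    """Run every applicable stage and write its report under ``out_dir``.

    Stages needing absent inputs (e.g. no FASTA → no digestion/unit/LD
    profile stage; no popmap → no differentiation stage) are skipped with
    a log line.  Returns the output directory.
    """
    from .ld import default_sample_chromosomes, fit_decay, local_ld_profile, windowed_ld
    from .rad import build_units, classify_sites, digest_genome, overlap_report, units_table

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    (out / "config.json").write_text(json.dumps(config.echo(), indent=2) + "\n")
    logger.info("radpop %s seed=%d", __version__, config.seed)

    gm = read_genotypes(config.genotypes)
    stage_counts = {"input": gm.n_markers}

    fc = FilterConfig(
        min_presence_fraction=config.min_presence_fraction, min_maf=config.min_maf
    )
    gm, removal_log = filter_markers(gm, fc)
    stage_counts["after_presence_maf"] = gm.n_markers
    removal_log.to_csv(out / "filter_log.tsv", sep="\t", index=False)
    missingness_report(gm).to_csv(out / "missingness.tsv", sep="\t", index=False)

    units = None
    if config.fasta:
        sites = digest_genome(config.fasta, config.motif)
        annotation = read_annotation(config.gff, config.het_bed)
        sites, class_counts = classify_sites(sites, annotation)
        eu, het = class_counts["euchromatin"], class_counts["heterochromatin"]
        pd.DataFrame(
            [
                ("euchromatin", eu, proportion_report(eu, eu + het)),
                ("heterochromatin", het, proportion_report(het, eu + het)),
            ],
            columns=["region_class", "n_sites", "pct"],
        ).to_csv(out / "site_classes.tsv", sep="\t", index=False)
        units, unassigned = build_units(sites, gm.markers, config.read_span)
        units_table(units).to_csv(out / "units.tsv", sep="\t", index=False)
        if annotation.genes:
            overlap_report(units, gm.markers, annotation).to_csv(
                out / "overlap_report.tsv", sep="\t", index=False
            )
        logger.info(
            "digestion: %d sites, %d units, %d unit-less SNPs",
            len(sites), len(units), len(unassigned),
        )
        if config.prune:
            gm, _ = prune_redundant(gm)
            stage_counts["after_redundancy_pruning"] = gm.n_markers
    pd.DataFrame(
        list(stage_counts.items()), columns=["stage", "n_markers"]
    ).to_csv(out / "stage_counts.tsv", sep="\t", index=False)

    popmap = read_popmap(config.popmap) if config.popmap else None
    if popmap is not None:
        diversity_table(gm, popmap).table.to_csv(
            out / "diversity.tsv", sep="\t", index=False
        )
        fst = pairwise_fst(gm, popmap, n_boot=config.n_boot, seed=config.seed)
        fst.matrix().to_csv(out / "fst_matrix.tsv", sep="\t")
        res = amova(gm, popmap, n_permutations=config.n_permutations, seed=config.seed)
        res.summary().assign(p_value=res.p_value).to_csv(
            out / "amova.tsv", sep="\t", index=False
        )
        scores, pct = pca(gm, n_components=min(10, gm.n_accessions - 1))
        scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pd.DataFrame({"component": scores.columns, "pct_variance": pct}).to_csv(
            out / "pca_variance.tsv", sep="\t", index=False
        )
        if popmap.coordinates is not None:
            coords = popmap.coordinates.loc[gm.accession_ids]
            r, p = mantel_ibd(
                allele_sharing_distance(gm), coords,
                n_permutations=config.n_permutations, seed=config.seed,
            )
            pd.DataFrame({"statistic": ["mantel_r", "p_value"], "value": [r, p]}).to_csv(
                out / "ibd.tsv", sep="\t", index=False
            )

    pairs = windowed_ld(gm, window_bp=config.ld_window_bp)
    pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
    if len(pairs) >= 10:
        fit = fit_decay(pairs, n=default_sample_chromosomes(pairs),
                        baseline=config.ld_baseline)
        pd.DataFrame(
            {
                "quantity": ["rho_per_bp", "n_chromosomes", "baseline",
                             "decay_distance_bp", "n_pairs"],
                "value": [fit.rho, fit.n, fit.baseline,
                          fit.decay_distance_bp, fit.n_pairs],
            }
        ).to_csv(out / "ld_decay.tsv", sep="\t", index=False)
    if units:
        profile = local_ld_profile(gm, units, baseline=config.ld_baseline)
        profile.records.to_csv(out / "local_ld_profile.tsv", sep="\t", index=False)
        profile.tallies.to_csv(out / "local_ld_summary.tsv", sep="\t", index=False)
    return out


def write_table1_style(report: pd.DataFrame, path: str | Path) -> None:
    """Marker/gene overlap summary in the published column layout."""
    report.rename(
        columns={
            "chrom": "Chr.",
            "snps": "SNPs",
            "genes_in_sequenced_regions": "Genes in sequenced regions",
            "genes_with_snps": "Genes with SNPs",
            "snps_in_gene_regions": "SNPs in gene regions",
        }
    ).to_csv(path, sep="\t", index=False)


def write_table3_style(tallies: pd.DataFrame, decay_kb: dict[str, float], path: str | Path) -> None:
    """Local-LD summary layout: per-chromosome decay distance (kb) and the
    >= / < baseline tallies with the proportion column."""
    df = tallies.copy()
    df.insert(1, "ld_decay_kb", [decay_kb.get(c, np.nan) for c in df["chrom"]])
    df.to_csv(path, sep="\t", index=False)
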