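"""Marker-retention filters and sequencing-unit redundancy pruning.

The retention pipeline mirrors the usual reduced-representation
workflow: a presence (call-rate) filter, then a minor-allele-frequency
filter, then removal of redundant SNPs — SNPs in complete LD (r² = 1)
with an earlier SNP of the same sequencing unit, keeping the first.
Each stage is logged so surviving counts can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .ld import r2_pair

logger = logging.getLogger(__name__)

#: r² within this distance of 1 counts as complete LD for pruning
COMPLETE_LD_TOL = 1e-9


@dataclass
class FilterConfig:
    """Default thresholds: presence in at least 75 of 99 accessions and
    minor allele frequency >= 0.05; redundancy pruned at r² = 1."""

    min_presence_fraction: float = 75 / 99
    min_maf: float = 0.05
    redundancy_r2: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.min_presence_fraction <= 1:
            raise ValueError("min_presence_fraction must be in (0, 1]")
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")


def allele_frequency(gm: GenotypeMatrix, marker_index: int) -> tuple[float, int]:
    """(alt-allele frequency, number of called individuals) at one marker.

    An all-missing marker returns (nan, 0).
    """
    col = gm.dosage[:, marker_index]
    called = col != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        return float("nan"), 0
    return float(col[called].sum() / (2 * n_called)), n_called


def allele_frequencies(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised alt frequency and call count for every marker."""
    called = gm.dosage != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2 * np.maximum(n_called, 1)), np.nan)
    return freq, n_called


def filter_markers(
    gm: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the presence filter, then the MAF filter.

    Keeps a marker iff n_called/N >= min_presence_fraction and
    MAF >= min_maf; marker order is preserved.  Returns the filtered
    matrix and a removal log (chrom, pos, stage, reason) with one row per
    dropped marker.
    """
    config = config or FilterConfig()
    freq, n_called = allele_frequencies(gm)
    presence = n_called / gm.n_accessions
    maf = np.minimum(freq, 1 - freq)

    keep = np.ones(gm.n_markers, dtype=bool)
    log_rows = []
    # stage order matters: presence first, MAF judged on survivors only
    low_presence = presence < config.min_presence_fraction
    for j in np.flatnonzero(low_presence):
        m = gm.markers[j]
        log_rows.append(
            (m.chromosome, m.position, "presence",
             f"called {n_called[j]}/{gm.n_accessions} < "
             f"{config.min_presence_fraction:.4f}")
        )
    keep &= ~low_presence
    low_maf = keep & ~(maf >= config.min_maf)  # NaN MAF (all-missing) drops too
    for j in np.flatnonzero(low_maf):
        m = gm.markers[j]
        reason = "undefined (no calls)" if n_called[j] == 0 else \
            f"MAF {maf[j]:.4f} < {config.min_maf}"
        log_rows.append((m.chromosome, m.position, "maf", reason))
    keep &= ~low_maf

    logger.info(
        "filter_markers: %d -> %d after presence -> %d after MAF",
        gm.n_markers, int((~low_presence).sum()), int(keep.sum()),
    )
    if keep.sum() == 0:
        logger.warning("filter_markers: no markers survive")
    log = pd.DataFrame(log_rows, columns=["chrom", "pos", "stage", "reason"])
    return gm.select_markers(np.flatnonzero(keep)), log


def prune_redundant(
    gm: GenotypeMatrix, redundancy_r2: float = 1.0
) -> tuple[GenotypeMatrix, dict[int, list[int]]]:
    """Drop SNPs in complete LD with a retained SNP of the same unit.

    Within each sequencing unit (``unit_id`` on the markers, assigned by
    :func:`radpop.rad.build_units`), SNPs are scanned in ascending
    position; a SNP is dropped iff its r² against ANY already-retained
    SNP of the same unit equals ``redundancy_r2`` (within 1e-9).  The
    first SNP of a unit is always kept; unit-less SNPs are kept; SNPs in
    different units are never compared.  r² uses the EM estimate on
    pairwise-complete observations, so with missing data complete LD is
    not transitive — hence the greedy scan against retained SNPs only.

    Returns (pruned matrix, unit_id -> kept marker indices in the input).
    """
    by_unit: dict[int, list[int]] = {}
    for j, m in enumerate(gm.markers):
        if m.unit_id is not None:
            by_unit.setdefault(m.unit_id, []).append(j)

    keep = np.ones(gm.n_markers, dtype=bool)
    kept_per_unit: dict[int, list[int]] = {}
    for uid, idx in by_unit.items():
        idx = sorted(idx, key=lambda j: gm.markers[j].position)
        retained: list[int] = []
        for j in idx:
            redundant = False
            for k in retained:
                r2 = r2_pair(gm.dosage[:, k], gm.dosage[:, j])
                if not np.isnan(r2) and abs(r2 - redundancy_r2) <= COMPLETE_LD_TOL:
                    redundant = True
                    break
            if redundant:
                keep[j] = False
            else:
                retained.append(j)
        kept_per_unit[uid] = retained
    logger.info("prune_redundant: %d -> %d markers", gm.n_markers, int(keep.sum()))
    return gm.select_markers(np.flatnonzero(keep)), kept_per_unit


def missingness_report(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-accession missing-call fraction, plus an overall-mean row."""
    frac = (gm.dosage == MISSING).mean(axis=1)
    df = pd.DataFrame(
        {"accession": gm.accession_ids, "missing_fraction": frac}
    )
    overall = pd.DataFrame(
        {"accession": ["__overall_mean__"], "missing_fraction": [float(frac.mean())]}
    )
    return pd.concat([df, overall], ignore_index=True)
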