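"""Genotype, annotation and population-map I/O.

The central in-memory object is :class:`GenotypeMatrix`: accessions ×
biallelic SNPs stored as alt-allele dosage (0, 1, 2) with a dedicated
``MISSING`` sentinel (-1).  Coordinates are 1-based inclusive throughout
(VCF/GFF convention); BED input is converted on read.  Phase in VCF ("|")
is read but discarded — every downstream statistic is defined on unphased
dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
"""Sentinel for an uncalled genotype.  Never conflated with dosage 0."""


class FormatError(ValueError):
    """Malformed file header or dialect."""


class RecordError(ValueError):
    """A single malformed/unsupported record (message names the record)."""


@dataclass
class MarkerInfo:
    """One biallelic SNP on the reference.

    ``unit_id`` is assigned later by sequencing-unit construction
    (:func:`radpop.rad.build_units`); ``None`` means unassigned.
    """

    chromosome: str
    position: int  # 1-based reference coordinate
    ref_allele: str
    alt_allele: str
    unit_id: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt alleles identical ({self.ref_allele}) at "
                f"{self.chromosome}:{self.position}"
            )


@dataclass
class GenotypeMatrix:
    """Accessions × markers alt-allele dosage matrix.

    dosage[i, j] is the number of alt alleles carried by accession i at
    marker j: 0, 1, 2 or MISSING (-1).  Markers are kept sorted by
    (chromosome, position); accession ids are unique.
    """

    accession_ids: list[str]
    markers: list[MarkerInfo]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.accession_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.accession_ids)}, {len(self.markers)})"
            )
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("accession ids are not unique")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise ValueError(f"invalid dosage values {bad.tolist()}")
        keys = [(m.chromosome, m.position) for m in self.markers]
        if keys != sorted(keys):
            # re-sort rather than reject: readers may deliver unsorted input
            idx = sorted(range(len(keys)), key=keys.__getitem__)
            self.markers = [self.markers[i] for i in idx]
            self.dosage = self.dosage[:, idx]

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([m.chromosome for m in self.markers], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position for m in self.markers], dtype=np.int64)

    def marker_frame(self) -> pd.DataFrame:
        """Marker metadata as a DataFrame (chrom, pos, ref, alt, unit_id)."""
        return pd.DataFrame(
            {
                "chrom": self.chromosomes,
                "pos": self.positions,
                "ref": [m.ref_allele for m in self.markers],
                "alt": [m.alt_allele for m in self.markers],
                "unit_id": [m.unit_id for m in self.markers],
            }
        )

    def select_markers(self, indices: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=np.intp)
        return GenotypeMatrix(
            list(self.accession_ids),
            [replace(self.markers[i]) for i in indices],
            self.dosage[:, indices].copy(),
        )

    def select_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        rows = [lookup[a] for a in ids]
        return GenotypeMatrix(
            list(ids), [replace(m) for m in self.markers], self.dosage[rows].copy()
        )


@dataclass
class PopulationMap:
    """Accession → subpopulation label, with optional ancestry fractions
    and geographic coordinates (decimal degrees)."""

    labels: dict[str, str]
    ancestry: pd.DataFrame | None = None  # accessions × ancestral components
    coordinates: pd.DataFrame | None = None  # columns lat, lon; index accession

    def __post_init__(self) -> None:
        if self.ancestry is not None:
            q = self.ancestry.to_numpy(float)
            if (q < 0).any():
                raise ValueError("ancestry fractions must be non-negative")
            if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("ancestry fractions must sum to 1 (±1e-6)")

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = set(self.labels) - set(gm.accession_ids)
        if missing:
            raise ValueError(f"labeled accessions absent from matrix: {sorted(missing)}")

    def groups(self, accession_ids: Iterable[str]) -> dict[str, list[str]]:
        """Label → accession ids, restricted and ordered to the given ids."""
        out: dict[str, list[str]] = {}
        for a in accession_ids:
            if a in self.labels:
                out.setdefault(self.labels[a], []).append(a)
        return out


@dataclass
class GenomeAnnotation:
    """Gene intervals and heterochromatin blocks, 1-based inclusive."""

    genes: list[tuple[str, int, int, str]] = field(default_factory=list)
    heterochromatin: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, *_ in [*self.genes, *self.heterochromatin]:
            if start < 1 or end < start:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
        self.heterochromatin = _merge_intervals(self.heterochromatin)

    def het_by_chrom(self) -> dict[str, np.ndarray]:
        """Merged heterochromatin intervals per chromosome as an (n, 2) array."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.heterochromatin:
            out.setdefault(chrom, []).append((s, e))
        return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


def _merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    merged: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2] + 1:
            merged[-1] = (chrom, merged[-1][1], max(e, merged[-1][2]))
        else:
            merged.append((chrom, s, e))
    return merged


# ---------------------------------------------------------------------------
# genotype readers / writers

def read_genotypes(path: str | Path, format: str = "auto") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the tab-separated dosage dialect.

    VCF: only the GT field is used; "./." and "." become MISSING; phase
    separators are ignored.  Multiallelic or non-SNP records raise
    :class:`RecordError`.  dosage_tsv: one row per marker
    (chrom, pos, ref, alt, one column per accession; 0/1/2/NA).
    """
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.samples)
    markers: list[MarkerInfo] = []
    columns: list[np.ndarray] = []
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise RecordError(
                f"record {i} ({rec.CHROM}:{rec.POS}) is not biallelic"
            )
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise RecordError(
                f"record {i} ({rec.CHROM}:{rec.POS}) is not a SNP"
            )
        markers.append(MarkerInfo(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        # gts012: 0/1/2 = dosage, 3 = uncalled
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        columns.append(gt)
    dosage = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, markers, dosage)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    expected = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != expected:
        raise FormatError(
            f"dosage_tsv must start with columns {expected}, got {list(df.columns[:4])}"
        )
    accessions = list(df.columns[4:])
    markers = [
        MarkerInfo(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    vals = df[accessions].to_numpy(dtype=float).T  # accession × marker
    dosage = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    return GenotypeMatrix(accessions, markers, dosage)


def write_genotypes(gm: GenotypeMatrix, path: str | Path, format: str = "auto") -> None:
    """Write VCF 4.2 (GT only) or dosage_tsv; round-trips exactly."""
    path = Path(path)
    if format == "auto":
        format = "vcf" if path.suffix == ".vcf" else "dosage_tsv"
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "dosage_tsv":
        _write_dosage_tsv(gm, path)
    else:
        raise ValueError(f"unknown format {format!r}")


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(m.chromosome for m in gm.markers):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accession_ids)
            + "\n"
        )
        for j, m in enumerate(gm.markers):
            gts = "\t".join(_GT[int(v)] for v in gm.dosage[:, j])
            fh.write(
                f"{m.chromosome}\t{m.position}\t.\t{m.ref_allele}\t"
                f"{m.alt_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def _write_dosage_tsv(gm: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(
        gm.dosage.T.astype(object), columns=gm.accession_ids
    ).mask(gm.dosage.T == MISSING, "NA")
    meta = gm.marker_frame().drop(columns="unit_id")
    pd.concat([meta, df], axis=1).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation and population map

def read_annotation(
    gff_path: str | Path | None, het_bed_path: str | Path | None = None
) -> GenomeAnnotation:
    """Load gene models (GFF3 "gene" features) and heterochromatin blocks
    (BED3, 0-based half-open, converted to 1-based inclusive)."""
    genes: list[tuple[str, int, int, str]] = []
    if gff_path is not None:
        import gffutils

        db = gffutils.create_db(
            str(gff_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        for feat in db.features_of_type("gene"):
            genes.append((feat.seqid, feat.start, feat.end, feat.id))
    het: list[tuple[str, int, int]] = []
    if het_bed_path is not None:
        bed = pd.read_csv(
            het_bed_path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
        )
        for r in bed.itertuples():
            if r.start < 0:
                raise ValueError(f"negative BED coordinate on {r.chrom}")
            het.append((str(r.chrom), int(r.start) + 1, int(r.end)))
    return GenomeAnnotation(genes=genes, heterochromatin=het)


def read_popmap(path: str | Path) -> PopulationMap:
    """Tab-separated population map: accession, label[, lat, lon]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "accession" not in cols or "label" not in cols:
        raise FormatError("popmap needs 'accession' and 'label' columns")
    labels = dict(zip(df["accession"], df["label"]))
    coords = None
    if {"lat", "lon"} <= set(cols):
        coords = (
            df.set_index("accession")[["lat", "lon"]].astype(float)
        )
    return PopulationMap(labels=labels, coordinates=coords)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    rows = {"accession": list(popmap.labels), "label": list(popmap.labels.values())}
    df = pd.DataFrame(rows)
    if popmap.coordinates is not None:
        df = df.merge(
            popmap.coordinates, left_on="accession", right_index=True, how="left"
        )
    df.to_csv(path, sep="\t", index=False)
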