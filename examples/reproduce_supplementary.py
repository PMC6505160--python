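"""Reproduce the collection-wide statistics from the deposited data.

The deposited inputs are NOT redistributed here; download them first:

* the supplementary genotype matrix (24,330 biallelic SNPs x ~98
  accessions) and accession metadata (subpopulation assignment,
  coordinates) from the study's Figshare deposit,
* the SL2.50 tomato reference FASTA, the ITAG2.4 gene-model GFF3 and a
  heterochromatin BED (EXPIM 2012 genetic-map assignment) if the
  digestion/unit stages are wanted.

Convert the genotype spreadsheet to the dosage_tsv dialect
(chrom, pos, ref, alt, one column per accession, values 0/1/2/NA) and
the metadata to a popmap TSV (accession, label[, lat, lon]), then:

    python examples/reproduce_supplementary.py \
        --genotypes data/external/table_s3_dosage.tsv \
        --popmap data/external/table_s1_popmap.tsv \
        [--fasta data/external/SL2.50.fa --gff ... --het-bed ...]

Computes: overall/per-subpopulation Ho and Hs, pairwise Fst, AMOVA
percent-variance-among with permutation p, and (with the genome inputs)
sequencing units, redundancy-pruned marker count, the 1-Mb windowed r²
table, the genome-wide and per-chromosome Hill–Weir decay distances at
baseline r² = 0.1, and the consecutive-unit local LD summary.
"""

import argparse
from pathlib import Path

import radpop as rp
from radpop.ld import default_sample_chromosomes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genotypes", required=True, type=Path)
    ap.add_argument("--popmap", required=True, type=Path)
    ap.add_argument("--fasta", type=Path)
    ap.add_argument("--gff", type=Path)
    ap.add_argument("--het-bed", type=Path)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--permutations", type=int, default=999)
    args = ap.parse_args()

    gm = rp.read_genotypes(args.genotypes)
    popmap = rp.read_popmap(args.popmap)
    print(f"{gm.n_accessions} accessions x {gm.n_markers} markers")

    div = rp.diversity_table(gm, popmap).table
    print("\nDiversity (compare the pooled row to the published "
          "Ho = 0.0761, Hs = 0.2786):")
    print(div.round(4).to_string(index=False))

    res = rp.amova(gm, popmap, n_permutations=args.permutations, seed=args.seed)
    print(f"\nAMOVA percent among subpopulations: {res.percent_among:.2f}% "
          f"(published: 41.96%), p = {res.p_value:.4g}")

    fst = rp.pairwise_fst(gm, popmap, n_boot=0, seed=args.seed)
    print("\nPairwise Fst matrix:")
    print(fst.matrix().round(4).to_string())

    if popmap.coordinates is not None:
        r, p = rp.mantel_ibd(
            rp.allele_sharing_distance(gm),
            popmap.coordinates.loc[gm.accession_ids],
            n_permutations=args.permutations, seed=args.seed,
        )
        print(f"\nMantel IBD r = {r:.2f} (published: 0.34), p = {p:.4g}")

    if args.fasta is None:
        print("\n(no --fasta: skipping digestion, pruning and LD stages)")
        return

    sites = rp.digest_genome(args.fasta, "CTGCAG")
    print(f"\n{len(sites)} PstI sites in the reference "
          f"(published for SL2.50: 82,814)")
    if args.het_bed:
        ann = rp.read_annotation(args.gff, args.het_bed)
        sites, counts = rp.classify_sites(sites, ann)
        pct = rp.proportion_report(counts["euchromatin"], len(sites))
        print(f"{pct}% of sites euchromatic")

    units, unassigned = rp.build_units(sites, gm.markers, read_span=93)
    print(f"{len(units)} sequencing units; {len(unassigned)} unit-less SNPs")
    pruned, _ = rp.prune_redundant(gm)
    print(f"redundancy pruning: {gm.n_markers} -> {pruned.n_markers} "
          f"(published: 24,330 -> 19,993)")

    pairs = rp.windowed_ld(gm, window_bp=1_000_000)
    n_chrom = default_sample_chromosomes(pairs)
    fit = rp.fit_decay(pairs, n=n_chrom, baseline=0.1)
    dd = fit.decay_distance_bp
    print(f"\noverall decay distance: "
          + (f"{dd / 1000:.0f} kb" if dd else "not reached")
          + " (published: 18 kb)")
    for chrom in sorted(set(pairs.chrom)):
        sub = pairs[pairs.chrom == chrom]
        if len(sub) < 10:
            continue
        f = rp.fit_decay(sub, n=n_chrom, baseline=0.1)
        d = f.decay_distance_bp
        print(f"  {chrom}: " + (f"{d / 1000:.0f} kb" if d else "not reached"))

    profile = rp.local_ld_profile(gm, units, baseline=0.1)
    print("\nConsecutive-unit local LD summary "
          "(published total: 4,698 / 8,304 / 36.13%):")
    print(profile.tallies.to_string(index=False))


if __name__ == "__main__":
    main()
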