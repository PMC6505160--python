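"""Marker retention: presence filter, MAF filter, redundancy pruning.

The filters mirror a reduced-representation workflow: a SNP must be
called in at least 75/99 of the accessions, its minor allele frequency
must reach 0.05, and within one sequencing unit SNPs in complete LD
(r² = 1) with an earlier SNP are dropped (only the first is kept).
"""

import radpop as rp

gm, _, _ = rp.simulate_structured_population(
    rp.SimParams(seed=11, K=2, F=0.15, n_per_pop=30, n_loci=500,
                 missing_rate=0.15)
)
print(f"input: {gm.n_markers} markers, {gm.n_accessions} accessions")

filtered, log = rp.filter_markers(
    gm, rp.FilterConfig(min_presence_fraction=0.8, min_maf=0.05)
)
by_stage = log.groupby("stage").size()
print(f"after presence+MAF: {filtered.n_markers} "
      f"(dropped: {by_stage.to_dict()})")

# duplicate a few columns into shared units to show pruning
for j, m in enumerate(filtered.markers):
    m.unit_id = j // 4
dup = filtered.dosage.copy()
dup[:, 1::4] = dup[:, 0::4][:, : dup[:, 1::4].shape[1]]  # clone unit-mates
gm2 = rp.GenotypeMatrix(filtered.accession_ids, filtered.markers, dup)
pruned, kept = rp.prune_redundant(gm2)
print(f"after redundancy pruning: {pruned.n_markers} markers "
      f"(every cloned unit-mate at r²=1 removed, first SNP kept)")

miss = rp.missingness_report(pruned)
overall = miss[miss.accession == "__overall_mean__"]["missing_fraction"].iloc[0]
print(f"mean missingness per accession: {100 * overall:.2f}%")
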