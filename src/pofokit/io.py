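"""Text-format export of simulated cohorts.

One phased VCF per chromosome (pipe-separated GT), separate VCFs for the X
chromosome and mtDNA, metadata and truth parent-of-origin TSVs, and the
4-column genetic-map TSV.  These mirror the shapes a real cohort analysis
would consume.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simkit import MALE, SimCohort

__all__ = ["write_cohort", "write_vcf"]

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path, chrom: str, positions, sample_ids, haplotype_rows,
              haploid: set | None = None) -> None:
    """Minimal phased VCF; ``haplotype_rows[i]`` is (2, n_sites) for sample i
    (or (1, n_sites)/-1-padded for haploid samples listed in ``haploid``)."""
    haploid = haploid or set()
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("##contig=<ID=%s>\n" % chrom)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for j, pos in enumerate(positions):
            gts = []
            for sid, haps in zip(sample_ids, haplotype_rows):
                if sid in haploid:
                    gts.append(str(int(haps[-1][j])))
                else:
                    gts.append(f"{int(haps[0][j])}|{int(haps[1][j])}")
            fh.write(
                f"{chrom}\t{int(pos)}\t{chrom}:{int(pos)}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def write_cohort(cohort: SimCohort, outdir) -> None:
    """Write VCFs, metadata, truth-PofO and map files for a cohort."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ids = cohort.genotyped_iids()
    rows_idx = [cohort.index(i) for i in ids]
    for chrom in cohort.chromosomes:
        write_vcf(out / f"chr{chrom}.vcf", chrom, cohort.positions[chrom],
                  ids, [cohort.obs[chrom][i] for i in rows_idx])
    males = {i for i in ids if cohort.sex(i) == MALE}
    write_vcf(out / "chrX.vcf", "X", cohort.x_positions, ids,
              [cohort.x_truth[i] for i in rows_idx], haploid=males)
    write_vcf(out / "chrMT.vcf", "MT",
              range(1, cohort.mt.shape[1] + 1), ids,
              [cohort.mt[i:i + 1] for i in rows_idx], haploid=set(ids))
    meta = cohort.meta[cohort.meta["iid"].isin(ids)]
    meta[["iid", "sex", "age"]].to_csv(out / "metadata.tsv", sep="\t",
                                       index=False)
    truth_rows = []
    for iid in ids:
        for chrom in cohort.chromosomes:
            truth_rows.append((iid, chrom, 0, "P"))
            truth_rows.append((iid, chrom, 1, "M"))
    pd.DataFrame(truth_rows, columns=["iid", "chrom", "hap_index", "parent"]
                 ).to_csv(out / "truth_pofo.tsv", sep="\t", index=False)
    cohort.gmap.to_tsv(out / "genetic_map.tsv")
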