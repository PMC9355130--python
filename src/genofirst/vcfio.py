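"""VCF v4.2 input/output for the per-source genotype matrices.

Writing goes through pysam (one uncompressed VCF per source, GRCh37
1-based coordinates); reading goes through cyvcf2.  Only records whose
FILTER is PASS or "." enter QC, and "./." genotypes are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .domain import GenotypeMatrix


def write_vcf(matrix: GenotypeMatrix, loci: pd.DataFrame, path: str) -> None:
    """Write one source matrix as an uncompressed VCF.

    ``loci`` maps variant_id -> (chrom, pos, ref, alt); variants absent from
    it are skipped.  Genotypes are unphased diploid GT calls.
    """
    loci = loci.set_index("variant_id") if "variant_id" in loci.columns else loci
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(f"##source=genofirst:{matrix.source}")
    for chrom in dict.fromkeys(loci.chrom.astype(str)):
        header.contigs.add(chrom)
    for sid in matrix.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(path, "w", header=header) as out:
        for vid in matrix.variant_ids:
            if vid not in loci.index:
                continue
            row = loci.loc[vid]
            i = matrix.variant_index(vid)
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                alleles=(str(row.ref), str(row.alt)),
                id=vid,
            )
            rec.filter.add("PASS")
            g = matrix.genotypes[i]
            for j, sid in enumerate(matrix.sample_ids):
                if g[j] < 0:
                    rec.samples[sid]["GT"] = (None, None)
                elif g[j] == 0:
                    rec.samples[sid]["GT"] = (0, 0)
                elif g[j] == 1:
                    rec.samples[sid]["GT"] = (0, 1)
                else:
                    rec.samples[sid]["GT"] = (1, 1)
            out.write(rec)


def read_vcf(path: str, source: str) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix, honoring the FILTER column."""
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    variant_ids: list[str] = []
    chroms: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if rec.FILTER is not None and rec.FILTER != "PASS":
            continue  # cyvcf2 reports PASS and "." as None/"PASS"
        gts = rec.genotype.array()  # (n_samples, ploidy+1)
        alleles = gts[:, :2]
        code = np.where(
            (alleles < 0).any(axis=1), -1, np.clip(alleles, 0, 1).sum(axis=1)
        ).astype(np.int8)
        variant_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        rows.append(code)
    vcf.close()
    geno = (
        np.vstack(rows) if rows else np.empty((0, len(sample_ids)), dtype=np.int8)
    )
    return GenotypeMatrix(
        source=source,
        variant_ids=variant_ids,
        chroms=chroms,
        sample_ids=sample_ids,
        genotypes=geno,
    )
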