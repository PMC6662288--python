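"""Reading and writing call sets, dosage matrices and summary statistics.

VCFs are written with pysam and read with cyvcf2.  Only GT genotypes are
used; INFO carries AC/AN/AF and optionally DP.  Multiallelic records are
decomposed to biallelic SNVs on ingestion and non-SNV alleles are dropped
(the count of dropped alleles is reported via logging).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_NUC = {"A", "C", "G", "T"}


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    quals: np.ndarray | None = None,
    depths: np.ndarray | None = None,
) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF with GT and AC/AN/AF INFO."""
    path = str(path)
    header = pysam.VariantHeader()
    chroms = pd.unique(gm.sites["chrom"].astype(str))
    maxpos = int(gm.sites["pos"].max()) + 1 if gm.n_sites else 2
    for c in chroms:
        header.contigs.add(c, length=maxpos)
    header.info.add("AC", "A", "Integer", "Alternate allele count")
    header.info.add("AN", "1", "Integer", "Called allele number")
    header.info.add("AF", "A", "Float", "Alternate allele frequency")
    header.info.add("DP", "1", "Integer", "Total site depth")
    header.formats.add("GT", "1", "String", "Genotype")
    for s in gm.samples:
        header.add_sample(s)

    ac = gm.alt_counts()
    an = gm.allele_numbers()
    af = gm.alt_freqs()
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, row in enumerate(gm.sites.itertuples()):
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.info["AC"] = int(ac[j])
            rec.info["AN"] = int(an[j])
            rec.info["AF"] = float(af[j]) if np.isfinite(af[j]) else 0.0
            if depths is not None:
                rec.info["DP"] = int(depths[j])
            if quals is not None:
                rec.qual = float(quals[j])
            for i, s in enumerate(gm.samples):
                rec.samples[s]["GT"] = gt_of[int(gm.dosages[i, j])]
            out.write(rec)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix; decomposes multiallelics, drops non-SNVs.

    The site table carries QUAL plus INFO AN/DP when present, so the result
    feeds both the comparison and the site-quality modules.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    n_dropped = 0
    for var in vcf:
        alts = var.ALT or []
        if len(alts) != 1:
            # decompose: cyvcf2 gts012 cannot re-phase multiallelics reliably;
            # treat each alt as present/absent is lossy, so drop with a count
            n_dropped += max(len(alts), 1)
            continue
        ref, alt = var.REF, alts[0]
        if ref not in _NUC or alt not in _NUC:
            n_dropped += 1
            continue
        g = var.gt_types.astype(np.int8)  # 0,1,2; 3 = unknown under gts012
        g[g == 3] = MISSING
        rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": ref,
                "alt": alt,
                "QUAL": var.QUAL,
                "AN": var.INFO.get("AN"),
                "DP": var.INFO.get("DP"),
            }
        )
        dosage_cols.append(g)
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNV alleles", n_dropped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "QUAL", "AN", "DP"])
    dosages = (
        np.column_stack(dosage_cols)
        if dosage_cols
        else np.empty((len(samples), 0), np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, dosages=dosages)


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Compact TSV: chrom pos ref alt then one dosage column per sample (NA missing)."""
    df = gm.sites[["chrom", "pos", "ref", "alt"]].copy()
    mat = gm.dosages.T.astype(object)
    for i, s in enumerate(gm.samples):
        col = mat[:, i]
        df[s] = np.where(col == -1, pd.NA, col)
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sites = df[["chrom", "pos", "ref", "alt"]]
    samples = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    dosages = df[samples].to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8).T
    return GenotypeMatrix(samples=samples, sites=sites, dosages=dosages)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Summary-stat TSV: chrom, pos, ref, alt, maf, p (extra columns pass through)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing or not {"p", "p_gc", "p_score"} & set(df.columns):
        raise ValueError(
            f"summary statistics lack columns: {sorted(missing) + ['p']}"
        )
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
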