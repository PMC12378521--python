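"""File I/O and marker/individual quality control.

Genotypes travel as VCF v4.2 (biallelic SNPs, GT field), phenotypes as a
two-column TSV (``sample_id``, ``value``), marker panels as one
``chrom:pos:id`` key per line.  QC applies, in order: individual call rate,
genotype (per-SNP) call rate, minor-allele frequency — the standard
pre-association filters — then mean-genotype imputation of whatever
missingness survives.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .containers import GenomeLayout, GenotypeMatrix, PhenotypeSet, SnpKey

__all__ = [
    "QcThresholds",
    "QcReport",
    "read_vcf",
    "write_vcf",
    "apply_qc",
    "read_phenotypes",
    "write_phenotypes",
    "read_snp_list",
    "write_snp_list",
]


@dataclass(frozen=True)
class QcThresholds:
    """Filtering thresholds; an entity is removed when its statistic falls
    strictly below the threshold (``maf < min_maf`` removes, ``== min_maf``
    is retained)."""

    min_individual_call_rate: float = 0.9
    min_genotype_call_rate: float = 0.9
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        for v in (self.min_individual_call_rate, self.min_genotype_call_rate, self.min_maf):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass
class QcReport:
    """Counts removed per rule, in application order."""

    individuals_removed: int = 0
    snps_low_call_rate: int = 0
    snps_low_maf: int = 0
    genotypes_imputed: int = 0
    removed_sample_ids: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {
                "rule": ["individual_call_rate", "snp_call_rate", "snp_maf", "imputed_genotypes"],
                "removed": [
                    self.individuals_removed,
                    self.snps_low_call_rate,
                    self.snps_low_maf,
                    self.genotypes_imputed,
                ],
            }
        ).to_csv(path, sep="\t", index=False)


def read_vcf(path: str | os.PathLike, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF into a minor-allele-count matrix with a missingness mask.

    Indels and non-biallelic records are dropped.  Genotypes are oriented to
    the minor allele of the realized sample (computed on non-missing calls);
    a tie at frequency 0.5 keeps the ALT-count orientation.
    """
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    contig_lengths = {c: vf.header.contigs[c].length for c in vf.header.contigs}

    chroms: list[str] = []
    positions: dict[str, list[int]] = {}
    ids: dict[str, list[str]] = {}
    columns: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    seen: set[tuple[str, int]] = set()

    records = vf.fetch(region=region) if region else vf
    for rec in records:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            continue  # indel or non-biallelic
        key = (rec.chrom, rec.pos)
        if key in seen:
            raise ValueError(f"duplicate record at {rec.chrom}:{rec.pos}")
        seen.add(key)
        col = np.zeros(len(samples), dtype=np.int8)
        miss = np.zeros(len(samples), dtype=bool)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                miss[i] = True
            else:
                col[i] = sum(gt)
        if rec.chrom not in positions:
            chroms.append(rec.chrom)
            positions[rec.chrom] = []
            ids[rec.chrom] = []
        positions[rec.chrom].append(rec.pos)
        ids[rec.chrom].append(rec.id or f"{rec.chrom}_{rec.pos}")
        columns.append(col)
        masks.append(miss)
    vf.close()

    if not columns:
        raise ValueError(f"no biallelic SNPs found in {path}")

    values = np.column_stack(columns)
    mask = np.column_stack(masks)

    # minor-allele orientation on non-missing calls
    with np.errstate(invalid="ignore"):
        freq = np.where(mask, np.nan, values.astype(float))
        freq = np.nanmean(freq, axis=0) / 2.0
    flip = freq > 0.5
    values[:, flip] = 2 - values[:, flip]
    values[mask] = 0
    maf = np.where(flip, 1.0 - freq, freq)

    chrom_spec = tuple(
        (c, contig_lengths.get(c) or int(max(positions[c]))) for c in chroms
    )
    layout = GenomeLayout(
        chrom_spec,
        tuple(np.array(positions[c], dtype=np.int64) for c in chroms),
        tuple(tuple(ids[c]) for c in chroms),
    )
    return GenotypeMatrix(values=values, sample_ids=samples, layout=layout, maf=maf, mask=mask)


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the panel as VCF v4.2, GT only, REF=A / ALT=C placeholders.

    The minor allele is written as ALT, so ``read_vcf(write_vcf(x))``
    round-trips the count matrix and coordinates exactly.
    """
    header = pysam.VariantHeader()
    for name, length in genotypes.layout.chromosomes:
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in genotypes.sample_ids:
        header.add_sample(s)
    mask = genotypes.mask
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for j, key in enumerate(genotypes.keys()):
            rec = out.new_record(
                contig=key.chromosome,
                start=key.position - 1,  # pysam start is 0-based
                alleles=("A", "C"),
                id=key.id or None,
            )
            col = genotypes.values[:, j]
            for i, s in enumerate(genotypes.sample_ids):
                if mask is not None and mask[i, j]:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    g = int(col[i])
                    rec.samples[s]["GT"] = (1, 1) if g == 2 else ((0, 1) if g == 1 else (0, 0))
            out.write(rec)


def apply_qc(
    genotypes: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the standard pre-association filters, in order.

    1. drop individuals with marker call rate below the threshold;
    2. drop SNPs with genotype call rate (over remaining individuals)
       below the threshold;
    3. drop SNPs with minor-allele frequency (on non-missing calls)
       strictly below ``min_maf``;
    4. impute residual missing calls with the per-SNP mean genotype rounded
       to the nearest of {0, 1, 2}.

    The output panel is complete (``mask=None``) and minor-allele
    re-oriented.  Re-running QC on its own output is a no-op.
    """
    report = QcReport()
    mask = genotypes.mask
    if mask is None:
        mask = np.zeros_like(genotypes.values, dtype=bool)
    values = genotypes.values.copy()
    n, p = values.shape

    # 1. individual call rate
    ind_cr = 1.0 - mask.mean(axis=1)
    keep_ind = ind_cr >= thresholds.min_individual_call_rate
    report.individuals_removed = int((~keep_ind).sum())
    report.removed_sample_ids = [s for s, k in zip(genotypes.sample_ids, keep_ind) if not k]
    if not keep_ind.any():
        raise ValueError("QC removed all individuals")
    values = values[keep_ind]
    mask = mask[keep_ind]
    sample_ids = [s for s, k in zip(genotypes.sample_ids, keep_ind) if k]

    # 2. SNP call rate
    snp_cr = 1.0 - mask.mean(axis=0)
    keep_cr = snp_cr >= thresholds.min_genotype_call_rate
    report.snps_low_call_rate = int((~keep_cr).sum())

    # 3. MAF on non-missing calls of survivors
    with np.errstate(invalid="ignore"):
        freq = np.where(mask, np.nan, values.astype(float))
        freq = np.nanmean(freq, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = keep_cr & (maf >= thresholds.min_maf)
    report.snps_low_maf = int(keep_cr.sum() - keep_maf.sum())

    if not keep_maf.any():
        raise ValueError("QC removed all SNPs")
    keys = [k for k, kp in zip(genotypes.keys(), keep_maf) if kp]
    values = values[:, keep_maf]
    mask = mask[:, keep_maf]
    freq = freq[keep_maf]

    # 4. mean-genotype imputation, rounded to {0,1,2}
    report.genotypes_imputed = int(mask.sum())
    if mask.any():
        fill = np.clip(np.rint(2.0 * freq), 0, 2).astype(values.dtype)
        values = np.where(mask, fill[None, :], values)

    # re-orient minor allele on the complete matrix
    freq_full = values.mean(axis=0) / 2.0
    flip = freq_full > 0.5
    values[:, flip] = 2 - values[:, flip]
    maf_out = np.where(flip, 1.0 - freq_full, freq_full)

    layout = genotypes.layout.subset(keys)
    out = GenotypeMatrix(
        values=values, sample_ids=sample_ids, layout=layout, maf=maf_out, mask=None
    )
    return out, report


def read_phenotypes(path: str | os.PathLike, genotypes: GenotypeMatrix) -> PhenotypeSet:
    """Read a ``sample_id<TAB>value`` table and align it to the panel order.

    Errors on duplicated ids, ids absent from the panel, and panel samples
    without a phenotype.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "value" not in df.columns:
        raise ValueError("phenotype table must have columns: sample_id, value")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated sample id(s): {sorted(set(dup))}")
    table = dict(zip(df["sample_id"], df["value"].astype(float)))
    panel = set(genotypes.sample_ids)
    extra = sorted(set(table) - panel)
    if extra:
        raise ValueError(f"phenotype sample id(s) not in panel: {extra}")
    missing = sorted(panel - set(table))
    if missing:
        raise ValueError(f"panel sample(s) without phenotype: {missing}")
    y = np.array([table[s] for s in genotypes.sample_ids], dtype=float)
    return PhenotypeSet(sample_ids=list(genotypes.sample_ids), y=y)


def write_phenotypes(phenotypes: PhenotypeSet, path: str | os.PathLike) -> None:
    pd.DataFrame({"sample_id": phenotypes.sample_ids, "value": phenotypes.y}).to_csv(
        path, sep="\t", index=False
    )


def write_snp_list(keys: list[SnpKey], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for k in keys:
            fh.write(f"{k.chromosome}:{k.position}:{k.id}\n")


def read_snp_list(path: str | os.PathLike) -> list[SnpKey]:
    keys = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(":")
            if len(parts) < 2:
                raise ValueError(f"malformed snp key at line {line_no}: {line!r}")
            chrom, pos = parts[0], int(parts[1])
            snp_id = ":".join(parts[2:]) if len(parts) > 2 else ""
            keys.append(SnpKey(chrom, pos, snp_id))
    return keys
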