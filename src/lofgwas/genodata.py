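"""Genotype and binary-phenotype data model with I/O and filtering.

Genotype calls are integer codes counting copies of allele 1 (the VCF REF
allele): 2 = homozygous allele 1, 1 = heterozygous, 0 = homozygous allele 2,
``MISSING`` (-1) = no call.  Binary traits use 1 for the wild-type
(pigmented) phenotype and 0 for the loss-of-function phenotype, with
``MISSING`` for unscorable samples.  SNP identifiers follow the
``S{chromosome}_{position}`` convention with 1-based positions.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call or trait score.
MISSING = -1

_SNP_ID_RE = re.compile(r"^S(.+)_(\d+)$")
_VALID_CALLS = frozenset({0, 1, 2, MISSING})


def snp_id(chromosome: str, position: int) -> str:
    """Canonical SNP identifier, e.g. ``S4_61667908``."""
    return f"S{chromosome}_{position}"


def _chrom_sort_key(chrom: str):
    """Natural ordering: numeric chromosome labels sort numerically."""
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype calls with per-SNP genomic metadata.

    SNPs are kept sorted by (chromosome, position); construction sorts
    them if needed and validates codes and identifier uniqueness.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    calls: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)

        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match calls rows")
        for arr, name in [
            (self.snp_ids, "snp_ids"),
            (self.chromosome, "chromosome"),
            (self.position, "position"),
            (self.allele1, "allele1"),
            (self.allele2, "allele2"),
        ]:
            if len(arr) != m:
                raise ValueError(f"{name} length does not match calls columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate snp ids")
        if not np.isin(self.calls, (0, 1, 2, MISSING)).all():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        if m and (self.position <= 0).any():
            raise ValueError("positions must be positive")
        for sid, chrom, pos in zip(self.snp_ids, self.chromosome, self.position):
            match = _SNP_ID_RE.match(str(sid))
            if match and (match.group(1) != str(chrom) or int(match.group(2)) != pos):
                raise ValueError(
                    f"snp id {sid!r} inconsistent with chromosome {chrom!r} / position {pos}"
                )
        order = sorted(
            range(m), key=lambda j: (_chrom_sort_key(str(self.chromosome[j])), self.position[j])
        )
        if order != list(range(m)):
            self._reorder_snps(np.asarray(order))

    def _reorder_snps(self, order: np.ndarray) -> None:
        self.snp_ids = self.snp_ids[order]
        self.chromosome = self.chromosome[order]
        self.position = self.position[order]
        self.allele1 = self.allele1[order]
        self.allele2 = self.allele2[order]
        self.calls = self.calls[:, order]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency over non-missing calls (NaN if all missing)."""
        present = self.calls != MISSING
        n_alleles = 2.0 * present.sum(axis=0)
        count1 = np.where(present, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq1 = np.where(n_alleles > 0, count1 / n_alleles, np.nan)
        return np.minimum(freq1, 1.0 - freq1)

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids[index],
            snp_ids=self.snp_ids.copy(),
            chromosome=self.chromosome.copy(),
            position=self.position.copy(),
            calls=self.calls[index, :],
            allele1=self.allele1.copy(),
            allele2=self.allele2.copy(),
        )

    def take_snps(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids.copy(),
            snp_ids=self.snp_ids[mask_or_index],
            chromosome=self.chromosome[mask_or_index],
            position=self.position[mask_or_index],
            calls=self.calls[:, mask_or_index],
            allele1=self.allele1[mask_or_index],
            allele2=self.allele2[mask_or_index],
        )

    def snp_index(self, sid: str) -> int:
        hits = np.nonzero(self.snp_ids == sid)[0]
        if len(hits) == 0:
            raise KeyError(f"snp id {sid!r} not found")
        return int(hits[0])


@dataclass
class PhenotypeTable:
    """Per-sample binary trait: 1 wild-type, 0 loss-of-function, MISSING unscored."""

    sample_ids: np.ndarray
    trait: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.trait = np.asarray(self.trait, dtype=np.int8)
        if len(self.sample_ids) != len(self.trait):
            raise ValueError("sample_ids and trait lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.isin(self.trait, (0, 1, MISSING)).all():
            raise ValueError("trait values must be in {0, 1, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a :class:`GenotypeMatrix`.

    REF maps to allele 1 and ALT to allele 2, so a 0/0 genotype becomes
    code 2.  Multi-allelic and non-SNP records are skipped (count logged);
    a file with zero usable records is an error.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    nucleotides = {"A", "C", "G", "T"}

    columns, chroms, positions, a1, a2 = [], [], [], [], []
    skipped = 0
    for var in vcf:
        alts = var.ALT
        if (
            len(alts) != 1
            or var.REF not in nucleotides
            or alts[0] not in nucleotides
        ):
            skipped += 1
            continue
        codes = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2 or min(alleles) < 0:
                codes[i] = MISSING
            else:
                codes[i] = 2 - (alleles[0] + alleles[1])
        columns.append(codes)
        chroms.append(str(var.CHROM))
        positions.append(int(var.POS))
        a1.append(var.REF)
        a2.append(alts[0])
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    if not columns:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    calls = np.column_stack(columns)
    ids = [snp_id(c, p) for c, p in zip(chroms, positions)]
    return GenotypeMatrix(
        sample_ids=np.asarray(samples, dtype=object),
        snp_ids=np.asarray(ids, dtype=object),
        chromosome=np.asarray(chroms, dtype=object),
        position=np.asarray(positions, dtype=np.int64),
        calls=calls,
        allele1=np.asarray(a1, dtype=object),
        allele2=np.asarray(a2, dtype=object),
    )


_GT_STRINGS = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT field only) for the genotype matrix."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = []
        for chrom in g.chromosome:
            if chrom not in seen:
                seen.append(chrom)
        for chrom in seen:
            max_pos = int(g.position[g.chromosome == chrom].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.sample_ids)
            + "\n"
        )
        for j in range(g.n_snps):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{g.chromosome[j]}\t{g.position[j]}\t{g.snp_ids[j]}\t"
                f"{g.allele1[j]}\t{g.allele2[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

def write_snp_table(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the tab-separated SNP-matrix dialect (header of snp ids, NA missing)."""
    with Path(path).open("w") as fh:
        fh.write("sample\t" + "\t".join(str(s) for s in g.snp_ids) + "\n")
        for i in range(g.n_samples):
            row = "\t".join(
                "NA" if c == MISSING else str(int(c)) for c in g.calls[i, :]
            )
            fh.write(f"{g.sample_ids[i]}\t{row}\n")


def read_snp_table(path: str | Path) -> GenotypeMatrix:
    """Read the tabular dialect back into a :class:`GenotypeMatrix`.

    Chromosome and position are recovered from the ``S{chr}_{pos}`` header
    ids; allele labels are not represented in this dialect and default to
    A (allele 1) / C (allele 2).
    """
    path = Path(path)
    with path.open() as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header and at least one sample row")
    header = rows[0]
    width = len(header)
    ids = header[1:]
    chroms, positions = [], []
    for sid in ids:
        match = _SNP_ID_RE.match(sid)
        if not match:
            raise ValueError(f"{path}: snp id {sid!r} not in S{{chr}}_{{pos}} form")
        chroms.append(match.group(1))
        positions.append(int(match.group(2)))
    sample_ids, call_rows = [], []
    for row in rows[1:]:
        if len(row) != width:
            raise ValueError(f"{path}: ragged row for sample {row[0]!r}")
        sample_ids.append(row[0])
        codes = []
        for tok in row[1:]:
            if tok.upper() == "NA":
                codes.append(MISSING)
            elif tok in ("0", "1", "2"):
                codes.append(int(tok))
            else:
                raise ValueError(f"{path}: invalid genotype code {tok!r}")
        call_rows.append(codes)
    m = len(ids)
    return GenotypeMatrix(
        sample_ids=np.asarray(sample_ids, dtype=object),
        snp_ids=np.asarray(ids, dtype=object),
        chromosome=np.asarray(chroms, dtype=object),
        position=np.asarray(positions, dtype=np.int64),
        calls=np.asarray(call_rows, dtype=np.int8),
        allele1=np.asarray(["A"] * m, dtype=object),
        allele2=np.asarray(["C"] * m, dtype=object),
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read a two-column delimited (tab or comma) sample/score file.

    Scores must be 0, 1 or NA.  An optional header row names the trait.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        raise ValueError(f"{path}: empty phenotype file")
    delim = "\t" if "\t" in lines[0] else ","
    rows = [line.split(delim) for line in lines]
    trait_name = "trait"
    first_score = rows[0][1].strip() if len(rows[0]) > 1 else ""
    is_header = first_score.upper() != "NA"
    if is_header:
        try:
            float(first_score)
            is_header = False
        except ValueError:
            pass
    if is_header:
        trait_name = first_score or "trait"
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no sample rows")
    sample_ids, scores = [], []
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"{path}: expected two columns, got {row!r}")
        sid, tok = row[0].strip(), row[1].strip().upper()
        if tok == "NA":
            scores.append(MISSING)
        elif tok in ("0", "1"):
            scores.append(int(tok))
        else:
            raise ValueError(f"{path}: non-binary score {row[1]!r} for sample {sid!r}")
        sample_ids.append(sid)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample ids")
    return PhenotypeTable(
        sample_ids=np.asarray(sample_ids, dtype=object),
        trait=np.asarray(scores, dtype=np.int8),
        trait_name=trait_name,
    )


def write_phenotype_table(p: PhenotypeTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"sample\t{p.trait_name}\n")
        for sid, t in zip(p.sample_ids, p.trait):
            fh.write(f"{sid}\t{'NA' if t == MISSING else int(t)}\n")


def score_replicates(
    replicates: Mapping[str, Sequence[int]], trait_name: str = "trait"
) -> PhenotypeTable:
    """Collapse per-sample replicate scores (e.g. three seeds per accession).

    Unanimous replicates give that score; discordant (segregating)
    replicates give MISSING, dropping the sample from downstream analysis.
    """
    sample_ids, scores = [], []
    for sid, reps in replicates.items():
        reps = list(reps)
        if not reps:
            raise ValueError(f"sample {sid!r} has no replicate scores")
        if any(r not in (0, 1) for r in reps):
            raise ValueError(f"sample {sid!r} has non-binary replicate scores {reps!r}")
        sample_ids.append(sid)
        scores.append(reps[0] if len(set(reps)) == 1 else MISSING)
    return PhenotypeTable(
        sample_ids=np.asarray(sample_ids, dtype=object),
        trait=np.asarray(scores, dtype=np.int8),
        trait_name=trait_name,
    )


# ---------------------------------------------------------------------------
# Filtering / alignment / imputation
# ---------------------------------------------------------------------------

def filter_maf(g: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency below ``min_maf``.

    Frequencies are computed on non-missing calls.  With ``min_maf > 0``
    monomorphic SNPs (and SNPs with no calls at all) are always removed.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    if min_maf == 0.0:
        return g.take_snps(np.ones(g.n_snps, dtype=bool))
    maf = g.maf()
    keep = np.nan_to_num(maf, nan=-1.0) >= min_maf
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_maf: removed %d of %d SNPs below MAF %g", n_removed, g.n_snps, min_maf)
    return g.take_snps(keep)


def align_samples(
    g: GenotypeMatrix, p: PhenotypeTable
) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict both objects to shared samples with a non-missing trait.

    Output order follows the genotype matrix's sample order; both outputs
    share it exactly.
    """
    trait_by_id = dict(zip(p.sample_ids, p.trait))
    keep_idx = [
        i
        for i, sid in enumerate(g.sample_ids)
        if sid in trait_by_id and trait_by_id[sid] != MISSING
    ]
    common = set(g.sample_ids) & set(p.sample_ids)
    if not common:
        raise ValueError("no overlapping sample ids between genotypes and phenotypes")
    if not keep_idx:
        raise ValueError("all overlapping samples have missing trait")
    idx = np.asarray(keep_idx)
    g_out = g.take_samples(idx)
    trait = np.asarray([trait_by_id[sid] for sid in g_out.sample_ids], dtype=np.int8)
    p_out = PhenotypeTable(
        sample_ids=g_out.sample_ids.copy(), trait=trait, trait_name=p.trait_name
    )
    dropped = len(common) - len(keep_idx)
    if dropped:
        logger.info("align_samples: dropped %d shared samples with missing trait", dropped)
    return g_out, p_out


def impute_mean(g: GenotypeMatrix) -> np.ndarray:
    """Real-valued dosage matrix with missing calls replaced by per-SNP means.

    Only the linear-model engines consume these dosages; the LOF scan
    works on raw calls and never sees imputed values.
    """
    calls = g.calls.astype(np.float64)
    miss = g.calls == MISSING
    if not miss.any():
        return calls
    n_present = (~miss).sum(axis=0)
    all_missing = np.nonzero(n_present == 0)[0]
    if len(all_missing):
        raise ValueError(
            f"SNP {g.snp_ids[all_missing[0]]!r} has no non-missing calls; cannot impute"
        )
    calls[miss] = np.nan
    col_means = np.nanmean(calls, axis=0)
    rows, cols = np.nonzero(miss)
    calls[rows, cols] = col_means[cols]
    return calls
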