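"""Simulators for structured inbred panels and biparental RIL families.

The panel simulator reproduces the genetic architecture that makes
loss-of-function (LOF) traits hard to map with linear models in diverse
inbred panels:

* K subpopulations differentiated by the Balding-Nichols model, with
  fully inbred individuals (genotypes 0 or 2 only);
* a causal gene A carrying two or more independent LOF alleles, each
  confined to a shared, older "tag" haplotype of intermediate frequency,
  plus extra markers in imperfect LD with the tag -- the configuration
  that produces synthetic associations at the tag markers;
* an epistatic gene B on another chromosome whose LOF allele also
  abolishes the phenotype (complementary epistasis: any homozygous LOF
  genotype at A or B gives the LOF phenotype);
* configurable penetrance and phenocopy rate for the binary trait.

Default frequencies put the tag at panel MAF ~0.42 and the focal LOF
allele at ~0.23, the intermediate-vs-lower frequency contrast typical of
synthetic associations, with subpopulation gradients so the causal
alleles are themselves structured.  The default phenocopy rate (0.29)
represents LOF phenotypes caused by loci outside the simulated pair --
in real panels a large share of the LOF class carries wild-type alleles
at every mapped causal gene -- and brings the pooled LOF-phenotype
proportion to ~0.58, matching the composition of tannin panels in which
the focal allele explains well under half of the LOF class.

The RIL simulator produces an F_t biparental family by repeated selfing
with Haldane (no-interference) crossovers, retaining the residual
heterozygosity expected at F_t (half-life one generation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix, PhenotypeTable, snp_id

_NUCS = np.array(list("ACGT"))

# panel layout constants: causal/tag markers sit above the neutral range
_NEUTRAL_SPAN = 60_000_000
_GENEA_CHROM_IDX = 0
_GENEB_CHROM_IDX = 1
_TAG_POS = 61_600_000
_GENEB_POS = 61_500_000


@dataclass
class PanelSimConfig:
    """Study conditions for the structured association panel.

    ``lof_allele_freqs`` rows are gene-A LOF alleles (first row = focal
    allele), columns are subpopulations; values are frequencies
    *conditional on carrying the tag haplotype*, so LOF alleles can never
    occur on the non-tag background.
    """

    n_subpops: int = 4
    samples_per_subpop: tuple[int, ...] = (75, 75, 75, 75)
    n_neutral_snps: int = 20_000
    n_chromosomes: int = 10
    fst: float = 0.2
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    tag_freq_by_subpop: tuple[float, ...] = (0.60, 0.52, 0.36, 0.20)
    lof_allele_freqs: tuple[tuple[float, ...], ...] = (
        (0.70, 0.58, 0.45, 0.28),
        (0.28, 0.24, 0.18, 0.12),
    )
    geneB_lof_freq_by_subpop: tuple[float, ...] = (0.04, 0.08, 0.13, 0.19)
    n_tag_linked_snps: int = 5
    tag_ld_flip_prob: float = 0.05
    penetrance: float = 1.0
    phenocopy_rate: float = 0.29
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be positive")
        if len(self.samples_per_subpop) != self.n_subpops:
            raise ValueError("samples_per_subpop length must equal n_subpops")
        if any(s < 1 for s in self.samples_per_subpop):
            raise ValueError("samples_per_subpop must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes (genes A and B are unlinked)")
        if len(self.lof_allele_freqs) < 2:
            raise ValueError("gene A needs at least 2 loss-of-function alleles")
        for row in self.lof_allele_freqs:
            if len(row) != self.n_subpops:
                raise ValueError("each lof_allele_freqs row needs one entry per subpop")
        for arr in (self.tag_freq_by_subpop, self.geneB_lof_freq_by_subpop):
            if len(arr) != self.n_subpops:
                raise ValueError("per-subpop frequency vectors must match n_subpops")
            if any(not 0.0 <= v <= 1.0 for v in arr):
                raise ValueError("frequencies must be in [0, 1]")
        cond = np.asarray(self.lof_allele_freqs, dtype=float)
        if (cond < 0).any() or (cond.sum(axis=0) > 1.0 + 1e-12).any():
            raise ValueError("conditional LOF-allele frequencies must sum to <= 1 per subpop")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0, 1]")
        if not 0.0 <= self.phenocopy_rate < 1.0:
            raise ValueError("phenocopy_rate must be in [0, 1)")
        if self.penetrance <= self.phenocopy_rate:
            raise ValueError("penetrance must exceed phenocopy_rate")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_subpop))

    @property
    def n_lof_alleles(self) -> int:
        return len(self.lof_allele_freqs)


@dataclass
class TruthRecord:
    """Identities of the simulated causal and tag markers, for evaluation."""

    causal_snp_ids_geneA: list[str]
    causal_snp_id_geneB: str
    tag_snp_id: str
    tag_linked_snp_ids: list[str]
    sample_ids: np.ndarray | None = None
    is_lof_geneA: np.ndarray | None = None
    is_lof_geneB: np.ndarray | None = None

    @property
    def focal_snp_id(self) -> str:
        """The first gene-A LOF allele: the panel's tan1-a-like positive control."""
        return self.causal_snp_ids_geneA[0]

    def all_snp_ids(self) -> list[str]:
        return (
            list(self.causal_snp_ids_geneA)
            + [self.causal_snp_id_geneB, self.tag_snp_id]
            + list(self.tag_linked_snp_ids)
        )

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("role\tsnp_id\n")
            for sid in self.causal_snp_ids_geneA:
                fh.write(f"causal_geneA\t{sid}\n")
            fh.write(f"causal_geneB\t{self.causal_snp_id_geneB}\n")
            fh.write(f"tag\t{self.tag_snp_id}\n")
            for sid in self.tag_linked_snp_ids:
                fh.write(f"tag_linked\t{sid}\n")

    @classmethod
    def read(cls, path: str | Path) -> "TruthRecord":
        df = pd.read_csv(path, sep="\t")
        by_role = {r: df.loc[df["role"] == r, "snp_id"].tolist() for r in df["role"].unique()}
        return cls(
            causal_snp_ids_geneA=by_role.get("causal_geneA", []),
            causal_snp_id_geneB=by_role.get("causal_geneB", [""])[0],
            tag_snp_id=by_role.get("tag", [""])[0],
            tag_linked_snp_ids=by_role.get("tag_linked", []),
        )


def balding_nichols_freqs(
    p_ancestral, fst: float, n_subpops: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-subpopulation allele frequencies under the Balding-Nichols model.

    Each subpopulation draws from Beta(p(1-F)/F, (1-p)(1-F)/F), whose
    mean is p and variance F p (1-p).  F = 0 returns the ancestral
    frequency for every subpopulation.  Accepts a scalar or vector of
    ancestral frequencies; output shape is (len(p), n_subpops) or
    (n_subpops,) for scalar input.
    """
    p = np.atleast_1d(np.asarray(p_ancestral, dtype=np.float64))
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if fst == 0.0:
        out = np.repeat(p[:, None], n_subpops, axis=1)
    else:
        ratio = (1.0 - fst) / fst
        a = p * ratio
        b = (1.0 - p) * ratio
        out = rng.beta(a[:, None], b[:, None], size=(len(p), n_subpops))
    return out[0] if np.isscalar(p_ancestral) or np.ndim(p_ancestral) == 0 else out


def _unique_sorted_positions(rng: np.random.Generator, count: int, high: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, high, size=2 * count + 16))
    while len(pos) < count:  # pragma: no cover - vanishingly rare
        pos = np.unique(np.concatenate([pos, rng.integers(1, high, size=count)]))
    return np.sort(rng.choice(pos, size=count, replace=False))


def simulate_phenotype(
    is_lof_genotype: np.ndarray,
    penetrance: float,
    phenocopy_rate: float,
    rng: np.random.Generator,
    sample_ids=None,
    trait_name: str = "trait",
) -> PhenotypeTable:
    """Binary trait from the per-sample causal genotype summary.

    A LOF genotype (homozygous for any gene-A LOF allele or for the
    gene-B LOF allele) scores 0 with probability ``penetrance``;
    a wild-type genotype scores 0 with probability ``phenocopy_rate``.
    """
    is_lof = np.asarray(is_lof_genotype, dtype=bool)
    n = len(is_lof)
    if sample_ids is None:
        sample_ids = np.asarray([f"s{i}" for i in range(n)], dtype=object)
    p_zero = np.where(is_lof, penetrance, phenocopy_rate)
    trait = np.where(rng.random(n) < p_zero, 0, 1).astype(np.int8)
    return PhenotypeTable(
        sample_ids=np.asarray(sample_ids, dtype=object), trait=trait, trait_name=trait_name
    )


def simulate_panel(
    cfg: PanelSimConfig,
) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Simulate the structured panel with the synthetic-association architecture.

    Neutral SNPs: ancestral frequencies uniform on the configured MAF
    band (mirrored about 0.5), Balding-Nichols subpopulation frequencies,
    fully inbred genotypes 2*Bernoulli.  Gene A: a tag haplotype column,
    one column per LOF allele (present only on tag carriers, mutually
    exclusive by construction), and noisy copies of the tag column.
    Gene B: an independent LOF column on another chromosome.  Output is
    bit-reproducible for a given config.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    subpop = np.repeat(np.arange(cfg.n_subpops), cfg.samples_per_subpop)
    sample_ids = np.asarray(
        [f"P{k + 1}_{i + 1:03d}" for k, n_k in enumerate(cfg.samples_per_subpop) for i in range(n_k)],
        dtype=object,
    )

    # --- neutral background ---------------------------------------------
    m = cfg.n_neutral_snps
    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    flip = rng.random(m) < 0.5
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)
    freqs = balding_nichols_freqs(p_anc, cfg.fst, cfg.n_subpops, rng)  # (m, K)

    calls_neutral = np.empty((n, m), dtype=np.int8)
    for k in range(cfg.n_subpops):
        rows = subpop == k
        calls_neutral[rows] = 2 * (rng.random((int(rows.sum()), m)) < freqs[:, k])

    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(cfg.n_chromosomes):
        pos_c = _unique_sorted_positions(rng, int(per_chrom[c]), _NEUTRAL_SPAN)
        chroms.extend([str(c + 1)] * len(pos_c))
        positions.append(pos_c)
    positions = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)

    # --- gene A block: tag haplotype + LOF alleles + linked markers ------
    tag_freq = np.asarray(cfg.tag_freq_by_subpop)
    cond = np.asarray(cfg.lof_allele_freqs)  # (n_alleles, K)
    tag = rng.random(n) < tag_freq[subpop]
    # partition tag carriers among LOF alleles (or the functional tag background)
    u = rng.random(n)
    cum = np.cumsum(cond, axis=0)  # (n_alleles, K)
    allele_idx = np.full(n, -1, dtype=np.int64)  # -1 = functional allele
    for a in range(cfg.n_lof_alleles - 1, -1, -1):
        lower = cum[a - 1][subpop] if a > 0 else 0.0
        hit = tag & (u >= lower) & (u < cum[a][subpop])
        allele_idx[hit] = a
    if all((allele_idx == a).sum() == 0 for a in range(cfg.n_lof_alleles)):
        warnings.warn("configured frequencies produced no gene-A LOF carriers", stacklevel=2)

    geneA_chrom = str(_GENEA_CHROM_IDX + 1)
    tag_col = (2 * tag).astype(np.int8)
    lof_cols = np.stack(
        [(2 * (allele_idx == a)).astype(np.int8) for a in range(cfg.n_lof_alleles)], axis=1
    )
    # focal allele 218 bp upstream of the tag; further alleles spaced nearby
    lof_pos = [_TAG_POS - 218] + [_TAG_POS + 1_500 * (a + 1) for a in range(1, cfg.n_lof_alleles)]
    flips = rng.random((n, cfg.n_tag_linked_snps)) < cfg.tag_ld_flip_prob
    linked_cols = (2 * (tag[:, None] ^ flips)).astype(np.int8)
    linked_pos = [_TAG_POS - 700_000 + 280_000 * j for j in range(cfg.n_tag_linked_snps)]

    # --- gene B ----------------------------------------------------------
    geneB_freq = np.asarray(cfg.geneB_lof_freq_by_subpop)
    lof_b = rng.random(n) < geneB_freq[subpop]
    if not lof_b.any():
        warnings.warn("configured frequencies produced no gene-B LOF carriers", stacklevel=2)
    geneB_chrom = str(_GENEB_CHROM_IDX + 1)

    # --- assemble ---------------------------------------------------------
    extra_cols = np.column_stack([tag_col, lof_cols, linked_cols, (2 * lof_b).astype(np.int8)])
    extra_chrom = [geneA_chrom] * (1 + cfg.n_lof_alleles + cfg.n_tag_linked_snps) + [geneB_chrom]
    extra_pos = [_TAG_POS] + lof_pos + linked_pos + [_GENEB_POS]

    calls = np.concatenate([calls_neutral, extra_cols], axis=1)
    chrom_all = np.asarray(chroms + extra_chrom, dtype=object)
    pos_all = np.concatenate([positions, np.asarray(extra_pos, dtype=np.int64)])
    ids = np.asarray([snp_id(c, int(p)) for c, p in zip(chrom_all, pos_all)], dtype=object)
    m_all = len(ids)
    pair = rng.integers(0, 4, size=m_all)
    offset = rng.integers(1, 4, size=m_all)
    allele1 = _NUCS[pair]
    allele2 = _NUCS[(pair + offset) % 4]

    g = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=ids,
        chromosome=chrom_all,
        position=pos_all,
        calls=calls,
        allele1=allele1.astype(object),
        allele2=allele2.astype(object),
    )

    is_lof_a = allele_idx >= 0
    pheno = simulate_phenotype(
        is_lof_a | lof_b, cfg.penetrance, cfg.phenocopy_rate, rng, sample_ids=sample_ids
    )
    truth = TruthRecord(
        causal_snp_ids_geneA=[snp_id(geneA_chrom, p) for p in lof_pos],
        causal_snp_id_geneB=snp_id(geneB_chrom, _GENEB_POS),
        tag_snp_id=snp_id(geneA_chrom, _TAG_POS),
        tag_linked_snp_ids=[snp_id(geneA_chrom, p) for p in linked_pos],
        sample_ids=sample_ids,
        is_lof_geneA=is_lof_a,
        is_lof_geneB=lof_b,
    )
    return g, pheno, truth


# ---------------------------------------------------------------------------
# RIL family
# ---------------------------------------------------------------------------

@dataclass
class RILSimConfig:
    """Biparental recombinant-inbred-line family (F_t = selfing generations + 1)."""

    n_rils: int = 263
    n_generations_selfing: int = 5
    n_markers: int = 1000
    map_length_morgans_per_chrom: float = 1.5
    n_chromosomes: int = 10
    parent_divergence: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rils, self.n_generations_selfing, self.n_markers, self.n_chromosomes) < 1:
            raise ValueError("counts must be positive")
        if self.map_length_morgans_per_chrom <= 0:
            raise ValueError("map length must be positive")
        if not 0.0 < self.parent_divergence <= 1.0:
            raise ValueError("parent_divergence must be in (0, 1]")


def _meiosis(
    hap_a: np.ndarray, hap_b: np.ndarray, chrom_slices, rec_fracs, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per line from a pair of haplotype arrays (n_lines x m).

    Haldane crossovers observed at marker loci are equivalent to
    independent Bernoulli(r_i) strand switches between adjacent markers,
    r_i = (1 - exp(-2 d_i)) / 2; chromosomes assort independently.
    """
    n, m = hap_a.shape
    use_b = np.empty((n, m), dtype=bool)
    for (start, stop), r in zip(chrom_slices, rec_fracs):
        width = stop - start
        strand = np.empty((n, width), dtype=np.int8)
        strand[:, 0] = rng.integers(0, 2, size=n)
        if width > 1:
            switches = (rng.random((n, width - 1)) < r).astype(np.int8)
            strand[:, 1:] = switches
            np.cumsum(strand, axis=1, out=strand)
            strand &= 1
        use_b[:, start:stop] = strand.astype(bool)
    return np.where(use_b, hap_b, hap_a)


def simulate_ril_family(
    cfg: RILSimConfig,
) -> tuple[GenotypeMatrix, np.ndarray, pd.DataFrame]:
    """Simulate an F_t RIL family by repeated selfing from two inbred parents.

    Returns the RIL genotype matrix (codes count parent-1 alleles),
    the 2 x m parent genotype codes, and the recombination map
    (snp_id, chromosome, position, morgans).  Markers monomorphic
    between the parents stay monomorphic in every line.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_markers
    per_chrom = np.full(cfg.n_chromosomes, m // cfg.n_chromosomes)
    per_chrom[: m % cfg.n_chromosomes] += 1

    chroms, positions, morgans, chrom_slices, rec_fracs = [], [], [], [], []
    start = 0
    for c in range(cfg.n_chromosomes):
        mc = int(per_chrom[c])
        if mc == 0:
            continue
        pos = np.linspace(1_000_000, 60_000_000, mc).astype(np.int64)
        gen = (
            np.linspace(0.0, cfg.map_length_morgans_per_chrom, mc)
            if mc > 1
            else np.zeros(1)
        )
        chroms.extend([str(c + 1)] * mc)
        positions.append(pos)
        morgans.append(gen)
        d = np.diff(gen)
        rec_fracs.append(0.5 * (1.0 - np.exp(-2.0 * d)))
        chrom_slices.append((start, start + mc))
        start += mc
    positions = np.concatenate(positions)
    morgans = np.concatenate(morgans)

    polymorphic = rng.random(m) < cfg.parent_divergence
    if not polymorphic.any():
        raise ValueError("zero polymorphic markers between the parents")

    n = cfg.n_rils
    # haplotypes hold parental origin: False = parent 1, True = parent 2;
    # monomorphic markers carry the shared parent-1 allele regardless of origin
    hap1 = np.zeros((n, m), dtype=bool)
    hap2 = np.ones((n, m), dtype=bool)  # F1: one chromosome from each parent
    for _ in range(cfg.n_generations_selfing):
        g1 = _meiosis(hap1, hap2, chrom_slices, rec_fracs, rng)
        g2 = _meiosis(hap1, hap2, chrom_slices, rec_fracs, rng)
        hap1, hap2 = g1, g2

    codes = ((~hap1).astype(np.int8) + (~hap2).astype(np.int8))
    codes[:, ~polymorphic] = 2

    ids = np.asarray([snp_id(c, int(p)) for c, p in zip(chroms, positions)], dtype=object)
    sample_ids = np.asarray([f"RIL{i + 1:04d}" for i in range(n)], dtype=object)
    allele1 = np.asarray(["A"] * m, dtype=object)
    allele2 = np.asarray(["C"] * m, dtype=object)
    g = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=ids,
        chromosome=np.asarray(chroms, dtype=object),
        position=positions,
        calls=codes,
        allele1=allele1,
        allele2=allele2,
    )
    parents = np.vstack(
        [np.full(m, 2, dtype=np.int8), np.where(polymorphic, 0, 2).astype(np.int8)]
    )
    recomb_map = pd.DataFrame(
        {"snp_id": ids, "chromosome": chroms, "position": positions, "morgans": morgans}
    )
    return g, parents, recomb_map
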