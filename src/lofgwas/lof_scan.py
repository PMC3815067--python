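"""Loss-of-function genome scan.

The scan exploits the asymmetry of loss-of-function (LOF) genetics under
complementary epistasis: a true LOF allele is never rescued, so its
carriers essentially always show the LOF phenotype, while the wild-type
allele at the same SNP can freely co-occur with LOF phenotypes caused by
other genes.  Linear models reward genotype-phenotype covariation at
*both* alleles and therefore favour intermediate-frequency tag SNPs that
partially track several LOF alleles at once; this scan instead tests each
allele class separately against the pooled LOF proportion and keeps the
smaller of the two exact binomial p-values, so a perfectly covarying LOF
allele dominates regardless of what the wild-type allele class does.

Per SNP, with L1/W1 the LOF/wild-type phenotype counts among homozygous
carriers of allele 1, L2/W2 the same for allele 2, and
P = (L1+L2)/(L1+L2+W1+W2) the pooled LOF proportion:

    LOF p = min( BinomTest(L1; L1+W1, P), BinomTest(L2; L2+W2, P) )
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .genodata import MISSING, GenotypeMatrix, PhenotypeTable
from .linear_models import AssociationTable

# Relative slack in the minimum-likelihood inclusion rule, guarding
# floating-point ties between outcome probabilities.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyCounts:
    """Phenotype counts within the two homozygous allele classes of one SNP."""

    L1: int
    W1: int
    L2: int
    W2: int

    def __post_init__(self) -> None:
        for name in ("L1", "W1", "L2", "W2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.L1 + self.W1 + self.L2 + self.W2

    @property
    def P(self) -> float:
        """Pooled loss-of-function proportion (L1+L2)/(L1+L2+W1+W2)."""
        if self.total == 0:
            raise ValueError("all four counts are zero; P undefined")
        return (self.L1 + self.L2) / self.total


def contingency_counts(
    snp_calls: np.ndarray, trait: np.ndarray, lof_level: int = 0
) -> ContingencyCounts:
    """Tally phenotypes within each homozygous allele class of one SNP.

    Homozygous allele-1 samples (code 2) fill L1/W1, homozygous allele-2
    samples (code 0) fill L2/W2.  Heterozygous calls, missing calls and
    missing traits are excluded; inbred panels make this loss negligible.
    ``lof_level`` selects which trait value is the LOF phenotype
    (default 0, absence of pigment).
    """
    if lof_level not in (0, 1):
        raise ValueError("lof_level must be 0 or 1")
    calls = np.asarray(snp_calls)
    tr = np.asarray(trait)
    if calls.shape != tr.shape:
        raise ValueError("snp_calls and trait must be aligned")
    usable = (tr != MISSING) & ((calls == 0) | (calls == 2))
    is_lof = tr == lof_level
    hom1 = usable & (calls == 2)
    hom2 = usable & (calls == 0)
    counts = ContingencyCounts(
        L1=int((hom1 & is_lof).sum()),
        W1=int((hom1 & ~is_lof).sum()),
        L2=int((hom2 & is_lof).sum()),
        W2=int((hom2 & ~is_lof).sum()),
    )
    if counts.total == 0:
        raise ValueError("no scorable homozygous samples at this SNP")
    return counts


def exact_binomial_p(x: int, n: int, p0: float, sided: str = "two") -> float:
    """Exact binomial test p-value for x successes in n trials under p0.

    ``sided="two"`` uses the minimum-likelihood convention: the p-value
    sums Binomial(n, p0) probabilities over every outcome whose
    probability does not exceed that of the observed x (within a small
    relative tolerance for floating-point ties).  ``sided="greater"``
    is the plain upper-tail sum P(X >= x).  Degenerate nulls are exact:
    under p0 = 0 or 1 the forced observation gives p = 1 and any other
    outcome has null probability zero.
    """
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if sided not in ("two", "greater"):
        raise ValueError("sided must be 'two' or 'greater'")
    if n == 0:
        return 1.0
    if p0 == 0.0:
        return 1.0 if x == 0 else 0.0
    if p0 == 1.0:
        return 1.0 if x == n else 0.0
    if sided == "greater":
        return float(min(1.0, binom.sf(x - 1, n, p0)))
    k = np.arange(n + 1)
    pmf = binom.pmf(k, n, p0)
    selected = pmf[pmf <= pmf[x] * (1.0 + _TIE_RTOL)]
    if len(selected) == n + 1:
        return 1.0  # every outcome is at most as likely as the observed one
    # ascending-order summation keeps the tiny-tail relative error small
    return float(min(1.0, np.sort(selected).sum()))


def lof_pvalue(counts: ContingencyCounts, sided: str = "two") -> float:
    """Minimum of the two per-allele exact binomial tests against pooled P."""
    p0 = counts.P
    p1 = exact_binomial_p(counts.L1, counts.L1 + counts.W1, p0, sided)
    p2 = exact_binomial_p(counts.L2, counts.L2 + counts.W2, p0, sided)
    return min(p1, p2)


def lof_genome_scan(
    g: GenotypeMatrix,
    p: PhenotypeTable,
    lof_level: int = 0,
    sided: str = "two",
) -> AssociationTable:
    """Run the per-SNP loss-of-function scan over an aligned panel.

    Inputs must already be sample-aligned (see
    :func:`lofgwas.genodata.align_samples`).  SNPs with no scorable
    homozygous calls are reported MISSING; an empty allele class on one
    side simply contributes a p-value of 1 for that side.  Raw calls are
    used throughout -- imputed dosages never enter this scan.
    """
    if g.n_samples != p.n_samples or not np.array_equal(g.sample_ids, p.sample_ids):
        raise ValueError("genotypes and phenotypes are not sample-aligned")
    tr = p.trait
    scored = tr != MISSING
    if not scored.any():
        raise ValueError("no samples with a scored trait")
    if lof_level not in (0, 1):
        raise ValueError("lof_level must be 0 or 1")

    calls = g.calls
    is_lof = scored & (tr == lof_level)
    is_wt = scored & (tr != lof_level)
    hom1 = calls == 2
    hom2 = calls == 0
    L1 = hom1[is_lof].sum(axis=0).astype(np.int64)
    W1 = hom1[is_wt].sum(axis=0).astype(np.int64)
    L2 = hom2[is_lof].sum(axis=0).astype(np.int64)
    W2 = hom2[is_wt].sum(axis=0).astype(np.int64)

    m = g.n_snps
    pvals = np.full(m, np.nan)
    n_used = (L1 + W1 + L2 + W2).astype(np.int64)
    for j in range(m):
        if n_used[j] == 0:
            continue
        counts = ContingencyCounts(int(L1[j]), int(W1[j]), int(L2[j]), int(W2[j]))
        pvals[j] = lof_pvalue(counts, sided=sided)
    pvals = np.where(np.isnan(pvals), np.nan, np.maximum(pvals, 1e-320))
    nan = np.full(m, np.nan)
    return AssociationTable(
        snp_ids=g.snp_ids.copy(),
        chromosome=g.chromosome.copy(),
        position=g.position.copy(),
        model_tag="lof",
        p_value=pvals,
        statistic=nan.copy(),
        effect=nan.copy(),
        n_used=n_used,
    )
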