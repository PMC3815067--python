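"""Kinship, principal components of genotype structure, and PC-count selection.

The kinship matrix K enters the mixed model as the covariance of the
polygenic random effect; the principal-component scores Q enter as fixed
covariates.  The number of PCs is chosen by BIC over nested least-squares
fits of the trait on the leading components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg


@dataclass
class KinshipMatrix:
    """Symmetric n x n genomic relationship matrix with sample labels."""

    sample_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
        df.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, path: str | Path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            sample_ids=df.index.to_numpy(dtype=object),
            values=df.to_numpy(dtype=np.float64),
        )


@dataclass
class PCResult:
    """Principal-component scores of the centered dosage matrix."""

    sample_ids: np.ndarray
    components: np.ndarray
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.components = np.asarray(self.components, dtype=np.float64)
        self.variance_explained = np.asarray(self.variance_explained, dtype=np.float64)
        if self.components.shape[0] != len(self.sample_ids):
            raise ValueError("component rows do not match sample count")
        if self.components.shape[1] != len(self.variance_explained):
            raise ValueError("variance_explained length does not match components")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def write(self, path: str | Path) -> None:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        df = pd.DataFrame(self.components, index=self.sample_ids, columns=cols)
        df.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, path: str | Path) -> "PCResult":
        df = pd.read_csv(path, sep="\t", index_col=0)
        comp = df.to_numpy(dtype=np.float64)
        # variance fractions are not serialized in the TSV; recompute share
        total = (comp**2).sum()
        ve = (comp**2).sum(axis=0) / total if total > 0 else np.zeros(comp.shape[1])
        return cls(df.index.to_numpy(dtype=object), comp, ve)


def kinship_vanraden(dosages: np.ndarray, sample_ids=None) -> KinshipMatrix:
    """Centered genomic relationship matrix (VanRaden method 1).

    Markers are centered at twice their allele frequency and the
    cross-product is normalized by 2 * sum p_j (1 - p_j).  Requires
    complete (mean-imputed) dosages and at least two polymorphic markers.
    """
    W = np.asarray(dosages, dtype=np.float64)
    if W.ndim != 2:
        raise ValueError("dosages must be an n x m matrix")
    n, m = W.shape
    if sample_ids is None:
        sample_ids = np.asarray([f"s{i}" for i in range(n)], dtype=object)
    if np.isnan(W).any():
        raise ValueError("dosages contain NaN; impute first")
    p = W.mean(axis=0) / 2.0
    het = p * (1.0 - p)
    if int((het > 0).sum()) < 2:
        raise ValueError("need at least two polymorphic markers for kinship")
    Wc = W - 2.0 * p
    denom = 2.0 * het.sum()
    K = (Wc @ Wc.T) / denom
    K = 0.5 * (K + K.T)
    return KinshipMatrix(sample_ids=np.asarray(sample_ids, dtype=object), values=K)


def kinship_ibs(dosages: np.ndarray, sample_ids=None) -> KinshipMatrix:
    """Identity-by-state allele-sharing kinship (alternative to VanRaden)."""
    W = np.asarray(dosages, dtype=np.float64)
    n, m = W.shape
    if sample_ids is None:
        sample_ids = np.asarray([f"s{i}" for i in range(n)], dtype=object)
    # mean fraction of shared alleles: 1 - |d_i - d_j| / 2 averaged over markers
    diff = np.abs(W[:, None, :] - W[None, :, :]).mean(axis=2)
    K = 1.0 - diff / 2.0
    return KinshipMatrix(sample_ids=np.asarray(sample_ids, dtype=object), values=0.5 * (K + K.T))


def pca(dosages: np.ndarray, k: int, sample_ids=None) -> PCResult:
    """Top-k principal components of the column-centered dosage matrix.

    Scores are left singular vectors scaled by singular values (classical
    MDS on Euclidean genotype distances gives the same configuration).
    Columns are not variance-standardized.
    """
    W = np.asarray(dosages, dtype=np.float64)
    if W.ndim != 2:
        raise ValueError("dosages must be an n x m matrix")
    n, m = W.shape
    if k < 1 or k > min(n, m) - 1:
        raise ValueError(f"k must be in [1, {min(n, m) - 1}]")
    if sample_ids is None:
        sample_ids = np.asarray([f"s{i}" for i in range(n)], dtype=object)
    Wc = W - W.mean(axis=0)
    U, sv, _ = linalg.svd(Wc, full_matrices=False)
    total = float((sv**2).sum())
    if total == 0:
        raise ValueError("dosage matrix has zero variance")
    rank = int((sv > sv[0] * 1e-12).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    scores = U[:, :k] * sv[:k]
    ve = (sv[:k] ** 2) / total
    return PCResult(np.asarray(sample_ids, dtype=object), scores, ve)


def select_num_pcs_bic(trait, pcs: PCResult, max_k: int) -> int:
    """Choose the number of PC covariates by BIC over k = 0..max_k.

    Each candidate fits ordinary least squares of the trait on an
    intercept plus the first k scores; BIC = n ln(RSS/n) + (k+1) ln n
    with the error variance profiled out.  Ties go to the smaller k.
    """
    y = np.asarray(getattr(trait, "trait", trait), dtype=np.float64)
    if y.std() == 0:
        raise ValueError("trait has zero variance")
    if max_k < 0 or max_k > pcs.n_components:
        raise ValueError(f"max_k must be in [0, {pcs.n_components}]")
    n = len(y)
    best_k, best_bic = 0, np.inf
    for k in range(max_k + 1):
        X = np.hstack([np.ones((n, 1)), pcs.components[:, :k]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        bic = n * np.log(rss / n) + (k + 1) * np.log(n)
        if bic < best_bic - 1e-12:
            best_k, best_bic = k, bic
    return best_k
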