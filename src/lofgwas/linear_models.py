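"""Single-marker association engines: GLM, mixed model (REML/P3D), compressed MLM.

The binary trait is treated as a quantitative 0/1 response throughout,
matching standard mixed-model GWAS practice for scored qualitative
traits.  The mixed model is

    y = X b + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I)

with K a genomic kinship matrix.  Variance components are estimated by
REML on the no-SNP (null) model via a one-time spectral decomposition of
K and a 1-D profile over delta = se2/sg2; per-SNP tests then use
generalized least squares in the rotated space with those components
held fixed ("population parameters previously determined", P3D).  The
compressed variant replaces individual kinship by the mean kinship of
hierarchically clustered groups, selecting the group count by REML
log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.cluster.hierarchy import fcluster
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import f as f_dist

from .genodata import MISSING, GenotypeMatrix, PhenotypeTable, impute_mean

logger = logging.getLogger(__name__)

_DELTA_GRID = np.logspace(-5, 5, 100)
_P_FLOOR = 1e-320
# relative variance threshold below which a residualized SNP is untestable
_SXX_RTOL = 1e-10

MODEL_TAGS = ("glm", "glm_q", "mlm", "mlm_q", "cmlm", "cmlm_q", "lof")


@dataclass
class AssociationTable:
    """Per-SNP association results; the common currency of all scan engines.

    ``p_value``/``statistic``/``effect`` are NaN for untestable
    (e.g. monomorphic) SNPs.
    """

    snp_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    model_tag: str
    p_value: np.ndarray
    statistic: np.ndarray
    effect: np.ndarray
    n_used: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.p_value = np.asarray(self.p_value, dtype=np.float64)
        self.statistic = np.asarray(self.statistic, dtype=np.float64)
        self.effect = np.asarray(self.effect, dtype=np.float64)
        self.n_used = np.asarray(self.n_used, dtype=np.int64)
        lengths = {
            len(a)
            for a in (
                self.snp_ids,
                self.chromosome,
                self.position,
                self.p_value,
                self.statistic,
                self.effect,
                self.n_used,
            )
        }
        if len(lengths) != 1:
            raise ValueError("AssociationTable column lengths differ")
        ok = np.isnan(self.p_value) | ((self.p_value > 0) & (self.p_value <= 1))
        if not ok.all():
            raise ValueError("p-values must lie in (0, 1] or be NaN")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def testable(self) -> np.ndarray:
        return ~np.isnan(self.p_value)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chromosome,
                "pos": self.position,
                "model": self.model_tag,
                "n_used": self.n_used,
                "effect": self.effect,
                "statistic": self.statistic,
                "p_value": self.p_value,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path: str | Path) -> "AssociationTable":
        df = pd.read_csv(path, sep="\t", na_values="NA", dtype={"chrom": str})
        model = df["model"].iloc[0] if len(df) else "glm"
        return cls(
            snp_ids=df["snp_id"].to_numpy(dtype=object),
            chromosome=df["chrom"].to_numpy(dtype=object),
            position=df["pos"].to_numpy(),
            model_tag=str(model),
            p_value=df["p_value"].to_numpy(dtype=np.float64),
            statistic=df["statistic"].to_numpy(dtype=np.float64),
            effect=df["effect"].to_numpy(dtype=np.float64),
            n_used=df["n_used"].to_numpy(),
        )


@dataclass
class VarianceComponents:
    """REML/ML variance components of the null mixed model."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    n: int
    n_fixed_effects: int

    @property
    def heritability(self) -> float:
        """sg2 / (sg2 + se2) on the kinship scale."""
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class CompressionPlan:
    """Sample-to-group assignment and group-level kinship for the CMLM."""

    n_groups: int
    group_assignment: np.ndarray
    group_kinship: np.ndarray
    linkage: str
    reml_loglik_at_fit: float | None = None

    def expanded_kinship(self) -> np.ndarray:
        """n x n covariance implied by the plan: K_eff[i,j] = Kg[g_i, g_j]."""
        a = self.group_assignment
        return self.group_kinship[np.ix_(a, a)]


# ---------------------------------------------------------------------------
# input coercion
# ---------------------------------------------------------------------------

def _as_trait(trait) -> np.ndarray:
    if isinstance(trait, PhenotypeTable):
        y = trait.trait.astype(np.float64)
        if (trait.trait == MISSING).any():
            raise ValueError("trait contains MISSING values; align samples first")
        return y
    y = np.asarray(trait, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("trait must be a vector")
    return y


def _as_dosages(geno) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (dosages, snp_ids, chromosome, position) from a matrix or array."""
    if isinstance(geno, GenotypeMatrix):
        return impute_mean(geno), geno.snp_ids, geno.chromosome, geno.position
    dos = np.asarray(geno, dtype=np.float64)
    if dos.ndim == 1:
        dos = dos[:, None]
    m = dos.shape[1]
    pos = np.arange(1, m + 1, dtype=np.int64)
    ids = np.asarray([f"S0_{j}" for j in pos], dtype=object)
    chrom = np.asarray(["0"] * m, dtype=object)
    return dos, ids, chrom, pos


def _design(n: int, covariates) -> np.ndarray:
    """Fixed-effect design: intercept plus sanitized covariate columns.

    Zero-variance covariate columns are dropped (they are confounded with
    the intercept); this keeps e.g. an all-constant PC harmless.
    """
    X = np.ones((n, 1))
    if covariates is None:
        return X
    C = np.asarray(getattr(covariates, "components", covariates), dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match number of samples")
    keep = C.std(axis=0) > 0
    if not keep.all():
        logger.info("dropping %d zero-variance covariate columns", int((~keep).sum()))
    return np.hstack([X, C[:, keep]])


# ---------------------------------------------------------------------------
# core per-marker OLS machinery (shared by GLM and rotated GLS scans)
# ---------------------------------------------------------------------------

def _marker_scan(y: np.ndarray, G: np.ndarray, X: np.ndarray, testable: np.ndarray):
    """Partial F-test (1 df) of each column of G added to the design X.

    Works in whatever (possibly rotated/weighted) coordinates the caller
    supplies; returns (beta, F, p, df).  Columns flagged untestable, or
    numerically collinear with X, come back NaN.
    """
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} samples for {p} fixed effects plus a marker")
    Q, _ = np.linalg.qr(X)
    My = y - Q @ (Q.T @ y)
    MG = G - Q @ (Q.T @ G)
    syy = float(My @ My)
    sxx = np.einsum("ij,ij->j", MG, MG)
    sxy = MG.T @ My
    scale = np.einsum("ij,ij->j", G, G) + 1.0
    ok = testable & (sxx > _SXX_RTOL * scale)
    df = n - p - 1

    beta = np.full(G.shape[1], np.nan)
    F = np.full(G.shape[1], np.nan)
    pv = np.full(G.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta[ok] = sxy[ok] / sxx[ok]
        ess = np.zeros_like(sxx)
        ess[ok] = sxy[ok] ** 2 / sxx[ok]
        rss = np.maximum(syy - ess, 0.0)
        F[ok] = np.where(rss[ok] > 0, ess[ok] / (rss[ok] / df), np.inf)
    pv[ok] = np.maximum(f_dist.sf(F[ok], 1, df), _P_FLOOR)
    return beta, F, pv, df


def _polymorphic(dosages: np.ndarray) -> np.ndarray:
    return dosages.std(axis=0) > 0


def _table(ids, chrom, pos, tag, beta, F, pv, n) -> AssociationTable:
    return AssociationTable(
        snp_ids=ids,
        chromosome=chrom,
        position=pos,
        model_tag=tag,
        p_value=pv,
        statistic=F,
        effect=beta,
        n_used=np.full(len(ids), n, dtype=np.int64),
    )


def glm_scan(geno, trait, covariates=None, model_tag: str | None = None) -> AssociationTable:
    """Ordinary least-squares scan: trait on intercept (+ covariates) + dosage.

    The SNP term's p-value is the partial F test with 1 numerator df and
    n - p - 1 denominator df.  Monomorphic SNPs are reported NaN.
    """
    y = _as_trait(trait)
    G, ids, chrom, pos = _as_dosages(geno)
    if len(y) != G.shape[0]:
        raise ValueError("trait and dosage rows differ; align samples first")
    X = _design(len(y), covariates)
    beta, F, pv, _ = _marker_scan(y, G, X, _polymorphic(G))
    tag = model_tag or ("glm" if covariates is None else "glm_q")
    return _table(ids, chrom, pos, tag, beta, F, pv, len(y))


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _eigh_kinship(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = np.asarray(K, dtype=np.float64)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship must be a symmetric square matrix")
    s, U = linalg.eigh(K)
    if s.min() < -1e-6 * max(1.0, s.max()):
        raise ValueError(f"kinship is not PSD (min eigenvalue {s.min():.3g})")
    return np.maximum(s, 0.0), U


def _neg2ll(delta: float, s: np.ndarray, yr: np.ndarray, Xr: np.ndarray, method: str):
    """Profile -2 log-likelihood over delta; sg2 and beta profiled out.

    REML convention includes + ln|X' V0^-1 X| - ln|X'X| so the value is
    invariant to linear reparameterization of the fixed effects.
    """
    n, p = Xr.shape
    D = s + delta
    Xd = Xr / D[:, None]
    A = Xr.T @ Xd
    b = Xd.T @ yr
    cf = linalg.cho_factor(A)
    beta = linalg.cho_solve(cf, b)
    e = yr - Xr @ beta
    q = float(e @ (e / D))
    logdet_D = float(np.log(D).sum())
    if method == "reml":
        sg2 = q / (n - p)
        logdet_A = 2.0 * float(np.log(np.diag(cf[0])).sum())
        sign, logdet_XX = np.linalg.slogdet(Xr.T @ Xr)
        val = (
            (n - p) * np.log(2 * np.pi * sg2)
            + (n - p)
            + logdet_D
            + logdet_A
            - logdet_XX
        )
    elif method == "ml":
        sg2 = q / n
        val = n * np.log(2 * np.pi * sg2) + n + logdet_D
    else:
        raise ValueError("method must be 'reml' or 'ml'")
    return float(val), sg2, beta, q


def _optimize_delta(s, yr, Xr, method: str) -> tuple[float, float]:
    """Grid search over delta refined by bounded minimization.

    Returns (delta, -2LL).  A refined optimum at the top of the grid is a
    boundary solution (sg2 -> 0).
    """
    vals = np.array([_neg2ll(d, s, yr, Xr, method)[0] for d in _DELTA_GRID])
    i = int(np.argmin(vals))
    lo = _DELTA_GRID[max(i - 1, 0)]
    hi = _DELTA_GRID[min(i + 1, len(_DELTA_GRID) - 1)]
    if lo == hi:
        return float(_DELTA_GRID[i]), float(vals[i])
    res = optimize.minimize_scalar(
        lambda t: _neg2ll(10.0**t, s, yr, Xr, method)[0],
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if res.fun <= vals[i]:
        return float(10.0**res.x), float(res.fun)
    return float(_DELTA_GRID[i]), float(vals[i])


def reml_fit(trait, fixed_design, kinship, method: str = "reml") -> VarianceComponents:
    """Fit variance components of y = Xb + u + e with u ~ N(0, sg2 K).

    The likelihood is profiled over delta = se2/sg2 on a log grid
    (1e-5..1e5) with bounded local refinement.  A boundary optimum is
    reported cleanly as sg2 = 0 with delta = +inf.
    """
    y = _as_trait(trait)
    X = np.asarray(fixed_design, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if y.std() == 0:
        raise ValueError("trait is constant; variance components undefined")
    K = kinship.values if hasattr(kinship, "values") else kinship
    s, U = _eigh_kinship(np.asarray(K, dtype=np.float64))
    yr = U.T @ y
    Xr = U.T @ X
    n, p = Xr.shape
    delta, neg2 = _optimize_delta(s, yr, Xr, method)
    _, sg2, _, _ = _neg2ll(delta, s, yr, Xr, method)
    loglik = -0.5 * neg2
    if delta >= 0.999 * _DELTA_GRID[-1]:
        # sg2 indistinguishable from 0: the model collapses to iid errors
        se2 = sg2 * delta
        return VarianceComponents(0.0, float(se2), np.inf, loglik, n, p)
    return VarianceComponents(float(sg2), float(sg2 * delta), float(delta), loglik, n, p)


# ---------------------------------------------------------------------------
# MLM / CMLM scans
# ---------------------------------------------------------------------------

def _p3d_scan(y, G, X, K, testable):
    """Null REML fit on K, then GLS per marker in the rotated space."""
    s, U = _eigh_kinship(K)
    yr = U.T @ y
    Xr = U.T @ X
    delta, neg2 = _optimize_delta(s, yr, Xr, "reml")
    _, sg2, _, _ = _neg2ll(delta, s, yr, Xr, "reml")
    n, p = Xr.shape
    boundary = delta >= 0.999 * _DELTA_GRID[-1]
    vc = VarianceComponents(
        0.0 if boundary else float(sg2),
        float(sg2 * delta),
        np.inf if boundary else float(delta),
        -0.5 * neg2,
        n,
        p,
    )
    w = 1.0 / np.sqrt(s + delta)
    ys = yr * w
    Xs = Xr * w[:, None]
    Gs = (U.T @ G) * w[:, None]
    beta, F, pv, _ = _marker_scan(ys, Gs, Xs, testable)
    return (beta, F, pv), vc, (s, U, delta)


def mlm_scan(
    geno, trait, kinship, covariates=None, mode: str = "p3d", model_tag: str | None = None
) -> AssociationTable:
    """Mixed-model scan with kinship K.

    ``mode="p3d"`` (default) estimates variance components once on the
    null model and reuses them for every marker; ``mode="exact"``
    re-optimizes delta per marker by profile maximum likelihood.
    """
    if mode not in ("p3d", "exact"):
        raise ValueError("mode must be 'p3d' or 'exact'")
    y = _as_trait(trait)
    G, ids, chrom, pos = _as_dosages(geno)
    if len(y) != G.shape[0]:
        raise ValueError("trait and dosage rows differ; align samples first")
    K = kinship.values if hasattr(kinship, "values") else np.asarray(kinship, dtype=np.float64)
    X = _design(len(y), covariates)
    testable = _polymorphic(G)
    tag = model_tag or ("mlm" if covariates is None else "mlm_q")

    if mode == "p3d":
        (beta, F, pv), _, _ = _p3d_scan(y, G, X, K, testable)
        return _table(ids, chrom, pos, tag, beta, F, pv, len(y))

    s, U = _eigh_kinship(K)
    yr = U.T @ y
    Xr = U.T @ X
    Gr = U.T @ G
    n, p = Xr.shape
    m = G.shape[1]
    beta = np.full(m, np.nan)
    F = np.full(m, np.nan)
    pv = np.full(m, np.nan)
    df = n - p - 1
    for j in range(m):
        if not testable[j]:
            continue
        Xj = np.hstack([Xr, Gr[:, j : j + 1]])
        delta, _ = _optimize_delta(s, yr, Xj, "ml")
        D = s + delta
        Xd = Xj / D[:, None]
        A = Xj.T @ Xd
        try:
            cf = linalg.cho_factor(A)
        except linalg.LinAlgError:
            continue
        bhat = linalg.cho_solve(cf, Xd.T @ yr)
        e = yr - Xj @ bhat
        q = float(e @ (e / D))
        sig2 = q / df if df > 0 else np.nan
        Ainv_last = linalg.cho_solve(cf, np.eye(p + 1)[:, -1])[-1]
        se2 = sig2 * Ainv_last
        if se2 <= 0:
            continue
        beta[j] = bhat[-1]
        F[j] = bhat[-1] ** 2 / se2
        pv[j] = max(float(f_dist.sf(F[j], 1, df)), _P_FLOOR)
    return _table(ids, chrom, pos, tag, beta, F, pv, len(y))


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------

def compress_kinship(kinship, n_groups: int, linkage: str = "average") -> CompressionPlan:
    """Cluster samples on kinship-derived distance and average K per group.

    Distance d_ij = max(K) - K_ij; hierarchical clustering (average or
    complete linkage) cut at ``n_groups``.  The boundary counts are
    special-cased: n groups is the identity plan (group kinship == K) and
    1 group is the grand mean.
    """
    K = kinship.values if hasattr(kinship, "values") else np.asarray(kinship, dtype=np.float64)
    n = K.shape[0]
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must be in [1, {n}]")
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    if n_groups == n:
        return CompressionPlan(n, np.arange(n), K.copy(), linkage)
    if n_groups == 1:
        return CompressionPlan(
            1, np.zeros(n, dtype=np.int64), np.array([[float(K.mean())]]), linkage
        )
    D = K.max() - K
    np.fill_diagonal(D, 0.0)
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    _, assign = np.unique(labels, return_inverse=True)
    g = assign.max() + 1
    ind = np.zeros((n, g))
    ind[np.arange(n), assign] = 1.0
    sizes = ind.sum(axis=0)
    Kg = (ind.T @ K @ ind) / np.outer(sizes, sizes)
    Kg = 0.5 * (Kg + Kg.T)
    return CompressionPlan(int(g), assign.astype(np.int64), Kg, linkage)


def default_group_grid(n: int, n_points: int = 10) -> list[int]:
    """~log-spaced candidate group counts from 1 to n."""
    grid = np.unique(np.round(np.logspace(0, np.log10(n), n_points)).astype(int))
    return [int(v) for v in grid if 1 <= v <= n]


def cmlm_scan(
    geno,
    trait,
    kinship,
    covariates=None,
    group_grid: Sequence[int] | None = None,
    linkage: str = "average",
    model_tag: str | None = None,
) -> tuple[AssociationTable, CompressionPlan]:
    """Compressed mixed-model scan.

    For each candidate group count the null mixed model is fitted with
    the group-level random effect (covariance = group kinship expanded
    through the sample-to-group incidence); the count maximizing the
    REML log-likelihood wins and all markers are scanned under it with
    P3D.
    """
    y = _as_trait(trait)
    G, ids, chrom, pos = _as_dosages(geno)
    if len(y) != G.shape[0]:
        raise ValueError("trait and dosage rows differ; align samples first")
    K = kinship.values if hasattr(kinship, "values") else np.asarray(kinship, dtype=np.float64)
    n = len(y)
    if group_grid is None:
        group_grid = default_group_grid(n)
    X = _design(n, covariates)
    testable = _polymorphic(G)

    best = None
    for g in group_grid:
        plan = compress_kinship(K, int(g), linkage=linkage)
        K_eff = plan.expanded_kinship()
        s, U = _eigh_kinship(K_eff)
        yr = U.T @ y
        Xr = U.T @ X
        _, neg2 = _optimize_delta(s, yr, Xr, "reml")
        plan.reml_loglik_at_fit = -0.5 * neg2
        if best is None or plan.reml_loglik_at_fit > best.reml_loglik_at_fit:
            best = plan
    logger.info(
        "cmlm_scan: selected %d groups (REML loglik %.4f)",
        best.n_groups,
        best.reml_loglik_at_fit,
    )
    tag = model_tag or ("cmlm" if covariates is None else "cmlm_q")
    (beta, F, pv), _, _ = _p3d_scan(y, G, X, best.expanded_kinship(), testable)
    return _table(ids, chrom, pos, tag, beta, F, pv, n), best
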