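"""Mixed-linear-model association scan (EMMA-style REML + P3D/EMMAX).

The null model  y = X b + g + e,  g ~ N(0, sigma2_g K),  e ~ N(0, sigma2_e I)
is fitted once per trait x environment by restricted maximum likelihood over
the single heritability parameter h = sigma2_g / (sigma2_g + sigma2_e) on the
eigenbasis of the kinship matrix K.  The scan then tests each SNP by
generalized least squares with the variance ratio fixed from the null fit
(the P3D/EMMAX approximation): the model is whitened with
D^{-1/2} U^T  (K = U S U^T, D = h S + (1-h) I), the SNP dosage is added as a
fixed effect, and a two-sided Wald t-test is reported with the residual
variance re-estimated per SNP.  In the limit h -> 0 this is exactly ordinary
least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import GenotypeMatrix, GrainmapError

log = logging.getLogger("grainmap")


@dataclass
class AssociationRecord:
    """Per-SNP association result for one trait x environment."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    trait: str
    environment: str
    effect: float  # trait units per alt allele
    se: float
    p: float
    pve_pct: float
    is_significant: bool = False


@dataclass
class MlmFit:
    """Null-model REML fit with the kinship eigendecomposition cached."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    covariates: np.ndarray  # n x p fixed-effect design (incl. intercept)
    eigvals: np.ndarray
    eigvecs: np.ndarray
    at_boundary: bool = False
    reml_loglik: float = field(default=float("nan"))

    @property
    def variance_ratio(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def _reml_neg_loglik(h: float, s: np.ndarray, Uy: np.ndarray, UX: np.ndarray) -> float:
    d = h * s + (1.0 - h)
    if np.any(d <= 0):
        return np.inf
    w = 1.0 / np.sqrt(d)
    Xw = UX * w[:, None]
    yw = Uy * w
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    n, p = Xw.shape
    if rss <= 0:
        return np.inf
    sign, logdet_XwX = np.linalg.slogdet(Xw.T @ Xw)
    if sign <= 0:
        return np.inf
    return 0.5 * ((n - p) * np.log(rss) + np.sum(np.log(d)) + logdet_XwX)


def fit_null_model(y, kinship: np.ndarray, covariates: np.ndarray | None = None) -> MlmFit:
    """REML fit of the polygenic null model by one-dimensional optimization
    of h = sigma2_g / (sigma2_g + sigma2_e) on the eigenbasis of K.

    ``covariates`` is an n x c matrix of fixed effects (e.g. top PCs); an
    intercept column is always prepended.  Deterministic.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not np.all(np.isfinite(y)):
        raise GrainmapError("phenotype vector contains non-finite values")
    if np.std(y) == 0:
        raise GrainmapError("phenotype vector is constant; variance components undefined")
    if kinship.shape != (n, n):
        raise GrainmapError(f"kinship shape {kinship.shape} does not conform to n={n}")

    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])

    s, U = np.linalg.eigh(kinship)
    s = np.clip(s, 0.0, None)
    Uy = U.T @ y
    UX = U.T @ X

    obj = lambda h: _reml_neg_loglik(h, s, Uy, UX)
    # coarse grid then local refinement: the 1-D REML surface can be multimodal
    grid = np.linspace(1e-6, 1 - 1e-6, 41)
    vals = [obj(h) for h in grid]
    h0 = grid[int(np.argmin(vals))]
    lo = max(h0 - 0.05, 1e-9)
    hi = min(h0 + 0.05, 1 - 1e-9)
    res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    h = float(res.x) if res.fun <= min(vals) else float(h0)

    at_boundary = h < 1e-4 or h > 1 - 1e-4
    if h < 1e-4:
        h = 0.0
        log.warning("REML optimum at boundary: sigma2_g = 0 accepted")

    d = h * s + (1.0 - h)
    w = 1.0 / np.sqrt(d)
    Xw, yw = UX * w[:, None], Uy * w
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    sigma_tot = float(resid @ resid) / (n - X.shape[1])
    return MlmFit(
        sigma_g2=h * sigma_tot,
        sigma_e2=(1.0 - h) * sigma_tot,
        h2=h,
        covariates=X,
        eigvals=s,
        eigvecs=U,
        at_boundary=at_boundary,
        reml_loglik=-float(res.fun),
    )


def scan(geno: GenotypeMatrix, y, fit: MlmFit, trait: str = "",
         environment: str = "") -> list[AssociationRecord]:
    """P3D/EMMAX scan: per-SNP GLS with the variance ratio fixed from the
    null fit.  Monomorphic variants are skipped (logged).  Deterministic and
    invariant to material ordering and to adding a constant to y."""
    y = np.asarray(y, dtype=float)
    n = geno.n_materials
    if y.size != n:
        raise GrainmapError("phenotype length does not match number of materials")

    h = fit.h2
    d = h * fit.eigvals + (1.0 - h)
    w = 1.0 / np.sqrt(d)
    Ut = fit.eigvecs.T
    yw = (Ut @ y) * w
    Xw = (Ut @ fit.covariates) * w[:, None]
    Gw = (Ut @ geno.dosage.astype(float)) * w[:, None]

    Q, _ = np.linalg.qr(Xw)
    My = yw - Q @ (Q.T @ yw)
    MG = Gw - Q @ (Q.T @ Gw)
    yss = float(My @ My)
    gg = np.einsum("ij,ij->j", MG, MG)
    gy = My @ MG

    mono = geno.dosage.std(axis=0) == 0
    testable = (~mono) & (gg > 1e-12)
    n_skipped = int((~testable).sum())
    if n_skipped:
        log.info("scan: skipped %d monomorphic/degenerate variants", n_skipped)

    p_fixed = fit.covariates.shape[1]
    df = n - p_fixed - 1
    if df <= 0:
        raise GrainmapError("not enough materials for the scan degrees of freedom")

    var_y = float(np.var(y))
    var_g = geno.dosage.astype(float).var(axis=0)

    records: list[AssociationRecord] = []
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(testable, gy / np.where(gg > 0, gg, 1.0), np.nan)
        rss = yss - beta**2 * gg
        sigma2 = rss / df
        se = np.sqrt(sigma2 / np.where(gg > 0, gg, 1.0))
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        pve = 100.0 * beta**2 * var_g / var_y if var_y > 0 else np.zeros_like(beta)

    for j in np.nonzero(testable)[0]:
        v = geno.variants[j]
        records.append(AssociationRecord(
            variant_id=v.id, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
            trait=trait, environment=environment,
            effect=float(beta[j]), se=float(se[j]),
            p=float(max(pvals[j], np.finfo(float).tiny)),
            pve_pct=float(pve[j]),
        ))
    return records


def pve(effect: float, dosage, y) -> float:
    """Percent phenotypic variance explained: 100 * effect^2 * Var(dosage) / Var(y)."""
    var_y = float(np.var(np.asarray(y, dtype=float)))
    if var_y == 0:
        raise GrainmapError("Var(y) = 0: PVE undefined")
    var_g = float(np.var(np.asarray(dosage, dtype=float)))
    return 100.0 * effect**2 * var_g / var_y


def significant_snps(records: list[AssociationRecord], alpha: float = 0.1,
                     n_tests: int | None = None) -> list[AssociationRecord]:
    """Bonferroni selection: keep records with p < alpha / n_tests (n_tests
    defaults to the number of records scanned).  Flags ``is_significant`` in
    place and returns the kept subset."""
    if not records:
        return []
    n_tests = n_tests if n_tests is not None else len(records)
    cutoff = alpha / n_tests
    log.info("significance threshold: %g (alpha=%g over %d tests)", cutoff, alpha, n_tests)
    kept = []
    for r in records:
        r.is_significant = r.p < cutoff
        if r.is_significant:
            kept.append(r)
    return kept
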