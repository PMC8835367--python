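"""Phenotype statistics: normality, trait correlations, broad-sense
heritability from replicates, and Mahalanobis / canonical-variate analysis.

Heritability is the classical entry-mean broad-sense estimate from a one-way
random-effects ANOVA across materials within one environment:

    H2 = sigma2_G / (sigma2_G + sigma2_e / r)

with sigma2_G = (MS_between - MS_within) / r, sigma2_e = MS_within and r the
mean replicate count, clamped to [0, 1].
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd
from scipy import stats

from .core import GrainmapError
from .io import material_means


def normality_test(values) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a normal with the sample's
    own mean and SD.  Returns (statistic, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise GrainmapError(f"normality test needs >= 8 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise GrainmapError("normality test undefined for constant input")
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def trait_correlations(pheno: pd.DataFrame, environment: str | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between traits, computed on
    per-material means (one environment, or pooled across environments).

    Entries with fewer than 3 complete material pairs are NaN.
    """
    traits = sorted(pheno["trait"].unique())
    cols = {t: material_means(pheno, t, environment) for t in traits}
    wide = pd.DataFrame(cols)
    corr = wide.corr(method="pearson", min_periods=3)
    return corr


def heritability(pheno: pd.DataFrame, trait: str, environment: str) -> float:
    """Broad-sense H2 for one trait in one environment (entry-mean basis)."""
    sub = pheno[(pheno["trait"] == trait) & (pheno["environment"] == environment)]
    if sub.empty:
        raise GrainmapError(f"no phenotype records for {trait} in {environment}")
    counts = sub.groupby("material")["value"].count()
    if (counts >= 2).sum() < 10:
        raise GrainmapError(
            f"heritability needs >= 2 replicates for >= 10 materials "
            f"({trait}/{environment}: {(counts >= 2).sum()} qualify)"
        )
    sub = sub[sub["material"].isin(counts[counts >= 2].index)]
    groups = sub.groupby("material")["value"]
    n_i = groups.count().to_numpy(dtype=float)
    means = groups.mean().to_numpy()
    grand = sub["value"].mean()
    a = len(n_i)
    N = n_i.sum()
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(((sub["value"] - groups.transform("mean")) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    r_bar = float(n_i.mean())
    sigma_g = max((ms_between - ms_within) / r_bar, 0.0)
    sigma_e = ms_within
    denom = sigma_g + sigma_e / r_bar
    if denom == 0:
        return 0.0
    return float(np.clip(sigma_g / denom, 0.0, 1.0))


def heritability_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Environment x trait H2 table with a final ``mean`` row (arithmetic
    mean over environments, full precision)."""
    traits = sorted(pheno["trait"].unique())
    envs = sorted(pheno["environment"].unique())
    rows = {env: {t: heritability(pheno, t, env) for t in traits} for env in envs}
    table = pd.DataFrame(rows).T[traits]
    table.loc["mean"] = table.mean(axis=0)
    table.index.name = "environment"
    return table


def mean_across_environments(values) -> float:
    """Arithmetic mean of per-environment heritabilities, full precision."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise GrainmapError("mean across environments needs >= 1 environment")
    return float(x.mean())


def load_table2() -> pd.DataFrame:
    """Packaged per-environment heritability table from the source study
    (environments x five traits)."""
    ref = importlib.resources.files("grainmap.data") / "table2.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="environment")


def mahalanobis_cva(data: pd.DataFrame, labels) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mahalanobis distances between group centroids (pooled within-group
    covariance) and canonical-variate scores.

    ``data`` is materials x traits; ``labels`` assigns each row to a group.
    Returns (group x group distance matrix, per-material CV scores ordered by
    decreasing between-group separation).
    """
    X = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    group_names = sorted(pd.unique(labels))
    if len(group_names) < 2:
        raise GrainmapError("mahalanobis_cva needs >= 2 groups")

    centroids = np.vstack([X[labels == g].mean(axis=0) for g in group_names])
    grand = X.mean(axis=0)
    n_tot, p = X.shape
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for g, c in zip(group_names, centroids):
        Xg = X[labels == g]
        d = Xg - c
        Sw += d.T @ d
        Sb += len(Xg) * np.outer(c - grand, c - grand)
    Sw /= n_tot - len(group_names)

    try:
        Sw_inv = np.linalg.inv(Sw)
    except np.linalg.LinAlgError:
        raise GrainmapError(
            "pooled within-group covariance is singular; try a trait subset"
        ) from None

    k = len(group_names)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = centroids[i] - centroids[j]
            D[i, j] = D[j, i] = float(np.sqrt(d @ Sw_inv @ d))
    dist = pd.DataFrame(D, index=group_names, columns=group_names)

    # canonical variates: eigenvectors of Sw^-1 Sb, ordered by eigenvalue
    evals, evecs = np.linalg.eig(Sw_inv @ Sb)
    order = np.argsort(evals.real)[::-1][: min(p, k - 1)]
    W = evecs[:, order].real
    scores = (X - grand) @ W
    index = data.index if isinstance(data, pd.DataFrame) else range(n_tot)
    scores = pd.DataFrame(scores, index=index,
                          columns=[f"CV{i + 1}" for i in range(W.shape[1])])
    return dist, scores
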