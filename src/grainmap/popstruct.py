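"""Population structure and linkage disequilibrium.

Kinship is the VanRaden genomic relationship matrix; PCA works on the
centered dosage matrix; LD is genotypic r^2 (squared Pearson correlation of
dosage vectors — identical to haplotype r^2 for inbred materials), binned by
physical distance, with the decay distance read off where the binned curve
falls to half its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, GrainmapError


def kinship(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix: centered-dosage cross-product
    scaled by 2 * sum p(1-p)."""
    p = geno.alt_freq()
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise GrainmapError("kinship undefined: all variants are monomorphic")
    Z = geno.dosage[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    return (Z @ Z.T) / denom


def pca(geno: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Top-k principal component scores of the centered dosage matrix.

    Sign convention: each component's largest-magnitude loading is positive.
    """
    if k <= 0:
        raise GrainmapError("k must be >= 1")
    if k >= geno.n_materials:
        raise GrainmapError(f"k must be < number of materials ({geno.n_materials})")
    X = geno.dosage - geno.dosage.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            scores[:, j] *= -1
    return scores


def pairwise_r2(geno: GenotypeMatrix, vid_a: str, vid_b: str) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs.

    Returns NaN when either vector has zero variance over the complete pairs.
    """
    ja, jb = geno.index_of(vid_a), geno.index_of(vid_b)
    a = geno.dosage[:, ja].astype(float)
    b = geno.dosage[:, jb].astype(float)
    if geno.missing is not None:
        ok = ~(geno.missing[:, ja] | geno.missing[:, jb])
        a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LdCurve:
    """Mean r^2 per distance bin: contiguous bins from 0 in steps of
    ``bin_bp``; ``bins`` has columns bin_start, bin_end, mid, mean_r2,
    n_pairs."""

    bins: pd.DataFrame
    bin_bp: int

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


def ld_decay(geno: GenotypeMatrix, bin_bp: int = 5000, max_dist_bp: int = 300_000,
             max_pairs_per_bin: int | None = None, seed: int = 0) -> LdCurve:
    """Bin all intra-chromosomal variant pairs within ``max_dist_bp`` by
    distance and average r^2 per bin.

    ``max_pairs_per_bin`` optionally subsamples each bin (seeded) to bound
    runtime on dense panels.
    """
    X = geno.dosage.astype(float)
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    for chrom in pd.unique(geno.chroms):
        sel = np.nonzero(geno.chroms == chrom)[0]
        pos = geno.positions[sel]
        order = np.argsort(pos)
        sel, pos = sel[order], pos[order]
        sub = X[:, sel]
        sd = sub.std(axis=0)
        poly = sd > 0
        sub, pos = sub[:, poly], pos[poly]
        if sub.shape[1] < 2:
            continue
        Z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
        n = Z.shape[0]
        m = Z.shape[1]
        for i in range(m - 1):
            hi = int(np.searchsorted(pos, pos[i] + max_dist_bp, side="right"))
            if hi <= i + 1:
                continue
            r = Z[:, i] @ Z[:, i + 1:hi] / n
            dists.append(pos[i + 1:hi] - pos[i])
            r2s.append(r * r)
    if not dists:
        raise GrainmapError("no variant pairs within max_dist_bp")
    dist = np.concatenate(dists).astype(float)
    r2 = np.concatenate(r2s)

    edges = np.arange(0, max_dist_bp + bin_bp, bin_bp)
    which = np.digitize(dist, edges) - 1
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(len(edges) - 1):
        sel = np.nonzero(which == b)[0]
        if max_pairs_per_bin is not None and sel.size > max_pairs_per_bin:
            sel = rng.choice(sel, size=max_pairs_per_bin, replace=False)
        rows.append({
            "bin_start": int(edges[b]), "bin_end": int(edges[b + 1]),
            "mid": float((edges[b] + edges[b + 1]) / 2),
            "mean_r2": float(r2[sel].mean()) if sel.size else float("nan"),
            "n_pairs": int(sel.size),
        })
    return LdCurve(bins=pd.DataFrame(rows), bin_bp=bin_bp)


def decay_distance(curve: LdCurve) -> float | None:
    """Distance (bp) at which the binned mean r^2 first falls to half of the
    curve's maximum bin mean, linearly interpolated between bin midpoints.

    Returns ``None`` when the curve never reaches half-maximum within range
    (callers should report the decay distance as >= the scan range).
    """
    bins = curve.bins[curve.bins["n_pairs"] > 0]
    if bins.empty:
        raise GrainmapError("LD curve is empty")
    mids = bins["mid"].to_numpy()
    means = bins["mean_r2"].to_numpy()
    half = means.max() / 2.0
    below = np.nonzero(means <= half)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(mids[0])
    x0, y0 = mids[i - 1], means[i - 1]
    x1, y1 = mids[i], means[i]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - half) / (y0 - y1) * (x1 - x0))
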