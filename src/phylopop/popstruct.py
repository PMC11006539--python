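"""Genotype-matrix PCA and Hardy-Weinberg diagnostics.

Genotypes are coded 0/1/2 alternate-allele counts (NaN = missing).  Columns
are standardised EIGENSTRAT-style — centred by twice the allele frequency
and scaled by the binomial standard deviation sqrt(2p(1-p)) — with missing
entries mean-imputed to zero after centring.  PCA is an eigendecomposition
of the sample covariance of the standardised matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "GenotypeMatrix",
    "PCAResult",
    "genotype_matrix_from_sites",
    "standardize",
    "pca",
    "het_vs_hwe",
    "cluster_recovery",
]


@dataclass
class GenotypeMatrix:
    """n samples x m sites of alt-allele counts; NaN marks missing calls."""

    samples: list
    site_ids: list
    G: np.ndarray

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (len(self.samples), len(self.site_ids)):
            raise ValueError("genotype matrix shape does not match labels")


def genotype_matrix_from_sites(sites, sample_names) -> GenotypeMatrix:
    """Alt-allele-count matrix from VariantSites (non-ref alleles counted)."""
    n = len(sample_names)
    G = np.full((n, len(sites)), np.nan)
    ids = []
    for j, s in enumerate(sites):
        ids.append(s.site_id)
        for i, gt in enumerate(s.genotypes):
            if gt is not None:
                G[i, j] = sum(1 for a in gt if a != 0)
    return GenotypeMatrix(list(sample_names), ids, G)


def standardize(gm: GenotypeMatrix):
    """EIGENSTRAT standardisation; returns (S, kept column indices).

    Monomorphic (zero-variance) columns are dropped with a warning; an
    all-monomorphic matrix is an error.
    """
    G = gm.G
    p = np.nanmean(G, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("all columns are monomorphic; nothing to standardize")
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} monomorphic column(s)", stacklevel=2)
    Gk = G[:, keep]
    pk = p[keep]
    S = (Gk - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    S[~np.isfinite(S)] = 0.0  # mean imputation: missing -> 0 after centring
    return S, np.where(keep)[0]


@dataclass
class PCAResult:
    coordinates: np.ndarray  # n x k
    explained_fraction: np.ndarray  # k


def pca(S: np.ndarray, k: int) -> PCAResult:
    """Top-k eigendecomposition of the sample covariance S S^T / m.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); each component
    is oriented so its largest-magnitude coordinate is positive.
    """
    n, m = S.shape
    if k > min(n - 1, m):
        raise ValueError("k must be <= min(n-1, m)")
    cov = S @ S.T / m
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    total = vals.sum()
    coords = np.empty((n, k))
    for j in range(k):
        v = vecs[:, j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, j] = v * np.sqrt(vals[j])
    explained = vals[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(coordinates=coords, explained_fraction=explained)


def het_vs_hwe(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site observed heterozygosity against the Hardy-Weinberg expectation.

    Columns: ``p_hat`` (alt-allele frequency over called genotypes),
    ``obs_het`` (fraction of heterozygotes) and ``exp_het`` = 2 p(1-p).
    """
    rows = []
    for j, sid in enumerate(gm.site_ids):
        col = gm.G[:, j]
        called = col[np.isfinite(col)]
        if called.size == 0:
            rows.append((sid, np.nan, np.nan, np.nan))
            continue
        p_hat = called.mean() / 2.0
        obs = float((called == 1).mean())
        rows.append((sid, p_hat, obs, 2.0 * p_hat * (1.0 - p_hat)))
    return pd.DataFrame(rows, columns=["site_id", "p_hat", "obs_het", "exp_het"]).set_index("site_id")


def cluster_recovery(result: PCAResult, truth_labels, k: int | None = None, seed: int = 0) -> float:
    """Best-permutation agreement of k-means on PC1-2 with the true labels.

    ``k`` defaults to the number of distinct truth labels; agreement is the
    fraction of samples matched under the optimal cluster-to-label
    assignment (Hungarian algorithm), in [0, 1].
    """
    truth = list(truth_labels)
    n = len(truth)
    if result.coordinates.shape[0] != n:
        raise ValueError("one truth label per sample is required")
    uniq = sorted(set(truth))
    if k is None:
        k = len(uniq)
    X = result.coordinates[:, :2]
    pred = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    conf = np.zeros((k, len(uniq)), dtype=int)
    label_idx = {lab: i for i, lab in enumerate(uniq)}
    for c, lab in zip(pred, truth):
        conf[c, label_idx[lab]] += 1
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum()) / n
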