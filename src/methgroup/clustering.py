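"""Methylation group discovery.

Determines how many stable methylation groups a cohort contains and assigns
samples to them, combining four views of the same feature matrix:

* consensus k-means over subsampling resamples (Monti-style), summarized by
  the consensus-CDF area A(k) and its relative change Delta(k);
* the gap statistic (log within-cluster dispersion against a Monte-Carlo
  uniform-box null) with the one-standard-error selection rule;
* agglomerative hierarchical clustering (Euclidean, Ward) for the heatmap
  view; and
* a 2-D embedding (PCA in-repo; UMAP / t-SNE delegated).

k-means itself is Lloyd's algorithm with a best-of-restarts policy and
farthest-point repair of empty clusters.  When there are more features than
samples, distances are computed in an exact lower-dimensional isometric
embedding of the rows (eigendecomposition of the centered Gram matrix), which
changes no label or dispersion value beyond float round-off.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .cohort import MethylationCohort

__all__ = [
    "FeatureMatrix",
    "ConsensusResult",
    "GapResult",
    "SelectKResult",
    "select_features",
    "kmeans",
    "consensus_cluster",
    "cdf_area",
    "gap_statistic",
    "pairwise_dispersion",
    "hierarchical_cluster",
    "embed",
    "select_k",
    "assign_groups",
]

logger = logging.getLogger("methgroup")


@dataclass
class FeatureMatrix:
    """Samples x selected CpG features (beta values, no masked entries)."""

    values: np.ndarray
    sample_ids: list[str]
    site_indices: np.ndarray  # indices into the cohort's site table

    @property
    def X(self) -> np.ndarray:
        return self.values


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def select_features(cohort: MethylationCohort, n_top: int = 5_000) -> FeatureMatrix:
    """Top-variance CpG features.

    Sites masked (low coverage) in any sample are excluded; the ``n_top``
    sites with the highest across-sample beta variance are kept, ties broken
    by genomic order.
    """
    if cohort.n_samples < 2:
        raise ValueError("need at least 2 samples to select features")
    keep = ~cohort.masked.any(axis=0)
    usable = np.flatnonzero(keep)
    if len(usable) < 10:
        raise ValueError(f"only {len(usable)} usable (unmasked) sites; need >= 10")
    B = cohort.beta[:, usable]
    var = B.var(axis=0)
    if np.all(var == 0):
        raise ValueError("degenerate input: zero beta variance at every usable site")
    if n_top > len(usable):
        warnings.warn(
            f"n_top={n_top} exceeds {len(usable)} usable sites; using all"
        )
        n_top = len(usable)
    order = np.lexsort((usable, -var))[:n_top]
    chosen = np.sort(usable[order])
    return FeatureMatrix(
        values=cohort.beta[:, chosen].copy(),
        sample_ids=list(cohort.sample_ids),
        site_indices=chosen,
    )


# ---------------------------------------------------------------------------
# k-means (Lloyd's algorithm)
# ---------------------------------------------------------------------------

def _reduce_rows(X: np.ndarray) -> np.ndarray:
    """Exact isometric embedding of rows into <= n dimensions (Gram eigh)."""
    n, d = X.shape
    if d <= n:
        return X
    Xc = X - X.mean(axis=0)
    G = Xc @ Xc.T
    w, V = np.linalg.eigh(G)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def _sq_dists(Y: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = (
        (Y**2).sum(axis=1)[:, None]
        - 2.0 * Y @ centers.T
        + (centers**2).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _lloyd_once(
    Y: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, float]:
    n = Y.shape[0]
    centers = Y[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1, dtype=int)
    for _ in range(max_iter):
        d2 = _sq_dists(Y, centers)
        new = d2.argmin(axis=1)
        for c in range(k):  # farthest-point repair of empty clusters
            if (new == c).any():
                continue
            sizes = np.bincount(new, minlength=k)
            cur = d2[np.arange(n), new]
            cur = np.where(sizes[new] > 1, cur, -np.inf)
            far = int(np.argmax(cur))
            new[far] = c
        if np.array_equal(new, labels):
            break
        labels = new
        for c in range(k):
            centers[c] = Y[labels == c].mean(axis=0)
    within_ss = float(((Y - centers[labels]) ** 2).sum())
    return labels, within_ss


def _kmeans_reduced(
    Y: np.ndarray, k: int, n_restarts: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    best_labels, best_ss = None, np.inf
    for _ in range(n_restarts):
        labels, ss = _lloyd_once(Y, k, rng)
        if ss < best_ss:
            best_labels, best_ss = labels, ss
    assert best_labels is not None
    return best_labels, best_ss


def kmeans(
    X, k: int, n_restarts: int = 20, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts Lloyd k-means with the squared-Euclidean objective.

    Returns ``(labels, centers, within_ss)``; labels are 0-based cluster
    indices, centers are cluster means in the original feature space, and
    ``within_ss = sum_i ||x_i - mu_c(i)||^2``.
    """
    X = _as_array(X)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    rng = np.random.default_rng(seed)
    Y = _reduce_rows(X)
    labels, within_ss = _kmeans_reduced(Y, k, n_restarts, rng)
    centers = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
    return labels, centers, within_ss


def pairwise_dispersion(X, labels: np.ndarray) -> float:
    """W = sum_r (1/(2 n_r)) sum_{i,j in C_r} d^2(i, j), squared Euclidean.

    Algebraically identical to the within-cluster sum of squares; kept as a
    separate, literal implementation so the identity can be asserted.
    """
    X = _as_array(X)
    total = 0.0
    for c in np.unique(labels):
        P = X[labels == c]
        n_r = len(P)
        d2 = _sq_dists(P, P)
        total += d2.sum() / (2.0 * n_r)
    return float(total)


# ---------------------------------------------------------------------------
# consensus clustering (Monti-style subsampling)
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Per-k consensus matrices from H subsampling resamples at fraction p."""

    k_range: list[int]
    H: int
    p: float
    matrices: dict[int, np.ndarray]
    sample_ids: list[str] = field(default_factory=list)


def consensus_cluster(
    X,
    k_range=range(2, 7),
    H: int = 100,
    p: float = 0.8,
    seed: int | None = None,
    n_restarts: int = 20,
    subsamples: list[np.ndarray] | None = None,
) -> ConsensusResult:
    """Consensus k-means: C_k(i,j) = co-clustering rate of i,j over the
    resamples in which both were drawn.

    Each resample draws ceil(p*n) samples without replacement and clusters
    them with best-of-restarts k-means.  Pairs never co-sampled get the
    neutral value 0.5 with a logged warning.  ``subsamples`` may supply
    explicit index sets (reused for every k) for reproducible small-scale
    verification.
    """
    mat = _as_array(X)
    n = mat.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if H < 2 and subsamples is None:
        raise ValueError("H must be >= 2")
    if n < max(ks) + 1:
        raise ValueError(f"need at least max(k)+1={max(ks) + 1} samples, have {n}")
    m = int(np.ceil(p * n))
    rng = np.random.default_rng(seed)
    sample_ids = X.sample_ids if isinstance(X, FeatureMatrix) else [str(i) for i in range(n)]
    matrices: dict[int, np.ndarray] = {}
    n_resamples = len(subsamples) if subsamples is not None else H
    for k in ks:
        num = np.zeros((n, n))
        den = np.zeros((n, n))
        for h in range(n_resamples):
            if subsamples is not None:
                idx = np.asarray(subsamples[h], dtype=int)
            else:
                idx = rng.choice(n, size=m, replace=False)
            Ys = _reduce_rows(mat[idx])
            labels, _ = _kmeans_reduced(Ys, k, n_restarts, rng)
            same = (labels[:, None] == labels[None, :]).astype(float)
            num[np.ix_(idx, idx)] += same
            den[np.ix_(idx, idx)] += 1.0
        never = den == 0
        np.fill_diagonal(never, False)
        if never.any():
            logger.warning(
                "consensus k=%d: %d sample pairs never co-sampled; set to 0.5",
                k, int(never.sum()) // 2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(den > 0, num / np.maximum(den, 1), 0.5)
        np.fill_diagonal(C, 1.0)
        matrices[k] = C
    return ConsensusResult(
        k_range=ks, H=n_resamples, p=p, matrices=matrices, sample_ids=sample_ids
    )


def cdf_area(result: ConsensusResult) -> pd.DataFrame:
    """Area under the consensus CDF, A(k), and its relative change Delta(k).

    The empirical CDF is taken over the n(n-1)/2 upper-triangle consensus
    entries; A(k) = sum_i (x_i - x_{i-1}) * CDF(x_{i-1}) over sorted distinct
    entry values.  Delta at the smallest k equals A there; for larger k,
    Delta(k) = (A(k) - A(k-1)) / A(k-1).  Requires a contiguous k range.
    """
    ks = result.k_range
    for prev, cur in zip(ks, ks[1:]):
        if cur != prev + 1:
            raise ValueError(f"k range not contiguous: missing k={prev + 1}")
    rows = []
    prev_area = None
    for k in ks:
        C = result.matrices[k]
        iu = np.triu_indices(C.shape[0], 1)
        entries = np.sort(C[iu])
        x = np.unique(entries)
        area = 0.0
        if len(x) > 1:
            cdf_vals = np.searchsorted(entries, x, side="right") / len(entries)
            area = float(np.sum(np.diff(x) * cdf_vals[:-1]))
        if prev_area is None:
            delta = area
        else:
            delta = (area - prev_area) / prev_area if prev_area > 0 else np.inf
        rows.append((k, area, delta))
        prev_area = area
    return pd.DataFrame(rows, columns=["k", "area", "delta"])


# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------

@dataclass
class GapResult:
    """Per-k dispersions and gap values; ``k_hat`` by the 1-SE rule."""

    table: pd.DataFrame
    k_hat: int
    B: int


def _gap_k_hat(ks: list[int], gap: np.ndarray, s: np.ndarray) -> int:
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - s[j + 1]:
            return ks[j]
    return ks[int(np.argmax(gap))]


def pca_scores(X, n_components: int) -> np.ndarray:
    """Scores on the top principal axes (SVD of the centered matrix)."""
    mat = _as_array(X)
    Xc = mat - mat.mean(axis=0)
    U, S, _Vt = np.linalg.svd(Xc, full_matrices=False)
    q = min(n_components, len(S))
    return U[:, :q] * S[:q]


def gap_statistic(
    X,
    k_range=range(1, 7),
    B: int = 50,
    seed: int | None = None,
    n_restarts: int = 10,
    n_pcs: int | None = None,
) -> GapResult:
    """Gap statistic with a featurewise uniform-box Monte-Carlo null.

    Gap(k) = (1/B) sum_b log W*_kb - log W_k, with W_k the within-cluster
    dispersion of the data at k and W*_kb that of reference datasets drawn
    uniformly over each feature's observed [min, max].  s_k is the reference
    log-dispersion standard deviation scaled by sqrt(1 + 1/B); k_hat is the
    smallest k with Gap(k) >= Gap(k+1) - s_{k+1}, else argmax Gap.

    ``n_pcs`` projects the data onto its top principal components before the
    comparison.  The uniform reference's marginal dispersion gain per extra
    cluster shrinks like 1/dimension, so on thousands of raw features the
    gap curve never flattens and the selection rule degenerates; computing
    the statistic on a low-dimensional score matrix (any k <= 6 structure
    lives in <= 5 axes) restores the stopping behaviour the statistic was
    designed around.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    mat = _as_array(X)
    if n_pcs is not None:
        mat = pca_scores(mat, n_pcs)
    n = mat.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if max(ks) > n:
        raise ValueError("max k exceeds number of samples")
    rng = np.random.default_rng(seed)
    Y = _reduce_rows(mat)
    W = np.empty(len(ks))
    for j, k in enumerate(ks):
        labels, ss = _kmeans_reduced(Y, k, n_restarts, rng)
        if np.bincount(labels, minlength=k).min() == 0:
            raise ValueError(f"empty cluster at k={k} after repair")
        W[j] = ss
    mins, maxs = mat.min(axis=0), mat.max(axis=0)
    log_wstar = np.empty((B, len(ks)))
    for b in range(B):
        Xb = rng.uniform(mins, maxs, size=mat.shape)
        Yb = _reduce_rows(Xb)
        for j, k in enumerate(ks):
            _, ss = _kmeans_reduced(Yb, k, n_restarts, rng)
            log_wstar[b, j] = np.log(ss)
    with np.errstate(divide="ignore"):
        log_w = np.log(W)
    ref_mean = log_wstar.mean(axis=0)
    gap = ref_mean - log_w
    s = log_wstar.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    k_hat = _gap_k_hat(ks, gap, s)
    table = pd.DataFrame(
        {"k": ks, "W": W, "log_W": log_w, "ref_log_W": ref_mean, "gap": gap, "s": s}
    )
    return GapResult(table=table, k_hat=int(k_hat), B=B)


# ---------------------------------------------------------------------------
# hierarchical clustering and embedding
# ---------------------------------------------------------------------------

def hierarchical_cluster(X, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering (Euclidean, Ward); returns (labels 1..k,
    dendrogram leaf order for heatmap rendering)."""
    mat = _as_array(X)
    if not np.isfinite(mat).all():
        raise ValueError("X contains non-finite values")
    if k > mat.shape[0]:
        raise ValueError("k exceeds number of samples")
    Z = hierarchy.linkage(mat, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    return labels.astype(int), order


def embed(
    X, method: str = "umap", n_neighbors: int = 15, seed: int | None = None
) -> np.ndarray:
    """2-D embedding of samples: 'pca' (in-repo SVD), 'umap' or 'tsne'."""
    mat = _as_array(X)
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to embed")
    if method == "pca":
        Xc = mat - mat.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: dominant loading of each axis is positive
        for j in range(min(2, Vt.shape[0])):
            i = int(np.argmax(np.abs(Vt[j])))
            if Vt[j, i] < 0:
                Vt[j] *= -1.0
                U[:, j] *= -1.0
        coords = U[:, :2] * S[:2]
        if coords.shape[1] < 2:  # rank-1 data
            coords = np.column_stack([coords, np.zeros(n)])
        return coords
    if method == "umap":
        import umap

        reducer = umap.UMAP(
            n_neighbors=min(n_neighbors, n - 1),
            n_components=2,
            random_state=seed if seed is not None else 0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(reducer.fit_transform(mat), dtype=float)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (n - 1) / 3.0)
        ts = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed if seed is not None else 0,
            init="pca",
        )
        return np.asarray(ts.fit_transform(mat), dtype=float)
    raise ValueError(f"unknown embedding method: {method!r}")


# ---------------------------------------------------------------------------
# k selection and final assignment
# ---------------------------------------------------------------------------

@dataclass
class SelectKResult:
    """Combined decision: gap statistic is primary, Delta-area corroborates."""

    k_selected: int
    k_gap: int            # raw gap k_hat over its full range (may be 1)
    k_gap_restricted: int  # gap rule re-applied over k >= 2
    k_delta: int          # Delta-area elbow over k >= 3 (threshold rule)
    concordant: bool
    diagnostics: pd.DataFrame


def select_k(
    consensus: ConsensusResult,
    gap: GapResult,
    delta_threshold: float = 0.1,
) -> SelectKResult:
    """Combine the gap statistic and the consensus Delta-area elbow.

    The primary decision is the gap-statistic 1-SE rule restricted to
    k >= 2; the corroborating Delta-area elbow is the largest k >= 3 whose
    relative CDF-area gain exceeds ``delta_threshold`` (else the smallest k
    in the consensus range).  Discordance is flagged, never fatal.
    """
    cdf = cdf_area(consensus)
    gks = list(gap.table["k"])
    cks = list(cdf["k"])
    if not set(gks) & set(cks):
        raise ValueError("gap and consensus k ranges are disjoint")
    sub = gap.table[gap.table["k"] >= 2].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("gap result contains no k >= 2")
    k_gap_restricted = _gap_k_hat(
        list(sub["k"]), sub["gap"].to_numpy(), sub["s"].to_numpy()
    )
    candidates = cdf[(cdf["k"] >= 3) & (cdf["delta"] >= delta_threshold)]
    k_delta = int(candidates["k"].max()) if len(candidates) else int(min(cks))
    concordant = k_gap_restricted == k_delta
    if not concordant:
        logger.warning(
            "k selection discordant: gap=%d, delta-area=%d", k_gap_restricted, k_delta
        )
    diagnostics = pd.merge(gap.table, cdf, on="k", how="outer").sort_values("k")
    return SelectKResult(
        k_selected=int(k_gap_restricted),
        k_gap=int(gap.k_hat),
        k_gap_restricted=int(k_gap_restricted),
        k_delta=k_delta,
        concordant=bool(concordant),
        diagnostics=diagnostics.reset_index(drop=True),
    )


def assign_groups(
    X, k: int, seed: int | None = None, n_restarts: int = 50
) -> np.ndarray:
    """Final 1..k group labels: best-of-restarts k-means on the full feature
    matrix, groups renumbered by descending size (ties by smallest member
    index)."""
    mat = _as_array(X)
    n = mat.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    if k == 1:
        return np.ones(n, dtype=int)
    labels, _, _ = kmeans(mat, k, n_restarts=n_restarts, seed=seed)
    order = sorted(
        range(k),
        key=lambda c: (-(labels == c).sum(), int(np.flatnonzero(labels == c)[0])),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.asarray([remap[c] for c in labels], dtype=int)
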