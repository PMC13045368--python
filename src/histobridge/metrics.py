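"""Quantitative evaluation suite for translated and edited images.

Set-level realism is scored by the Fréchet distance between Gaussians
fitted to image features (FID), its before/after difference (dFID), and an
inverted normalized variant (real-vs-real FID over synthetic-vs-real FID,
~1 when synthetic images are indistinguishable from a real split).
Pair-level similarity uses SSIM with a sliding uniform window and the
derived structural distance (1 - SSIM)/2 in [0, 1].  Feature-space tools
cover cosine distance, Isolation-Forest inlier scores in [-1, 1],
majority-vote top-k retrieval accuracy, and the percentage-reduction
editing-effectiveness statistic computed from top-K retrieval distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import IsolationForest

__all__ = ["FeatureGaussian", "fit_feature_gaussian", "fid", "delta_fid",
           "inverted_normalized_fid", "ssim_map", "structural_distance",
           "cosine_distance", "inlier_scores", "retrieval_mv_at_k",
           "editing_effectiveness"]


# ----------------------------------------------------------------- FID family
@dataclass(frozen=True)
class FeatureGaussian:
    """Sample mean and (unbiased) covariance of a feature set."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int

    def __post_init__(self):
        if self.mu.ndim != 1 or self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("mu must be (d,) and sigma (d, d)")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")


def fit_feature_gaussian(features: np.ndarray) -> FeatureGaussian:
    """Fit mean and unbiased covariance to an n x d feature matrix (n >= 2)."""
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 2 or f.shape[0] < 2:
        raise ValueError(f"need an n x d matrix with n >= 2, got shape {f.shape}")
    mu = f.mean(axis=0)
    sigma = np.cov(f, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    sigma = 0.5 * (sigma + sigma.T)
    return FeatureGaussian(mu=mu, sigma=sigma, n=f.shape[0])


def _sqrtm_psd(m: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (m + m.T))
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(a: FeatureGaussian, b: FeatureGaussian) -> float:
    """Fréchet distance  ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^(1/2)).

    The matrix square root is taken through the symmetric product
    ``S_a^(1/2) S_b S_a^(1/2)``, which is PSD, so the computation stays in
    real symmetric eigendecompositions throughout.
    """
    if a.mu.size != b.mu.size:
        raise ValueError(f"dimension mismatch: {a.mu.size} vs {b.mu.size}")
    diff = a.mu - b.mu
    sa_half = _sqrtm_psd(a.sigma)
    inner = _sqrtm_psd(sa_half @ b.sigma @ sa_half)
    val = float(diff @ diff + np.trace(a.sigma) + np.trace(b.sigma)
                - 2.0 * np.trace(inner))
    if val < -1e-6:
        raise FloatingPointError(f"FID came out significantly negative: {val}")
    return max(val, 0.0)


def delta_fid(before: np.ndarray, after: np.ndarray,
              reference: np.ndarray) -> float:
    """FID(before, ref) - FID(after, ref); positive when translation helped."""
    ref = fit_feature_gaussian(reference)
    return fid(fit_feature_gaussian(before), ref) - fid(fit_feature_gaussian(after), ref)


def inverted_normalized_fid(real_a: np.ndarray, real_b: np.ndarray,
                            synth: np.ndarray) -> float:
    """FID(real_a, real_b) / FID(synth, real_b); ~1 for indistinguishable synth."""
    gb = fit_feature_gaussian(real_b)
    denom = fid(fit_feature_gaussian(synth), gb)
    if denom <= 0:
        raise ZeroDivisionError("FID(synth, real_b) is zero; sets are degenerate")
    return fid(fit_feature_gaussian(real_a), gb) / denom


# ----------------------------------------------------------------------- SSIM
def _ssim_single(x: np.ndarray, y: np.ndarray, window: int,
                 c1: float, c2: float) -> np.ndarray:
    wx = sliding_window_view(x, (window, window))
    wy = sliding_window_view(y, (window, window))
    n = window * window
    mx = wx.mean(axis=(-1, -2))
    my = wy.mean(axis=(-1, -2))
    # sample (ddof=1) second moments, the scikit-image convention
    vx = (wx ** 2).mean(axis=(-1, -2)) - mx ** 2
    vy = (wy ** 2).mean(axis=(-1, -2)) - my ** 2
    cxy = (wx * wy).mean(axis=(-1, -2)) - mx * my
    corr = n / (n - 1.0)
    vx, vy, cxy = vx * corr, vy * corr, cxy * corr
    return ((2 * mx * my + c1) * (2 * cxy + c2)
            / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


def ssim_map(x: np.ndarray, y: np.ndarray, window: int = 7,
             c1: float = 0.01 ** 2, c2: float = 0.03 ** 2,
             ) -> tuple[float, np.ndarray]:
    """Mean SSIM and the per-window SSIM map (valid windows only).

    Images may be HxW or HxWxC; channels are scored separately and the maps
    averaged.  Defaults assume data range 1 (images in [0, 1]), window 7,
    and sample-covariance normalization.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if min(x.shape[0], x.shape[1]) < window:
        raise ValueError("image smaller than the SSIM window")
    if x.ndim == 2:
        smap = _ssim_single(x, y, window, c1, c2)
    else:
        smap = np.mean([_ssim_single(x[..., c], y[..., c], window, c1, c2)
                        for c in range(x.shape[2])], axis=0)
    return float(smap.mean()), smap


def structural_distance(x: np.ndarray, y: np.ndarray, window: int = 7,
                        c1: float = 0.01 ** 2, c2: float = 0.03 ** 2,
                        ) -> tuple[float, np.ndarray]:
    """(1 - SSIM)/2 per window, in [0, 1]; 0 for identical images."""
    _, smap = ssim_map(x, y, window, c1, c2)
    dmap = np.clip((1.0 - smap) / 2.0, 0.0, 1.0)
    return float(dmap.mean()), dmap


# -------------------------------------------------------------- feature space
def cosine_distance(f: np.ndarray, g: np.ndarray) -> float:
    """1 - cos(f, g); lies in [0, 2]."""
    f = np.asarray(f, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    if f.size != g.size:
        raise ValueError(f"dimension mismatch: {f.size} vs {g.size}")
    nf, ng = np.linalg.norm(f), np.linalg.norm(g)
    if nf == 0 or ng == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(np.clip(1.0 - f @ g / (nf * ng), 0.0, 2.0))


def _cosine_distance_matrix(q: np.ndarray, db: np.ndarray) -> np.ndarray:
    qn = q / np.linalg.norm(q, axis=1, keepdims=True)
    dn = db / np.linalg.norm(db, axis=1, keepdims=True)
    return np.clip(1.0 - qn @ dn.T, 0.0, 2.0)


def inlier_scores(train_features: np.ndarray, query_features: np.ndarray,
                  seed: int = 0, n_trees: int = 100) -> np.ndarray:
    """Isolation-Forest decision scores rescaled to [-1, 1] (higher = inlier)."""
    train = np.asarray(train_features, dtype=np.float64)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValueError("training feature set must be a nonempty n x d matrix")
    forest = IsolationForest(n_estimators=n_trees, random_state=seed)
    forest.fit(train)
    raw = forest.decision_function(np.asarray(query_features, dtype=np.float64))
    return np.clip(2.0 * raw, -1.0, 1.0)


def retrieval_mv_at_k(query_features: np.ndarray, query_labels,
                      db_features: np.ndarray, db_labels, k: int) -> float:
    """Majority-vote accuracy over the k nearest database items (cosine).

    Vote ties are broken in favor of the label whose best-ranked (nearest)
    supporting item comes first.
    """
    q = np.asarray(query_features, dtype=np.float64)
    db = np.asarray(db_features, dtype=np.float64)
    query_labels = np.asarray(query_labels)
    db_labels = np.asarray(db_labels)
    if db.shape[0] == 0:
        raise ValueError("database is empty")
    if k < 1 or k > db.shape[0]:
        raise ValueError(f"k={k} outside [1, {db.shape[0]}]")
    dist = _cosine_distance_matrix(q, db)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    correct = 0
    for qi in range(q.shape[0]):
        votes: dict = {}
        first_rank: dict = {}
        for rank, j in enumerate(order[qi]):
            lab = db_labels[j]
            votes[lab] = votes.get(lab, 0) + 1
            first_rank.setdefault(lab, rank)
        winner = min(votes, key=lambda lab: (-votes[lab], first_rank[lab]))
        correct += int(winner == query_labels[qi])
    return correct / q.shape[0]


def _topk_mean_distance(query: np.ndarray, db: np.ndarray, k: int) -> float:
    d = _cosine_distance_matrix(query[None, :], db)[0]
    return float(np.sort(d)[:k].mean())


def editing_effectiveness(query_before: np.ndarray, query_after: np.ndarray,
                          db_features: np.ndarray, K: int = 5) -> float:
    """Percentage reduction in mean top-K retrieval distance after editing.

    ``(dbar(q) - dbar(q~)) / dbar(q)`` with ``dbar`` the mean cosine distance
    of a query to its own top-K retrieved database items; positive when the
    edited image moved closer to the target-condition database.
    """
    db = np.asarray(db_features, dtype=np.float64)
    if K < 1 or K > db.shape[0]:
        raise ValueError(f"K={K} outside [1, {db.shape[0]}]")
    d_before = _topk_mean_distance(np.asarray(query_before, np.float64).ravel(), db, K)
    d_after = _topk_mean_distance(np.asarray(query_after, np.float64).ravel(), db, K)
    if d_before == 0:
        raise ZeroDivisionError("mean retrieval distance of the original query is 0")
    return (d_before - d_after) / d_before
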