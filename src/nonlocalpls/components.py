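"""Discriminability and reproducibility analysis of latent components.

Once a latent decomposition is fitted, its per-subject scores are a compact
representation of each subject.  This module asks two questions of them:

* **Discriminability** — can a two-class Fisher linear discriminant on the
  scores separate clinical groups?  Separation is quantified by the area
  under the ROC curve of *leave-one-out* discriminant values (each subject
  scored by a model fit without it), and each component's contribution by
  the absolute value of its LDA weight (computed on standardized scores so
  magnitudes are comparable).

* **Reproducibility** — do the most discriminative components reappear when
  the model is refit on a different training draw?  Components of two fits
  are greedily matched by absolute Pearson correlation of their spatial maps
  (both modalities concatenated), accepting matches above a threshold
  (default 0.5) and always taking the strongest available pair first.
  Counting, per reference component, how many repeats produced a matching
  component that was also among that repeat's top-ranked set gives the
  reproducibility profile.

Also provided: extraction of a component's "network" — threshold the map at
a quantile of its absolute values, clean it with a morphological opening,
and label the surviving connected clusters, recording each cluster's sign
(correlated vs anticorrelated hubs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import ball, disk

__all__ = [
    "DiscriminabilityResult",
    "MatchTable",
    "lda_loo_auc",
    "rank_components",
    "component_signatures",
    "match_components",
    "reproducibility_counts",
    "extract_network",
]


@dataclass
class DiscriminabilityResult:
    comparison: tuple[str, str]
    lda_weights: np.ndarray
    loo_scores: np.ndarray
    labels: np.ndarray
    auc: float
    top_components: np.ndarray


@dataclass
class MatchTable:
    """Cross-fit component correspondences: (i, j, correlation) triples."""

    pairs: list[tuple[int, int, float]]
    unmatched_i: list[int]
    unmatched_j: list[int]
    threshold: float

    def partner_of(self, i: int) -> int | None:
        for a, b, _ in self.pairs:
            if a == i:
                return b
        return None


# ---------------------------------------------------------------------------
# LDA / ROC
# ---------------------------------------------------------------------------

def _fisher_direction(Z: np.ndarray, is_pos: np.ndarray, ridge: float) -> np.ndarray:
    mu_pos = Z[is_pos].mean(axis=0)
    mu_neg = Z[~is_pos].mean(axis=0)
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    cov_pos = np.cov(Z[is_pos], rowvar=False, ddof=1) if n_pos > 1 else 0.0
    cov_neg = np.cov(Z[~is_pos], rowvar=False, ddof=1) if n_neg > 1 else 0.0
    pooled = ((n_pos - 1) * np.atleast_2d(cov_pos) + (n_neg - 1) * np.atleast_2d(cov_neg)) / (
        n_pos + n_neg - 2
    )
    pooled = pooled + ridge * np.eye(Z.shape[1])
    try:
        w = np.linalg.solve(pooled, mu_pos - mu_neg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular beyond ridge rescue"
        ) from exc
    # orient toward the positive class
    if (mu_pos - mu_neg) @ w < 0:  # pragma: no cover - cannot happen for PSD pooled
        w = -w
    return w


def _rank_auc(values: np.ndarray, is_pos: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation, ties shared."""
    from scipy.stats import rankdata

    ranks = rankdata(values)
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def lda_loo_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    label_pair: tuple[str, str],
    ridge: float = 1e-6,
    n_top: int = 5,
) -> DiscriminabilityResult:
    """Leave-one-out Fisher LDA on latent scores for one group comparison.

    ``label_pair = (positive, negative)``.  Subjects outside the pair are
    ignored.  Scores are standardized per fold with training statistics;
    each held-out subject receives the discriminant value of the model fit
    without it, and the AUC is computed from those values by pair-ranking.
    The reported weights come from the all-subject fit on standardized
    scores; ``top_components`` ranks them by absolute value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos, neg = label_pair
    sel = (labels == pos) | (labels == neg)
    if not sel.any():
        raise ValueError(f"no subjects with labels {label_pair}")
    Z = scores[sel]
    y = labels[sel] == pos
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("each class needs at least 2 subjects")

    def standardize(train: np.ndarray, apply_to: np.ndarray):
        mu, sd = train.mean(axis=0), train.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        return (apply_to - mu) / sd

    w_full = _fisher_direction(standardize(Z, Z), y, ridge)

    n = Z.shape[0]
    loo = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Zt, yt = Z[keep], y[keep]
        w = _fisher_direction(standardize(Zt, Zt), yt, ridge)
        loo[i] = standardize(Zt, Z[i : i + 1])[0] @ w

    return DiscriminabilityResult(
        comparison=(pos, neg),
        lda_weights=w_full,
        loo_scores=loo,
        labels=labels[sel],
        auc=_rank_auc(loo, y),
        top_components=rank_components(w_full, n_top),
    )


def rank_components(weights: np.ndarray, n_top: int = 5) -> np.ndarray:
    """Indices of the ``n_top`` largest |weights|, descending; ties -> lower index."""
    weights = np.asarray(weights)
    order = np.argsort(-np.abs(weights), kind="stable")
    return order[: min(n_top, weights.size)]


# ---------------------------------------------------------------------------
# cross-repeat matching
# ---------------------------------------------------------------------------

def component_signatures(model) -> np.ndarray:
    """Concatenated (x-weight, y-weight) map per component, rows x voxels.

    Using both modalities makes matching stricter: a component only
    reproduces if *both* of its spatial patterns reappear together.
    """
    return np.concatenate([model.W, model.C], axis=0).T


def match_components(
    maps_i: np.ndarray, maps_j: np.ndarray, threshold: float = 0.5
) -> MatchTable:
    """Greedy strongest-first matching of two component sets.

    Repeatedly accepts the unmatched pair with the largest absolute Pearson
    correlation, as long as it exceeds ``threshold``.  Symmetric in its
    arguments (up to index swap).
    """
    maps_i = np.atleast_2d(maps_i)
    maps_j = np.atleast_2d(maps_j)
    if maps_i.shape[1] != maps_j.shape[1]:
        raise ValueError(
            f"component maps live on different grids: {maps_i.shape[1]} vs {maps_j.shape[1]} voxels"
        )

    def _std_rows(M):
        Mc = M - M.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Mc, axis=1, keepdims=True)
        return np.divide(Mc, norms, out=np.zeros_like(Mc), where=norms > 0)

    corr = _std_rows(maps_i) @ _std_rows(maps_j).T
    abs_corr = np.abs(corr)
    pairs: list[tuple[int, int, float]] = []
    free_i = set(range(maps_i.shape[0]))
    free_j = set(range(maps_j.shape[0]))
    work = abs_corr.copy()
    while free_i and free_j:
        i, j = np.unravel_index(np.argmax(work), work.shape)
        if work[i, j] <= threshold:
            break
        pairs.append((int(i), int(j), float(corr[i, j])))
        free_i.discard(int(i))
        free_j.discard(int(j))
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return MatchTable(
        pairs=pairs,
        unmatched_i=sorted(free_i),
        unmatched_j=sorted(free_j),
        threshold=threshold,
    )


def reproducibility_counts(
    signatures: list[np.ndarray],
    top_sets: list[np.ndarray],
    reference: int = 0,
    threshold: float = 0.5,
) -> tuple[np.ndarray, dict[int, list[int]]]:
    """How often each reference-repeat component reproduces across repeats.

    For each component of repeat ``reference``, count the *other* repeats in
    which it has a qualifying match (|r| > threshold, strongest-first) whose
    partner is also in that repeat's top-ranked set.  Components of other
    repeats with no reference match are reported separately per repeat.
    """
    if len(signatures) != len(top_sets) or len(signatures) < 2:
        raise ValueError("need signatures and top sets for at least 2 repeats")
    ref_sig = signatures[reference]
    counts = np.zeros(ref_sig.shape[0], dtype=int)
    unmatched: dict[int, list[int]] = {}
    for r, (sig, top) in enumerate(zip(signatures, top_sets)):
        if r == reference:
            continue
        table = match_components(ref_sig, sig, threshold)
        top = set(int(t) for t in np.asarray(top).ravel())
        for i, j, _ in table.pairs:
            if j in top:
                counts[i] += 1
        unmatched[r] = table.unmatched_j
    return counts, unmatched


# ---------------------------------------------------------------------------
# network extraction
# ---------------------------------------------------------------------------

def extract_network(
    component_map: np.ndarray,
    quantile_threshold: float = 0.95,
    opening_radius: int = 1,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold + morphological opening + connected-component labelling.

    Binarises ``|map|`` at the given quantile of its absolute values (within
    the mask if one is given), opens the binary volume with a ball
    structuring element of ``opening_radius`` (radius 0 skips the opening),
    and labels 6-connected clusters.  Returns the cluster label volume and a
    table with each cluster's voxel count and dominant sign (+1 correlated /
    -1 anticorrelated hub).
    """
    vol = np.asarray(component_map, dtype=float)
    if not 0 < quantile_threshold < 1:
        raise ValueError("quantile_threshold must lie in (0, 1)")
    region = np.ones(vol.shape, bool) if mask is None else np.asarray(mask, bool)
    thr = np.quantile(np.abs(vol[region]), quantile_threshold)
    binary = (np.abs(vol) >= thr) & region
    if opening_radius > 0:
        selem = ball(opening_radius) if vol.ndim == 3 else disk(opening_radius)
        binary = ndimage.binary_opening(binary, structure=selem)
    if not binary.any():
        warnings.warn("no voxels survive thresholding + opening", stacklevel=2)
        return np.zeros(vol.shape, dtype=np.int32), pd.DataFrame(
            columns=["cluster", "n_voxels", "sign"]
        )
    # default ndimage structure = faces-only connectivity (6-connected in 3D)
    labels, n = ndimage.label(binary)
    rows = []
    for lab in range(1, n + 1):
        sel = labels == lab
        rows.append((lab, int(sel.sum()), int(np.sign(vol[sel].mean()) or 1)))
    return labels.astype(np.int32), pd.DataFrame(rows, columns=["cluster", "n_voxels", "sign"])
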