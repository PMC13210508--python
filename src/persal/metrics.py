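"""Saliency evaluation metrics: NSS, CC, AUC-Borji, shuffled AUC, cosine.

The AUC variants follow the MIT/Tuebingen saliency-benchmark definitions.
Positives are the map values at ground-truth fixation cells.  AUC-Borji
draws its negatives uniformly at random over all cells, shuffled AUC draws
them from fixation locations pooled over *other* images (so a purely
centre-biased map gains no credit).  Each split's AUC is the Mann-Whitney
statistic with ties counted 1/2, averaged over ``n_splits`` seeded splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .saliency import SaliencyMap

__all__ = [
    "FixationSet",
    "fixations_from_samples",
    "nss",
    "cc",
    "auc_borji",
    "shuffled_auc",
    "map_cosine",
]


@dataclass
class FixationSet:
    """Deduplicated in-bounds fixation cells for one image."""

    image_id: str
    points: np.ndarray  # (n, 2) int array of (x, y)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=int).reshape(-1, 2)
        self.points = np.unique(pts, axis=0) if len(pts) else pts

    def __len__(self) -> int:
        return len(self.points)


def fixations_from_samples(samples, width: int, height: int,
                           image_id: str = "") -> FixationSet:
    """Raw in-bounds merged gaze cells, deduplicated per cell."""
    pts = []
    for s in samples:
        if s.xy is None:
            continue
        x, y = int(np.floor(s.xy[0])), int(np.floor(s.xy[1]))
        if 0 <= x < width and 0 <= y < height:
            pts.append((x, y))
    return FixationSet(image_id=image_id, points=np.asarray(pts, dtype=int))


def _values_at(smap: SaliencyMap, points: np.ndarray) -> np.ndarray:
    return smap.values[points[:, 1], points[:, 0]]


def nss(smap: SaliencyMap, fix: FixationSet) -> float:
    """Normalized scanpath saliency: mean z-scored map value at fixations.

    The map is standardized to mean 0, population SD 1 over all cells; a
    constant map (zero SD) scores 0 by convention.
    """
    if len(fix) == 0:
        return float("nan")
    v = smap.values
    sd = v.std()
    if sd == 0:
        return 0.0
    z = (v - v.mean()) / sd
    return float(z[fix.points[:, 1], fix.points[:, 0]].mean())


def cc(map_a: SaliencyMap, map_b: SaliencyMap) -> float:
    """Pearson correlation between two maps over cells; NaN if constant."""
    a, b = map_a.values.ravel(), map_b.values.ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have equal dimensions")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _auc_tie_half(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2, via average ranks."""
    ranks = rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_borji(
    smap: SaliencyMap,
    fix: FixationSet,
    n_rand: int | None = None,
    n_splits: int = 100,
    seed: int = 0,
) -> float:
    """AUC with uniform-random negative locations, averaged over splits.

    ``n_rand`` defaults to the number of fixations per split.
    """
    if len(fix) == 0:
        return float("nan")
    pos = _values_at(smap, fix.points)
    if n_rand is None:
        n_rand = len(fix)
    rng = np.random.default_rng(seed)
    h, w = smap.values.shape
    flat = smap.values.ravel()
    aucs = []
    for _ in range(n_splits):
        neg = flat[rng.integers(0, h * w, size=n_rand)]
        aucs.append(_auc_tie_half(pos, neg))
    return float(np.mean(aucs))


def shuffled_auc(
    smap: SaliencyMap,
    fix: FixationSet,
    other_fixations: Sequence[FixationSet],
    n_rand: int | None = None,
    n_splits: int = 100,
    seed: int = 0,
) -> float:
    """AUC with negatives drawn from other images' fixation locations.

    Sampling the null from real fixations of unrelated images removes the
    credit a map earns merely by predicting the shared central bias.
    """
    pool = np.concatenate(
        [f.points for f in other_fixations if len(f)], axis=0
    ) if other_fixations else np.empty((0, 2), dtype=int)
    if len(pool) == 0:
        raise ValueError("shuffled AUC requires a nonempty other-image fixation pool")
    if len(fix) == 0:
        return float("nan")
    pos = _values_at(smap, fix.points)
    if n_rand is None:
        n_rand = len(fix)
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_splits):
        idx = rng.integers(0, len(pool), size=n_rand)
        neg = _values_at(smap, pool[idx])
        aucs.append(_auc_tie_half(pos, neg))
    return float(np.mean(aucs))


def map_cosine(map_a: SaliencyMap, map_b: SaliencyMap) -> float:
    """Cosine similarity of the flattened maps; NaN for a zero map."""
    a, b = map_a.values.ravel(), map_b.values.ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have equal dimensions")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))
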