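"""Binary interest labels from pupil-diameter anomalies.

Pupil diameter dilates with interest, but its baseline differs between
people (and can drift between recording days), so raw diameters are first
standardized within a group — all samples of one subject, or of one
subject-day when sessions span days.  If the standardized diameters were
pure noise they would be ~N(0, 1); interest shows up as excess mass in the
tails.  A sample is anomalous when its squared Mahalanobis distance — for a
scalar, simply z^2 — exceeds the chi-squared(df=1) quantile at 1 - alpha.
The two-sided anomalous region has total mass alpha under the null; only
the dilation (upper) side labels interest, so the null flag rate of the
label itself is alpha / 2 per sample.

An image is labelled 1 for a subject when the dilation is *sustained*: at
least a fraction (default 0.10) of its standardized samples cross the upper
threshold.  With ~300 samples per presentation a single exceedance is a
near-certain event even under the null (1 - 0.95^300 at the 10% level), so
the per-sample test must be aggregated over the presentation before it can
discriminate; "any"-exceedance and mean-based rules remain available as
config alternatives.  Collecting the labels over a fixed image order gives
the subject's binary user characteristic vector (one entry per image).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gaze_io import GazeLog, merged_samples

__all__ = [
    "PupilSeries",
    "AnomalyThreshold",
    "InterestVector",
    "standardize",
    "standardize_logs",
    "threshold_for",
    "label_image",
    "build_interest_vector",
    "cosine_similarity",
    "similarity_matrix",
    "write_interest_vectors",
    "read_interest_vectors",
    "save_pupil_diagnostics",
]


@dataclass
class PupilSeries:
    """Standardized pupil diameters z_t for one subject-image presentation."""

    subject_id: str
    image_id: str
    day: int
    values: np.ndarray  # dimensionless z-scores, one per merged sample


@dataclass(frozen=True)
class AnomalyThreshold:
    """Chi-squared(df=1) anomaly cutoff at significance level alpha."""

    alpha: float
    a_sq: float  # squared-distance cutoff
    z_upper: float
    z_lower: float


def threshold_for(alpha: float) -> AnomalyThreshold:
    """Two-sided anomaly threshold of total null mass ``alpha``.

    ``a_sq`` is the chi-squared(df=1) quantile at 1 - alpha; since the
    squared Mahalanobis distance of a scalar z-score is z^2, the anomalous
    region is |z| >= sqrt(a_sq).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    a_sq = float(stats.chi2.ppf(1 - alpha, df=1))
    z = float(np.sqrt(a_sq))
    return AnomalyThreshold(alpha=alpha, a_sq=a_sq, z_upper=z, z_lower=-z)


def standardize(values: np.ndarray) -> np.ndarray:
    """Z-score an array by its own (population) mean and SD."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("standardization needs >= 2 non-missing samples")
    sd = values.std()
    if sd == 0:
        raise ValueError("standardization undefined for zero-variance group")
    return (values - values.mean()) / sd


def standardize_logs(
    logs: Iterable[GazeLog], per_day: bool = False
) -> list[PupilSeries]:
    """Standardize merged pupil diameters grouped by subject (or subject-day).

    Pooling is over every sample the group contributes across all of its
    images (tM samples for t samples per image and M images), so interest
    on one image shifts that image's z-scores relative to the subject's
    whole session.  ``per_day`` restricts the pooling to one recording day,
    removing day-to-day baseline drift.
    """
    rows = []
    for log in logs:
        for i, s in enumerate(merged_samples(log)):
            if s.pupil is not None:
                rows.append((log.subject_id, log.image_id, log.day, i, s.pupil))
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["subject_id", "image_id", "day", "i", "pupil"])
    group_cols = ["subject_id", "day"] if per_day else ["subject_id"]
    out: list[PupilSeries] = []
    for _, g in df.groupby(group_cols, sort=False):
        vals = g["pupil"].to_numpy()
        if len(vals) < 2 or vals.std() == 0:
            raise ValueError(
                "group too small or zero-variance for standardization: "
                f"subject={g['subject_id'].iloc[0]}"
            )
        z = (vals - vals.mean()) / vals.std()
        g = g.assign(z=z)
        for (img, day), gg in g.groupby(["image_id", "day"], sort=False):
            out.append(
                PupilSeries(
                    subject_id=str(gg["subject_id"].iloc[0]),
                    image_id=str(img),
                    day=int(day),
                    values=gg.sort_values("i")["z"].to_numpy(),
                )
            )
    return out


Aggregation = Literal["any", "fraction", "mean"]


def label_image(
    series: PupilSeries,
    thr: AnomalyThreshold,
    aggregation: Aggregation = "fraction",
    fraction: float = 0.1,
) -> int:
    """Binary interest label for one image.

    Returns 1 iff the standardized pupil series shows dilation beyond the
    upper anomaly threshold; constriction beyond the lower threshold is
    anomalous under the two-sided test but never labels interest.
    ``aggregation`` chooses how samples combine: ``fraction`` (default)
    needs at least ``fraction`` of samples above threshold (sustained
    dilation), ``any`` needs a single exceedance, ``mean`` thresholds the
    series mean.
    """
    z = np.asarray(series.values, dtype=float)
    if z.size == 0:
        warnings.warn(
            f"empty pupil series for subject={series.subject_id} "
            f"image={series.image_id}; labelling 0",
            stacklevel=2,
        )
        return 0
    if aggregation == "any":
        return int(np.any(z >= thr.z_upper))
    if aggregation == "fraction":
        return int(np.mean(z >= thr.z_upper) >= fraction)
    if aggregation == "mean":
        return int(z.mean() >= thr.z_upper)
    raise ValueError(f"unknown aggregation {aggregation!r}")


@dataclass
class InterestVector:
    """Binary per-image interest labels I_n for one subject."""

    subject_id: str
    image_ids: list[str]
    entries: np.ndarray  # {0,1}, length M, ordered like image_ids
    missing_images: list[str] | None = None

    def __len__(self) -> int:
        return len(self.entries)


def build_interest_vector(
    logs: Sequence[GazeLog],
    image_order: Sequence[str],
    alpha: float = 0.10,
    per_day: bool = False,
    aggregation: Aggregation = "fraction",
) -> InterestVector:
    """Build I_n for one subject from their logs over M images.

    ``image_order`` fixes the shared entry order across subjects.  Images
    with no usable pupil data get entry 0 and are reported in
    ``missing_images``.
    """
    subjects = {log.subject_id for log in logs}
    if len(subjects) > 1:
        raise ValueError(f"logs span multiple subjects: {sorted(subjects)}")
    thr = threshold_for(alpha)
    series = standardize_logs(logs, per_day=per_day)
    by_image: Mapping[str, PupilSeries] = {s.image_id: s for s in series}
    entries = np.zeros(len(image_order), dtype=np.int8)
    missing = []
    for m, image_id in enumerate(image_order):
        s = by_image.get(str(image_id))
        if s is None:
            missing.append(str(image_id))
            continue
        entries[m] = label_image(s, thr, aggregation=aggregation)
    return InterestVector(
        subject_id=next(iter(subjects)) if subjects else "",
        image_ids=[str(i) for i in image_order],
        entries=entries,
        missing_images=missing,
    )


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of two equal-length non-negative vectors; NaN for a zero vector."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(np.dot(u, v) / (nu * nv))


def similarity_matrix(vectors: Sequence[InterestVector]) -> pd.DataFrame:
    """Pairwise cosine-similarity matrix of subjects' interest vectors."""
    ids = [v.subject_id for v in vectors]
    n = len(vectors)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            c = cosine_similarity(vectors[i].entries, vectors[j].entries)
            mat[i, j] = mat[j, i] = c
    return pd.DataFrame(mat, index=ids, columns=ids)


def write_interest_vectors(vectors: Sequence[InterestVector], path: str | Path) -> None:
    rows = [
        {"subject_id": v.subject_id, "image_id": img, "label": int(lab)}
        for v in vectors
        for img, lab in zip(v.image_ids, v.entries)
    ]
    pd.DataFrame(rows, columns=["subject_id", "image_id", "label"]).to_csv(
        path, index=False
    )


def save_pupil_diagnostics(z: np.ndarray, path: str | Path, title: str = "") -> None:
    """Histogram and normal QQ plot of standardized pupil diameters.

    A two-centre (bimodal) shape in these panels is the signature of a
    between-day baseline shift and indicates per-day standardization.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = np.asarray(z, dtype=float).ravel()
    fig, (ax_h, ax_q) = plt.subplots(1, 2, figsize=(8, 3.2))
    ax_h.hist(z, bins=60, density=True, color="#4878b0")
    ax_h.set_xlabel("standardized pupil diameter")
    ax_h.set_ylabel("density")
    stats.probplot(z, dist="norm", plot=ax_q)
    ax_q.set_title("")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def read_interest_vectors(path: str | Path) -> list[InterestVector]:
    df = pd.read_csv(path, dtype={"subject_id": str, "image_id": str})
    out = []
    for subj, g in df.groupby("subject_id", sort=False):
        out.append(
            InterestVector(
                subject_id=str(subj),
                image_ids=[str(i) for i in g["image_id"]],
                entries=g["label"].to_numpy(dtype=np.int8),
            )
        )
    return out
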