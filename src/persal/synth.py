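"""Synthetic gaze/pupil world with planted interest structure.

The study's human data are not deposited, so this module generates data
with the statistical structure the method assumes and nothing more:

* stimuli are procedural — coloured geometric objects on a textured
  background, placed with a centre-concentrated prior (mimicking how
  photographers frame subjects), each object carrying a category and a
  base salience;
* gaze is a mixture of a central-bias Gaussian and per-object Gaussians
  whose weights add the subject's interest in the object's category to the
  object's base salience; the tracker's binocular pair is the sampled
  point plus small independent per-eye jitter; 300 samples span a 5-second
  presentation;
* pupil diameter is Gaussian around a per-subject baseline (optionally
  shifted per recording day); when the subject's maximum category interest
  in the image exceeds a planted threshold, a dilation of
  ``dilation_delta`` baseline SDs is added over a contiguous sub-window of
  the presentation.

Everything is deterministic under the world seed; per-(subject, image)
streams use spawned seed sequences so a single log can be regenerated
without building the rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import saliency as sal
from .gaze_io import GazeLog, GazeRecord, merged_samples, write_gaze_logs
from .interest import InterestVector, build_interest_vector, write_interest_vectors
from .saliency import CountGrid, SaliencyMap, aggregate_usm, count_fixations, smooth_to_map

__all__ = [
    "WorldParams",
    "SyntheticWorld",
    "SceneObject",
    "generate_world",
    "sample_gaze",
    "sample_pupil",
    "render_image",
    "planted_interest",
    "build_corpus",
    "Corpus",
]

_PALETTE = np.array(
    [
        [0.85, 0.25, 0.25],
        [0.25, 0.65, 0.30],
        [0.25, 0.40, 0.85],
        [0.90, 0.75, 0.20],
        [0.70, 0.30, 0.75],
        [0.20, 0.75, 0.75],
        [0.90, 0.50, 0.20],
        [0.55, 0.55, 0.55],
    ]
)


@dataclass
class WorldParams:
    """Study-condition defaults: 8 subjects, 1000 images, 300 samples / 5 s."""

    n_subjects: int = 8
    n_images: int = 1000
    image_size: tuple[int, int] = (1920, 1080)  # (W, H) pixels
    n_categories: int = 8
    objects_per_image: tuple[int, int] = (2, 4)  # inclusive range
    central_bias_sigma: float | None = None  # default: min(W, H) / 5
    object_sigma_frac: float = 0.35  # gaze spread around an object, x radius
    central_weight: float = 1.5  # mixture weight of the central component
    samples_per_image: int = 300
    presentation_seconds: float = 5.0
    eye_jitter_sd: float = 2.0  # px, independent per eye
    pupil_base_mean: tuple[float, float] = (3.0, 4.0)  # mm, per-subject range
    pupil_base_sd: float = 0.2  # mm
    dilation_delta: float = 2.5  # dilation in units of pupil_base_sd
    dilation_window_frac: float = 0.4  # contiguous fraction of samples dilated
    interest_threshold: float = 1.0  # planted: interested iff max weight > this
    preferred_weight: float = 2.5  # interest weight for a subject's liked categories
    background_weight: float = 0.1  # interest weight elsewhere
    n_days: int = 1  # recording days per subject
    day_shift_sd: float = 0.0  # per-day baseline shift, units of pupil_base_sd
    seed: int = 0


@dataclass
class SceneObject:
    x: float
    y: float
    radius: float
    category: int
    base_salience: float
    shape: int  # 0 disk, 1 square, 2 ellipse


@dataclass
class SyntheticWorld:
    params: WorldParams
    objects: list[list[SceneObject]]  # per image
    interest_matrix: np.ndarray  # (n_subjects, n_categories) weights >= 0
    pupil_base: np.ndarray  # (n_subjects,) baseline mean, mm
    day_of_image: np.ndarray  # (n_subjects, n_images) day index >= 1
    day_shift: np.ndarray  # (n_subjects, n_days) shift in mm

    @property
    def image_ids(self) -> list[str]:
        return [f"img{m:04d}" for m in range(self.params.n_images)]

    @property
    def subject_ids(self) -> list[str]:
        return [f"subj{n}" for n in range(self.params.n_subjects)]

    def _stream(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.params.seed, spawn_key=tuple(key))
        )


def generate_world(params: WorldParams | None = None, **overrides) -> SyntheticWorld:
    """Build a deterministic world: object layouts and planted interests."""
    if params is None:
        params = WorldParams(**overrides)
    elif overrides:
        raise ValueError("pass either params or keyword overrides, not both")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed))
    W, H = params.image_size

    objects: list[list[SceneObject]] = []
    lo, hi = params.objects_per_image
    for _ in range(params.n_images):
        n_obj = int(rng.integers(lo, hi + 1))
        scene = []
        for _ in range(n_obj):
            for _attempt in range(20):
                # centre-concentrated placement, clipped to the frame
                x = rng.normal(W / 2, W / 5)
                y = rng.normal(H / 2, H / 5)
                r = rng.uniform(0.04, 0.10) * min(W, H)
                if r <= x <= W - r and r <= y <= H - r:
                    break
            else:
                x, y, r = W / 2, H / 2, 0.05 * min(W, H)
            scene.append(
                SceneObject(
                    x=float(np.clip(x, r, W - r)),
                    y=float(np.clip(y, r, H - r)),
                    radius=float(r),
                    category=int(rng.integers(params.n_categories)),
                    base_salience=float(rng.uniform(0.5, 1.5)),
                    shape=int(rng.integers(3)),
                )
            )
        objects.append(scene)

    # each subject strongly prefers 1-2 categories, mildly everything else
    interest = np.full(
        (params.n_subjects, params.n_categories), params.background_weight
    )
    for n in range(params.n_subjects):
        k = int(rng.integers(1, 3))
        liked = rng.choice(params.n_categories, size=k, replace=False)
        interest[n, liked] = params.preferred_weight

    pupil_base = rng.uniform(*params.pupil_base_mean, size=params.n_subjects)
    # images split into contiguous day blocks per subject
    day_of_image = np.ones((params.n_subjects, params.n_images), dtype=int)
    if params.n_days > 1:
        edges = np.linspace(0, params.n_images, params.n_days + 1).astype(int)
        for d in range(params.n_days):
            day_of_image[:, edges[d] : edges[d + 1]] = d + 1
    day_shift = rng.normal(
        0.0, params.day_shift_sd * params.pupil_base_sd,
        size=(params.n_subjects, params.n_days),
    )
    if params.n_days >= 1:
        day_shift[:, 0] = 0.0  # day 1 is the reference baseline

    return SyntheticWorld(
        params=params,
        objects=objects,
        interest_matrix=interest,
        pupil_base=pupil_base,
        day_of_image=day_of_image,
        day_shift=day_shift,
    )


def planted_interest(world: SyntheticWorld, subject: int, image: int) -> bool:
    """Ground truth: is the subject's max category interest in the image
    above the planted threshold?"""
    cats = {o.category for o in world.objects[image]}
    if not cats:
        return False
    w = max(world.interest_matrix[subject, c] for c in cats)
    return bool(w > world.params.interest_threshold)


def _gaze_points(
    world: SyntheticWorld, subject: int, image: int, rng: np.random.Generator
) -> np.ndarray:
    p = world.params
    W, H = p.image_size
    cbs = p.central_bias_sigma or min(W, H) / 5.0
    scene = world.objects[image]
    weights = [p.central_weight] + [
        o.base_salience + world.interest_matrix[subject, o.category] for o in scene
    ]
    weights = np.asarray(weights) / np.sum(weights)
    comp = rng.choice(len(weights), size=p.samples_per_image, p=weights)
    pts = np.empty((p.samples_per_image, 2))
    central = comp == 0
    pts[central, 0] = rng.normal(W / 2, cbs, central.sum())
    pts[central, 1] = rng.normal(H / 2, cbs, central.sum())
    for k, o in enumerate(scene, start=1):
        mask = comp == k
        s = o.radius * p.object_sigma_frac
        pts[mask, 0] = rng.normal(o.x, s, mask.sum())
        pts[mask, 1] = rng.normal(o.y, s, mask.sum())
    return np.clip(pts, [0, 0], [W - 1e-6, H - 1e-6])


def sample_pupil(
    world: SyntheticWorld, subject: int, image: int
) -> np.ndarray:
    """Raw pupil diameters (mm), one per tracker sample."""
    p = world.params
    rng = world._stream(1, subject, image)
    day = int(world.day_of_image[subject, image])
    base = world.pupil_base[subject] + world.day_shift[subject, day - 1]
    values = rng.normal(base, p.pupil_base_sd, size=p.samples_per_image)
    if planted_interest(world, subject, image) and p.dilation_delta > 0:
        w = max(1, int(round(p.dilation_window_frac * p.samples_per_image)))
        start = int(rng.integers(0, p.samples_per_image - w + 1))
        values[start : start + w] += p.dilation_delta * p.pupil_base_sd
    return values


def sample_gaze(world: SyntheticWorld, subject: int, image: int) -> GazeLog:
    """One presentation: exactly ``samples_per_image`` binocular records."""
    p = world.params
    rng = world._stream(0, subject, image)
    pts = _gaze_points(world, subject, image, rng)
    pupils = sample_pupil(world, subject, image)
    jitter = rng.normal(0.0, p.eye_jitter_sd, size=(p.samples_per_image, 2, 2))
    ts = np.linspace(0.0, p.presentation_seconds, p.samples_per_image, endpoint=False)
    pupil_jitter = rng.normal(0.0, 0.02, size=(p.samples_per_image, 2))
    records = []
    for i in range(p.samples_per_image):
        records.append(
            GazeRecord(
                timestamp=float(ts[i]),
                left_xy=(pts[i, 0] + jitter[i, 0, 0], pts[i, 1] + jitter[i, 0, 1]),
                right_xy=(pts[i, 0] + jitter[i, 1, 0], pts[i, 1] + jitter[i, 1, 1]),
                left_pupil=float(max(pupils[i] + pupil_jitter[i, 0], 0.1)),
                right_pupil=float(max(pupils[i] + pupil_jitter[i, 1], 0.1)),
            )
        )
    return GazeLog(
        subject_id=world.subject_ids[subject],
        image_id=world.image_ids[image],
        day=int(world.day_of_image[subject, image]),
        records=records,
    )


def render_image(
    world: SyntheticWorld, image: int, scale: float = 1.0
) -> np.ndarray:
    """Procedural stimulus: objects over a smooth textured background.

    Returns an (H*scale, W*scale, 3) float array in [0, 1].  Object colour
    encodes category, so ground-truth masks are implicit in the layout.
    """
    p = world.params
    W = max(16, int(round(p.image_size[0] * scale)))
    H = max(16, int(round(p.image_size[1] * scale)))
    rng = world._stream(2, image)
    # low-frequency background texture
    coarse = rng.uniform(0.25, 0.45, size=(max(2, H // 32), max(2, W // 32), 3))
    reps = (int(np.ceil(H / coarse.shape[0])), int(np.ceil(W / coarse.shape[1])))
    bg = np.kron(coarse, np.ones((reps[0], reps[1], 1)))[:H, :W]
    img = bg.copy()
    yy, xx = np.mgrid[0:H, 0:W]
    sx, sy = W / p.image_size[0], H / p.image_size[1]
    for o in world.objects[image]:
        cx, cy, r = o.x * sx, o.y * sy, o.radius * (sx + sy) / 2
        color = _PALETTE[o.category % len(_PALETTE)]
        if o.shape == 0:
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        elif o.shape == 1:
            mask = (np.abs(xx - cx) <= r) & (np.abs(yy - cy) <= r)
        else:
            mask = ((xx - cx) / r) ** 2 + ((yy - cy) / (0.6 * r)) ** 2 <= 1
        img[mask] = color
    return np.clip(img, 0.0, 1.0)


@dataclass
class Corpus:
    """Everything downstream modules consume, generated in memory."""

    world: SyntheticWorld
    images: list[np.ndarray]  # rendered stimuli at map scale
    logs: dict[tuple[str, str], GazeLog]  # (subject_id, image_id) -> log
    grids: dict[tuple[str, str], CountGrid]
    psms: dict[tuple[str, str], SaliencyMap]
    usms: list[SaliencyMap]  # per image
    interest_vectors: list[InterestVector]
    training_triples: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    # (image, I_n entries, PSM values) per subject-image pair


def build_corpus(
    world: SyntheticWorld,
    map_scale: float = 1.0,
    alpha: float = 0.10,
    kernel_size: int | None = None,
    sigma: float | None = None,
    per_day: bool = False,
) -> Corpus:
    """Generate the full fixture set for a world.

    Saliency maps are built directly at ``map_scale`` times the stimulus
    resolution, with the smoothing kernel and sigma scaled by the same
    factor so the physical smoothing is unchanged (sigma 24 px at full
    scale).  Interest vectors use the anomaly pipeline at significance
    ``alpha``.
    """
    p = world.params
    W = max(16, int(round(p.image_size[0] * map_scale)))
    H = max(16, int(round(p.image_size[1] * map_scale)))
    if sigma is None:
        sigma = sal.DEFAULT_SIGMA * map_scale
    if kernel_size is None:
        kernel_size = max(3, int(round(sal.DEFAULT_KERNEL_SIZE * map_scale)))

    logs: dict[tuple[str, str], GazeLog] = {}
    grids: dict[tuple[str, str], CountGrid] = {}
    psms: dict[tuple[str, str], SaliencyMap] = {}
    for n, subj in enumerate(world.subject_ids):
        for m, img in enumerate(world.image_ids):
            log = sample_gaze(world, n, m)
            logs[(subj, img)] = log
            samples = merged_samples(log)
            if map_scale != 1.0:
                samples = [
                    type(s)(xy=(s.xy[0] * map_scale, s.xy[1] * map_scale), pupil=s.pupil)
                    if s.xy is not None else s
                    for s in samples
                ]
            grid = count_fixations(samples, W, H)
            grids[(subj, img)] = grid
            psms[(subj, img)] = smooth_to_map(grid, kernel_size, sigma)

    usms = [
        aggregate_usm(
            [grids[(subj, img)] for subj in world.subject_ids], kernel_size, sigma
        )
        for img in world.image_ids
    ]

    vectors = [
        build_interest_vector(
            [logs[(subj, img)] for img in world.image_ids],
            world.image_ids,
            alpha=alpha,
            per_day=per_day,
        )
        for subj in world.subject_ids
    ]

    images = [render_image(world, m, scale=map_scale) for m in range(p.n_images)]
    triples = [
        (
            images[m],
            vectors[n].entries.astype(float),
            psms[(subj, img)].values,
        )
        for n, subj in enumerate(world.subject_ids)
        for m, img in enumerate(world.image_ids)
    ]
    return Corpus(
        world=world,
        images=images,
        logs=logs,
        grids=grids,
        psms=psms,
        usms=usms,
        interest_vectors=vectors,
        training_triples=triples,
    )


def write_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    """Write a corpus in the formats the other modules read."""
    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    write_gaze_logs(list(corpus.logs.values()), out / "gaze.csv")
    write_interest_vectors(corpus.interest_vectors, out / "interest.csv")
    for (subj, img), smap in corpus.psms.items():
        sal.save_map_png(smap, out / "maps" / f"psm_{subj}_{img}.png")
    for img_id, usm in zip(corpus.world.image_ids, corpus.usms):
        sal.save_map_png(usm, out / "maps" / f"usm_{img_id}.png")
    import json
    from dataclasses import asdict

    manifest = asdict(corpus.world.params)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
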