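"""Multispectral particle discrimination (EMBER-style analysis).

A confocal microscope sweeps excitation and emission windows over a field of
fibril particles, producing one image per excitation/emission channel.  The
default protocol combines a dual sweep (excitations 470-670 nm in 20-nm
steps, each with contiguous 20-nm emission windows from 10 nm above the
excitation up to 780 nm; 110 channels) with a single-excitation 405-nm sweep
(420-780 nm; 18 channels), for 128 spectral images in total.

The analysis chain: adaptive (local-mean / Bradley-style) thresholding of
the maximum-intensity projection segments particles; per-particle mean
intensities across the channel stack give spectral profiles; profiles are
sum-normalized, embedded with PCA, and two particle classes (e.g. fibrils of
two protein variants) are separated with a quadratic discriminant.  The
resubstitution accuracy of that classifier is the discrimination score; the
mean over polyanion inducers summarizes a dye's overall discriminating
power.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.measure import label as cc_label, regionprops
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .plate_io import ValidationError

logger = logging.getLogger("fluoroscreen")


# ---------------------------------------------------------------------------
# Scan grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanChannel:
    """One excitation wavelength plus one emission detection window (nm)."""

    ex_nm: float
    em_start_nm: float
    em_end_nm: float

    def __post_init__(self) -> None:
        if not self.em_end_nm > self.em_start_nm:
            raise ValidationError("emission window must have positive width")

    @property
    def em_center_nm(self) -> float:
        return 0.5 * (self.em_start_nm + self.em_end_nm)


DEFAULT_LAMBDA_SPEC: dict[str, float] = {
    "ex_from": 470, "ex_to": 670, "ex_step": 20,
    "em_offset": 10, "em_window": 20, "em_stop": 780,
}
DEFAULT_MONO_SPEC: dict[str, float] = {
    "ex": 405, "em_from": 420, "em_stop": 780, "em_window": 20,
}


def build_scan_grid(
    lambda_spec: Mapping[str, float] | None = DEFAULT_LAMBDA_SPEC,
    mono_spec: Mapping[str, float] | None = DEFAULT_MONO_SPEC,
) -> list[ScanChannel]:
    """Enumerate the acquisition channels of a dual-sweep protocol.

    The dual (excitation x emission) part lists excitations ``ex_from`` to
    ``ex_to`` inclusive in ``ex_step`` increments; each excitation gets
    contiguous ``em_window``-wide emission windows starting ``em_offset`` nm
    above it and ending at ``em_stop``.  The optional single-excitation part
    appends windows from ``em_from`` to ``em_stop``.  Ordering is
    excitation-major, then emission; the defaults yield 110 + 18 = 128
    channels.
    """
    channels: list[ScanChannel] = []
    if lambda_spec is not None:
        ex_from, ex_to = float(lambda_spec["ex_from"]), float(lambda_spec["ex_to"])
        ex_step = float(lambda_spec["ex_step"])
        offset = float(lambda_spec["em_offset"])
        window = float(lambda_spec["em_window"])
        stop = float(lambda_spec["em_stop"])
        if ex_step <= 0 or window <= 0:
            raise ValidationError("ex_step and em_window must be positive")
        n_ex = int(round((ex_to - ex_from) / ex_step)) + 1
        for i in range(n_ex):
            ex = ex_from + i * ex_step
            em_start = ex + offset
            span = stop - em_start
            if span <= 0:
                raise ValidationError(
                    f"em_stop {stop} nm is not reachable from excitation {ex} nm"
                )
            remainder = span % window
            if remainder > 1e-9 and window - remainder > 1e-9:
                raise ValidationError(
                    f"emission span {span} nm at excitation {ex} nm is not a "
                    f"multiple of the window width {window} nm "
                    f"(remainder {remainder} nm)"
                )
            for j in range(int(round(span / window))):
                channels.append(
                    ScanChannel(ex, em_start + j * window, em_start + (j + 1) * window)
                )
    if mono_spec is not None:
        ex = float(mono_spec["ex"])
        em_from = float(mono_spec["em_from"])
        stop = float(mono_spec["em_stop"])
        window = float(mono_spec["em_window"])
        span = stop - em_from
        remainder = span % window
        if remainder > 1e-9 and window - remainder > 1e-9:
            raise ValidationError(
                f"emission span {span} nm of the single-excitation sweep is not "
                f"a multiple of {window} nm (remainder {remainder} nm)"
            )
        for j in range(int(round(span / window))):
            channels.append(ScanChannel(ex, em_from + j * window, em_from + (j + 1) * window))
    return channels


# ---------------------------------------------------------------------------
# Stacks, segmentation, profiles
# ---------------------------------------------------------------------------

@dataclass
class EmberStack:
    """A spectral image stack: one 2-D intensity image per scan channel."""

    channels: list[ScanChannel]
    images: np.ndarray  # shape (n_channels, height, width)
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValidationError("images must be a (channels, height, width) array")
        if self.images.shape[0] != len(self.channels):
            raise ValidationError(
                f"{self.images.shape[0]} image planes but {len(self.channels)} channels"
            )


@dataclass
class ParticleMask:
    """Pixels of one segmented particle."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    area: int
    centroid: tuple[float, float]


def segment_particles(
    stack: EmberStack,
    window_fraction: float = 0.125,
    sensitivity: float = 0.0,
    min_area: int = 10,
) -> list[ParticleMask]:
    """Segment bright particles from the spectral stack.

    The stack is reduced to its maximum-intensity projection (so particles
    bright in only a few channels survive), thresholded with a local-mean
    adaptive rule -- a pixel is foreground when its intensity exceeds the
    mean over a square window (side = ``window_fraction`` of the image side)
    scaled by ``1 + sensitivity`` -- then 8-connected components below
    ``min_area`` pixels are dropped.  An all-constant image yields zero
    particles (logged, not an error).
    """
    if stack.images.shape[0] == 0:
        raise ValidationError("empty stack")
    projection = stack.images.max(axis=0)
    side = min(projection.shape)
    window = max(1, int(round(window_fraction * side)))
    local_mean = uniform_filter(projection, size=window, mode="nearest")
    foreground = projection > local_mean * (1.0 + sensitivity)
    if not foreground.any():
        logger.info("segmentation found no foreground pixels (flat image?)")
        return []
    labels = cc_label(foreground, connectivity=2)
    masks: list[ParticleMask] = []
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        masks.append(
            ParticleMask(
                pixels=np.asarray(region.coords),
                area=int(region.area),
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
            )
        )
    return masks


@dataclass
class ParticleProfile:
    """Mean intensity of one particle in every scan channel."""

    values: np.ndarray
    label: str | None = None
    condition: dict = field(default_factory=dict)


def extract_profiles(stack: EmberStack, masks: Sequence[ParticleMask]) -> list[ParticleProfile]:
    """Per-particle spectral profiles: mean intensity over mask pixels per channel."""
    n_ch, h, w = stack.images.shape
    profiles: list[ParticleProfile] = []
    for i, mask in enumerate(masks):
        if mask.pixels.size == 0:
            raise ValidationError(f"particle {i} has an empty mask")
        rows, cols = mask.pixels[:, 0], mask.pixels[:, 1]
        if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
            raise ValidationError(f"particle {i} mask extends outside the image")
        values = stack.images[:, rows, cols].mean(axis=1)
        profiles.append(
            ParticleProfile(values, label=stack.condition.get("label"),
                            condition=dict(stack.condition))
        )
    return profiles


def normalize_profiles(profiles: Sequence[ParticleProfile]) -> list[ParticleProfile]:
    """Divide each profile by its total intensity so it sums to one.

    Sum-to-one normalization makes profiles pure spectral shapes, invariant
    to particle brightness and laser power.
    """
    out: list[ParticleProfile] = []
    for i, p in enumerate(profiles):
        total = float(p.values.sum())
        if total <= 0:
            raise ValidationError(f"particle {i} has non-positive total intensity")
        out.append(ParticleProfile(p.values / total, p.label, dict(p.condition)))
    return out


# ---------------------------------------------------------------------------
# PCA + quadratic discriminant
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    """Per-particle scores on the retained principal components."""

    coordinates: np.ndarray  # (n_particles, n_components)
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # (n_components, n_features) loadings
    mean: np.ndarray


def _fix_component_signs(components: np.ndarray, coords: np.ndarray) -> None:
    """Make each component's largest-magnitude loading positive (in place)."""
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1.0
            coords[:, k] *= -1.0


def pca_embed(
    profiles: Sequence[ParticleProfile] | np.ndarray,
    n_components: int = 2,
) -> Embedding:
    """Mean-centered PCA of the (normalized) profile matrix.

    The embedding is deterministic: each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if isinstance(profiles, np.ndarray):
        matrix = np.asarray(profiles, dtype=float)
    else:
        matrix = np.vstack([p.values for p in profiles])
    if matrix.shape[0] < n_components + 1:
        raise ValidationError(
            f"need at least {n_components + 1} profiles for {n_components} "
            f"components, got {matrix.shape[0]}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-identical input
        coords = pca.fit_transform(matrix)
        evr = np.nan_to_num(pca.explained_variance_ratio_)
    components = pca.components_.copy()
    _fix_component_signs(components, coords)
    return Embedding(coords, evr, components, pca.mean_.copy())


def qda_discrimination(
    embedding: Embedding | np.ndarray,
    labels: Sequence[str],
    reg_param: float = 0.0,
    *,
    cross_validate: bool = False,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Quadratic-discriminant accuracy separating two particle classes.

    Per-class means and covariances with empirical priors (particle counts
    per condition are unbalanced).  By default the score is the
    resubstitution accuracy -- the fraction of the fitted particles the
    classifier assigns to the correct class; pass ``cross_validate=True``
    for a stratified k-fold estimate instead.
    """
    X = embedding.coordinates if isinstance(embedding, Embedding) else np.asarray(embedding)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("one label per particle required")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValidationError(f"expected exactly 2 classes, got {list(classes)}")
    n_features = X.shape[1]
    if counts.min() < n_features + 2:
        raise ValidationError(
            f"each class needs >= {n_features + 2} members to estimate a "
            f"{n_features}-D covariance; got counts {dict(zip(classes, counts))}"
        )
    pooled = 0.0
    for cls in classes:
        cov = np.atleast_2d(np.cov(X[y == cls], rowvar=False))
        if reg_param == 0.0 and np.linalg.matrix_rank(cov) < n_features:
            raise ValidationError(
                f"class {cls!r} has a singular covariance; pass reg_param > 0 "
                f"to regularize"
            )
        pooled += float(np.trace(cov)) / (n_features * classes.size)
    # QDA is equivariant under a common feature rescaling; normalize to unit
    # pooled within-class variance so the fit is independent of intensity
    # units and of the between-class separation
    if pooled > 0:
        X = X / np.sqrt(pooled)
    clf = QuadraticDiscriminantAnalysis(reg_param=reg_param, store_covariance=True, tol=1e-12)
    if cross_validate:
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return float(cross_val_score(clf, X, y, cv=cv).mean())
    clf.fit(X, y)
    return float(clf.score(X, y))


@dataclass
class DiscriminationResult:
    """Per-inducer discrimination accuracies and their mean (overall score)."""

    per_inducer_accuracy: dict[int, float]
    overall: float


def discrimination_score(per_inducer: Mapping[int, float]) -> DiscriminationResult:
    """Average per-inducer QDA accuracies into one overall discrimination score."""
    if not per_inducer:
        raise ValidationError("empty per-inducer accuracy map")
    for inducer, acc in per_inducer.items():
        if not 0.0 <= acc <= 1.0:
            raise ValidationError(f"accuracy for inducer {inducer} outside [0, 1]: {acc}")
    overall = float(np.mean(list(per_inducer.values())))
    return DiscriminationResult(dict(per_inducer), overall)


def discriminate_stacks(
    stack_a: EmberStack,
    stack_b: EmberStack,
    *,
    n_components: int = 2,
    reg_param: float = 0.0,
    min_area: int = 10,
    sensitivity: float = 0.0,
) -> tuple[float, Embedding, np.ndarray]:
    """Full pipeline on a pair of stacks: segment, profile, PCA, QDA accuracy.

    Returns (accuracy, embedding, labels).  Labels come from each stack's
    ``condition["label"]`` (falling back to "A"/"B").
    """
    profiles: list[ParticleProfile] = []
    labels: list[str] = []
    for default, stack in (("A", stack_a), ("B", stack_b)):
        masks = segment_particles(stack, sensitivity=sensitivity, min_area=min_area)
        ps = normalize_profiles(extract_profiles(stack, masks))
        lab = stack.condition.get("label", default)
        profiles.extend(ps)
        labels.extend([lab] * len(ps))
    embedding = pca_embed(profiles, n_components=n_components)
    accuracy = qda_discrimination(embedding, labels, reg_param=reg_param)
    return accuracy, embedding, np.asarray(labels)


# ---------------------------------------------------------------------------
# Stack I/O (multi-page TIFF + JSON channel manifest)
# ---------------------------------------------------------------------------

def write_ember_stack(stack: EmberStack, tiff_path: str | Path, manifest_path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(Path(tiff_path), stack.images.astype(np.float32))
    manifest = {
        "condition": stack.condition,
        "channels": [
            {"ex_nm": c.ex_nm, "em_start_nm": c.em_start_nm, "em_end_nm": c.em_end_nm}
            for c in stack.channels
        ],
    }
    Path(manifest_path).write_text(json.dumps(manifest, indent=1))


def read_ember_stack(tiff_path: str | Path, manifest_path: str | Path) -> EmberStack:
    import tifffile

    images = np.asarray(tifffile.imread(Path(tiff_path)), dtype=float)
    if images.ndim == 2:
        images = images[None]
    manifest = json.loads(Path(manifest_path).read_text())
    channels = [
        ScanChannel(c["ex_nm"], c["em_start_nm"], c["em_end_nm"])
        for c in manifest["channels"]
    ]
    return EmberStack(channels, images, dict(manifest.get("condition", {})))
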