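"""Seeded generators emulating the screen's statistical structure.

Every pipeline stage is testable without instrument data: these generators
produce melt-screen plates (with the three counter-screen control types),
spectral image stacks whose particle profiles shift between two polymorph
classes, and sigmoidal aggregation traces -- each alongside a ground-truth
record sufficient to compute confusion matrices without re-reading generator
internals.

Dye behavior is modeled with archetypes: pan-binders light up on every
fibril sample, variant-selective binders on one protein variant only,
monomer-binders additionally react with the monomeric-protein counter
screen (and must be excluded by triage), inert dyes stay at baseline, and
bright artefacts fluoresce strongly everywhere including the dye-alone
control.  A binder's melt signature is a logistic decay with a midpoint
below 55 degC, so the fluorescence maximum falls at the start of the ramp --
high initial fluorescence followed by temperature-dependent decay.

All generators are pure functions of (parameters, seed): each well, image
or trace draws from its own named substream, so enlarging a dataset never
perturbs the parts already generated.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .ember_discrimination import EmberStack, ScanChannel, build_scan_grid
from .plate_io import (
    DEFAULT_KINETIC_CHANNELS,
    DEFAULT_PADSF_CHANNELS,
    KineticRead,
    MeltCurve,
    ScreenRun,
    ValidationError,
    Well,
    default_ramp,
)

ARCHETYPE_KINDS = (
    "pan_binder", "wt_selective", "p301s_selective",
    "monomer_binder", "inert", "bright_artifact",
)


@dataclass(frozen=True)
class DyeArchetype:
    """Planted behavior class of one dye, with its melt-signature parameters.

    ``amplitude`` is chosen well above the top rule boundary (2,500 RFU) and
    ``melt_midpoint`` below the 55 degC cut so a noise-free active well maps
    to the top score; ``bright_artifact`` dyes instead sit at a flat
    ``bright_level`` in every well.
    """

    kind: str
    amplitude: float = 3000.0
    melt_midpoint: float = 45.0
    baseline: float = 200.0
    noise_sd: float = 0.0
    bright_level: float = 6000.0
    decay_width: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPE_KINDS:
            raise ValidationError(f"unknown archetype kind {self.kind!r}")


#: Default archetype proportions: a mostly inert library with a few percent
#: of each interesting behavior, echoing the low hit rates of real dye
#: library screens.
DEFAULT_ARCHETYPE_MIX: dict[str, float] = {
    "pan_binder": 0.02,
    "wt_selective": 0.02,
    "p301s_selective": 0.02,
    "monomer_binder": 0.02,
    "bright_artifact": 0.02,
    "inert": 0.90,
}


def default_conditions() -> list[tuple[str, int]]:
    """The full screen design: 2 protein variants x 13 polyanion inducers."""
    return [(variant, inducer) for variant in ("WT", "P301S") for inducer in range(1, 14)]


@dataclass
class GroundTruth:
    """Planted labels emitted alongside every generated dataset."""

    # melt screen
    archetypes: dict[str, str] = field(default_factory=dict)
    intended_scores: dict[tuple[str, str], int] = field(default_factory=dict)
    expected_hits: list[str] = field(default_factory=list)
    expected_monomer_excluded: list[str] = field(default_factory=list)
    bright_artifacts: list[str] = field(default_factory=list)
    # spectral stacks
    class_labels: list[str] = field(default_factory=list)
    spectral_shift_nm: float | None = None
    particle_centers: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    particle_true_masks: dict[str, list[np.ndarray]] = field(default_factory=dict)
    # kinetics
    t_mid_h: float | None = None
    plateau: float | None = None
    baseline: float | None = None


def _rng(seed: int, *tags) -> np.random.Generator:
    """Named substream: a generator keyed by the seed plus a tag tuple."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        entropy.append(zlib.crc32(str(tag).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Melt screen
# ---------------------------------------------------------------------------

def _logistic_decay(temps: np.ndarray, amplitude: float, midpoint: float, width: float) -> np.ndarray:
    return amplitude / (1.0 + np.exp((temps - midpoint) / width))


def _is_active(kind: str, sample_type: str, variant: str | None) -> bool:
    if sample_type == "fibril":
        return kind in ("pan_binder", "monomer_binder") or (
            kind == "wt_selective" and variant == "WT"
        ) or (kind == "p301s_selective" and variant == "P301S")
    if sample_type == "monomer":
        return kind == "monomer_binder"
    return False


def _assign_archetypes(
    n_dyes: int, mix: dict[str, float], rng: np.random.Generator
) -> list[str]:
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValidationError("archetype proportions must sum to 1")
    # largest-remainder apportionment, then a seeded shuffle
    kinds = sorted(mix)
    exact = {k: mix[k] * n_dyes for k in kinds}
    counts = {k: int(exact[k]) for k in kinds}
    short = n_dyes - sum(counts.values())
    for k in sorted(kinds, key=lambda k: exact[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    assignment = [k for k in kinds for _ in range(counts[k])]
    rng.shuffle(assignment)
    return assignment


@dataclass
class ScreenDataset:
    """Two replicate screens with their controls and the planted truth."""

    runs: tuple[ScreenRun, ScreenRun]
    controls: tuple[ScreenRun, ScreenRun]
    truth: GroundTruth


def gen_screen(
    n_dyes: int = 306,
    conditions: list[tuple[str, int]] | None = None,
    archetype_mix: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScreenDataset:
    """Generate a two-replicate melt screen with controls and ground truth.

    Each dye is assigned an archetype; its active wells carry a logistic
    melt decay (high plateau at ramp start, midpoint below 55 degC) in one
    dye-specific response channel, inactive wells and controls sit at
    baseline, and bright artefacts sit at a high flat level everywhere.
    Replicate 2 reuses the same archetypes with an independent noise stream.

    The main runs hold fibril wells plus the monomeric-protein counter
    screen (one monomer well per protein variant per dye); the control runs
    hold the matched polyanion-only and dye-alone wells.
    """
    if conditions is None:
        conditions = default_conditions()
    if not conditions:
        raise ValidationError("empty condition list")
    mix = dict(DEFAULT_ARCHETYPE_MIX if archetype_mix is None else archetype_mix)
    dyes = [f"D{i + 1:03d}" for i in range(n_dyes)]
    kinds = _assign_archetypes(n_dyes, mix, _rng(seed, "archetypes"))
    channel_names = [c.name for c in DEFAULT_PADSF_CHANNELS]
    ramp = default_ramp()
    variants = sorted({v for v, _ in conditions})

    truth = GroundTruth(archetypes=dict(zip(dyes, kinds)))
    for dye, kind in zip(dyes, kinds):
        if kind == "bright_artifact":
            truth.bright_artifacts.append(dye)
        for variant, inducer in conditions:
            sample = f"{variant}_ind{inducer:02d}"
            truth.intended_scores[(dye, sample)] = (
                10 if _is_active(kind, "fibril", variant) else 0
            )
        for variant in variants:
            truth.intended_scores[(dye, f"monomer_{variant}")] = (
                10 if _is_active(kind, "monomer", variant) else 0
            )
        if kind in ("pan_binder", "wt_selective", "p301s_selective"):
            # selective binders need their variant present in the design
            if any(_is_active(kind, "fibril", v) for v, _ in conditions):
                truth.expected_hits.append(dye)
        elif kind == "monomer_binder":
            truth.expected_monomer_excluded.append(dye)

    def make_curve(dye: str, kind_idx: int, sample: str, stype: str, variant, channel, rep):
        kind = kinds[kind_idx]
        arch = DyeArchetype(kind, noise_sd=noise_sd)
        response_channel = channel_names[
            _rng(seed, "channel", dye).integers(len(channel_names))
        ]
        if kind == "bright_artifact":
            base = np.full_like(ramp, arch.bright_level)
        elif _is_active(kind, stype, variant) and channel == response_channel:
            base = arch.baseline + _logistic_decay(
                ramp, arch.amplitude, arch.melt_midpoint, arch.decay_width
            )
        else:
            base = np.full_like(ramp, arch.baseline)
        if noise_sd > 0:
            noise_rng = _rng(seed, "noise", rep, dye, sample, stype, channel)
            base = base + noise_rng.normal(0.0, noise_sd, ramp.size)
        return MeltCurve(ramp.copy(), base, DEFAULT_PADSF_CHANNELS[channel_names.index(channel)])

    runs: list[ScreenRun] = []
    control_runs: list[ScreenRun] = []
    for rep in (1, 2):
        wells: list[Well] = []
        controls: list[Well] = []
        seen_controls: set[tuple[str, str]] = set()
        for idx, dye in enumerate(dyes):
            for variant, inducer in conditions:
                sample = f"{variant}_ind{inducer:02d}"
                wells.append(Well(
                    dye, sample, "fibril",
                    {ch: make_curve(dye, idx, sample, "fibril", variant, ch, rep)
                     for ch in channel_names},
                    protein_variant=variant, inducer_id=inducer,
                ))
                only = f"ind{inducer:02d}_only"
                if (dye, only) not in seen_controls:
                    seen_controls.add((dye, only))
                    controls.append(Well(
                        dye, only, "polyanion_only",
                        {ch: make_curve(dye, idx, only, "polyanion_only", None, ch, rep)
                         for ch in channel_names},
                        inducer_id=inducer,
                    ))
            for variant in variants:
                sample = f"monomer_{variant}"
                wells.append(Well(
                    dye, sample, "monomer",
                    {ch: make_curve(dye, idx, sample, "monomer", variant, ch, rep)
                     for ch in channel_names},
                    protein_variant=variant,
                ))
            controls.append(Well(
                dye, "dye_alone", "no_protein",
                {ch: make_curve(dye, idx, "dye_alone", "no_protein", None, ch, rep)
                 for ch in channel_names},
            ))
        runs.append(ScreenRun(f"synthetic_rep{rep}", rep, wells))
        control_runs.append(ScreenRun(f"synthetic_rep{rep}_controls", rep, controls))
    return ScreenDataset((runs[0], runs[1]), (control_runs[0], control_runs[1]), truth)


# ---------------------------------------------------------------------------
# Spectral image stacks
# ---------------------------------------------------------------------------

def _spectral_response(channels: list[ScanChannel], peak_ex: float, peak_em: float,
                       width_nm: float) -> np.ndarray:
    ex = np.array([c.ex_nm for c in channels])
    em = np.array([c.em_center_nm for c in channels])
    return np.exp(-((ex - peak_ex) ** 2 + (em - peak_em) ** 2) / (2.0 * width_nm ** 2))


def gen_ember(
    n_particles_per_class: int = 12,
    image_size: int = 96,
    peak_ex_em: tuple[float, float] = (520.0, 580.0),
    shift_nm: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    peak_intensity: float = 1000.0,
    blob_sigma_px: float = 2.5,
    spectral_width_nm: float = 60.0,
) -> tuple[EmberStack, EmberStack, GroundTruth]:
    """Generate a pair of spectral stacks for two polymorph classes.

    Particles are Gaussian intensity blobs on a jittered grid (no overlap);
    each particle's per-channel intensity follows a bivariate Gaussian
    response over (excitation, emission-center) wavelengths, centered at
    ``peak_ex_em`` for class A and shifted by ``shift_nm`` along both axes
    for class B, plus i.i.d. Gaussian pixel noise of ``noise_sd`` (absolute
    units; the blob peak is ``peak_intensity``).  A shift pushing the peak
    outside the scanned wavelength range is clamped with a warning.

    Ground truth records class labels, the applied shift, particle centers
    and reference masks (pixels above 10% of each blob's peak).
    """
    channels = build_scan_grid()
    ex_lo = min(c.ex_nm for c in channels)
    ex_hi = max(c.ex_nm for c in channels)
    em_lo = min(c.em_center_nm for c in channels)
    em_hi = max(c.em_center_nm for c in channels)

    def clamp_peak(pex: float, pem: float) -> tuple[float, float]:
        cx = min(max(pex, ex_lo), ex_hi)
        cy = min(max(pem, em_lo), em_hi)
        if (cx, cy) != (pex, pem):
            warnings.warn(
                f"spectral peak ({pex}, {pem}) nm outside the scan grid; "
                f"clamped to ({cx}, {cy}) nm",
                stacklevel=2,
            )
        return cx, cy

    truth = GroundTruth(class_labels=["A", "B"], spectral_shift_nm=shift_nm)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    stacks: list[EmberStack] = []
    for label, shift in (("A", 0.0), ("B", shift_nm)):
        pex, pem = clamp_peak(peak_ex_em[0] + shift, peak_ex_em[1] + shift)
        response = _spectral_response(channels, pex, pem, spectral_width_nm)
        rng = _rng(seed, "ember", label)
        images = np.zeros((len(channels), image_size, image_size))
        centers: list[tuple[float, float]] = []
        masks: list[np.ndarray] = []
        if n_particles_per_class > 0:
            n_cells = int(np.ceil(np.sqrt(n_particles_per_class)))
            cell = image_size / n_cells
            margin = 4.0 * blob_sigma_px
            if cell < 2 * margin:
                raise ValidationError(
                    f"{n_particles_per_class} particles of sigma {blob_sigma_px} px "
                    f"do not fit a {image_size}-px image without overlap"
                )
            cell_ids = rng.permutation(n_cells * n_cells)[:n_particles_per_class]
            for cid in cell_ids:
                row_c = (cid // n_cells) * cell + cell / 2
                col_c = (cid % n_cells) * cell + cell / 2
                jitter = (cell / 2 - margin)
                cy = row_c + rng.uniform(-jitter, jitter)
                cx = col_c + rng.uniform(-jitter, jitter)
                brightness = peak_intensity * rng.uniform(0.5, 1.0)
                blob = brightness * np.exp(
                    -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * blob_sigma_px ** 2)
                )
                images += response[:, None, None] * blob[None, :, :]
                centers.append((cy, cx))
                # reference support: the 1/e^2 beam-waist disk (r = 2 sigma)
                fg = blob > brightness * np.exp(-2.0)
                masks.append(np.argwhere(fg))
        if noise_sd > 0:
            images = images + rng.normal(0.0, noise_sd, images.shape)
        stacks.append(EmberStack(channels, images, {"label": label}))
        truth.particle_centers[label] = centers
        truth.particle_true_masks[label] = masks
    return stacks[0], stacks[1], truth


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def gen_kinetics(
    t_mid_h: float = 12.0,
    rate: float = 1.5,
    plateau: float = 3000.0,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    sampling_dt_h: float = 0.5,
    seed: int = 0,
    *,
    t_max_h: float = 48.0,
    dye_id: str = "DYE",
    condition_id: str = "COND",
) -> tuple[KineticRead, GroundTruth]:
    """Generate one sigmoidal aggregation trace with additive Gaussian noise.

    The underlying curve is ``baseline + plateau / (1 + exp(-(t - t_mid)/rate))``
    sampled every ``sampling_dt_h`` hours over [0, ``t_max_h``]; the truth
    records the midpoint and plateau.  ``plateau=0`` yields a degenerate
    constant trace (which the normalization stage rejects by design).
    """
    if sampling_dt_h <= 0:
        raise ValidationError("sampling_dt_h must be positive")
    times = np.arange(0.0, t_max_h + sampling_dt_h / 2, sampling_dt_h)
    values = baseline + plateau / (1.0 + np.exp(-(times - t_mid_h) / rate))
    if noise_sd > 0:
        values = values + _rng(seed, "kinetics", dye_id, condition_id).normal(
            0.0, noise_sd, times.size
        )
    read = KineticRead(times, values, DEFAULT_KINETIC_CHANNELS[0], dye_id, condition_id)
    truth = GroundTruth(t_mid_h=t_mid_h, plateau=plateau, baseline=baseline)
    return read, truth
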