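"""Synthetic phantom cohort with simulated multi-observer delineations.

The study design this emulates: a cohort of subjects (default 19), each with
one lesion, delineated under three modality-guidance arms (CECT, MIP,
multiple-parameter MR) by two observers in two sessions — 12 gross tumour
volume (GTV) contours per subject, each paired with a 0–5 mm peritumoral
ring, i.e. 456 contour records under the defaults. Delineation uncertainty
is simulated as a smooth random displacement of the true lesion surface,
with magnitudes ordered inter-observer > intra-observer and
MIP > CECT > MR (MR offering the highest lesion contrast and therefore the
most reproducible contours).

Arm labels follow the convention ``<prefix><index>`` with index 1, 2 =
observer 1 sessions 1, 2 and index 3, 4 = observer 2 sessions 1, 2
(e.g. ``3DCT1`` … ``3DCT4``, ``MIP1`` …, ``MR1`` …).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import ImageVolume, RoiMask, peritumoral_ring

__all__ = [
    "PhantomParams",
    "ObserverProfile",
    "StudyDesign",
    "DelineationRecord",
    "CohortBundle",
    "DEFAULT_PROFILES",
    "MODALITY_PREFIX",
    "generate_phantom",
    "simulate_delineation",
    "generate_cohort",
]

MODALITIES = ("CECT", "MIP", "MR")
#: Arm-label prefix per modality, matching the conventional structure names.
MODALITY_PREFIX = {"CECT": "3DCT", "MIP": "MIP", "MR": "MR"}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity model of one phantom subject.

    The default grid is 64 x 64 x 48 voxels at 0.97 x 0.97 x 3.0 mm — the
    in-plane/slice spacing of the CT protocol being emulated — holding an
    ellipsoidal lesion in a textured background.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (0.97, 0.97, 3.0)
    lesion_radius_mm: tuple[float, float, float] = (15.0, 13.0, 12.0)
    lesion_mean_intensity: float = 90.0
    background_mean_intensity: float = 40.0
    texture_correlation_length_mm: float = 4.0
    noise_sd: float = 12.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for ax, (n, sp, r) in enumerate(
            zip(self.grid_shape, self.spacing, self.lesion_radius_mm)
        ):
            if 2 * r >= (n - 1) * sp:
                raise ValueError(
                    f"lesion semi-axis {r} mm does not fit strictly inside the grid "
                    f"along axis {ax} ({n} voxels x {sp} mm)"
                )


@dataclass(frozen=True)
class ObserverProfile:
    """Delineation-uncertainty model for one modality-guidance arm.

    ``sigma_intra_mm`` is the SD of the surface displacement between repeat
    sessions of the same observer; ``sigma_inter_mm`` the SD of the
    observer-level displacement (shared by that observer's sessions);
    ``bias_mm`` a systematic over-(+)/under-(−)segmentation offset.
    """

    modality: str
    sigma_intra_mm: float
    sigma_inter_mm: float
    bias_mm: float = 0.0
    correlation_length_mm: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.sigma_intra_mm <= self.sigma_inter_mm:
            raise ValueError(
                "require 0 <= sigma_intra_mm <= sigma_inter_mm, got "
                f"{self.sigma_intra_mm} / {self.sigma_inter_mm}"
            )


#: Default per-modality profiles encoding the contrast ordering
#: sigma(MIP) > sigma(CECT) > sigma(MR).
DEFAULT_PROFILES: dict[str, ObserverProfile] = {
    "MR": ObserverProfile("MR", sigma_intra_mm=0.5, sigma_inter_mm=1.0),
    "CECT": ObserverProfile("CECT", sigma_intra_mm=1.0, sigma_inter_mm=2.0),
    "MIP": ObserverProfile("MIP", sigma_intra_mm=1.5, sigma_inter_mm=3.0),
}


@dataclass(frozen=True)
class StudyDesign:
    """Cardinality of the delineation study."""

    n_subjects: int = 19
    modalities: tuple[str, ...] = MODALITIES
    n_observers: int = 2
    n_sessions: int = 2
    tissues: tuple[str, ...] = ("tumor", "peritumor")
    master_seed: int = 20210919
    ring_radius_mm: float = 5.0

    def __post_init__(self) -> None:
        if min(self.n_subjects, len(self.modalities), self.n_observers, self.n_sessions, len(self.tissues)) < 1:
            raise ValueError("all design counts must be >= 1")

    @property
    def n_records(self) -> int:
        return (
            self.n_subjects
            * len(self.modalities)
            * self.n_observers
            * self.n_sessions
            * len(self.tissues)
        )


@dataclass(frozen=True)
class DelineationRecord:
    """One contour instance of the study."""

    subject: int
    tissue: str
    modality: str
    observer: int
    session: int
    arm_label: str
    mask: RoiMask


@dataclass
class CohortBundle:
    """Everything one simulated study produces."""

    records: list[DelineationRecord]
    images: dict[int, ImageVolume]
    true_masks: dict[int, RoiMask]
    design: StudyDesign
    provenance: dict = field(default_factory=dict)

    def select(self, **kw) -> list[DelineationRecord]:
        """Filter records by any DelineationRecord field, e.g.
        ``select(tissue="tumor", modality="MR")``."""
        out = self.records
        for key, val in kw.items():
            out = [r for r in out if getattr(r, key) == val]
        return out


def _child_seed(*keys: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=keys[0], spawn_key=tuple(keys[1:]))


def _smooth_unit_field(
    shape, spacing, correlation_length_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-SD Gaussian random field with mm-scale correlation."""
    noise = rng.standard_normal(shape)
    if correlation_length_mm <= 0:
        return noise
    sigma_vox = [correlation_length_mm / sp for sp in spacing]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="nearest")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return smooth / sd


def _ellipsoid_mask(shape, spacing, radius_mm) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(
        ((g - c) * sp / r) ** 2 for g, c, sp, r in zip(grids, center, spacing, radius_mm)
    )
    return r2 <= 1.0


def generate_phantom(params: PhantomParams, seed: int) -> tuple[ImageVolume, RoiMask]:
    """Generate a textured phantom image and its ground-truth lesion mask.

    The image is lesion/background mean intensities plus a spatially
    correlated Gaussian texture of SD ``noise_sd``; identical seeds give
    bit-identical volumes.
    """
    rng = np.random.default_rng(_child_seed(seed, 0))
    lesion = _ellipsoid_mask(params.grid_shape, params.spacing, params.lesion_radius_mm)
    img = np.full(params.grid_shape, params.background_mean_intensity, dtype=np.float64)
    img[lesion] = params.lesion_mean_intensity
    if params.noise_sd > 0:
        img += params.noise_sd * _smooth_unit_field(
            params.grid_shape, params.spacing, params.texture_correlation_length_mm, rng
        )
    volume = ImageVolume(img, params.spacing)
    mask = RoiMask(lesion.astype(np.uint8), params.spacing)
    return volume, mask


def _signed_distance_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Positive outside the mask, negative inside, in mm."""
    fg = mask.astype(bool)
    dist_out = ndimage.distance_transform_edt(~fg, sampling=spacing)
    dist_in = ndimage.distance_transform_edt(fg, sampling=spacing)
    return dist_out - dist_in


def simulate_delineation(
    true_mask: RoiMask,
    profile: ObserverProfile,
    observer: int,
    session: int,
    seed: int,
    spacing: tuple[float, float, float] | None = None,
) -> RoiMask:
    """Simulate one observer/session delineation of a true lesion mask.

    The true surface is displaced along its outward normal by a smooth
    random field: an observer-level component of SD ``sigma_inter_mm``
    (shared by the observer's sessions under the same ``seed``), a
    session-level component of SD ``sigma_intra_mm``, and the constant
    ``bias_mm``. The perturbed mask is the largest connected component of
    ``{x : signed_distance(x) <= displacement(x)}``.
    """
    if true_mask.is_empty():
        raise ValueError("cannot delineate an empty true mask")
    sp = true_mask.spacing if spacing is None else tuple(float(s) for s in spacing)
    shape = true_mask.shape

    if profile.sigma_inter_mm == 0 and profile.sigma_intra_mm == 0 and profile.bias_mm == 0:
        return RoiMask(true_mask.array.copy(), sp, true_mask.origin)

    rng_obs = np.random.default_rng(_child_seed(seed, 1, observer))
    rng_ses = np.random.default_rng(_child_seed(seed, 2, observer, session))
    disp = np.full(shape, float(profile.bias_mm))
    if profile.sigma_inter_mm > 0:
        disp += profile.sigma_inter_mm * _smooth_unit_field(
            shape, sp, profile.correlation_length_mm, rng_obs
        )
    if profile.sigma_intra_mm > 0:
        disp += profile.sigma_intra_mm * _smooth_unit_field(
            shape, sp, profile.correlation_length_mm, rng_ses
        )

    sdf = _signed_distance_mm(true_mask.array, sp)
    new = sdf <= disp
    if not new.any():
        raise ValueError(
            "delineation perturbation annihilated the mask; use smaller sigma/bias "
            f"(profile {profile.modality}: intra={profile.sigma_intra_mm}, "
            f"inter={profile.sigma_inter_mm}, bias={profile.bias_mm})"
        )
    # keep the largest 26-connected component so the contour stays one lesion
    lab, n = ndimage.label(new, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        new = lab == (int(np.argmax(sizes)) + 1)
    return RoiMask(new.astype(np.uint8), sp, true_mask.origin)


def _subject_params(base: PhantomParams, rng: np.random.Generator) -> PhantomParams:
    """Per-subject anatomy: lesion size and contrast vary across the cohort."""
    scale = rng.uniform(0.75, 1.15, size=3)
    radius = tuple(float(r * s) for r, s in zip(base.lesion_radius_mm, scale))
    contrast_jitter = float(rng.normal(0.0, 6.0))
    return replace(
        base,
        lesion_radius_mm=radius,
        lesion_mean_intensity=base.lesion_mean_intensity + contrast_jitter,
    )


def generate_cohort(
    design: StudyDesign = StudyDesign(),
    phantom: PhantomParams = PhantomParams(),
    profiles: dict[str, ObserverProfile] | None = None,
) -> CohortBundle:
    """Simulate the full study: phantoms, GTV delineations, peritumoral rings.

    Returns a bundle whose record list has exactly the design cardinality
    (456 under the defaults: 19 subjects x 3 modalities x 2 observers x
    2 sessions x 2 tissues). Regeneration from the same ``master_seed`` is
    bit-identical.
    """
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    for m in design.modalities:
        if m not in profiles:
            raise ValueError(f"no observer profile for modality '{m}'")

    records: list[DelineationRecord] = []
    images: dict[int, ImageVolume] = {}
    true_masks: dict[int, RoiMask] = {}
    for subj in range(1, design.n_subjects + 1):
        subj_rng = np.random.default_rng(_child_seed(design.master_seed, 10, subj))
        params = _subject_params(phantom, subj_rng)
        subj_seed = int(subj_rng.integers(0, 2**31 - 1))
        image, true_mask = generate_phantom(params, seed=subj_seed)
        images[subj] = image
        true_masks[subj] = true_mask

        for mi, modality in enumerate(design.modalities):
            arm_seed = int(
                np.random.default_rng(
                    _child_seed(design.master_seed, 20, subj, mi)
                ).integers(0, 2**31 - 1)
            )
            for obs in range(1, design.n_observers + 1):
                for ses in range(1, design.n_sessions + 1):
                    idx = (obs - 1) * design.n_sessions + ses
                    label = f"{MODALITY_PREFIX.get(modality, modality)}{idx}"
                    try:
                        gtv = simulate_delineation(
                            true_mask, profiles[modality], observer=obs, session=ses, seed=arm_seed
                        )
                    except ValueError as exc:
                        raise RuntimeError(
                            f"delineation failed for subject {subj}, arm {label}: {exc}"
                        ) from exc
                    tissue_masks = {"tumor": gtv}
                    if "peritumor" in design.tissues:
                        tissue_masks["peritumor"] = peritumoral_ring(
                            gtv, radius_mm=design.ring_radius_mm
                        )
                    for tissue in design.tissues:
                        records.append(
                            DelineationRecord(
                                subject=subj,
                                tissue=tissue,
                                modality=modality,
                                observer=obs,
                                session=ses,
                                arm_label=label,
                                mask=tissue_masks[tissue],
                            )
                        )
    assert len(records) == design.n_records
    return CohortBundle(
        records=records,
        images=images,
        true_masks=true_masks,
        design=design,
        provenance={
            "master_seed": design.master_seed,
            "phantom": phantom,
            "profiles": profiles,
        },
    )
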