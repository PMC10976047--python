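"""Synthetic 3D lesion phantoms with realistic foreground/background imbalance.

Each subject is a head-sized volume containing an ellipsoidal "brain" of
smoothly varying tissue intensity plus noise, and a set of small
hyperintense ellipsoidal lesions placed uniformly inside the brain without
touching each other.  Lesion sizes follow a log-normal distribution around
a configurable mean (default 111 voxels), and lesions are added until the
achieved lesion fraction of brain voxels is within +-25% of the target.
Two presets emulate the imbalance regimes of public lesion datasets:
``wmh_like`` (lesion fraction ~1.5% of brain voxels) and ``lit_like``
(~0.14%, new-lesion activity in longitudinal MS).

Everything is deterministic under the supplied seeds.  What the phantoms do
*not* emulate: MRI physics (bias fields, partial volume, acquisition
anisotropy), anatomy beyond a convex brain, and longitudinal change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "Subject", "Cohort", "generate_subject",
           "generate_cohort", "load_cohort"]

MIN_LESION_VOXELS = 5
FRACTION_TOLERANCE = 0.25  # accept achieved fraction within +-25% of target


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic imbalanced-volume generator."""

    volume_shape: Tuple[int, int, int] = (96, 96, 96)
    n_channels: int = 1
    target_fg_fraction: float = 0.0154
    mean_lesion_size: float = 111.0
    lesion_size_sigma: float = 0.7
    noise_sigma: float = 0.05
    brain_axes_fraction: Tuple[float, float, float] = (0.30, 0.27, 0.24)
    n_subjects: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fg_fraction < 0.05):
            raise ValueError("target_fg_fraction must lie in [0, 0.05)")
        if self.mean_lesion_size < 1:
            raise ValueError("mean_lesion_size must be >= 1")
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")

    @classmethod
    def wmh_like(cls, **overrides) -> "PhantomSpec":
        """Imbalance regime of vascular white-matter-hyperintensity cohorts:
        lesion load ~1.5% of brain voxels, mean lesion ~111 voxels."""
        return replace(cls(target_fg_fraction=0.0154, mean_lesion_size=111.0),
                       **overrides)

    @classmethod
    def lit_like(cls, **overrides) -> "PhantomSpec":
        """Imbalance regime of longitudinal new-lesion activity: lesion load
        ~0.14% of brain voxels, mean lesion ~116 voxels."""
        return replace(cls(target_fg_fraction=0.0014, mean_lesion_size=116.0),
                       **overrides)


@dataclass
class Subject:
    """One phantom: image channels, lesion mask, brain mask and statistics."""

    subject_id: str
    image: np.ndarray        # (C, D, H, W) float32
    lesion_mask: np.ndarray  # (D, H, W) uint8
    brain_mask: np.ndarray   # (D, H, W) uint8
    meta: Dict = field(default_factory=dict)


@dataclass
class Cohort:
    spec: PhantomSpec
    subjects: List[Subject]

    @property
    def subject_ids(self) -> List[str]:
        return [s.subject_id for s in self.subjects]

    def __len__(self) -> int:
        return len(self.subjects)

    def __getitem__(self, i: int) -> Subject:
        return self.subjects[i]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _lesion_radii(n_voxels: float, rng: np.random.Generator) -> np.ndarray:
    """Semi-axes of a random-anisotropy ellipsoid of given voxel volume."""
    aniso = np.exp(rng.normal(0.0, 0.25, size=3))
    aniso /= aniso.prod() ** (1.0 / 3.0)
    r0 = (3.0 * n_voxels / (4.0 * np.pi)) ** (1.0 / 3.0)
    return np.maximum(r0 * aniso, 0.6)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_lesions(spec: PhantomSpec, brain: np.ndarray,
                   rng: np.random.Generator) -> Tuple[np.ndarray, List[int]]:
    shape = spec.volume_shape
    brain_vox = int(brain.sum())
    target = spec.target_fg_fraction * brain_vox
    lesions = np.zeros(shape, dtype=np.uint8)
    # lesions must not touch, so components stay separable: keep a 1-voxel gap
    blocked = ~brain
    sizes: List[int] = []
    mu = np.log(spec.mean_lesion_size) - spec.lesion_size_sigma**2 / 2.0
    hi_band = (1.0 + FRACTION_TOLERANCE) * target
    lo_band = (1.0 - FRACTION_TOLERANCE) * target
    placed = 0
    failures = 0

    def try_place(size: float):
        radii = _lesion_radii(size, rng)
        for _ in range(200):
            center = np.array([rng.uniform(r + 1, s - r - 1)
                               for s, r in zip(shape, radii)])
            blob = _ellipsoid_mask(shape, center, radii)
            if blob.any() and not (blob & blocked).any():
                return blob
        return None

    done = False
    while placed < target and not done:
        size = float(np.exp(rng.normal(mu, spec.lesion_size_sigma)))
        # never *request* a size that would overshoot the acceptance band
        size = max(min(size, hi_band - placed), MIN_LESION_VOXELS)
        blob = None
        while True:
            candidate = try_place(size)
            if candidate is None:
                failures += 1
                if failures > 50:
                    raise RuntimeError(
                        f"cannot reach lesion fraction "
                        f"{spec.target_fg_fraction:g}: placed {placed} of "
                        f"{target:.0f} voxels in {len(sizes)} lesions before "
                        f"running out of room"
                    )
                break
            n = int(candidate.sum())
            if placed + n <= hi_band:
                blob = candidate
                break
            # the rasterised blob overshoots the band
            if placed >= lo_band:
                done = True  # already inside the band; stop without it
                break
            if size <= MIN_LESION_VOXELS:
                raise RuntimeError(
                    f"target lesion fraction {spec.target_fg_fraction:g} "
                    f"unreachable: even a minimal lesion overshoots the "
                    f"+-25% acceptance band"
                )
            size = max(size * 0.75, MIN_LESION_VOXELS)
        if blob is None:
            continue
        failures = 0
        lesions[blob] = 1
        blocked |= ndimage.binary_dilation(blob)
        n = int(blob.sum())
        sizes.append(n)
        placed += n
    achieved = placed / brain_vox if brain_vox else 0.0
    if target and not (
        (1 - FRACTION_TOLERANCE) * spec.target_fg_fraction
        <= achieved <=
        (1 + FRACTION_TOLERANCE) * spec.target_fg_fraction
    ):
        raise RuntimeError(
            f"achieved lesion fraction {achieved:.4%} outside +-25% of "
            f"target {spec.target_fg_fraction:.4%}"
        )
    return lesions, sizes


def _tissue_channel(spec: PhantomSpec, brain: np.ndarray,
                    rng: np.random.Generator, base: float,
                    texture_amp: float) -> np.ndarray:
    field3d = rng.standard_normal(spec.volume_shape)
    texture = ndimage.gaussian_filter(field3d, sigma=4.0)
    texture *= texture_amp / max(texture.std(), 1e-12)
    noise = rng.normal(0.0, spec.noise_sigma, size=spec.volume_shape)
    channel = (base + texture + noise) * brain
    return channel


def generate_subject(spec: PhantomSpec, subject_seed: int,
                     subject_id: Optional[str] = None) -> Subject:
    """Generate one phantom subject, deterministic under ``subject_seed``."""
    rng = np.random.default_rng(subject_seed)
    shape = spec.volume_shape
    center = [s / 2.0 - 0.5 for s in shape]
    radii = [f * s for f, s in zip(spec.brain_axes_fraction, shape)]
    brain = _ellipsoid_mask(shape, center, radii)

    lesions, sizes = _place_lesions(spec, brain, rng)

    channels = []
    contrasts = [(1.0, 0.08), (0.8, 0.06)][: spec.n_channels]
    for base, amp in contrasts:
        ch = _tissue_channel(spec, brain, rng, base, amp)
        tissue_vals = ch[brain & (lesions == 0)]
        p99 = float(np.percentile(tissue_vals, 99))
        jitter = rng.normal(0.0, 0.02, size=int(lesions.sum()))
        ch[lesions == 1] = p99 + 0.3 + jitter
        channels.append(ch.astype(np.float32))
    image = np.stack(channels)

    brain_vox = int(brain.sum())
    meta = {
        "achieved_fraction": float(lesions.sum() / brain_vox),
        "target_fraction": spec.target_fg_fraction,
        "n_lesions": len(sizes),
        "lesion_sizes": sizes,
        "brain_voxels": brain_vox,
        "subject_seed": int(subject_seed),
    }
    return Subject(subject_id=subject_id or f"sub-{subject_seed:04d}",
                   image=image, lesion_mask=lesions,
                   brain_mask=brain.astype(np.uint8), meta=meta)


def generate_cohort(spec: PhantomSpec, n_subjects: Optional[int] = None,
                    out_dir=None) -> Cohort:
    """Generate a cohort of phantoms; optionally write it to disk as NIfTI
    volumes plus a JSON manifest."""
    n = n_subjects if n_subjects is not None else spec.n_subjects
    base = np.random.SeedSequence(spec.seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31))
                     for s in base.spawn(n)]
    subjects = [
        generate_subject(spec, seed, subject_id=f"sub-{i:03d}")
        for i, seed in enumerate(subject_seeds)
    ]
    cohort = Cohort(spec=spec, subjects=subjects)
    if out_dir is not None:
        save_cohort(cohort, out_dir)
    return cohort


# ---------------------------------------------------------------------------
# disk round trip
# ---------------------------------------------------------------------------

_AFFINE = np.eye(4)  # 1 mm isotropic


def save_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"spec": asdict(cohort.spec), "subjects": []}
    for s in cohort.subjects:
        sdir = out / s.subject_id
        sdir.mkdir(exist_ok=True)
        try:
            for c in range(s.image.shape[0]):
                nib.save(nib.Nifti1Image(s.image[c], _AFFINE),
                         str(sdir / f"image_c{c}.nii.gz"))
            nib.save(nib.Nifti1Image(s.lesion_mask, _AFFINE),
                     str(sdir / "lesion_mask.nii.gz"))
            nib.save(nib.Nifti1Image(s.brain_mask, _AFFINE),
                     str(sdir / "brain_mask.nii.gz"))
        except OSError as exc:
            raise OSError(f"failed writing subject to {sdir}: {exc}") from exc
        manifest["subjects"].append({"subject_id": s.subject_id, **s.meta})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cohort(in_dir) -> Cohort:
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    spec_dict = manifest["spec"]
    for key in ("volume_shape", "brain_axes_fraction"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = PhantomSpec(**spec_dict)
    subjects = []
    for entry in manifest["subjects"]:
        sdir = root / entry["subject_id"]
        channels = []
        for c in range(spec.n_channels):
            channels.append(np.asarray(
                nib.load(str(sdir / f"image_c{c}.nii.gz")).get_fdata(),
                dtype=np.float32))
        lesion = np.asarray(
            nib.load(str(sdir / "lesion_mask.nii.gz")).get_fdata()
        ).astype(np.uint8)
        brain = np.asarray(
            nib.load(str(sdir / "brain_mask.nii.gz")).get_fdata()
        ).astype(np.uint8)
        meta = {k: v for k, v in entry.items() if k != "subject_id"}
        subjects.append(Subject(subject_id=entry["subject_id"],
                                image=np.stack(channels),
                                lesion_mask=lesion, brain_mask=brain,
                                meta=meta))
    return Cohort(spec=spec, subjects=subjects)
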