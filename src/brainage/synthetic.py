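"""Age-encoded phantom volumes and synthetic cohorts.

Real structural MRI encodes age mostly through morphology: ventricular
enlargement and global grey-matter loss.  The phantoms here reduce that to
the minimal learnable structure — a concentric ellipsoidal "head" whose
central low-intensity "ventricle" grows linearly with age, surrounded by
uniform "brain" tissue and a bright "skull/scalp" shell — plus the two main
nuisance processes a preprocessing chain must handle: additive noise and a
smooth multiplicative intensity bias field.  Alzheimer's disease is modelled
as accelerated aging: an AD subject's morphology is rendered at
chronological age + Delta while the manifest keeps the chronological age,
which is exactly the construction that makes the brain-age gap a biomarker.

Geometry is deliberately *not* anatomically realistic; it only needs a
monotone, recoverable structure-age mapping at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_manifest import Cohort, SubjectRecord, VolumeImage, save_manifest, write_volume

logger = logging.getLogger("brainage")


@dataclass
class PhantomParams:
    """Geometry, intensity and nuisance parameters of the phantom family.

    Radii are in voxels of the x axis; the ventricle is an ellipsoid with
    semi-axes ``(r, r, r * shape_z/shape_x)`` where
    ``r = ventricle_base_radius + ventricle_growth * age``.  ``sex_scale``
    is the fractional whole-brain *volume* difference between the sexes
    (male brains rendered larger).  The bias field is ``exp(a * p(x,y,z))``
    for a random quadratic ``p`` normalised to unit max amplitude, the same
    multiplicative smooth-artifact model N4-style correction assumes.
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    brain_axes_frac: float = 0.40      # brain semi-axis as a fraction of each dim
    shell_axes_frac: float = 0.46      # outer edge of the bright shell
    ventricle_base_radius: float = 2.0  # voxels at age 0
    ventricle_growth: float = 0.075     # voxels per year
    shell_intensity: float = 1.5
    brain_intensity: float = 1.0
    ventricle_intensity: float = 0.2
    sex_scale: float = 0.10
    noise_sd: float = 0.05
    bias_amplitude: float = 0.10
    ad_delta_mean: float = 5.0
    ad_delta_sd: float = 2.0
    max_age: float = 100.0             # oldest effective age the geometry must admit

    def __post_init__(self) -> None:
        if self.ventricle_base_radius <= 0 or self.brain_axes_frac <= 0:
            raise ValueError("radii must be positive")
        if min(self.shell_intensity, self.brain_intensity, self.ventricle_intensity) <= 0:
            raise ValueError("intensities must be positive")
        if self.shell_axes_frac <= self.brain_axes_frac:
            raise ValueError("shell must lie outside the brain ellipsoid")
        # the ventricle must fit inside the *smaller* (female) brain at max_age
        r_max = self.ventricle_base_radius + self.ventricle_growth * self.max_age
        female = (1.0 - self.sex_scale / 2.0) ** (1.0 / 3.0)
        aniso = self.shape[2] / self.shape[0]
        vent = (r_max, r_max, max(r_max * aniso, 0.5))
        brain = tuple(self.brain_axes_frac * n * female for n in self.shape)
        if any(v >= b - 1.0 for v, b in zip(vent, brain)):
            raise ValueError(
                f"ventricle semi-axes {tuple(round(v, 2) for v in vent)} at max_age "
                f"{self.max_age} would breach the brain ellipsoid "
                f"{tuple(round(b, 2) for b in brain)}; shrink growth or max_age"
            )

    def sex_factor(self, sex: int) -> float:
        """Linear scale factor giving a +/- sex_scale/2 volume change."""
        sign = +1.0 if int(sex) == 1 else -1.0
        return (1.0 + sign * self.sex_scale / 2.0) ** (1.0 / 3.0)


@dataclass
class PhantomRegions:
    """Ground-truth region masks of one phantom."""

    brain: np.ndarray      # brain interior incl. ventricle, excl. shell
    ventricle: np.ndarray  # the age-encoding central region
    shell: np.ndarray      # bright skull/scalp shell


def params_for_shape(shape: tuple[int, int, int], max_age: float = 100.0,
                     **overrides) -> PhantomParams:
    """Phantom parameters with the ventricle geometry scaled to a grid.

    The base radius scales with the x dimension; the growth rate is capped
    so the ventricle still fits inside the (smaller, female) brain ellipsoid
    at ``max_age`` on every axis, with the one-voxel discretisation margin.
    On the canonical 32x32x16 grid this reproduces the defaults.
    """
    shape = tuple(int(n) for n in shape)
    f = shape[0] / 32.0
    base = 2.0 * f
    probe = PhantomParams()  # source of the remaining defaults
    female = (1.0 - probe.sex_scale / 2.0) ** (1.0 / 3.0)
    aniso = shape[2] / shape[0]
    limits = [probe.brain_axes_frac * shape[0] * female - 1.0,
              (probe.brain_axes_frac * shape[2] * female - 1.0) / max(aniso, 1e-6)]
    r_allowed = 0.98 * min(limits)
    growth = min(0.075 * f, max((r_allowed - base) / max_age, 1e-4))
    return PhantomParams(shape=shape, ventricle_base_radius=base,
                         ventricle_growth=growth, max_age=max_age, **overrides)


def _ellipsoid(shape: tuple[int, int, int], semi_axes: tuple[float, float, float]) -> np.ndarray:
    coords = [np.arange(n, dtype=float) - (n - 1) / 2.0 for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    a, b, c = semi_axes
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


def bias_field(shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """A smooth multiplicative field: exp of a random quadratic, unit mean scale."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x * x, y * y, z * z]
    coeffs = rng.uniform(-1.0, 1.0, size=len(terms))
    p = sum(c * t for c, t in zip(coeffs, terms))
    peak = np.max(np.abs(p))
    if peak > 0:
        p = p / peak
    return np.exp(amplitude * p)


def make_phantom(
    age: float,
    sex: int,
    params: Optional[PhantomParams] = None,
    seed: int = 0,
) -> tuple[VolumeImage, PhantomRegions]:
    """Render one phantom; deterministic for fixed (age, sex, params, seed).

    Returns the volume (with its ground-truth brain mask attached) and the
    full set of region masks.  Raises if the requested age would push the
    ventricle through the brain ellipsoid.
    """
    params = params or PhantomParams()
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    shape = params.shape
    f = params.sex_factor(sex)
    brain_axes = tuple(params.brain_axes_frac * n * f for n in shape)
    shell_axes = tuple(params.shell_axes_frac * n * f for n in shape)
    r = params.ventricle_base_radius + params.ventricle_growth * age
    aniso = shape[2] / shape[0]
    vent_axes = (r, r, max(r * aniso, 0.5))
    if any(v >= b - 1.0 for v, b in zip(vent_axes, brain_axes)):
        raise ValueError(
            f"ventricle semi-axes {tuple(round(v, 2) for v in vent_axes)} at age {age} "
            f"breach the brain ellipsoid (semi-axes {tuple(round(b, 2) for b in brain_axes)})"
        )

    head = _ellipsoid(shape, shell_axes)
    brain = _ellipsoid(shape, brain_axes)
    vent = _ellipsoid(shape, vent_axes)
    shell = head & ~brain

    grid = np.zeros(shape, dtype=np.float64)
    grid[shell] = params.shell_intensity
    grid[brain] = params.brain_intensity
    grid[vent] = params.ventricle_intensity

    rng = np.random.default_rng(seed)
    if params.bias_amplitude > 0:
        field = bias_field(shape, params.bias_amplitude, rng)
        field = field / field[brain].mean()
        grid = grid * field
    if params.noise_sd > 0:
        grid = grid + rng.normal(0.0, params.noise_sd, size=shape)

    vol = VolumeImage(grid=grid, spacing=(1.0, 1.0, 1.0), mask=brain)
    return vol, PhantomRegions(brain=brain, ventricle=vent, shell=shell)


def make_cohort(
    n_subjects: int,
    age_range: tuple[float, float] = (20.0, 80.0),
    ad_fraction: float = 0.0,
    scans_per_subject: int = 1,
    params: Optional[PhantomParams] = None,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> tuple[Cohort, "np.ndarray"]:
    """Generate a cohort of phantoms on disk with its manifest.

    Ages are uniform on ``age_range``.  ``round(ad_fraction * n)`` subjects
    are AD; their morphology is rendered at chronological age + Delta with
    Delta ~ Normal(ad_delta_mean, ad_delta_sd) truncated at zero, while the
    manifest records the chronological age — the accelerated-aging model of
    the disease.  Writes ``manifest.csv``, one NIfTI per scan and one
    ground-truth brain-mask NIfTI per scan; returns the cohort and the
    per-subject effective (rendered) ages.
    """
    params = params or PhantomParams()
    lo, hi = age_range
    if hi <= lo:
        raise ValueError(f"age range upper bound {hi} must exceed lower bound {lo}")
    if not (0.0 <= ad_fraction <= 1.0):
        raise ValueError("ad_fraction must be in [0, 1]")
    if 0.0 < ad_fraction < 1.0 and n_subjects < 2:
        raise ValueError("need at least 2 subjects for a mixed CN/AD cohort")
    if scans_per_subject < 1:
        raise ValueError("scans_per_subject must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, size=n_subjects)
    sexes = rng.integers(0, 2, size=n_subjects)
    n_ad = int(round(ad_fraction * n_subjects))
    ad_idx = set(rng.choice(n_subjects, size=n_ad, replace=False).tolist())
    deltas = np.maximum(0.0, rng.normal(params.ad_delta_mean, params.ad_delta_sd, size=n_subjects))
    scan_seeds = rng.integers(0, 2**31 - 1, size=n_subjects * scans_per_subject)

    records = []
    effective = np.empty(n_subjects)
    k = 0
    for i in range(n_subjects):
        is_ad = i in ad_idx
        eff_age = float(ages[i] + (deltas[i] if is_ad else 0.0))
        effective[i] = eff_age
        sid = f"sub-{i:04d}"
        for s in range(scans_per_subject):
            vol, _ = make_phantom(eff_age, int(sexes[i]), params, seed=int(scan_seeds[k]))
            scan_path = out_dir / f"{sid}_scan-{s}.nii.gz"
            write_volume(vol, scan_path)
            write_volume(
                VolumeImage(grid=vol.mask.astype(np.uint8), spacing=vol.spacing),
                out_dir / f"{sid}_scan-{s}_mask.nii.gz",
            )
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    scan_path=str(scan_path),
                    age=float(ages[i]),
                    sex=int(sexes[i]),
                    diagnosis="AD" if is_ad else "CN",
                )
            )
            k += 1
    cohort = Cohort(records=records)
    save_manifest(cohort, out_dir / "manifest.csv")
    return cohort, effective
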