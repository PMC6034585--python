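"""Synthetic brain phantom generation with planted ground truth.

Phantoms are simple bihemispheric volumes: each hemisphere holds a stack of
axis-aligned white-matter blocks (the "parcellation"), wrapped in a grey-matter
shell and a thin CSF rim.  White-matter intensity is planted per region as

    base WM mean + hemisphere offset + region delta - class attenuation

on a 0-255 scale, so every downstream estimate has an exact target.  An
optional spherical lesion overwrites tissue with a dark infarct; regions are
then attenuated by their lesion-adjacency class (perilesional, ipsilesional
remote, contralesional), which is how the generator realizes the group-level
intensity ordering the analysis is designed to detect.  Additive Gaussian
noise and a smooth multiplicative bias field model scanner degradation.

Geometry conventions: axis 0 is left-right with the midsagittal plane between
the two central voxel columns (left hemisphere is ``x < nx // 2``); axis 2 is
axial, inferior to superior.  Region labels 1..n are the left hemisphere,
n+1..2n the right, with ``homologue(r) = r ± n``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "SyntheticSubject",
    "generate_subject",
    "generate_cohort",
    "control_preset",
    "stroke_preset",
    "TISSUE_BACKGROUND",
    "TISSUE_CSF",
    "TISSUE_GM",
    "TISSUE_WM",
    "TISSUE_LESION",
]

TISSUE_BACKGROUND = 0
TISSUE_CSF = 1
TISSUE_GM = 2
TISSUE_WM = 3
TISSUE_LESION = 4

#: region classes relative to a lesion
PERILESIONAL = "perilesional"
IPSILESIONAL_REMOTE = "ipsilesional_remote"
CONTRALESIONAL_HOMOLOGUE = "contralesional_homologue"
CONTRALESIONAL_OTHER = "contralesional_other"
LESION_OVERLAP = "lesion_overlap"
CONTROL_CLASS = "control"


@dataclass(frozen=True)
class LesionSpec:
    """A spherical focal lesion in voxel space."""

    center: tuple[int, int, int]
    radius_mm: float
    intensity: float = 45.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic subject.

    Intensities are on a 0-255 scale.  ``hemisphere_wm_offsets`` models the
    right-greater-than-left dominance asymmetry seen in typically developing
    children; the three attenuations plant the lesion-class intensity
    gradient of a stroke subject.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_regions_per_hemisphere: int = 8
    tissue_means: dict = field(
        default_factory=lambda: {
            "WM": 117.13,
            "GM": 80.0,
            "CSF": 40.0,
            "background": 0.0,
        }
    )
    hemisphere_wm_offsets: dict = field(
        default_factory=lambda: {"left": 0.0, "right": 0.0}
    )
    region_deltas: dict = field(default_factory=dict)
    lesion: LesionSpec | None = None
    perilesional_attenuation: float = 0.0
    remote_attenuation: float = 0.0
    contra_attenuation: float = 0.0
    noise_sd: float = 0.0
    bias_field_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_regions_per_hemisphere < 2:
            raise ValueError("need at least 2 regions per hemisphere")
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 8 voxels")
        if min(self.voxel_size_mm) <= 0:
            raise ValueError("voxel sizes must be positive")
        for name in ("perilesional_attenuation", "remote_attenuation",
                     "contra_attenuation", "noise_sd", "bias_field_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SyntheticSubject:
    """One simulated participant: aligned volumes plus the planted truth."""

    intensity: np.ndarray
    tissue_labels: np.ndarray
    parcellation: np.ndarray
    lesion_mask: np.ndarray
    truth: pd.DataFrame
    spec: PhantomSpec
    affine: np.ndarray

    @property
    def wm_mask(self) -> np.ndarray:
        return self.tissue_labels == TISSUE_WM

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue_labels != TISSUE_BACKGROUND

    def lut(self) -> pd.DataFrame:
        """Region lookup table (id, name, hemisphere, homologue_id)."""
        return self.truth[["region_id", "name", "hemisphere", "homologue_id"]].copy()


def _wm_box(grid_shape: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    """Left-hemisphere WM box; the right box is its mirror image."""
    nx, ny, nz = grid_shape
    half = nx // 2
    x0, x1 = max(2, nx // 8), half - max(2, nx // 12)
    y0, y1 = max(2, ny // 4), ny - max(2, ny // 4)
    z0, z1 = max(2, nz // 6), nz - max(2, nz // 6)
    return slice(x0, x1), slice(y0, y1), slice(z0, z1)


def _build_labels(spec: PhantomSpec) -> np.ndarray:
    """Mirror-symmetric parcellation: left ids 1..n stacked along z, right ids
    obtained by reflecting the left half and adding n."""
    n = spec.n_regions_per_hemisphere
    sx, sy, sz = _wm_box(spec.grid_shape)
    z_edges = np.linspace(sz.start, sz.stop, n + 1).astype(int)
    if np.any(np.diff(z_edges) < 1):
        raise ValueError(
            f"grid too small for {n} regions per hemisphere along z"
        )
    left = np.zeros(spec.grid_shape, dtype=np.int32)
    for i in range(n):
        left[sx, sy, z_edges[i]:z_edges[i + 1]] = i + 1
    mirrored = left[::-1, :, :]
    labels = left + np.where(mirrored > 0, mirrored + n, 0)
    return labels


def _build_tissue(labels: np.ndarray) -> np.ndarray:
    wm = labels > 0
    struct = ndimage.generate_binary_structure(3, 3)
    gm = ndimage.binary_dilation(wm, struct, iterations=2) & ~wm
    csf = ndimage.binary_dilation(wm | gm, struct) & ~(wm | gm)
    tissue = np.zeros(labels.shape, dtype=np.int16)
    tissue[csf] = TISSUE_CSF
    tissue[gm] = TISSUE_GM
    tissue[wm] = TISSUE_WM
    return tissue


def _rasterize_lesion(
    lesion: LesionSpec,
    grid_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    brain: np.ndarray,
) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=float)
    d2 = np.zeros(grid_shape)
    for ax in range(3):
        d2 += ((coords[ax] - lesion.center[ax]) * voxel_size_mm[ax]) ** 2
    sphere = d2 <= lesion.radius_mm**2
    mask = sphere & brain
    if not mask.any():
        raise ValueError("lesion does not intersect the brain")
    xs = np.nonzero(mask)[0]
    half = grid_shape[0] // 2
    if xs.min() < half <= xs.max():
        raise ValueError("lesion must be unilateral")
    return mask


def _classify_planted(
    labels: np.ndarray,
    lesion_mask: np.ndarray,
    n: int,
    overlap_fraction: float = 0.5,
) -> dict[int, str]:
    """Lesion-adjacency classes used to plant attenuations.

    Mirrors the downstream classifier's rule (26-connectivity contact,
    >= 50% overlap -> lesion_overlap) so planted and recovered classes agree.
    """
    half = labels.shape[0] // 2
    xs = np.nonzero(lesion_mask)[0]
    lesion_hemi = "left" if xs.mean() < half else "right"
    struct = ndimage.generate_binary_structure(3, 3)
    ring = ndimage.binary_dilation(lesion_mask, struct) & ~lesion_mask
    touching = set(np.unique(labels[ring])) - {0}
    inside_counts = np.bincount(labels[lesion_mask].ravel(), minlength=2 * n + 1)
    sizes = np.bincount(labels.ravel(), minlength=2 * n + 1)

    classes: dict[int, str] = {}
    remote: set[int] = set()
    for r in range(1, 2 * n + 1):
        hemi = "left" if r <= n else "right"
        if hemi == lesion_hemi:
            if sizes[r] > 0 and inside_counts[r] / sizes[r] >= overlap_fraction:
                classes[r] = LESION_OVERLAP
            elif r in touching:
                classes[r] = PERILESIONAL
            else:
                classes[r] = IPSILESIONAL_REMOTE
                remote.add(r)
    for r in range(1, 2 * n + 1):
        hemi = "left" if r <= n else "right"
        if hemi != lesion_hemi:
            h = r + n if r <= n else r - n
            classes[r] = (
                CONTRALESIONAL_HOMOLOGUE if h in remote else CONTRALESIONAL_OTHER
            )
    return classes


def _bias_field(
    grid_shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (random quadratic), scaled
    so the quadratic has unit max absolute value."""
    axes = [np.linspace(-1.0, 1.0, s) for s in grid_shape]
    u, v, w = np.meshgrid(*axes, indexing="ij")
    c = rng.normal(size=9)
    poly = (
        c[0] * u + c[1] * v + c[2] * w
        + c[3] * u * v + c[4] * u * w + c[5] * v * w
        + c[6] * u**2 + c[7] * v**2 + c[8] * w**2
    )
    poly /= max(np.abs(poly).max(), 1e-12)
    return 1.0 + amplitude * poly


def generate_subject(spec: PhantomSpec) -> SyntheticSubject:
    """Generate one phantom subject from its spec.

    With ``noise_sd == 0`` and ``bias_field_amplitude == 0`` the mean
    intensity over each region's WM voxels equals the planted mean exactly.
    Raises if any planted intensity falls outside [0, 255] or if the lesion
    crosses the midsagittal plane.
    """
    n = spec.n_regions_per_hemisphere
    labels = _build_labels(spec)
    tissue = _build_tissue(labels)
    brain = tissue != TISSUE_BACKGROUND
    rng = np.random.default_rng(spec.seed)

    lesion_mask = np.zeros(spec.grid_shape, dtype=bool)
    classes: dict[int, str] = {}
    if spec.lesion is not None:
        lesion_mask = _rasterize_lesion(
            spec.lesion, spec.grid_shape, spec.voxel_size_mm, brain
        )
        classes = _classify_planted(labels, lesion_mask, n)

    atten_by_class = {
        PERILESIONAL: spec.perilesional_attenuation,
        LESION_OVERLAP: spec.perilesional_attenuation,
        IPSILESIONAL_REMOTE: spec.remote_attenuation,
        CONTRALESIONAL_HOMOLOGUE: spec.contra_attenuation,
        CONTRALESIONAL_OTHER: spec.contra_attenuation,
    }

    planted: dict[int, float] = {}
    for r in range(1, 2 * n + 1):
        hemi = "left" if r <= n else "right"
        mean = (
            spec.tissue_means["WM"]
            + spec.hemisphere_wm_offsets.get(hemi, 0.0)
            + spec.region_deltas.get(r, 0.0)
            - atten_by_class.get(classes.get(r, ""), 0.0)
        )
        planted[r] = mean

    out_of_range = {
        k: v
        for k, v in {
            **{f"region {r}": m for r, m in planted.items()},
            **{f"tissue {t}": m for t, m in spec.tissue_means.items()},
            **(
                {"lesion": spec.lesion.intensity} if spec.lesion is not None else {}
            ),
        }.items()
        if not (0.0 <= v <= 255.0)
    }
    if out_of_range:
        raise ValueError(
            f"planted intensities outside [0, 255]: {out_of_range}"
        )

    vol = np.zeros(spec.grid_shape, dtype=np.float64)
    vol[tissue == TISSUE_CSF] = spec.tissue_means["CSF"]
    vol[tissue == TISSUE_GM] = spec.tissue_means["GM"]
    for r in range(1, 2 * n + 1):
        vol[labels == r] = planted[r]
    if spec.lesion is not None:
        tissue = tissue.copy()
        tissue[lesion_mask] = TISSUE_LESION
        vol[lesion_mask] = spec.lesion.intensity

    if spec.bias_field_amplitude > 0:
        vol[brain] *= _bias_field(spec.grid_shape, spec.bias_field_amplitude, rng)[brain]
    if spec.noise_sd > 0:
        vol[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))

    wm_sizes = np.bincount(
        labels[(tissue == TISSUE_WM)].ravel(), minlength=2 * n + 1
    )
    rows = []
    for r in range(1, 2 * n + 1):
        hemi = "left" if r <= n else "right"
        rows.append(
            {
                "region_id": r,
                "name": f"{hemi}_wm_{(r - 1) % n + 1}",
                "hemisphere": hemi,
                "homologue_id": r + n if r <= n else r - n,
                "planted_class": classes.get(r, CONTROL_CLASS),
                "planted_mean": planted[r],
                "n_wm_voxels": int(wm_sizes[r]),
            }
        )
    truth = pd.DataFrame(rows)

    affine = np.diag(list(spec.voxel_size_mm) + [1.0])
    return SyntheticSubject(
        intensity=vol,
        tissue_labels=tissue,
        parcellation=labels,
        lesion_mask=lesion_mask,
        truth=truth,
        spec=spec,
        affine=affine,
    )


def control_preset(**overrides) -> PhantomSpec:
    """Typically developing control: right-dominant WM asymmetry.

    Planted hemisphere means 122.24 (right) and 117.13 (left) on the 0-255
    scale, the group means observed in the control cohort.
    """
    params = dict(
        tissue_means={"WM": 117.13, "GM": 80.0, "CSF": 40.0, "background": 0.0},
        hemisphere_wm_offsets={"left": 0.0, "right": 5.11},
        noise_sd=5.0,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def stroke_preset(**overrides) -> PhantomSpec:
    """Left-hemisphere arterial ischemic stroke.

    Attenuations are chosen so planted class means are 86.33 (perilesional),
    94.06 (ipsilesional remote) and 100.96 (contralesional homologue) against
    a premorbid WM mean of 117.13.
    """
    params = dict(
        tissue_means={"WM": 117.13, "GM": 80.0, "CSF": 40.0, "background": 0.0},
        lesion=LesionSpec(center=(17, 31, 30), radius_mm=9.0, intensity=45.0),
        perilesional_attenuation=117.13 - 86.33,
        remote_attenuation=117.13 - 94.06,
        contra_attenuation=117.13 - 100.96,
        noise_sd=5.0,
    )
    params.update(overrides)
    return PhantomSpec(**params)


def generate_cohort(
    n_stroke: int,
    n_control: int,
    stroke_spec: PhantomSpec | None = None,
    control_spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir=None,
    subject_offset_sd: float = 0.0,
):
    """Generate a cohort of stroke and control subjects.

    Per-subject seeds are derived deterministically from ``seed``.
    ``subject_offset_sd`` adds a per-subject random shift to the WM base mean
    (defaults to 0: all between-subject variability then comes from voxel
    noise averaging).  When ``out_dir`` is given, volumes are written as
    NIfTI and the manifest/truth tables as CSV.

    Returns ``(subjects, manifest)``.
    """
    if n_stroke < 0 or n_control < 0:
        raise ValueError("cohort sizes must be nonnegative")
    stroke_spec = stroke_spec if stroke_spec is not None else stroke_preset()
    control_spec = control_spec if control_spec is not None else control_preset()
    rng = np.random.default_rng(seed)

    plan = [("stroke", stroke_spec, i + 1) for i in range(n_stroke)]
    plan += [("control", control_spec, i + 1) for i in range(n_control)]

    subjects: list[SyntheticSubject] = []
    records = []
    for group, base_spec, idx in plan:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        offset = float(rng.normal(0.0, subject_offset_sd)) if subject_offset_sd > 0 else 0.0
        spec_i = replace(base_spec, seed=sub_seed)
        if offset != 0.0:
            tm = dict(spec_i.tissue_means)
            tm["WM"] = tm["WM"] + offset
            spec_i = replace(spec_i, tissue_means=tm)
        subject = generate_subject(spec_i)
        subject_id = f"{group}_{idx:02d}"
        rec = {"subject_id": subject_id, "group": group, "seed": sub_seed}
        if out_dir is not None:
            from . import io as mio

            paths = mio.save_subject(subject, out_dir, subject_id)
            rec.update(paths)
        subjects.append(subject)
        records.append(rec)

    manifest = pd.DataFrame(records)
    if out_dir is not None:
        from pathlib import Path

        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return subjects, manifest
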