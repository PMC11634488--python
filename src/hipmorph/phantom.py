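"""Synthetic Dixon phantoms, rater perturbations and cohorts with known truth.

The phantom emulates the study's imaging setup — an axial stack of
co-registered fat and water images at 1.5 mm isotropic resolution containing
lateral-hip muscles — with analytic shape primitives (axis-aligned ellipsoids
and elliptic tubes) so that ground-truth volume and fat-infiltration profiles
are known in closed form.

Intensity model: total signal S = 1000 inside muscle; ``water = S*(1 - MFI)``
and ``fat = S*MFI`` where MFI is the designed fat fraction at the voxel's
proximal fraction, so ``fat/(fat+water)`` equals the designed profile exactly
before noise. Background carries zero signal. Gaussian noise (SD expressed as
a fraction of S) is added to both channels and clipped at zero.

All randomness flows from a single integer seed per call; no global state.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .dixon_io import DixonVolume, LabelMask

__all__ = [
    "MFIProfile",
    "MuscleShape",
    "PhantomSpec",
    "CohortSpec",
    "MuscleEffect",
    "OverlapError",
    "generate_phantom",
    "perturb_mask",
    "generate_cohort",
    "simulate_profile_group",
    "default_phantom_spec",
    "DEFAULT_LABEL_MAP",
]

SIGNAL = 1000.0

MUSCLES = ("Gmax", "Gmed", "Gmin", "TFL")

DEFAULT_LABEL_MAP: dict[int, tuple[str, str]] = {
    1: ("Gmax", "L"), 2: ("Gmed", "L"), 3: ("Gmin", "L"), 4: ("TFL", "L"),
    5: ("Gmax", "R"), 6: ("Gmed", "R"), 7: ("Gmin", "R"), 8: ("TFL", "R"),
}


class OverlapError(ValueError):
    """Two muscle primitives rasterize onto the same voxel."""


@dataclass(frozen=True)
class MFIProfile:
    """Parametric fat-infiltration profile over proximal fraction p in [0,1].

    kinds: ``constant`` (value), ``linear`` (start -> end),
    ``quadratic`` (c0 + c1*p + c2*p^2). Values are validated to stay in [0,1]
    at the 101 evaluation nodes.
    """

    kind: Literal["constant", "linear", "quadratic"] = "constant"
    params: tuple[float, ...] = (0.1,)

    def __call__(self, p: np.ndarray | float) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if self.kind == "constant":
            out = np.full_like(p, self.params[0])
        elif self.kind == "linear":
            a, b = self.params
            out = a + (b - a) * p
        elif self.kind == "quadratic":
            c0, c1, c2 = self.params
            out = c0 + c1 * p + c2 * p**2
        else:  # pragma: no cover
            raise ValueError(f"unknown profile kind {self.kind}")
        return out

    def validate(self) -> None:
        vals = self(np.linspace(0, 1, 101))
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError(f"MFI profile leaves [0,1]: {self}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "MFIProfile":
        return cls(kind=d["kind"], params=tuple(float(x) for x in d["params"]))


@dataclass(frozen=True)
class MuscleShape:
    """One muscle primitive: an axis-aligned ellipsoid or elliptic tube.

    ``center_mm`` and ``semi_axes_mm`` are in world millimetres; the tube's
    third semi-axis is its half-length along the axial (S-I) axis.
    """

    label: int
    muscle: str
    side: str
    primitive: Literal["ellipsoid", "tube"]
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def validate(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError(f"label {self.label}: semi-axes must be positive")

    def analytic_volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        if self.primitive == "ellipsoid":
            return 4.0 / 3.0 * np.pi * a * b * c
        return np.pi * a * b * (2.0 * c)  # elliptic cylinder


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 72)
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    muscles: list[MuscleShape] = field(default_factory=list)
    mfi_profiles: dict[int, MFIProfile] = field(default_factory=dict)
    noise_sd: float = 0.0  # fraction of the S=1000 in-muscle signal
    seed: int = 0

    def validate(self) -> None:
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for m in self.muscles:
            m.validate()
        for lid, prof in self.mfi_profiles.items():
            prof.validate()
        labels = [m.label for m in self.muscles]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate label ids in muscle list")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    @property
    def label_map(self) -> dict[int, tuple[str, str]]:
        return {m.label: (m.muscle, m.side) for m in self.muscles}


def _rasterize(shape: MuscleShape, spec: PhantomSpec) -> np.ndarray:
    vx = np.asarray(spec.voxel_size_mm)
    grids = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(spec.grid_shape, vx)], indexing="ij"
    )
    cx, cy, cz = shape.center_mm
    a, b, c = shape.semi_axes_mm
    u = (grids[0] - cx) / a
    v = (grids[1] - cy) / b
    w = (grids[2] - cz) / c
    if shape.primitive == "ellipsoid":
        return u**2 + v**2 + w**2 <= 1.0
    return (u**2 + v**2 <= 1.0) & (np.abs(w) <= 1.0)


def generate_phantom(spec: PhantomSpec) -> tuple[DixonVolume, LabelMask]:
    """Rasterize the muscle primitives and synthesise fat/water intensities.

    The fat fraction inside each muscle is constant within an axial slice and
    follows the muscle's designed profile over its proximal-to-distal span
    (proximal = most superior slice). Overlapping primitives are an error.
    """
    spec.validate()
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for shape in spec.muscles:
        vox = _rasterize(shape, spec)
        clash = vox & (labels != 0)
        if clash.any():
            other = int(labels[clash].flat[0])
            raise OverlapError(
                f"muscle shapes overlap: labels {other} and {shape.label}"
            )
        labels[vox] = shape.label

    fat = np.zeros(spec.grid_shape, dtype=float)
    water = np.zeros(spec.grid_shape, dtype=float)
    ax = 2  # phantom affine is diagonal RAS: array axis 2 is superior-inferior
    for shape in spec.muscles:
        prof = spec.mfi_profiles.get(shape.label, MFIProfile("constant", (0.0,)))
        region = labels == shape.label
        occupied = np.where(region.any(axis=(0, 1)))[0]
        # proximal = most superior = largest index under the diagonal affine
        z_prox, z_dist = occupied.max(), occupied.min()
        span = max(z_prox - z_dist, 1)
        for z in occupied:
            p = (z_prox - z) / span
            mfi = float(prof(p))
            sl = region[:, :, z]
            fat[:, :, z][sl] = SIGNAL * mfi
            water[:, :, z][sl] = SIGNAL * (1.0 - mfi)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sd * SIGNAL
        fat = np.clip(fat + rng.normal(0, sd, fat.shape), 0, None)
        water = np.clip(water + rng.normal(0, sd, water.shape), 0, None)

    dixon = DixonVolume(fat=fat, water=water, affine=spec.affine)
    mask = LabelMask(labels=labels, affine=spec.affine, label_map=spec.label_map)
    return dixon, mask


_NEIGHBOR_SHIFTS = [(axis, step) for axis in range(3) for step in (-1, 1)]


def _neighbor_labels(labels: np.ndarray) -> np.ndarray:
    """Stack of the six face-neighbour label arrays (edge-padded, so array
    borders are not spuriously treated as label boundaries)."""
    out = np.empty((6,) + labels.shape, dtype=labels.dtype)
    for i, (axis, step) in enumerate(_NEIGHBOR_SHIFTS):
        padded = np.pad(labels, [(1, 1) if a == axis else (0, 0) for a in range(3)],
                        mode="edge")
        sl = [slice(None)] * 3
        sl[axis] = slice(1 + step, labels.shape[axis] + 1 + step)
        out[i] = padded[tuple(sl)]
    return out


def perturb_mask(mask: LabelMask, boundary_flip_prob: float, seed: int) -> LabelMask:
    """Simulate a second rater (or an automated segmenter) by flipping labels
    on label boundaries only.

    Each voxel with at least one differing 6-neighbour is, with probability
    ``boundary_flip_prob``, reassigned the label of a uniformly chosen
    differing neighbour (which may be background). All flips are evaluated
    against the original mask, so the perturbation does not cascade.
    """
    if not 0.0 <= boundary_flip_prob <= 1.0:
        raise ValueError("boundary_flip_prob must be in [0, 1]")
    labels = mask.labels
    if boundary_flip_prob == 0.0:
        return LabelMask(labels=labels.copy(), affine=mask.affine.copy(),
                         label_map=dict(mask.label_map))
    neigh = _neighbor_labels(labels)
    differs = neigh != labels[None]
    boundary = differs.any(axis=0)
    rng = np.random.default_rng(seed)
    flip = boundary & (rng.random(labels.shape) < boundary_flip_prob)

    idx = np.where(flip)
    d = differs[:, idx[0], idx[1], idx[2]]           # (6, n_flip)
    counts = d.sum(axis=0)
    pick = np.floor(rng.random(len(counts)) * counts).astype(int)
    cum = np.cumsum(d, axis=0)
    chosen_dir = np.argmax((cum == pick + 1) & d, axis=0)
    new_vals = neigh[chosen_dir, idx[0], idx[1], idx[2]]

    out = labels.copy()
    out[idx] = new_vals
    return LabelMask(labels=out, affine=mask.affine.copy(),
                     label_map=dict(mask.label_map))


@dataclass(frozen=True)
class MuscleEffect:
    """Per-muscle volume-generating parameters for synthetic cohorts (mm^3).

    Covariate coefficients act additively on volume; defaults encode plausible
    confounding (larger volume with BMI and male sex) so that the adjusted
    and unadjusted group contrasts differ.
    """

    baseline_mm3: float
    group_effect_mm3: float
    noise_sd_mm3: float
    beta_age: float = 0.0      # mm^3 per year
    beta_bmi: float = 0.0      # mm^3 per kg/m^2
    beta_female: float = 0.0   # female minus male
    beta_af: float = 0.0       # Australian football minus soccer


def _default_muscle_effects() -> dict[str, MuscleEffect]:
    # Baselines sized so the group effects correspond to single-digit percent
    # differences; residual SDs of the order implied by study-scale CIs.
    def eff(base, effect, sd):
        return MuscleEffect(
            baseline_mm3=base, group_effect_mm3=effect, noise_sd_mm3=sd,
            beta_age=-0.002 * base, beta_bmi=0.02 * base,
            beta_female=-0.18 * base, beta_af=0.03 * base,
        )

    return {
        "Gmax": eff(760_000.0, 18_265.0, 120_000.0),
        "Gmed": eff(305_000.0, 23_858.0, 50_000.0),
        "Gmin": eff(90_000.0, 3_893.0, 19_000.0),
        "TFL": eff(71_600.0, 6_660.0, 16_000.0),
    }


@dataclass
class CohortSpec:
    """Study-scale synthetic cohort: covariate distributions mirror the
    demographics table (group sizes 180/48, female fraction 0.19/0.29,
    Australian-football fraction 0.49/0.42, age ~ N(28.3, 5.9),
    BMI ~ N(24.7, 3.2))."""

    n_symptomatic: int = 180
    n_control: int = 48
    muscles: dict[str, MuscleEffect] = field(default_factory=_default_muscle_effects)
    age_mean: float = 28.3
    age_sd: float = 5.9
    bmi_mean: float = 24.7
    bmi_sd: float = 3.2
    female_prob: dict[str, float] = field(
        default_factory=lambda: {"symptomatic": 0.19, "control": 0.29})
    af_prob: dict[str, float] = field(
        default_factory=lambda: {"symptomatic": 0.49, "control": 0.42})
    kick_right_prob: dict[str, float] = field(
        default_factory=lambda: {"F": 0.78, "M": 0.82})
    seed: int = 0

    def validate(self) -> None:
        if self.n_symptomatic < 2 or self.n_control < 2:
            raise ValueError("need at least 2 participants per group")
        for name, m in self.muscles.items():
            if m.noise_sd_mm3 < 0:
                raise ValueError(f"{name}: noise sd must be non-negative")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort with known ground-truth volume model.

    Volume for muscle m: baseline + beta.age*(age - mean) + beta.bmi*(BMI -
    mean) + beta_female*[female] + beta_af*[AF] + effect*[symptomatic] +
    Gaussian noise. Ground-truth parameters are recorded in
    ``df.attrs['truth']`` for recovery tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n in (("symptomatic", spec.n_symptomatic), ("control", spec.n_control)):
        sex = np.where(rng.random(n) < spec.female_prob[group], "F", "M")
        sport = np.where(rng.random(n) < spec.af_prob[group], "AF", "soccer")
        age = rng.normal(spec.age_mean, spec.age_sd, n)
        bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, n)
        p_right = np.array([spec.kick_right_prob[s] for s in sex])
        kick = np.where(rng.random(n) < p_right, "R", "L")
        symp_limb = np.where(rng.random(n) < 0.5, "R", "L") if group == "symptomatic" else [None] * n
        for i in range(n):
            rows.append({
                "group": group, "sex": sex[i], "sport": sport[i],
                "age": age[i], "bmi": bmi[i],
                "kicking_limb": kick[i], "symptomatic_limb": symp_limb[i],
            })
    df = pd.DataFrame(rows)
    df.insert(0, "participant_id", [f"P{i:04d}" for i in range(len(df))])

    for name, m in spec.muscles.items():
        vol = (
            m.baseline_mm3
            + m.beta_age * (df["age"].to_numpy() - spec.age_mean)
            + m.beta_bmi * (df["bmi"].to_numpy() - spec.bmi_mean)
            + m.beta_female * (df["sex"] == "F").to_numpy()
            + m.beta_af * (df["sport"] == "AF").to_numpy()
            + m.group_effect_mm3 * (df["group"] == "symptomatic").to_numpy()
            + rng.normal(0, m.noise_sd_mm3, len(df))
        )
        df[f"vol_{name}"] = vol

    df.attrs["truth"] = {
        name: {
            "baseline_mm3": m.baseline_mm3,
            "group_effect_mm3": m.group_effect_mm3,
            "noise_sd_mm3": m.noise_sd_mm3,
        }
        for name, m in spec.muscles.items()
    }
    return df


def simulate_profile_group(
    base: MFIProfile | np.ndarray,
    n: int,
    noise_sd: float,
    seed: int,
    smooth_fwhm_nodes: float = 12.0,
    effect: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Simulate n subject-level 101-node MFI curves around a shared mean.

    Each subject's curve is the base profile plus ``effect`` plus smooth
    Gaussian noise (white noise convolved with a Gaussian kernel of the given
    FWHM in node units, rescaled to pointwise SD ``noise_sd``), clipped to
    [0, 1]. Subjects are i.i.d., so two groups drawn with effect 0 are
    exchangeable — the null condition for family-wise error checks.
    """
    grid = np.linspace(0.0, 1.0, 101)
    mean = base(grid) if callable(base) else np.asarray(base, dtype=float)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n, 101))
    sigma = smooth_fwhm_nodes / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    smooth = gaussian_filter1d(white, sigma=sigma, axis=1, mode="nearest")
    # pointwise SD of smoothed unit white noise is ~ (2*sqrt(pi)*sigma)^(-1/2);
    # rescale so the subject-level pointwise SD equals noise_sd
    theo_sd = 1.0 / np.sqrt(2.0 * np.sqrt(np.pi) * sigma)
    smooth *= noise_sd / theo_sd
    return np.clip(mean + effect + smooth, 0.0, 1.0)


def default_phantom_spec(seed: int = 0, noise_sd: float = 0.0) -> PhantomSpec:
    """A compact two-sided lateral-hip phantom: four muscles per side with
    qualitatively distinct fat-infiltration profiles (proximally elevated
    Gmax/Gmed-like, distally rising TFL-like)."""
    muscles, profiles = [], {}
    # (name, primitive, semi-axes mm, A-P center mm, designed MFI profile);
    # A-P placements keep the shapes pairwise disjoint on the 96 mm grid.
    layout = [
        ("Gmax", "ellipsoid", (20.0, 14.0, 32.0), 78.0, MFIProfile("linear", (0.30, 0.10))),
        ("Gmed", "ellipsoid", (14.0, 12.0, 26.0), 48.0, MFIProfile("quadratic", (0.25, -0.4, 0.3))),
        ("Gmin", "tube", (8.0, 7.0, 18.0), 26.0, MFIProfile("linear", (0.18, 0.12))),
        ("TFL", "tube", (6.0, 5.0, 22.0), 10.0, MFIProfile("linear", (0.08, 0.25))),
    ]
    grid = (64, 64, 72)
    vox = (1.5, 1.5, 1.5)
    extent = [g * v for g, v in zip(grid, vox)]
    x_centers = {"L": 0.27 * extent[0], "R": 0.73 * extent[0]}
    label = 0
    for side in ("L", "R"):
        for name, prim, axes, y_center, prof in layout:
            label += 1
            muscles.append(MuscleShape(
                label=label, muscle=name, side=side, primitive=prim,
                center_mm=(x_centers[side], y_center, 0.5 * extent[2]),
                semi_axes_mm=axes,
            ))
            profiles[label] = prof
    return PhantomSpec(grid_shape=grid, voxel_size_mm=vox, muscles=muscles,
                       mfi_profiles=profiles, noise_sd=noise_sd, seed=seed)
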