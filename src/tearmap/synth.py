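"""Synthetic cohort generator for orthokeratology tear-film studies.

Emulates the statistical structure the downstream analysis assumes:

* three wear-duration groups (10-29, 30-90, >=91 days) of 13/28/51 eyes;
* pre-treatment maps with a good central zone degrading quadratically
  toward the periphery;
* post-treatment deterioration that spares the centre (smoothstep ramp
  between 1.0 and 3.5 mm radius) and concentrates in nasal/temporal
  hotspots at 3 mm radius, the temporal one stronger;
* OD/OS mirror symmetry (nasal at 0 deg for OD, 180 deg for OS) and a
  small constant laterality offset making left-eye maps slightly better;
* per-eye baseline offsets, i.i.d. Gaussian measurement noise (clamped
  at zero, since quality factors are nonnegative), and optional
  QC-failing maps.

Amplitudes are calibrated so that the *noise-free* group-level
area-weighted mean over the 4 mm analysis zone reproduces the reference
global means (OD: 0.14/0.15/0.1525 for G1/G2/G3; OS 0.01 lower).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Cohort, EyeRecord, PolarGrid, TearFilmMap
from .mapping import CENTRAL_QC_RADIUS, DEFAULT_ZONE_RADIUS, global_mean, make_standard_grid

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "default_params",
    "generate_eye",
    "generate_cohort",
    "generate_curvature",
    "true_fields",
]

GROUP_NAMES = ("G1", "G2", "G3")


@dataclass
class GeneratorParams:
    """Calibration of the synthetic cohort; see module docstring for geometry."""

    grid: PolarGrid
    q_center: float = 0.08          # central tear-quality factor
    q_slope: float = 0.12           # quadratic radial coefficient (value added at r = max)
    effect_amp: tuple = (0.0, 0.0, 0.0)    # peripheral ramp amplitude per group
    hotspot_amp: tuple = (0.0, 0.0, 0.0)   # temporal hotspot amplitude per group
    nasal_fraction: float = 0.6     # nasal hotspot amplitude relative to temporal
    hotspot_sigma: float = 0.8      # mm
    hotspot_radius: float = 3.0     # mm
    os_offset: float = -0.01        # constant laterality offset applied to OS maps
    day_modulation: float = 0.15    # log-linear within-group wear-time modulation
    subject_sd: float = 0.04        # across-eye baseline offset SD
    noise_sd: float = 0.02          # within-map measurement noise SD
    wear_day_ranges: tuple = ((10, 29), (30, 90), (91, 180))
    group_sizes: tuple = (13, 28, 51)
    qc_fail_rate: float = 0.0
    include_curvature: bool = True
    curvature_base: float = 43.5    # dioptres at the apex
    curvature_falloff: float = 1.2  # prolate peripheral flattening (D at r = max)
    curvature_bowl: tuple = (2.0, 2.5, 3.0)  # central flattening depth per group (D)
    curvature_bowl_sigma: float = 1.5        # mm
    seed: int = 0

    def __post_init__(self):
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        if not 0 <= self.qc_fail_rate < 1:
            raise ValueError("qc_fail_rate must be in [0, 1)")
        los = [r[0] for r in self.wear_day_ranges]
        his = [r[1] for r in self.wear_day_ranges]
        if any(lo > hi for lo, hi in self.wear_day_ranges) or any(
            his[i] >= los[i + 1] for i in range(len(los) - 1)
        ):
            raise ValueError("wear_day_ranges must be disjoint and ordered")

    def group_index(self, wear_days: int) -> int:
        for g, (lo, hi) in enumerate(self.wear_day_ranges):
            if lo <= wear_days <= hi:
                return g
        raise ValueError(
            f"wear_days={wear_days} outside all generator ranges {self.wear_day_ranges}"
        )

    def calibration_day(self, group_index: int) -> float:
        """Log-midpoint day of a group: the modulation-neutral wear time."""
        lo, hi = self.wear_day_ranges[group_index]
        return math.sqrt(lo * hi)


@dataclass
class GroundTruth:
    """Noise-free fields underlying one generated eye (same grid as the record)."""

    pre: np.ndarray
    post: np.ndarray

    @property
    def effect(self) -> np.ndarray:
        return self.post - self.pre


def _smoothstep_ramp(r: np.ndarray, r0: float = 1.0, r1: float = 3.5) -> np.ndarray:
    """Radial deterioration ramp: 0 below r0 mm, 1 above r1 mm, smooth between."""
    t = np.clip((r - r0) / (r1 - r0), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _hotspot_field(params: GeneratorParams, eye: str,
                   r: np.ndarray, th_deg: np.ndarray) -> np.ndarray:
    """Unit-peak temporal + scaled nasal Gaussian hotspots, mirrored for OS."""
    nasal = 0.0 if eye == "OD" else 180.0
    temporal = (nasal + 180.0) % 360.0
    x = r * np.cos(np.deg2rad(th_deg))
    y = r * np.sin(np.deg2rad(th_deg))
    out = np.zeros_like(r)
    for angle, amp in ((temporal, 1.0), (nasal, params.nasal_fraction)):
        cx = params.hotspot_radius * math.cos(math.radians(angle))
        cy = params.hotspot_radius * math.sin(math.radians(angle))
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        out += amp * np.exp(-d2 / (2.0 * params.hotspot_sigma**2))
    return out


def _day_factor(params: GeneratorParams, g: int, wear_days: float) -> float:
    lo, hi = params.wear_day_ranges[g]
    if hi == lo:
        return 1.0
    neutral = params.calibration_day(g)
    return 1.0 + params.day_modulation * (
        math.log(wear_days) - math.log(neutral)
    ) / (math.log(hi) - math.log(lo))


def true_fields(params: GeneratorParams, eye: str, wear_days: float,
                subject_offset: float = 0.0) -> GroundTruth:
    """Noise-free pre/post fields for one eye on the generator grid."""
    g = params.group_index(int(round(wear_days))) if float(wear_days).is_integer() \
        else params.group_index(int(wear_days))
    r, th = params.grid.mesh()
    base = params.q_center + (params.os_offset if eye == "OS" else 0.0)
    pre = base + params.q_slope * (r / params.grid.max_radius) ** 2 + subject_offset
    mod = _day_factor(params, g, wear_days)
    effect = mod * (
        params.effect_amp[g] * _smoothstep_ramp(r)
        + params.hotspot_amp[g] * _hotspot_field(params, eye, r, th)
    )
    return GroundTruth(pre=pre, post=pre + effect)


def default_params(grid: PolarGrid | None = None, seed: int = 0) -> GeneratorParams:
    """Packaged calibration reproducing the reference group-level global means.

    The peripheral-effect scale of each group is the single free amplitude;
    it is solved (linearly, on the grid's own area-weighted quadrature) so
    that the noise-free OD post-treatment global mean over the 4 mm zone
    equals 0.14 / 0.15 / 0.1525 for G1 / G2 / G3 at each group's
    log-midpoint wear day.  The OS maps are the same fields lowered by a
    constant 0.01 (hence 0.13 / 0.14 / 0.1425).
    """
    grid = grid if grid is not None else make_standard_grid()
    params = GeneratorParams(grid=grid, seed=seed)
    r, th = grid.mesh()

    def zone_mean(values):
        return global_mean(
            TearFilmMap(grid=grid, values=np.maximum(values, 0.0)),
            DEFAULT_ZONE_RADIUS,
        )

    pre = params.q_center + params.q_slope * (r / grid.max_radius) ** 2
    m_pre = zone_mean(pre)
    # unit effect field: ramp + relatively-scaled hotspots, temporal:nasal = 1:0.6
    hotspot_rel = 0.6
    unit = _smoothstep_ramp(r) + hotspot_rel * _hotspot_field(params, "OD", r, th)
    m_unit = zone_mean(pre + unit) - m_pre
    targets = (0.14, 0.15, 0.1525)
    scales = tuple((t - m_pre) / m_unit for t in targets)
    return replace(
        params,
        effect_amp=scales,
        hotspot_amp=tuple(s * hotspot_rel for s in scales),
    )


def _make_map(grid, values, session, flags=frozenset()):
    return TearFilmMap(grid=grid, values=values, modality="tear_quality",
                       session=session, artefact_flags=flags)


def generate_eye(params: GeneratorParams, eye: str, wear_days: int,
                 rng: np.random.Generator) -> tuple[EyeRecord, GroundTruth]:
    """One eye: noise-free fields + subject offset + clamped Gaussian noise."""
    g = params.group_index(int(wear_days))
    offset = float(rng.normal(0.0, params.subject_sd)) if params.subject_sd > 0 else 0.0
    truth = true_fields(params, eye, int(wear_days), subject_offset=offset)
    shape = params.grid.shape

    def noisy(field):
        vals = field + (rng.normal(0.0, params.noise_sd, shape)
                        if params.noise_sd > 0 else 0.0)
        return np.maximum(vals, 0.0)

    pre_map = _make_map(params.grid, noisy(truth.pre), "pre")
    post_map = _make_map(params.grid, noisy(truth.post), "post")
    record = EyeRecord(
        subject_id=f"SYN-{eye}-{wear_days:03d}-{rng.integers(0, 10**9):09d}",
        eye=eye, wear_days=int(wear_days),
        pre_map=pre_map, post_map=post_map,
    )
    if params.include_curvature:
        pre_c, post_c = generate_curvature(params, eye, wear_days, rng)
        record.pre_curvature, record.post_curvature = pre_c, post_c
    return record, truth


def generate_curvature(params: GeneratorParams, eye: str, wear_days: int,
                       rng: np.random.Generator,
                       decentration: tuple[float, float] | None = None,
                       ) -> tuple[TearFilmMap, TearFilmMap]:
    """Pre/post tangential curvature: prolate profile plus a decentred flattening bowl.

    The bowl centre is displaced by a seeded decentration vector of up to
    1 mm unless an explicit ``decentration`` (dx, dy) is given; bowl depth
    is nondecreasing across wear-duration groups.
    """
    g = params.group_index(int(wear_days))
    r, th = params.grid.mesh()
    x = r * np.cos(np.deg2rad(th))
    y = r * np.sin(np.deg2rad(th))
    pre = params.curvature_base - params.curvature_falloff * (r / params.grid.max_radius) ** 2
    if decentration is None:
        mag = float(rng.uniform(0.0, 1.0))
        ang = float(rng.uniform(0.0, 2.0 * math.pi))
        decentration = (mag * math.cos(ang), mag * math.sin(ang))
    dx, dy = decentration
    depth = params.curvature_bowl[g] * _day_factor(params, g, wear_days)
    bowl = depth * np.exp(
        -((x - dx) ** 2 + (y - dy) ** 2) / (2.0 * params.curvature_bowl_sigma**2)
    )
    post = pre - bowl
    mk = lambda v, s: TearFilmMap(grid=params.grid, values=v,
                                  modality="tangential_curvature", session=s)
    return mk(pre, "pre"), mk(post, "post")


def _corrupt_record(record: EyeRecord, rng: np.random.Generator) -> None:
    """Make one of the tear-quality maps QC-failing (in place)."""
    target = record.pre_map if rng.random() < 0.5 else record.post_map
    if rng.random() < 0.5:
        vals = target.values.copy()
        vals[target.grid.ring_radii <= CENTRAL_QC_RADIUS, :] = np.nan
        target.values = vals
    else:
        flag = "low_contrast" if rng.random() < 0.5 else "blink_artefact"
        target.artefact_flags = target.artefact_flags | {flag}


def generate_cohort(params: GeneratorParams, eye: str,
                    ) -> tuple[Cohort, list[GroundTruth]]:
    """A full single-laterality cohort (sum of group_sizes records).

    Wear days are sampled uniformly within each group's range.  A
    ``qc_fail_rate`` fraction of records is corrupted (central disc
    masked out or an artefact flag set) to exercise downstream QC.
    Identical params + seed give identical cohorts.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=params.seed, spawn_key=(0 if eye == "OD" else 1,)))
    records, truths = [], []
    for g, (n, (lo, hi)) in enumerate(zip(params.group_sizes, params.wear_day_ranges)):
        for i in range(n):
            wear_days = int(rng.integers(lo, hi + 1))
            record, truth = generate_eye(params, eye, wear_days, rng)
            record.subject_id = f"S{g + 1}{i + 1:03d}"
            if params.qc_fail_rate > 0 and rng.random() < params.qc_fail_rate:
                _corrupt_record(record, rng)
            records.append(record)
            truths.append(truth)
    cohort = Cohort(records=records, provenance={
        "source": "synthetic", "seed": params.seed, "eye": eye,
        "group_sizes": list(params.group_sizes),
    })
    return cohort, truths
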