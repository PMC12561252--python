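"""Core data model: polar grids, tear-film maps, per-eye records and cohorts.

All maps live on a :class:`PolarGrid` — a set of concentric rings crossed
with a set of meridians.  Values are tear-film quality factors
(dimensionless, *lower is better*) or tangential curvature (dioptres).
Missing cells are represented by NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Recognised map modalities.
MODALITIES = ("tear_quality", "tangential_curvature")
#: Recognised sessions.
SESSIONS = ("pre", "post")
#: Recognised artefact flags (read from the acquisition header).
ARTEFACT_FLAGS = ("low_contrast", "blink_artefact")
#: Laterality codes: right eye (OD), left eye (OS).
EYES = ("OD", "OS")

#: Wear-duration group boundaries in days: G1 = 10-29, G2 = 30-90, G3 = >=91.
GROUP_RANGES = {"G1": (10, 29), "G2": (30, 90), "G3": (91, None)}


def group_for_wear_days(wear_days: int) -> str:
    """Map a wear duration in days onto the study group labels G1/G2/G3."""
    d = int(wear_days)
    if d < 0:
        raise ValueError(f"wear_days must be >= 0, got {d}")
    for name, (lo, hi) in GROUP_RANGES.items():
        if d >= lo and (hi is None or d <= hi):
            return name
    raise ValueError(f"wear_days={d} falls outside all group ranges (min 10)")


@dataclass(frozen=True)
class PolarGrid:
    """Sampling pattern: strictly increasing ring radii x meridian angles.

    Parameters
    ----------
    ring_radii:
        Ring radii in mm, strictly increasing, all > 0.
    meridian_angles:
        Meridian angles in degrees, strictly increasing, in [0, 360).
        Angles are counter-clockwise with 0 deg at chart-right.
    """

    ring_radii: np.ndarray
    meridian_angles: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.ring_radii, dtype=float)
        a = np.asarray(self.meridian_angles, dtype=float)
        object.__setattr__(self, "ring_radii", r)
        object.__setattr__(self, "meridian_angles", a)
        if r.ndim != 1 or r.size < 2:
            raise ValueError("need at least 2 rings")
        if a.ndim != 1 or a.size < 8:
            raise ValueError("need at least 8 meridians")
        if np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("ring radii must be strictly increasing and > 0")
        if np.any(np.diff(a) <= 0) or a[0] < 0 or a[-1] >= 360:
            raise ValueError("meridian angles must be strictly increasing in [0, 360)")

    @property
    def n_rings(self) -> int:
        return self.ring_radii.size

    @property
    def n_meridians(self) -> int:
        return self.meridian_angles.size

    @property
    def max_radius(self) -> float:
        return float(self.ring_radii[-1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rings, self.n_meridians)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, theta) meshes of shape (n_rings, n_meridians)."""
        return np.meshgrid(self.ring_radii, self.meridian_angles, indexing="ij")

    def cartesian_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        r, th = self.mesh()
        return r * np.cos(np.deg2rad(th)), r * np.sin(np.deg2rad(th))

    def ring_widths(self) -> np.ndarray:
        """Radial extent of each ring's annulus (midpoint boundaries, clipped at 0)."""
        r = self.ring_radii
        mids = (r[:-1] + r[1:]) / 2.0
        inner = np.concatenate([[max(0.0, r[0] - (r[1] - r[0]) / 2.0)], mids])
        outer = np.concatenate([mids, [r[-1] + (r[-1] - r[-2]) / 2.0]])
        return outer - inner

    def area_weights(self) -> np.ndarray:
        """Per-cell area weights proportional to r * dr * dtheta, shape (n_rings, n_meridians)."""
        dr = self.ring_widths()
        a = self.meridian_angles
        da = np.diff(np.concatenate([a, [a[0] + 360.0]]))
        return np.outer(self.ring_radii * dr, da)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PolarGrid):
            return NotImplemented
        return (
            self.ring_radii.shape == other.ring_radii.shape
            and self.meridian_angles.shape == other.meridian_angles.shape
            and np.array_equal(self.ring_radii, other.ring_radii)
            and np.array_equal(self.meridian_angles, other.meridian_angles)
        )

    def __hash__(self):
        return hash((self.ring_radii.tobytes(), self.meridian_angles.tobytes()))


@dataclass
class TearFilmMap:
    """A scalar field on a polar grid (NaN = missing)."""

    grid: PolarGrid
    values: np.ndarray
    modality: str = "tear_quality"
    session: str = "pre"
    artefact_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")
        self.artefact_flags = frozenset(self.artefact_flags)
        unknown = self.artefact_flags - set(ARTEFACT_FLAGS)
        if unknown:
            raise ValueError(f"unknown artefact flags {sorted(unknown)}")
        if self.modality == "tear_quality":
            present = self.values[np.isfinite(self.values)]
            if present.size and present.min() < 0:
                raise ValueError("tear_quality values must be >= 0")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def copy_with(self, **kw) -> "TearFilmMap":
        args = dict(
            grid=self.grid,
            values=self.values.copy(),
            modality=self.modality,
            session=self.session,
            artefact_flags=self.artefact_flags,
        )
        args.update(kw)
        return TearFilmMap(**args)

    def allclose(self, other: "TearFilmMap", rtol=1e-12, atol=1e-12) -> bool:
        return (
            self.grid == other.grid
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.allclose(
                np.nan_to_num(self.values), np.nan_to_num(other.values),
                rtol=rtol, atol=atol,
            )
        )


@dataclass
class EyeRecord:
    """One eye's paired session data plus wear metadata."""

    subject_id: str
    eye: str
    wear_days: int
    pre_map: TearFilmMap
    post_map: TearFilmMap
    pre_curvature: Optional[TearFilmMap] = None
    post_curvature: Optional[TearFilmMap] = None

    def __post_init__(self):
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        self.wear_days = int(self.wear_days)
        group_for_wear_days(self.wear_days)  # validates range
        if self.pre_map.session != "pre" or self.post_map.session != "post":
            raise ValueError("pre_map/post_map session labels inconsistent")
        if self.pre_map.modality != "tear_quality" or self.post_map.modality != "tear_quality":
            raise ValueError("pre_map/post_map must be tear_quality maps")
        if self.pre_map.grid != self.post_map.grid:
            raise ValueError("pre and post maps must share one grid")
        for m in (self.pre_curvature, self.post_curvature):
            if m is not None and m.modality != "tangential_curvature":
                raise ValueError("curvature maps must have tangential_curvature modality")

    @property
    def group(self) -> str:
        return group_for_wear_days(self.wear_days)

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.eye)

    def maps(self) -> list[TearFilmMap]:
        out = [self.pre_map, self.post_map]
        for m in (self.pre_curvature, self.post_curvature):
            if m is not None:
                out.append(m)
        return out


@dataclass
class Cohort:
    """A collection of eye records sharing one laterality-agnostic standard grid."""

    records: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate subject x eye keys: {dupes}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter(self, eye: str | None = None, group: str | None = None) -> "Cohort":
        recs = [
            r
            for r in self.records
            if (eye is None or r.eye == eye) and (group is None or r.group == group)
        ]
        return Cohort(records=recs, provenance=dict(self.provenance))
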