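"""Landmark-based leaf morphometrics.

A digitised grapevine leaf is represented by 21 labelled 2-D landmarks
(vein bases, branch points, vein/lobe tips and sinuses).  From those
coordinates the module derives the 16 ampelometric phenotypes used
downstream: four vein lengths, six polygon areas and six shape ratios.

Landmark semantics (indices 1-21):

1-4    vein-base width points across the petiole insertion, from the
       proximal side (1) to the free side of the midvein (4)
5-7    petiolar-vein junction on the proximal vein (distal base,
       proximal base, width landmark)
8-10   distal-vein branch junction (distal base, proximal base, width)
11-13  midvein branch junction (distal base, proximal base, width)
14     tip of the petiolar vein
15     tip of the proximal lobe
16     proximal sinus
17     tip of the distal vein branch
18     tip of the distal lobe
19     distal sinus
20     tip of the midvein branch
21     leaf tip

Lengths come straight from the Pythagorean theorem; areas from the
shoelace formula over configurable landmark cycles; coordinates are
assumed calibrated to centimetres (an optional uniform scale can be
applied at read time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    GeometryError,
    InconsistentGeometryError,
    InvalidCoordinateError,
    UndefinedRatioError,
)

__all__ = [
    "LandmarkSet",
    "PolygonConfig",
    "LeafTraits",
    "TRAIT_NAMES",
    "euclidean_distance",
    "shoelace_area",
    "midpoint",
    "vein_lengths",
    "leaf_areas",
    "shape_ratios",
    "compute_traits",
    "qc_landmarks",
    "traits_table",
    "read_landmarks",
    "write_landmarks",
]

N_LANDMARKS = 21

POSITIONS = ("apical", "middle", "basal")
PRESENTATIONS = ("own_rooted", "grafted")
DAYLENGTHS = (13, 14)

#: The 16 phenotype names, in reporting order (10 size then 6 shape).
TRAIT_NAMES = (
    "mid_vein_length",
    "prox_vein_length",
    "dist_vein_length",
    "xvii_vein_length",
    "total_area",
    "blade_area",
    "vein_area",
    "mid_vein_area",
    "prox_vein_area",
    "dist_vein_area",
    "veins_to_blade",
    "prox_to_dist",
    "prox_to_mid",
    "dist_to_mid",
    "xvii_to_mid",
    "petiolar_sinus_to_area",
)


@dataclass(frozen=True)
class LandmarkSet:
    """One leaf: 21 labelled landmarks plus its design metadata.

    ``points`` is indexed 0..20 for landmarks 1..21; coordinates in cm.
    """

    leaf_id: str
    genotype_id: str
    presentation: str
    position: str
    daylength_h: int
    year: int
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise InvalidCoordinateError(
                f"leaf {self.leaf_id!r}: expected {N_LANDMARKS} (x, y) pairs, "
                f"got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidCoordinateError(
                f"leaf {self.leaf_id!r}: non-finite landmark coordinates"
            )
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}, got {self.position!r}")
        if self.presentation not in PRESENTATIONS:
            raise ValueError(
                f"presentation must be one of {PRESENTATIONS}, got {self.presentation!r}"
            )
        if int(self.daylength_h) not in DAYLENGTHS:
            raise ValueError(f"daylength_h must be in {DAYLENGTHS}, got {self.daylength_h!r}")
        object.__setattr__(self, "points", pts)

    def point(self, index: int) -> np.ndarray:
        """Landmark by its 1-based anatomical index."""
        if not 1 <= index <= N_LANDMARKS:
            raise IndexError(f"landmark index {index} outside 1..{N_LANDMARKS}")
        return self.points[index - 1]


@dataclass(frozen=True)
class PolygonConfig:
    """Landmark cycles defining the area polygons and the L5 pair.

    Defaults traverse each vein outline as: first base point, width
    landmark, main vein tip, distal branch base, branch tip, proximal
    branch base, second base point — an ordering that is a simple
    polygon for leaves laid out with the margin topology above.  All
    cycles use 1-based landmark indices and are fully configurable.
    """

    boundary_cycle: tuple[int, ...] = (14, 15, 16, 17, 18, 19, 20, 21)
    mid_vein_cycle: tuple[int, ...] = (4, 13, 21, 11, 20, 12, 3)
    dist_vein_cycle: tuple[int, ...] = (3, 10, 18, 8, 17, 9, 2)
    prox_vein_cycle: tuple[int, ...] = (2, 7, 15, 5, 14, 6, 1)
    sinus_pair: tuple[int, int] = (6, 14)

    def __post_init__(self) -> None:
        for name in ("boundary_cycle", "mid_vein_cycle", "dist_vein_cycle", "prox_vein_cycle"):
            cyc = tuple(int(i) for i in getattr(self, name))
            if len(set(cyc)) < 3:
                raise ValueError(f"{name} needs >=3 distinct landmark indices, got {cyc}")
            if any(not 1 <= i <= N_LANDMARKS for i in cyc):
                raise ValueError(f"{name} has indices outside 1..{N_LANDMARKS}: {cyc}")
            object.__setattr__(self, name, cyc)
        pair = tuple(int(i) for i in self.sinus_pair)
        if len(pair) != 2 or pair[0] == pair[1]:
            raise ValueError(f"sinus_pair must be two distinct indices, got {pair}")
        if any(not 1 <= i <= N_LANDMARKS for i in pair):
            raise ValueError(f"sinus_pair indices outside 1..{N_LANDMARKS}: {pair}")
        object.__setattr__(self, "sinus_pair", pair)

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PolygonConfig":
        kwargs = {k: tuple(v) for k, v in d.items()}
        return cls(**kwargs)


@dataclass(frozen=True)
class LeafTraits:
    """The 16 phenotypes of one leaf (lengths cm, areas cm^2)."""

    mid_vein_length: float
    prox_vein_length: float
    dist_vein_length: float
    xvii_vein_length: float
    total_area: float
    blade_area: float
    vein_area: float
    mid_vein_area: float
    prox_vein_area: float
    dist_vein_area: float
    veins_to_blade: float
    prox_to_dist: float
    prox_to_mid: float
    dist_to_mid: float
    xvii_to_mid: float
    petiolar_sinus_to_area: float

    def as_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in TRAIT_NAMES})

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TRAIT_NAMES}


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Straight-line distance between two coordinate pairs (cm)."""
    px, py = float(p[0]), float(p[1])
    qx, qy = float(q[0]), float(q[1])
    if not all(math.isfinite(v) for v in (px, py, qx, qy)):
        raise InvalidCoordinateError(f"non-finite coordinates: {p!r}, {q!r}")
    return math.hypot(px - qx, py - qy)


def midpoint(p: Sequence[float], q: Sequence[float]) -> np.ndarray:
    return (np.asarray(p, dtype=float) + np.asarray(q, dtype=float)) / 2.0


def shoelace_area(vertices: Sequence[Sequence[float]]) -> float:
    """Unsigned polygon area via the shoelace formula.

    |sum_i (x_i * y_{i+1} - x_{i+1} * y_i)| / 2 with cyclic wraparound.
    Invariant under cyclic rotation and order reversal of the vertices.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise GeometryError(f"polygon needs >=3 (x, y) vertices, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise InvalidCoordinateError("non-finite polygon vertices")
    x, y = v[:, 0], v[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    return float(abs(cross.sum()) / 2.0)


def polygon_is_simple(vertices: Sequence[Sequence[float]]) -> bool:
    """True when the closed polygon has no self-intersections."""
    from shapely.geometry import Polygon

    return Polygon(np.asarray(vertices, dtype=float)).is_valid


def _cycle_points(ls: LandmarkSet, cycle: Iterable[int]) -> np.ndarray:
    return np.array([ls.point(i) for i in cycle], dtype=float)


def vein_lengths(ls: LandmarkSet, cfg: PolygonConfig | None = None) -> dict[str, float]:
    """The five length measures L1..L5 (cm).

    L1: midpoint(P3, P4) -> P21 (midvein); L2: midpoint(P2, P3) -> P18
    (distal vein); L3: P2 -> P17 (xvii vein); L4: midpoint(P1, P2) ->
    P15 (proximal vein); L5: petiolar-sinus width over the configured
    landmark pair (default P6-P14).
    """
    cfg = cfg or PolygonConfig()
    pts = ls.points
    if np.allclose(pts, pts[0]):
        raise GeometryError(f"leaf {ls.leaf_id!r}: all landmarks coincident")
    a, b = cfg.sinus_pair
    return {
        "L1": euclidean_distance(midpoint(ls.point(3), ls.point(4)), ls.point(21)),
        "L2": euclidean_distance(midpoint(ls.point(2), ls.point(3)), ls.point(18)),
        "L3": euclidean_distance(ls.point(2), ls.point(17)),
        "L4": euclidean_distance(midpoint(ls.point(1), ls.point(2)), ls.point(15)),
        "L5": euclidean_distance(ls.point(a), ls.point(b)),
    }


def leaf_areas(ls: LandmarkSet, cfg: PolygonConfig | None = None) -> dict[str, float]:
    """Total, per-vein, summed-vein and blade areas (cm^2).

    vein_area = mid + prox + dist; blade_area = total - vein_area.
    Raises when the vein polygons exceed the leaf boundary.
    """
    cfg = cfg or PolygonConfig()
    total = shoelace_area(_cycle_points(ls, cfg.boundary_cycle))
    mid = shoelace_area(_cycle_points(ls, cfg.mid_vein_cycle))
    prox = shoelace_area(_cycle_points(ls, cfg.prox_vein_cycle))
    dist = shoelace_area(_cycle_points(ls, cfg.dist_vein_cycle))
    vein = mid + prox + dist
    blade = total - vein
    if blade <= 0:
        raise InconsistentGeometryError(
            f"leaf {ls.leaf_id!r}: vein area {vein:.4g} >= total area {total:.4g}"
        )
    return {
        "total_area": total,
        "mid_vein_area": mid,
        "prox_vein_area": prox,
        "dist_vein_area": dist,
        "vein_area": vein,
        "blade_area": blade,
    }


def shape_ratios(lengths: dict[str, float], areas: dict[str, float]) -> dict[str, float]:
    """The six shape phenotypes derived from lengths and areas.

    veins_to_blade is the natural log of vein_area / blade_area.
    """
    denominators = {
        "veins_to_blade": areas["blade_area"],
        "prox_to_dist": lengths["L2"],
        "prox_to_mid": lengths["L1"],
        "dist_to_mid": lengths["L1"],
        "xvii_to_mid": lengths["L1"],
        "petiolar_sinus_to_area": areas["total_area"],
    }
    for trait, den in denominators.items():
        if den == 0:
            raise UndefinedRatioError(f"zero denominator for trait {trait!r}")
    if areas["vein_area"] <= 0:
        raise UndefinedRatioError("veins_to_blade undefined: vein_area <= 0")
    return {
        "veins_to_blade": math.log(areas["vein_area"] / areas["blade_area"]),
        "prox_to_dist": lengths["L4"] / lengths["L2"],
        "prox_to_mid": lengths["L4"] / lengths["L1"],
        "dist_to_mid": lengths["L2"] / lengths["L1"],
        "xvii_to_mid": lengths["L3"] / lengths["L1"],
        "petiolar_sinus_to_area": lengths["L5"] / areas["total_area"],
    }


def compute_traits(ls: LandmarkSet, cfg: PolygonConfig | None = None) -> LeafTraits:
    """All 16 phenotypes for one leaf, deterministically."""
    cfg = cfg or PolygonConfig()
    try:
        lengths = vein_lengths(ls, cfg)
        areas = leaf_areas(ls, cfg)
        ratios = shape_ratios(lengths, areas)
    except (GeometryError, UndefinedRatioError, InvalidCoordinateError) as exc:
        raise type(exc)(f"leaf {ls.leaf_id!r}: {exc}") from exc
    return LeafTraits(
        mid_vein_length=lengths["L1"],
        prox_vein_length=lengths["L4"],
        dist_vein_length=lengths["L2"],
        xvii_vein_length=lengths["L3"],
        total_area=areas["total_area"],
        blade_area=areas["blade_area"],
        vein_area=areas["vein_area"],
        mid_vein_area=areas["mid_vein_area"],
        prox_vein_area=areas["prox_vein_area"],
        dist_vein_area=areas["dist_vein_area"],
        **ratios,
    )


def qc_landmarks(
    ls: LandmarkSet,
    cfg: PolygonConfig | None = None,
    max_vein_to_diameter: float = 1.25,
    duplicate_tol: float = 1e-6,
) -> list[str]:
    """Quality-control flags for one digitised leaf.

    Reports (never raises) on: a self-intersecting boundary cycle, a
    leaf tip (P21) that is not the most distal boundary point, any vein
    length exceeding ``max_vein_to_diameter`` times the boundary
    diameter, and duplicate coordinates.
    """
    cfg = cfg or PolygonConfig()
    flags: list[str] = []
    boundary = _cycle_points(ls, cfg.boundary_cycle)

    if not polygon_is_simple(boundary):
        flags.append("boundary-self-intersection")

    # y increases toward the leaf tip (package coordinate convention)
    tip_y = ls.point(21)[1]
    if tip_y < boundary[:, 1].max() - 1e-12:
        flags.append("tip-not-distal")

    diffs = boundary[:, None, :] - boundary[None, :, :]
    diameter = float(np.sqrt((diffs**2).sum(-1)).max())
    if diameter > 0:
        try:
            lengths = vein_lengths(ls, cfg)
        except GeometryError:
            lengths = {}
            flags.append("degenerate-geometry")
        for name, value in lengths.items():
            if value > max_vein_to_diameter * diameter:
                flags.append(f"vein-too-long:{name}")
    else:
        flags.append("degenerate-geometry")

    pd_all = ls.points[:, None, :] - ls.points[None, :, :]
    dist_all = np.sqrt((pd_all**2).sum(-1))
    iu = np.triu_indices(N_LANDMARKS, k=1)
    if np.any(dist_all[iu] < duplicate_tol):
        flags.append("duplicate-coordinate")
    return flags


# ---------------------------------------------------------------------------
# Tabular interface


_META_COLUMNS = ["leaf_id", "genotype_id", "presentation", "position", "daylength_h", "year"]


def _coord_columns() -> list[str]:
    return [f"{ax}{i}" for i in range(1, N_LANDMARKS + 1) for ax in ("x", "y")]


def read_landmarks(path, scale: float = 1.0, on_bad: str = "raise"):
    """Read a landmark CSV (one row per leaf, 21 coordinate pairs).

    The header must carry the metadata columns and x1, y1, ..., x21,
    y21; all 21 pairs are required.  ``scale`` applies a uniform
    pixel-to-cm calibration factor.  With ``on_bad="collect"`` the
    return value is ``(leaves, failures)`` where failures lists
    ``{"line": ..., "error": ...}`` for malformed rows instead of
    raising on the first one.
    """
    if on_bad not in ("raise", "collect"):
        raise ValueError("on_bad must be 'raise' or 'collect'")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _META_COLUMNS + _coord_columns() if c not in df.columns]
    if missing:
        raise FormatError(
            f"landmark CSV is missing required columns (all 21 landmark "
            f"pairs are mandatory): {missing}"
        )
    leaves = []
    failures = []
    for idx, row in df.iterrows():
        try:
            pts = np.array(
                [[row[f"x{i}"], row[f"y{i}"]] for i in range(1, N_LANDMARKS + 1)],
                dtype=float,
            )
            leaves.append(
                LandmarkSet(
                    leaf_id=str(row["leaf_id"]),
                    genotype_id=str(row["genotype_id"]),
                    presentation=str(row["presentation"]),
                    position=str(row["position"]),
                    daylength_h=int(row["daylength_h"]),
                    year=int(row["year"]),
                    points=pts * float(scale),
                )
            )
        except (ValueError, InvalidCoordinateError) as exc:
            if on_bad == "raise":
                raise
            failures.append({"line": int(idx) + 2, "error": str(exc)})
    if on_bad == "collect":
        return leaves, failures
    return leaves


def write_landmarks(leaves: Iterable[LandmarkSet], path, header_comment: str | None = None) -> None:
    rows = []
    for ls in leaves:
        row: dict = {
            "leaf_id": ls.leaf_id,
            "genotype_id": ls.genotype_id,
            "presentation": ls.presentation,
            "position": ls.position,
            "daylength_h": ls.daylength_h,
            "year": ls.year,
        }
        for i in range(1, N_LANDMARKS + 1):
            row[f"x{i}"] = ls.points[i - 1, 0]
            row[f"y{i}"] = ls.points[i - 1, 1]
        rows.append(row)
    df = pd.DataFrame(rows, columns=_META_COLUMNS + _coord_columns())
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def traits_table(
    leaves: Iterable[LandmarkSet],
    cfg: PolygonConfig | None = None,
    qc: bool = False,
) -> pd.DataFrame:
    """Per-leaf trait table: metadata columns followed by the 16 traits.

    With ``qc=True`` an extra ``qc_flags`` column carries a
    semicolon-joined flag list per leaf.
    """
    cfg = cfg or PolygonConfig()
    rows = []
    for ls in leaves:
        traits = compute_traits(ls, cfg)
        row = {
            "leaf_id": ls.leaf_id,
            "genotype_id": ls.genotype_id,
            "presentation": ls.presentation,
            "position": ls.position,
            "daylength_h": ls.daylength_h,
            "year": ls.year,
            **traits.as_dict(),
        }
        if qc:
            row["qc_flags"] = ";".join(qc_landmarks(ls, cfg))
        rows.append(row)
    return pd.DataFrame(rows)
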