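"""Leaf microstructure: generation, import/export, morphometrics, meshing.

A :class:`LeafGeometry` is a labelled 2-D cross-section of a leaf: an
adaxial and abaxial epidermis strip (homogeneous effective media, no
resolved stomata), a band of mesophyll cells separated by intercellular air
space, and one vascular bundle whose xylem faces the adaxial epidermis.
Each mesophyll cell nests, from the outside in: a 0.5 µm cell wall, a
cytosol sleeve, a closed chloroplast layer placed 0.5 µm inside the
plasmalemma and occupying a fixed share of the cell area, an inner
cytoplasm sleeve, and a single large vacuole.  CO2 entering the vacuole
therefore crosses the wall, the plasmalemma, the chloroplast envelope twice
and the tonoplast.

Because the original micrographs behind such models are generally not
available, the generator builds a synthetic tessellation: Lloyd-relaxed
Voronoi cells in the mesophyll band, eroded apart until the whole-section
chloroplast and cytosol area fractions hit their targets.  Real
microstructures can be supplied instead as labelled rasters.

Coordinates are in µm with the adaxial surface at y = 0 and y increasing
toward the abaxial surface.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial import Voronoi
from shapely.geometry import LineString, Polygon, box

__all__ = [
    "PhaseLabel",
    "GAS_PHASES",
    "AQUEOUS_PHASES",
    "MembraneKind",
    "MembraneInterface",
    "GeometryGenParams",
    "CellRecord",
    "LeafGeometry",
    "ComputationalMesh",
    "GeometryError",
    "InfeasibleGeometryError",
    "TopologyError",
    "generate_leaf_microstructure",
    "offset_inward",
    "place_chloroplast_layer",
    "phase_fractions",
    "photosynthetic_capacity_profile",
    "mesh",
    "export_labeled_raster",
    "import_labeled_raster",
    "save_geometry_json",
    "load_geometry_json",
]


class GeometryError(ValueError):
    """Base class for geometry construction errors."""


class InfeasibleGeometryError(GeometryError):
    """Requested morphological targets cannot be realised."""


class TopologyError(GeometryError):
    """Overlapping or otherwise inconsistent region polygons."""


class PhaseLabel(IntEnum):
    """Tissue phases.  PORE is the only free gas phase; the EPIDERMIS is a
    homogeneous effective gas-conducting medium lumping the stomata."""

    PORE = 0
    EPIDERMIS = 1
    CELL_WALL = 2
    CYTOSOL = 3
    CHLOROPLAST = 4
    VACUOLE = 5
    PHLOEM = 6
    XYLEM = 7


GAS_PHASES = frozenset({PhaseLabel.PORE, PhaseLabel.EPIDERMIS})
AQUEOUS_PHASES = frozenset(
    {
        PhaseLabel.CELL_WALL,
        PhaseLabel.CYTOSOL,
        PhaseLabel.CHLOROPLAST,
        PhaseLabel.VACUOLE,
        PhaseLabel.PHLOEM,
        PhaseLabel.XYLEM,
    }
)


class MembraneKind(IntEnum):
    PLASMALEMMA = 0
    CHLOROPLAST_ENVELOPE = 1
    TONOPLAST = 2


@dataclass(frozen=True)
class MembraneInterface:
    """A membrane curve with its permeability multiplier.

    The chloroplast envelope is a double membrane, so its permeability is
    half the single-membrane value (multiplier 1/2).
    """

    kind: MembraneKind
    curve: tuple[tuple[float, float], ...]
    multiplier: float
    cell_id: int

    def __post_init__(self) -> None:
        if self.multiplier not in (1.0, 0.5):
            raise ValueError("membrane multiplier must be 1 or 1/2")

    @property
    def length_um(self) -> float:
        return LineString(self.curve).length


@dataclass(frozen=True)
class GeometryGenParams:
    """Morphological parameters of the synthetic microstructure generator.

    ``fc`` / ``fm`` are the target whole-section areal fractions of
    chloroplast and cytosol; ``chloroplast_share`` the chloroplast layer's
    share of each mesophyll-cell area.  ``vacuole_area_scale`` fixes the
    vacuole/cell area ratio explicitly; when ``None`` (default) the vacuole
    share of each cell is derived so that the cytosol fraction hits ``fm``.
    """

    thickness_um: float = 184.0
    width_um: float = 120.0
    epidermis_um: float = 20.0
    wall_um: float = 0.5
    chloroplast_offset_um: float = 0.5
    chloroplast_share: float = 0.20
    vacuole_area_scale: Optional[float] = None
    fc: float = 0.104
    fm: float = 0.169
    n_cells: Optional[int] = None  # default: ~3.0e-3 cells/µm² of band
    bundle_radius_um: float = 16.0
    contact_gap_um: float = 1.0
    contact_fraction: float = 0.85
    min_cell_area_um2: float = 190.0
    lloyd_iters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vacuole_area_scale is not None and not 0 < self.vacuole_area_scale < 1:
            raise ValueError("vacuole area scale must lie in (0, 1)")
        if not 0 < self.chloroplast_share < 1:
            raise ValueError("chloroplast share must lie in (0, 1)")
        if self.wall_um <= 0 or self.chloroplast_offset_um <= 0:
            raise ValueError("offsets must be positive")
        if self.fc + self.fm >= 1:
            raise ValueError("fc + fm must be < 1")
        if min(self.fc, self.fm) <= 0:
            raise ValueError("fc and fm must be positive")
        if self.thickness_um <= 2 * self.epidermis_um:
            raise ValueError("leaf thinner than the two epidermis strips")


@dataclass
class CellRecord:
    """One cell with its nested construction polygons.

    ``interior`` is the cell polygon offset inward by the wall thickness
    (its boundary is the plasmalemma).  Mesophyll cells additionally carry
    the chloroplast layer bounds and the vacuole; vascular cells only the
    wall and a homogeneous interior.
    """

    cell_id: int
    kind: str  # "mesophyll" | "phloem" | "xylem"
    polygon: Polygon
    interior: Polygon
    chl_outer: Optional[Polygon] = None
    chl_inner: Optional[Polygon] = None
    vacuole: Optional[Polygon] = None

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def wall_area(self) -> float:
        return self.polygon.area - self.interior.area

    @property
    def chloroplast_area(self) -> float:
        if self.chl_outer is None:
            return 0.0
        inner = self.chl_inner.area if self.chl_inner is not None else 0.0
        return self.chl_outer.area - inner

    @property
    def vacuole_area(self) -> float:
        return self.vacuole.area if self.vacuole is not None else 0.0

    @property
    def cytosol_area(self) -> float:
        if self.kind != "mesophyll":
            return 0.0
        return (
            self.interior.area - self.chloroplast_area - self.vacuole_area
        )

    @property
    def interior_label(self) -> PhaseLabel:
        return {
            "mesophyll": PhaseLabel.CYTOSOL,
            "phloem": PhaseLabel.PHLOEM,
            "xylem": PhaseLabel.XYLEM,
        }[self.kind]


@dataclass
class LeafGeometry:
    """A labelled leaf cross-section (polygons, µm).

    ``extra_regions`` are free labelled polygons painted before the cells;
    they exist for hand-built fixtures (slabs, strips) and imported shapes.
    A raster-backed geometry (from :func:`import_labeled_raster`) stores the
    label grid instead of polygons.
    """

    width_um: float
    thickness_um: float
    cells: list[CellRecord] = field(default_factory=list)
    epidermis_polys: list[Polygon] = field(default_factory=list)
    extra_regions: list[tuple[PhaseLabel, Polygon]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    raster_labels: Optional[np.ndarray] = None
    raster_h_um: Optional[float] = None

    # -- morphometrics -----------------------------------------------------

    @property
    def domain_area(self) -> float:
        return self.width_um * self.thickness_um

    @property
    def is_raster_backed(self) -> bool:
        return self.raster_labels is not None

    @property
    def mesophyll_cells(self) -> list[CellRecord]:
        return [c for c in self.cells if c.kind == "mesophyll"]

    @property
    def membranes(self) -> list[MembraneInterface]:
        out: list[MembraneInterface] = []
        for c in self.cells:
            out.append(
                MembraneInterface(
                    MembraneKind.PLASMALEMMA,
                    tuple(c.interior.exterior.coords),
                    1.0,
                    c.cell_id,
                )
            )
            for ring in (c.chl_outer, c.chl_inner):
                if ring is not None and not ring.is_empty:
                    out.append(
                        MembraneInterface(
                            MembraneKind.CHLOROPLAST_ENVELOPE,
                            tuple(ring.exterior.coords),
                            0.5,
                            c.cell_id,
                        )
                    )
            if c.vacuole is not None and not c.vacuole.is_empty:
                out.append(
                    MembraneInterface(
                        MembraneKind.TONOPLAST,
                        tuple(c.vacuole.exterior.coords),
                        1.0,
                        c.cell_id,
                    )
                )
        return out

    def check_topology(self) -> None:
        """Raise :class:`TopologyError` if painted regions overlap."""
        polys = [c.polygon for c in self.cells] + self.epidermis_polys + [
            p for _, p in self.extra_regions
        ]
        if not polys:
            return
        total = sum(p.area for p in polys)
        union = shapely.unary_union(polys).area
        if total > self.domain_area * (1 + 1e-9) or total - union > 1e-6 * max(total, 1.0):
            raise TopologyError("region polygons overlap or exceed the domain")


def phase_fractions(geometry: LeafGeometry) -> dict[PhaseLabel, float]:
    """Areal fraction of every phase; fractions are >= 0 and sum to 1.

    Polygon-backed geometries are measured exactly from polygon areas (the
    pore fraction is the remainder of the bounding box); raster-backed ones
    by pixel counting.
    """
    if geometry.is_raster_backed:
        labels = geometry.raster_labels
        n = labels.size
        return {
            lab: float(np.count_nonzero(labels == lab)) / n for lab in PhaseLabel
        }
    geometry.check_topology()
    areas = dict.fromkeys(PhaseLabel, 0.0)
    for lab, poly in geometry.extra_regions:
        areas[lab] += poly.area
    for poly in geometry.epidermis_polys:
        areas[PhaseLabel.EPIDERMIS] += poly.area
    for c in geometry.cells:
        areas[PhaseLabel.CELL_WALL] += c.wall_area
        if c.kind == "mesophyll":
            areas[PhaseLabel.CHLOROPLAST] += c.chloroplast_area
            areas[PhaseLabel.VACUOLE] += c.vacuole_area
            areas[PhaseLabel.CYTOSOL] += c.cytosol_area
        else:
            areas[c.interior_label] += c.interior.area
    total = geometry.domain_area
    assigned = sum(areas.values()) - areas[PhaseLabel.PORE]
    areas[PhaseLabel.PORE] += max(total - assigned, 0.0)
    return {lab: a / total for lab, a in areas.items()}


# -- polygon offsetting ----------------------------------------------------


def offset_inward(polygon: Polygon, distance: float, name: str = "polygon") -> Polygon:
    """Offset a simple polygon inward by ``distance`` normal to every edge.

    Mitred joins preserve corners, matching the band-between-offsets
    construction of cell walls and organelle layers.  Raises
    :class:`InfeasibleGeometryError` (naming the cell) if the offset
    annihilates the polygon.
    """
    if distance < 0:
        raise ValueError("offset distance must be non-negative")
    if distance == 0:
        return polygon
    out = polygon.buffer(-distance, join_style="mitre", mitre_limit=10.0)
    if out.is_empty or out.area <= 0:
        raise InfeasibleGeometryError(
            f"inward offset of {distance} µm annihilates {name}"
        )
    if out.geom_type == "MultiPolygon":  # pinched concave shape
        out = max(out.geoms, key=lambda g: g.area)
    return out


def _offset_area(polygon: Polygon, distance: float) -> float:
    out = polygon.buffer(-distance, join_style="mitre", mitre_limit=10.0)
    return out.area


def _offset_for_area(polygon: Polygon, target_area: float, name: str) -> float:
    """Inward-offset distance at which the offset polygon has a given area."""
    if target_area >= polygon.area:
        raise InfeasibleGeometryError(f"target area exceeds {name} area")
    hi = 1.0
    while _offset_area(polygon, hi) > target_area:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover
            raise InfeasibleGeometryError(f"offset search diverged for {name}")
    return brentq(
        lambda t: _offset_area(polygon, t) - target_area, 0.0, hi, xtol=1e-9
    )


def place_chloroplast_layer(
    cell: Polygon,
    share: float = 0.20,
    wall_um: float = 0.5,
    gap_um: float = 0.5,
    name: str = "cell",
) -> tuple[Polygon, Polygon]:
    """Place the chloroplast layer inside a cell polygon.

    The layer is the band between the inward offsets at ``wall_um +
    gap_um`` (its outer edge, 0.5 µm inside the plasmalemma by default) and
    at ``wall_um + gap_um + t``, with the thickness ``t`` solved so the band
    occupies ``share`` of the cell area.  Returns ``(outer, inner)`` offset
    polygons; the chloroplast ring is their difference and ``inner`` bounds
    the inner cytoplasm.  ``share = 0`` returns an empty ring.
    """
    if not 0 <= share < 1:
        raise ValueError("share must lie in [0, 1)")
    outer = offset_inward(cell, wall_um + gap_um, name)
    if share == 0:
        return Polygon(), outer
    inner_area = outer.area - share * cell.area
    if inner_area <= 0:
        raise InfeasibleGeometryError(
            f"{name} too small to host a chloroplast layer of share {share}"
        )
    t = _offset_for_area(cell, inner_area, name)
    inner = offset_inward(cell, t, name)
    return outer, inner


# -- synthetic generation --------------------------------------------------


def _lloyd_voronoi(
    points: np.ndarray,
    rect: tuple[float, float, float, float],
    iters: int,
    pinned: Sequence[int],
) -> list[Polygon]:
    """Voronoi tessellation of a rectangle via mirrored points, with Lloyd
    relaxation (pinned seed indices are not moved)."""
    x0, y0, x1, y1 = rect
    clip = box(x0, y0, x1, y1)
    pts = points.copy()
    for _ in range(iters + 1):
        mirrors = np.vstack(
            [
                pts * [-1, 1] + [2 * x0, 0],
                pts * [-1, 1] + [2 * x1, 0],
                pts * [1, -1] + [0, 2 * y0],
                pts * [1, -1] + [0, 2 * y1],
            ]
        )
        vor = Voronoi(np.vstack([pts, mirrors]))
        polys = []
        for i in range(len(pts)):
            verts = vor.vertices[vor.regions[vor.point_region[i]]]
            polys.append(Polygon(verts).intersection(clip))
        centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])
        centroids[list(pinned)] = pts[list(pinned)]
        pts = centroids
    return polys


def generate_leaf_microstructure(params: GeometryGenParams) -> LeafGeometry:
    """Generate a synthetic leaf cross-section hitting the area targets.

    Deterministic for a fixed seed.  If a particular tessellation cannot
    realise the targets (too many sub-threshold cells after carving the
    lacunae), up to three further deterministic sub-seeded tessellations are
    tried before giving up.
    """
    last: Optional[InfeasibleGeometryError] = None
    for attempt in range(8):
        try:
            return _generate_attempt(params, attempt)
        except InfeasibleGeometryError as exc:
            last = exc
    raise last


def _generate_attempt(params: GeometryGenParams, attempt: int) -> LeafGeometry:
    """One generation attempt with the tessellation stream ``attempt``.

    The mesophyll band is tessellated into Lloyd-relaxed Voronoi cells; two
    pinned seeds inside the vascular-bundle circle guarantee a xylem cell
    facing the adaxial epidermis and a phloem cell below it.  Mesophyll
    cells are eroded apart uniformly until their total area equals
    ``fc·W·d / chloroplast_share`` (so the chloroplast fraction hits
    ``fc``); each cell then receives its wall, chloroplast layer (fixed
    share of the cell area) and vacuole (share derived from ``fm`` unless
    ``vacuole_area_scale`` is set).  Deterministic for a fixed seed.

    Raises :class:`InfeasibleGeometryError` when the targets cannot be
    reached (instead of silently clipping).
    """
    p = params
    rng = np.random.default_rng([p.seed, attempt])
    w, d, te = p.width_um, p.thickness_um, p.epidermis_um
    y0, y1 = te, d - te
    cx = w / 2.0

    # seeds: pinned bundle pair + random mesophyll points
    rb = p.bundle_radius_um
    pinned_pts = np.array([[cx, y0 + 0.35 * rb], [cx, y0 + 1.3 * rb]])
    n_cells = p.n_cells
    if n_cells is None:
        n_cells = int(round(3.0e-3 * w * (y1 - y0)))
    n_free = max(n_cells - 2, 4)
    margin = 3.0
    free = rng.uniform(
        [margin, y0 + margin], [w - margin, y1 - margin], size=(n_free, 2)
    )
    pts = np.vstack([pinned_pts, free])
    polys = _lloyd_voronoi(pts, (0.0, y0, w, y1), p.lloyd_iters, pinned=(0, 1))

    # vascular bundle membership: pinned cells plus any cell whose centroid
    # falls inside the bundle circle
    bundle_center = np.array([cx, y0 + 0.7 * rb])
    vascular_idx = {0, 1}
    for i, poly in enumerate(polys):
        c = np.array([poly.centroid.x, poly.centroid.y])
        if np.linalg.norm(c - bundle_center) < rb:
            vascular_idx.add(i)

    meso_polys = [
        polys[i]
        for i in range(len(polys))
        if i not in vascular_idx and polys[i].area >= p.min_cell_area_um2
    ]
    vasc_polys = [polys[i] for i in sorted(vascular_idx)]

    # erode mesophyll cells until their total area hits the target
    a_target = p.fc * w * d / p.chloroplast_share
    a_avail = sum(q.area for q in meso_polys)
    if a_target > 0.97 * a_avail:
        raise InfeasibleGeometryError(
            f"chloroplast target fc={p.fc} needs {a_target:.0f} µm² of "
            f"mesophyll cells but only {a_avail:.0f} µm² is available"
        )

    # Real mesophyll is compact: neighbouring cells nearly touch along
    # shared faces (narrow gas channels of width ``contact_gap_um``) while
    # the intercellular lacunae sit at the cell corners.  Shrinking each
    # cell with a round join of radius r and re-expanding by r − gap/2
    # rounds the corners off (creating the lacunae) but keeps the flat
    # contact faces at the narrow gap; r is solved for the porosity implied
    # by the area target.
    half_gap = p.contact_gap_um / 2.0

    from shapely.geometry import Point

    # Mesophyll cells touch their neighbours over part of their boundary
    # (the tissue is compact; contacts restrict intercellular diffusion):
    # each shared Voronoi face is a sealed contact with probability
    # ``contact_fraction``, otherwise a gas channel of width
    # ``contact_gap_um``.  Sealed faces are restored as "bridges" after the
    # uniform erosion.
    bridges: list[list[Polygon]] = [[] for _ in meso_polys]
    from shapely.ops import substring

    for i in range(len(meso_polys)):
        for k in range(i + 1, len(meso_polys)):
            shared = meso_polys[i].exterior.intersection(meso_polys[k].exterior)
            if shared.is_empty or shared.length < 4 * half_gap:
                continue
            if rng.random() >= p.contact_fraction:
                continue
            if shared.geom_type == "MultiLineString":
                shared = max(shared.geoms, key=lambda s: s.length)
            if shared.geom_type != "LineString":
                continue
            mid = substring(shared, 0.15, 0.85, normalized=True)
            strip = mid.buffer(half_gap * 1.5, cap_style="flat")
            bridges[i].append(strip.intersection(meso_polys[i]))
            bridges[k].append(strip.intersection(meso_polys[k]))

    def erode_one_src(q: Polygon, br: list[Polygon], rho: float) -> Optional[Polygon]:
        shr = q.buffer(-half_gap, join_style="mitre", mitre_limit=10.0)
        if shr.is_empty:
            return None
        if br:
            shr = shapely.unary_union([shr] + br)
        if rho > 0:
            verts = list(q.exterior.coords)[:-1]
            lacunae = shapely.unary_union(
                [Point(v).buffer(rho, quad_segs=8) for v in verts]
            )
            shr = shr.difference(lacunae)
        if shr.geom_type == "MultiPolygon":
            shr = max(shr.geoms, key=lambda g: g.area)
        if shr.geom_type != "Polygon" or shr.is_empty or shr.area <= 0:
            return None
        return Polygon(shr.exterior, [r for r in shr.interiors])

    def eroded(rho: float) -> list[Optional[Polygon]]:
        return [
            erode_one_src(q, br, rho) for q, br in zip(meso_polys, bridges)
        ]

    def area_at(rho: float) -> float:
        return sum(q.area for q in eroded(rho) if q is not None)

    if area_at(0.0) < a_target:
        raise InfeasibleGeometryError(
            "porosity target unreachable at the requested contact gap"
        )
    rho_hi = 10.0
    while area_at(rho_hi) > a_target:
        rho_hi *= 1.5
        if rho_hi > 100.0:
            raise InfeasibleGeometryError("junction lacunae search diverged")
    # dropping sub-threshold fragments loses area; re-solve with the
    # survivors until the set is stable
    for _ in range(8):
        rho_sol = brentq(lambda r: area_at(r) - a_target, 0.0, rho_hi, xtol=1e-6)
        # later attempts tolerate slightly smaller cells rather than fail
        min_area = p.min_cell_area_um2 * (0.85 ** max(0, attempt - 1))
        small = [q is None or q.area < min_area for q in eroded(rho_sol)]
        if not any(small):
            break
        meso_polys = [q for q, s in zip(meso_polys, small) if not s]
        bridges = [b for b, s in zip(bridges, small) if not s]
        if area_at(0.0) < a_target:
            raise InfeasibleGeometryError("targets infeasible after dropping slivers")
    else:
        raise InfeasibleGeometryError("sliver pruning did not stabilise")
    meso_final = [q for q in eroded(rho_sol) if q is not None]

    cyto_share = p.fm * p.chloroplast_share / p.fc
    cells: list[CellRecord] = []
    cid = 0
    for q in meso_final:
        name = f"mesophyll cell {cid}"
        interior = offset_inward(q, p.wall_um, name)
        chl_outer, chl_inner = place_chloroplast_layer(
            q, p.chloroplast_share, p.wall_um, p.chloroplast_offset_um, name
        )
        wall_area = q.area - interior.area
        if p.vacuole_area_scale is not None:
            vac_area = p.vacuole_area_scale * q.area
        else:
            vac_area = q.area * (1.0 - p.chloroplast_share - cyto_share) - wall_area
        if vac_area <= 0:
            vacuole = None
        else:
            chl_t = _offset_for_area(q, chl_inner.area, name)
            dmin = chl_t + 0.6  # keep an inner-cytoplasm sleeve >= 0.6 µm
            dv = _offset_for_area(q, vac_area, name)
            dv = max(dv, dmin)
            vacuole = offset_inward(q, dv, name)
        cells.append(
            CellRecord(cid, "mesophyll", q, interior, chl_outer, chl_inner, vacuole)
        )
        cid += 1

    for q in vasc_polys:
        name = f"vascular cell {cid}"
        kind = "xylem" if q.bounds[1] <= y0 + 2.0 else "phloem"
        interior = offset_inward(q, p.wall_um, name)
        cells.append(CellRecord(cid, kind, q, interior))
        cid += 1
    kinds = {c.kind for c in cells}
    if "xylem" not in kinds or "phloem" not in kinds:
        raise InfeasibleGeometryError(
            "vascular bundle lacks a xylem or phloem cell; adjust the bundle radius"
        )

    geom = LeafGeometry(
        width_um=w,
        thickness_um=d,
        cells=cells,
        epidermis_polys=[box(0, 0, w, te), box(0, d - te, w, d)],
        provenance={"generator": dataclasses.asdict(p)},
    )
    fr = phase_fractions(geom)
    if abs(fr[PhaseLabel.CHLOROPLAST] - p.fc) > 0.005:
        raise InfeasibleGeometryError(
            f"generated chloroplast fraction {fr[PhaseLabel.CHLOROPLAST]:.4f} "
            f"misses target {p.fc}"
        )
    if p.vacuole_area_scale is None and abs(fr[PhaseLabel.CYTOSOL] - p.fm) > 0.005:
        raise InfeasibleGeometryError(
            f"generated cytosol fraction {fr[PhaseLabel.CYTOSOL]:.4f} "
            f"misses target {p.fm}"
        )
    return geom


# -- depth profile ---------------------------------------------------------


def photosynthetic_capacity_profile(
    geometry: LeafGeometry, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Relative photosynthetic capacity p(y): the fraction of the leaf width
    occupied by chloroplast at each depth, averaged over ``n_bins`` strips.

    p is 0 in the epidermis strips and dips across the vascular bundle,
    which carries no chloroplasts.  Returns (bin centres, p).
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    d, w = geometry.thickness_um, geometry.width_um
    edges = np.linspace(0.0, d, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    p = np.zeros(n_bins)
    if geometry.is_raster_backed:
        labels = geometry.raster_labels
        ny = labels.shape[0]
        ych = (np.arange(ny) + 0.5) * geometry.raster_h_um
        frac = (labels == PhaseLabel.CHLOROPLAST).mean(axis=1)
        idx = np.clip(np.digitize(ych, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = idx == b
            p[b] = frac[sel].mean() if sel.any() else 0.0
        return centres, p
    chl_polys = []
    for c in geometry.mesophyll_cells:
        if c.chl_outer is not None and not c.chl_outer.is_empty:
            ring = c.chl_outer.difference(c.chl_inner) if c.chl_inner else c.chl_outer
            chl_polys.append(ring)
    for lab, poly in geometry.extra_regions:
        if lab == PhaseLabel.CHLOROPLAST:
            chl_polys.append(poly)
    for b in range(n_bins):
        strip = box(0, edges[b], w, edges[b + 1])
        a = sum(poly.intersection(strip).area for poly in chl_polys)
        p[b] = a / strip.area
    return centres, p


# -- meshing ---------------------------------------------------------------


@dataclass
class ComputationalMesh:
    """Cell-centred labelled raster mesh.

    ``labels[j, i]`` is the phase at pixel centre ``((i+0.5)h, (j+0.5)h)``;
    membranes and Henry interfaces live on the faces between pixels of the
    appropriate phase pairs, so no element straddles a membrane by
    construction.  ``inner_cyto`` marks cytoplasm interior to the
    chloroplast layer (needed for the serial resistance analysis).
    """

    labels: np.ndarray
    cell_ids: np.ndarray
    inner_cyto: np.ndarray
    h_um: float
    width_um: float
    thickness_um: float
    geometry: Optional[LeafGeometry] = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_elements(self) -> int:
        return self.labels.size

    @property
    def element_area_um2(self) -> float:
        return self.h_um**2

    @property
    def element_volume_m3(self) -> float:
        """Volume of one element at unit (1 m) out-of-plane depth."""
        return (self.h_um * 1e-6) ** 2

    def y_centres_um(self) -> np.ndarray:
        return (np.arange(self.labels.shape[0]) + 0.5) * self.h_um

    def x_centres_um(self) -> np.ndarray:
        return (np.arange(self.labels.shape[1]) + 0.5) * self.h_um

    def refined(self) -> "ComputationalMesh":
        if self.geometry is None:
            raise GeometryError("cannot refine a mesh without its geometry")
        return mesh(self.geometry, self.h_um / 2.0)


def _paint(
    grid: np.ndarray, value, poly: Polygon, h: float, mask_grid: Optional[np.ndarray] = None
) -> None:
    if poly.is_empty:
        return
    ny, nx = grid.shape
    x0, y0, x1, y1 = poly.bounds
    i0 = max(int(np.floor(x0 / h - 0.5)), 0)
    i1 = min(int(np.ceil(x1 / h + 0.5)), nx - 1)
    j0 = max(int(np.floor(y0 / h - 0.5)), 0)
    j1 = min(int(np.ceil(y1 / h + 0.5)), ny - 1)
    if i1 < i0 or j1 < j0:
        return
    xs = (np.arange(i0, i1 + 1) + 0.5) * h
    ys = (np.arange(j0, j1 + 1) + 0.5) * h
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    sub = grid[j0 : j1 + 1, i0 : i1 + 1]
    sub[inside] = value
    if mask_grid is not None:
        mask_grid[j0 : j1 + 1, i0 : i1 + 1][inside] = True


def mesh(geometry: LeafGeometry, h_um: float) -> ComputationalMesh:
    """Rasterise a geometry to a labelled mesh at pixel pitch ``h_um``.

    Pixel centres sample the polygons; each cell is painted outside-in
    (wall, cytosol, chloroplast, inner cytoplasm, vacuole) so nested layers
    at least one pixel thick stay closed.  Raises for resolutions that
    cannot resolve the cell wall (``h > 2 × wall thickness``).
    """
    if h_um <= 0:
        raise ValueError("mesh resolution must be positive")
    if geometry.is_raster_backed:
        return _mesh_from_raster(geometry, h_um)
    wall = min(
        (g["generator"]["wall_um"] for g in [geometry.provenance] if "generator" in g),
        default=0.5,
    )
    if h_um > 2 * wall:
        raise GeometryError(
            f"h = {h_um} µm cannot resolve cell walls of {wall} µm "
            "(thin features: cell wall)"
        )
    nx = int(round(geometry.width_um / h_um))
    ny = int(round(geometry.thickness_um / h_um))
    labels = np.full((ny, nx), int(PhaseLabel.PORE), dtype=np.int8)
    cell_ids = np.full((ny, nx), -1, dtype=np.int32)
    inner = np.zeros((ny, nx), dtype=bool)
    for lab, poly in geometry.extra_regions:
        _paint(labels, int(lab), poly, h_um)
    yc = (np.arange(ny) + 0.5) * h_um
    te_mask = (yc < _epidermis_thickness(geometry)) | (
        yc > geometry.thickness_um - _epidermis_thickness(geometry)
    )
    if geometry.epidermis_polys:
        labels[te_mask, :] = int(PhaseLabel.EPIDERMIS)
    for c in geometry.cells:
        _paint(labels, int(PhaseLabel.CELL_WALL), c.polygon, h_um)
        _paint(cell_ids, c.cell_id, c.polygon, h_um)
        _paint(labels, int(c.interior_label), c.interior, h_um)
        if c.kind == "mesophyll":
            if c.chl_outer is not None and not c.chl_outer.is_empty:
                _paint(labels, int(PhaseLabel.CHLOROPLAST), c.chl_outer, h_um)
            if c.chl_inner is not None and not c.chl_inner.is_empty:
                _paint(labels, int(PhaseLabel.CYTOSOL), c.chl_inner, h_um)
                _paint(inner, True, c.chl_inner, h_um)
            if c.vacuole is not None and not c.vacuole.is_empty:
                _paint(labels, int(PhaseLabel.VACUOLE), c.vacuole, h_um)
    return ComputationalMesh(
        labels, cell_ids, inner, h_um, geometry.width_um, geometry.thickness_um, geometry
    )


def _epidermis_thickness(geometry: LeafGeometry) -> float:
    if not geometry.epidermis_polys:
        return 0.0
    top = geometry.epidermis_polys[0]
    return top.bounds[3] - top.bounds[1]


def _mesh_from_raster(geometry: LeafGeometry, h_um: float) -> ComputationalMesh:
    """Nearest-neighbour resample of an imported raster to pitch ``h_um``."""
    src = geometry.raster_labels
    hs = geometry.raster_h_um
    nx = int(round(geometry.width_um / h_um))
    ny = int(round(geometry.thickness_um / h_um))
    xi = np.clip(((np.arange(nx) + 0.5) * h_um / hs).astype(int), 0, src.shape[1] - 1)
    yi = np.clip(((np.arange(ny) + 0.5) * h_um / hs).astype(int), 0, src.shape[0] - 1)
    labels = src[np.ix_(yi, xi)].astype(np.int8)
    aqueous = np.isin(labels, [int(l) for l in AQUEOUS_PHASES])
    cell_ids, _ = ndimage.label(aqueous)
    cell_ids = cell_ids.astype(np.int32) - 1
    inner = np.zeros_like(aqueous)
    return ComputationalMesh(
        labels, cell_ids, inner, h_um, geometry.width_um, geometry.thickness_um, geometry
    )


def mesh_from_labels(labels: np.ndarray, h_um: float) -> ComputationalMesh:
    """Wrap a raw label array as a mesh (for hand-built fixture domains)."""
    labels = np.asarray(labels, dtype=np.int8)
    ny, nx = labels.shape
    return ComputationalMesh(
        labels,
        np.full((ny, nx), -1, dtype=np.int32),
        np.zeros((ny, nx), dtype=bool),
        h_um,
        nx * h_um,
        ny * h_um,
    )


def mesophyll_cell_count(geometry: LeafGeometry) -> int:
    """Number of distinct mesophyll cells (connected components containing
    cytosol for raster-backed geometries)."""
    if not geometry.is_raster_backed:
        return len(geometry.mesophyll_cells)
    labels = geometry.raster_labels
    aqueous = np.isin(labels, [int(l) for l in AQUEOUS_PHASES - {PhaseLabel.PHLOEM, PhaseLabel.XYLEM}])
    comp, n = ndimage.label(aqueous)
    count = 0
    for k in range(1, n + 1):
        if np.any(labels[comp == k] == PhaseLabel.CYTOSOL):
            count += 1
    return count


# -- raster / JSON i/o -----------------------------------------------------


def export_labeled_raster(
    geometry: LeafGeometry, path: str | Path, um_per_pixel: float = 0.5
) -> Path:
    """Write an 8-bit labelled raster (PNG) plus a JSON sidecar giving the
    label→code map and the pixel size."""
    import imageio.v3 as iio

    path = Path(path)
    m = geometry if geometry.is_raster_backed else mesh(geometry, um_per_pixel)
    labels = geometry.raster_labels if geometry.is_raster_backed else m.labels
    iio.imwrite(path, labels.astype(np.uint8))
    sidecar = {
        "um_per_pixel": um_per_pixel if not geometry.is_raster_backed else geometry.raster_h_um,
        "width_um": geometry.width_um,
        "thickness_um": geometry.thickness_um,
        "label_codes": {lab.name: int(lab) for lab in PhaseLabel},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def import_labeled_raster(
    path: str | Path, um_per_pixel: Optional[float] = None
) -> LeafGeometry:
    """Read a labelled raster (with optional JSON sidecar) into a
    raster-backed :class:`LeafGeometry`.  Unknown label codes raise."""
    import imageio.v3 as iio

    path = Path(path)
    labels = np.asarray(iio.imread(path))
    if labels.ndim == 3:
        labels = labels[..., 0]
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        um_per_pixel = um_per_pixel or sc["um_per_pixel"]
    if um_per_pixel is None:
        raise GeometryError("µm-per-pixel must be given (no sidecar found)")
    valid = {int(l) for l in PhaseLabel}
    codes = set(np.unique(labels).tolist())
    if not codes <= valid:
        raise GeometryError(f"unknown label codes in raster: {sorted(codes - valid)}")
    ny, nx = labels.shape
    return LeafGeometry(
        width_um=nx * um_per_pixel,
        thickness_um=ny * um_per_pixel,
        provenance={"import_path": str(path)},
        raster_labels=labels.astype(np.int8),
        raster_h_um=float(um_per_pixel),
    )


def _poly_to_coords(poly: Optional[Polygon]):
    if poly is None or poly.is_empty:
        return None
    return [list(xy) for xy in poly.exterior.coords]


def _coords_to_poly(coords):
    return Polygon(coords) if coords else None


def save_geometry_json(geometry: LeafGeometry, path: str | Path) -> Path:
    """Serialise a polygon-backed geometry (labelled polygons + provenance)."""
    if geometry.is_raster_backed:
        raise GeometryError("raster-backed geometries export via export_labeled_raster")
    doc = {
        "width_um": geometry.width_um,
        "thickness_um": geometry.thickness_um,
        "provenance": geometry.provenance,
        "epidermis": [_poly_to_coords(p) for p in geometry.epidermis_polys],
        "extra_regions": [
            {"label": lab.name, "coords": _poly_to_coords(p)}
            for lab, p in geometry.extra_regions
        ],
        "cells": [
            {
                "cell_id": c.cell_id,
                "kind": c.kind,
                "polygon": _poly_to_coords(c.polygon),
                "interior": _poly_to_coords(c.interior),
                "chl_outer": _poly_to_coords(c.chl_outer),
                "chl_inner": _poly_to_coords(c.chl_inner),
                "vacuole": _poly_to_coords(c.vacuole),
            }
            for c in geometry.cells
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_geometry_json(path: str | Path) -> LeafGeometry:
    doc = json.loads(Path(path).read_text())
    cells = [
        CellRecord(
            c["cell_id"],
            c["kind"],
            _coords_to_poly(c["polygon"]),
            _coords_to_poly(c["interior"]),
            _coords_to_poly(c.get("chl_outer")),
            _coords_to_poly(c.get("chl_inner")),
            _coords_to_poly(c.get("vacuole")),
        )
        for c in doc["cells"]
    ]
    return LeafGeometry(
        width_um=doc["width_um"],
        thickness_um=doc["thickness_um"],
        cells=cells,
        epidermis_polys=[_coords_to_poly(p) for p in doc["epidermis"]],
        extra_regions=[
            (PhaseLabel[r["label"]], _coords_to_poly(r["coords"]))
            for r in doc["extra_regions"]
        ],
        provenance=doc.get("provenance", {}),
    )
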