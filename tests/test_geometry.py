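"""Microstructure generation, polygon offsets, morphometrics, meshing and
raster round trips."""

import json

import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon, box

from leafgas import (
    GeometryGenParams,
    LeafGeometry,
    MembraneKind,
    PhaseLabel,
    export_labeled_raster,
    generate_leaf_microstructure,
    import_labeled_raster,
    load_geometry_json,
    mesh,
    offset_inward,
    phase_fractions,
    photosynthetic_capacity_profile,
    place_chloroplast_layer,
    save_geometry_json,
)
from leafgas.geometry import (
    GeometryError,
    InfeasibleGeometryError,
    TopologyError,
    _offset_for_area,
    mesophyll_cell_count,
)

from conftest import TEST_GEOM_KW

P = PhaseLabel
PROTOPLAST = [int(P.CYTOSOL), int(P.CHLOROPLAST), int(P.VACUOLE), int(P.PHLOEM), int(P.XYLEM)]


def halfplane_offset_oracle(poly: Polygon, d: float) -> Polygon:
    """Independent inward offset of a convex polygon: intersect the inward
    half-planes of every edge shifted by ``d`` (polygon clipping, no
    buffering involved)."""
    xy = np.asarray(poly.exterior.coords)
    big = box(*poly.buffer(1.0).bounds)
    out = big
    sign = 1.0 if shapely.is_ccw(poly.exterior) else -1.0
    for a, b in zip(xy[:-1], xy[1:]):
        t = b - a
        n = sign * np.array([t[1], -t[0]])  # outward normal
        n = n / np.linalg.norm(n)
        shift = -n * d
        # half-plane on the inner side of the shifted (extended) edge line
        far = 1e3
        t_hat = t / np.linalg.norm(t)
        p1, p2 = a + shift - t_hat * far, b + shift + t_hat * far
        quad = Polygon([p1, p2, p2 - n * far, p1 - n * far])
        out = out.intersection(quad)
    return out


class TestOffsetInward:
    def test_unit_square(self):
        sq = box(0, 0, 1, 1)
        out = offset_inward(sq, 0.25)
        assert out.area == pytest.approx(0.25, abs=1e-9)
        assert out.bounds == pytest.approx((0.25, 0.25, 0.75, 0.75))

    def test_zero_distance_identity(self):
        sq = box(0, 0, 3, 2)
        assert offset_inward(sq, 0.0).equals(sq)

    def test_hexagon_matches_clipping_oracle(self):
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        hexagon = Polygon(np.c_[10 * np.cos(ang), 10 * np.sin(ang)])
        got = offset_inward(hexagon, 0.5)
        want = halfplane_offset_oracle(hexagon, 0.5)
        assert got.area == pytest.approx(want.area, rel=5e-3)

    def test_annihilation_names_the_cell(self):
        with pytest.raises(InfeasibleGeometryError, match="tiny cell"):
            offset_inward(box(0, 0, 1, 1), 0.6, name="tiny cell")

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_random_convex_polygons_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ang = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(5, 10)))
        if np.max(np.diff(ang, append=ang[0] + 2 * np.pi)) > 2.5:
            return  # nearly-degenerate sliver: inradius too small
        r = rng.uniform(8, 20)
        poly = Polygon(np.c_[r * np.cos(ang), r * np.sin(ang)])
        d = 0.2 * np.sqrt(poly.area / np.pi)
        try:
            got = offset_inward(poly, d)
        except InfeasibleGeometryError:
            return
        want = halfplane_offset_oracle(poly, d)
        assert got.area == pytest.approx(want.area, rel=5e-3)


class TestChloroplastLayer:
    def test_circle_ring_area_share(self):
        cell = Point(0, 0).buffer(20.0, quad_segs=128)
        outer, inner = place_chloroplast_layer(cell, share=0.20)
        ring = outer.area - inner.area
        assert ring == pytest.approx(0.20 * cell.area, rel=0.01)
        # outer edge is 0.5 µm inside the plasmalemma (wall 0.5 + gap 0.5)
        assert outer.area == pytest.approx(np.pi * 19.0**2, rel=0.01)

    def test_zero_share_gives_empty_ring(self):
        cell = Point(0, 0).buffer(15.0, quad_segs=64)
        ring, inner = place_chloroplast_layer(cell, share=0.0)
        assert ring.is_empty
        assert inner.area == pytest.approx(offset_inward(cell, 1.0).area)

    def test_half_share_against_annulus_closed_form(self):
        r = 20.0
        cell = Point(0, 0).buffer(r, quad_segs=256)
        outer, inner = place_chloroplast_layer(cell, share=0.5)
        # closed form: pi(r_o^2 - r_i^2) = 0.5 pi r^2 with r_o = r - 1
        r_i = np.sqrt((r - 1.0) ** 2 - 0.5 * r**2)
        assert np.sqrt(inner.area / np.pi) == pytest.approx(r_i, rel=5e-3)

    def test_too_small_cell_raises(self):
        with pytest.raises(InfeasibleGeometryError):
            place_chloroplast_layer(Point(0, 0).buffer(1.2), share=0.2)


class TestVacuoleScaling:
    def test_sixty_percent_area_is_46_percent_spherical_volume(self):
        cell = Point(0, 0).buffer(20.0, quad_segs=256)
        d = _offset_for_area(cell, 0.60 * cell.area, "cell")
        vac = offset_inward(cell, d)
        assert vac.area / cell.area == pytest.approx(0.60, rel=1e-6)
        # similar circles: volume ratio = (area ratio)^(3/2)
        assert (vac.area / cell.area) ** 1.5 == pytest.approx(0.46, abs=0.01)


class TestPhaseFractions:
    def test_two_equal_rectangles(self):
        g = LeafGeometry(
            width_um=10.0,
            thickness_um=10.0,
            extra_regions=[(P.CYTOSOL, box(0, 5, 10, 10))],
        )
        fr = phase_fractions(g)
        assert fr[P.PORE] == pytest.approx(0.5)
        assert fr[P.CYTOSOL] == pytest.approx(0.5)

    def test_fractions_sum_to_one_and_hit_targets(self, small_geometry):
        fr = phase_fractions(small_geometry)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
        assert fr[P.CHLOROPLAST] == pytest.approx(0.104, abs=0.005)
        assert fr[P.CYTOSOL] == pytest.approx(0.169, abs=0.005)

    def test_scale_invariance(self):
        r1 = box(0, 2, 4, 6)
        g1 = LeafGeometry(8.0, 8.0, extra_regions=[(P.CELL_WALL, r1)])
        g2 = LeafGeometry(
            16.0, 16.0, extra_regions=[(P.CELL_WALL, shapely.affinity.scale(r1, 2, 2, origin=(0, 0)))]
        )
        assert phase_fractions(g1) == phase_fractions(g2)

    def test_overlapping_regions_raise(self):
        g = LeafGeometry(
            10.0,
            10.0,
            extra_regions=[(P.CYTOSOL, box(0, 0, 6, 10)), (P.CELL_WALL, box(4, 0, 10, 10))],
        )
        with pytest.raises(TopologyError):
            phase_fractions(g)


class TestGenerator:
    def test_deterministic_for_fixed_seed(self):
        p = GeometryGenParams(seed=3, **TEST_GEOM_KW)
        g1, g2 = generate_leaf_microstructure(p), generate_leaf_microstructure(p)
        c1 = [list(c.polygon.exterior.coords) for c in g1.cells]
        c2 = [list(c.polygon.exterior.coords) for c in g2.cells]
        assert json.dumps(c1) == json.dumps(c2)

    def test_chloroplast_share_per_cell(self, small_geometry):
        shares = [c.chloroplast_area / c.area for c in small_geometry.mesophyll_cells]
        assert np.mean(shares) == pytest.approx(0.20, abs=0.01)

    def test_target_hit_rate_over_50_seeds(self):
        hits = 0
        for seed in range(50):
            try:
                g = generate_leaf_microstructure(
                    GeometryGenParams(seed=seed, **TEST_GEOM_KW)
                )
            except InfeasibleGeometryError:
                continue
            fr = phase_fractions(g)
            if (
                abs(fr[P.CHLOROPLAST] - 0.104) <= 0.005
                and abs(fr[P.CYTOSOL] - 0.169) <= 0.005
            ):
                hits += 1
        assert hits >= 48  # >= 95 % of 50

    def test_infeasible_targets_raise_explicitly(self):
        with pytest.raises(InfeasibleGeometryError):
            generate_leaf_microstructure(
                GeometryGenParams(seed=0, fc=0.40, fm=0.169, **TEST_GEOM_KW)
            )

    def test_explicit_vacuole_scale_is_respected(self):
        g = generate_leaf_microstructure(
            GeometryGenParams(seed=0, vacuole_area_scale=0.30, **TEST_GEOM_KW)
        )
        scales = [c.vacuole_area / c.area for c in g.mesophyll_cells if c.vacuole]
        assert np.median(scales) == pytest.approx(0.30, abs=0.02)

    def test_xylem_faces_adaxial_epidermis(self, small_geometry):
        te = 20.0
        xylem = [c for c in small_geometry.cells if c.kind == "xylem"]
        phloem = [c for c in small_geometry.cells if c.kind == "phloem"]
        assert xylem and phloem
        assert min(c.polygon.bounds[1] for c in xylem) <= te + 2.0

    def test_membrane_inventory(self, small_geometry):
        kinds = {m.kind for m in small_geometry.membranes}
        assert kinds == {
            MembraneKind.PLASMALEMMA,
            MembraneKind.CHLOROPLAST_ENVELOPE,
            MembraneKind.TONOPLAST,
        }
        assert all(
            m.multiplier == (0.5 if m.kind == MembraneKind.CHLOROPLAST_ENVELOPE else 1.0)
            for m in small_geometry.membranes
        )


class TestCapacityProfile:
    def test_zero_in_epidermis_and_dip_over_bundle(self, small_geometry):
        y, p = photosynthetic_capacity_profile(small_geometry, 92)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(p[y < 20.0] == 0)
        assert np.all(p[y > small_geometry.thickness_um - 20.0] == 0)
        # the vascular bundle (no chloroplasts) depresses p at its depths
        vasc = [c for c in small_geometry.cells if c.kind in ("phloem", "xylem")]
        y0 = min(c.polygon.bounds[1] for c in vasc)
        y1 = max(c.polygon.bounds[3] for c in vasc)
        bundle = p[(y >= y0) & (y <= y1)]
        meso = p[(y > y1) & (y < small_geometry.thickness_um - 20.0)]
        assert bundle.mean() < meso.mean()

    def test_constructed_half_width_strip(self):
        g = LeafGeometry(
            width_um=10.0,
            thickness_um=10.0,
            extra_regions=[(P.CHLOROPLAST, box(0, 4, 5, 6))],
        )
        y, p = photosynthetic_capacity_profile(g, 5)
        assert p[2] == pytest.approx(0.5)
        assert p[0] == 0.0

    def test_profile_integral_matches_pixel_count_oracle(self, small_geometry):
        y, p = photosynthetic_capacity_profile(small_geometry, 184)
        m = mesh(small_geometry, 0.5)
        pix = (m.labels == int(P.CHLOROPLAST)).mean()
        assert np.trapezoid(p, y) / small_geometry.thickness_um == pytest.approx(
            pix, abs=0.004
        )


class TestMesh:
    def test_area_conservation_under_refinement(self, small_geometry):
        m1 = mesh(small_geometry, 0.5)
        a1 = m1.n_elements * m1.element_area_um2
        assert a1 == pytest.approx(small_geometry.domain_area, rel=1e-3)

    def test_no_element_straddles_a_membrane(self, small_mesh):
        # a protoplast pixel face-adjacent to gas would mean the wall ring
        # (and hence the plasmalemma) is unresolved somewhere
        L = small_mesh.labels
        for a, b in (
            (L[1:, :], L[:-1, :]),
            (L[:, 1:], L[:, :-1]),
        ):
            bad = (np.isin(a, [0, 1]) & np.isin(b, PROTOPLAST)) | (
                np.isin(b, [0, 1]) & np.isin(a, PROTOPLAST)
            )
            assert bad.sum() == 0

    def test_plasmalemma_closed_around_each_cell(self, small_geometry, small_mesh):
        # each mesophyll cell's wall pixels form a closed ring: filling the
        # ring's holes must cover the cell's entire interior
        from scipy import ndimage

        for c in small_geometry.mesophyll_cells:
            mine = small_mesh.cell_ids == c.cell_id
            wall = mine & (small_mesh.labels == int(P.CELL_WALL))
            interior = mine & np.isin(small_mesh.labels, PROTOPLAST)
            assert interior.any() and wall.any()
            assert np.all(ndimage.binary_fill_holes(wall)[interior])

    def test_unresolvable_resolution_raises(self, small_geometry):
        with pytest.raises(GeometryError, match="cell wall"):
            mesh(small_geometry, 1.5)


class TestRasterIO(object):
    def test_round_trip_preserves_labels_and_fractions(self, small_geometry, tmp_path):
        path = tmp_path / "leaf.png"
        export_labeled_raster(small_geometry, path, um_per_pixel=0.5)
        imported = import_labeled_raster(path)
        m = mesh(small_geometry, 0.5)
        assert np.array_equal(imported.raster_labels, m.labels)
        fr_poly = phase_fractions(small_geometry)
        fr_rast = phase_fractions(imported)
        for lab in PhaseLabel:
            assert fr_rast[lab] == pytest.approx(fr_poly[lab], abs=0.01)

    def test_all_pore_raster(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "pore.png"
        iio.imwrite(path, np.zeros((10, 10), dtype=np.uint8))
        g = import_labeled_raster(path, um_per_pixel=1.0)
        assert phase_fractions(g)[P.PORE] == 1.0

    def test_unknown_codes_rejected(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "bad.png"
        iio.imwrite(path, np.full((4, 4), 99, dtype=np.uint8))
        with pytest.raises(GeometryError, match="unknown label"):
            import_labeled_raster(path, um_per_pixel=1.0)

    def test_single_cell_blob_detected(self, tmp_path):
        import imageio.v3 as iio

        lab = np.zeros((20, 20), dtype=np.uint8)
        lab[5:15, 5:15] = int(P.CELL_WALL)
        lab[7:13, 7:13] = int(P.CYTOSOL)
        path = tmp_path / "cell.png"
        iio.imwrite(path, lab)
        g = import_labeled_raster(path, um_per_pixel=0.5)
        assert mesophyll_cell_count(g) == 1

    def test_geometry_json_round_trip(self, small_geometry, tmp_path):
        path = tmp_path / "geom.json"
        save_geometry_json(small_geometry, path)
        back = load_geometry_json(path)
        fr1, fr2 = phase_fractions(small_geometry), phase_fractions(back)
        for lab in PhaseLabel:
            assert fr2[lab] == pytest.approx(fr1[lab], abs=1e-9)
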