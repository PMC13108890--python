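"""Synthetic-geometry unit and property tests."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ehtsim.geometry import (
    EHTSpec,
    InfarctSpec,
    LayerThresholds,
    assign_layers,
    attach_eht,
    build_sheet,
    default_boundary_sets,
    excise_scar,
    generate_fibers,
    label_infarct,
    select_pacing_sites,
    solve_layer_coordinates,
    TissueModel,
)


class TestBuildSheet:
    @pytest.mark.parametrize(
        "extent,res,n_nodes,n_elems",
        [
            ((10, 10), 1.0, 121, 200),
            ((2, 2, 1), 1.0, 18, 24),  # 3*3*2 nodes, 4 cubes x 6 tets
        ],
    )
    def test_structured_counts(self, extent, res, n_nodes, n_elems):
        m = build_sheet(extent, res)
        assert m.n_nodes == n_nodes
        assert len(m.elements) == n_elems
        assert (m.region == "HZ").all()

    def test_noninteger_spacing_matches_index_enumeration(self):
        # independent oracle: enumerate grid indices per axis
        m = build_sheet((40, 40), 0.3)
        n_axis = int(np.ceil(40 / 0.3 - 1e-9)) + 1
        assert m.n_nodes == n_axis**2

    def test_rejects_nonpositive_resolution(self):
        with pytest.raises(ValueError, match="resolution"):
            build_sheet((10, 10), 0.0)

    def test_default_fibers_unit_norm(self):
        m = build_sheet((5, 5), 1.0)
        assert np.allclose(np.linalg.norm(m.fiber, axis=1), 1.0, atol=1e-9)

    def test_mesh_measure_covers_domain(self):
        from ehtsim.geometry import _element_measure

        m = build_sheet((7, 3), 0.5)
        assert np.isclose(_element_measure(m.nodes, m.elements).sum(), 21.0)
        s = build_sheet((2, 2, 1), 0.5)
        assert np.isclose(_element_measure(s.nodes, s.elements).sum(), 4.0)


class TestLayerCoordinates:
    def test_slab_harmonic_field_is_linear(self):
        m = build_sheet((10, 4), 0.5)
        m = solve_layer_coordinates(m)
        # transmural across y: node at mid-depth must sit at 0.5
        mid = np.abs(m.nodes[:, 1] - 2.0) < 1e-9
        assert np.allclose(m.transmural_coord[mid], 0.5, atol=1e-6)
        assert np.allclose(m.transmural_coord, m.nodes[:, 1] / 4.0, atol=1e-6)

    def test_maximum_principle(self):
        m = solve_layer_coordinates(build_sheet((6, 3), 0.5))
        for c in (m.transmural_coord, m.apicobasal_coord):
            assert c.min() >= -1e-12 and c.max() <= 1 + 1e-12

    def test_l_shaped_domain_matches_dense_solve(self):
        # carve an L from a square, solve with the sparse path and compare
        # against an independent dense direct solve of the same system
        m = build_sheet((4, 4), 0.5)
        keep = ~((m.nodes[:, 0] > 2.0 + 1e-9) & (m.nodes[:, 1] > 2.0 + 1e-9))
        idx = np.nonzero(keep)[0]
        remap = -np.ones(m.n_nodes, dtype=int)
        remap[idx] = np.arange(idx.size)
        el_keep = keep[m.elements].all(axis=1)
        lm = TissueModel(
            nodes=m.nodes[idx],
            elements=remap[m.elements[el_keep]],
            region=m.region[idx],
        )
        bs = default_boundary_sets(lm)
        sol = solve_layer_coordinates(lm, {"transmural": bs["transmural"]})

        from ehtsim.monodomain import simplex_stiffness

        K = simplex_stiffness(
            lm.nodes, lm.elements, np.tile(np.eye(2), (len(lm.elements), 1, 1))
        ).toarray()
        zero, one = bs["transmural"]
        fixed = np.zeros(lm.n_nodes, dtype=bool)
        fixed[zero] = fixed[one] = True
        g = np.zeros(lm.n_nodes)
        g[one] = 1.0
        free = ~fixed
        dense = np.zeros(lm.n_nodes)
        dense[fixed] = g[fixed]
        dense[free] = np.linalg.solve(K[np.ix_(free, free)], -K[np.ix_(free, fixed)] @ g[fixed])
        assert np.allclose(sol.transmural_coord, dense, atol=1e-8)

    def test_rejects_overlapping_boundaries(self):
        m = build_sheet((4, 2), 1.0)
        bs = default_boundary_sets(m)
        endo, _ = bs["transmural"]
        with pytest.raises(ValueError, match="overlap"):
            solve_layer_coordinates(m, {"transmural": (endo, endo)})


class TestAssignLayers:
    def test_default_transmural_proportions_on_slab(self):
        m = assign_layers(solve_layer_coordinates(build_sheet((4, 20), 0.5)))
        y = m.nodes[:, 1]
        frac_endo = (m.transmural_layer == "ENDO").mean()
        # 40% of thickness, within one grid layer of 21
        assert abs(frac_endo - 0.40) <= 1.0 / 41 + 1e-9
        frac_epi = (m.transmural_layer == "EPI").mean()
        assert abs(frac_epi - 0.25) <= 1.0 / 41 + 1e-9

    def test_apicobasal_proportions_on_slab(self):
        m = assign_layers(solve_layer_coordinates(build_sheet((25, 4), 0.5)))
        frac_base = (m.apicobasal_layer == "BASE").mean()
        assert abs(frac_base - 0.48) <= 1.0 / 51 + 1e-9
        frac_apex = (m.apicobasal_layer == "APEX").mean()
        assert abs(frac_apex - 0.17) <= 1.0 / 51 + 1e-9

    def test_degenerate_proportions_single_label(self):
        m = solve_layer_coordinates(build_sheet((4, 4), 1.0))
        m = assign_layers(m, LayerThresholds(transmural=(100, 0, 0), apicobasal=(48, 35, 17)))
        assert set(m.transmural_layer[m.transmural_coord < 1.0]) == {"ENDO"}

    def test_requires_coordinates(self):
        with pytest.raises(ValueError, match="coordinates"):
            assign_layers(build_sheet((4, 4), 1.0))

    def test_proportions_must_sum_to_100(self):
        with pytest.raises(ValueError, match="sum"):
            LayerThresholds(transmural=(50, 30, 10))


class TestLabelInfarct:
    def test_zero_bz_width_gives_no_border_zone(self):
        m = build_sheet((40, 40), 1.0)
        m = label_infarct(m, InfarctSpec(center=(20, 20), sz_radius=5, bz_width=0))
        assert (m.region == "BZ").sum() == 0
        assert (m.region == "SZ").sum() > 0

    def test_annulus_area_fraction_matches_analytic(self):
        m = build_sheet((40, 40), 0.25)
        m = label_infarct(m, InfarctSpec(center=(20, 20), sz_radius=5, bz_width=3))
        frac_bz = (m.region == "BZ").mean()
        expected = np.pi * (8**2 - 5**2) / 1600
        assert abs(frac_bz - expected) < 0.01

    def test_fractional_depth_limits_scar_to_epicardial_half(self):
        m = solve_layer_coordinates(build_sheet((20, 4), 0.5))
        m = label_infarct(
            m, InfarctSpec(center=(10, 2), sz_radius=30, bz_width=0, transmural_depth=0.5)
        )
        sz = m.region == "SZ"
        assert sz.any()
        assert (m.transmural_coord[sz] >= 0.5 - 1e-9).all()
        assert not sz[m.transmural_coord < 0.5 - 1e-9].any()

    def test_outside_domain_warns_and_keeps_labels(self):
        m = build_sheet((10, 10), 1.0)
        with pytest.warns(UserWarning, match="outside"):
            out = label_infarct(m, InfarctSpec(center=(100, 100), sz_radius=2, bz_width=1))
        assert (out.region == "HZ").all()


class TestExciseScar:
    def _three_region_triangle(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        elements = np.array([[0, 1, 2]])
        region = np.array(["SZ", "BZ", "HZ"], dtype="<U8")
        return TissueModel(nodes=nodes, elements=elements, region=region)

    def test_all_scar_triangle_removed_and_nodes_excised(self):
        m = self._three_region_triangle()
        m.region[:] = "SZ"
        out = excise_scar(m)
        assert len(out.elements) == 0
        assert (out.region == "EXCISED").all()

    def test_mixed_triangle_retags_scar_node_to_bz(self):
        # tie between BZ and HZ in the element: BZ wins by the stated rule
        out = excise_scar(self._three_region_triangle())
        assert len(out.elements) == 1
        assert out.region[0] == "BZ"

    def test_identity_without_scar(self):
        m = build_sheet((5, 5), 1.0)
        out = excise_scar(m)
        assert np.array_equal(out.elements, m.elements)
        assert np.array_equal(out.region, m.region)

    def test_idempotent(self):
        m = build_sheet((20, 20), 1.0)
        m = label_infarct(m, InfarctSpec(center=(10, 10), sz_radius=4, bz_width=2))
        once = excise_scar(m)
        twice = excise_scar(once)
        assert np.array_equal(once.elements, twice.elements)
        assert np.array_equal(once.region, twice.region)

    def test_transmural_scar_disconnects_interior_island(self):
        # a scar annulus isolates its interior: no conductive path crosses
        m = build_sheet((30, 30), 1.0)
        xy = m.nodes
        d = np.linalg.norm(xy - [15, 15], axis=1)
        m.region[(d >= 5) & (d <= 9)] = "SZ"
        out = excise_scar(m)
        n = out.n_nodes
        rows, cols = [], []
        for el in out.elements:
            for a in range(3):
                for b in range(a + 1, 3):
                    rows += [el[a], el[b]]
                    cols += [el[b], el[a]]
        adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        ncomp, labels = sp.csgraph.connected_components(adj.tocsr(), directed=False)
        inner = np.nonzero(d < 4)[0]
        outer = np.nonzero(d > 10)[0]
        assert labels[inner[0]] != labels[outer[0]]
        assert (labels[inner] == labels[inner[0]]).all()


class TestAttachEHT:
    def _infarcted(self, res=1.0):
        m = build_sheet((60, 60), res)
        m = label_infarct(m, InfarctSpec(center=(30, 30), sz_radius=8, bz_width=3))
        return excise_scar(m)

    def test_l1_centers_footprint_on_infarct(self):
        m = self._infarcted()
        out = attach_eht(m, EHTSpec(footprint=(20, 20)))
        eht = out.region == "EHT"
        centroid = out.nodes[eht][:, :2].mean(axis=0)
        assert np.linalg.norm(centroid - [30, 30]) < 1.0

    def test_l2_half_overlap_geometry(self):
        # footprint shifted by half its side across a straight scar edge
        # at x = 50 (signed-distance infarct): exactly half the graft
        # nodes overlie the infarct
        m = build_sheet((80, 80), 0.5)
        m = label_infarct(
            m,
            InfarctSpec(
                center=(40, 40),
                sz_radius=30,
                bz_width=0,
                signed_distance=lambda xy: xy[:, 0] - 50.0,
            ),
        )
        out = attach_eht(m, EHTSpec(footprint=(20, 20), location="L2"), center=(40, 40))
        first = out.meta["eht"]["first_node"]
        host = out.eht_host[first:]
        over_infarct = np.isin(m.region[host], ("SZ", "BZ")).mean()
        assert abs(over_infarct - 0.5) < 0.06

    def test_c10_conductivity_value(self):
        from ehtsim.monodomain import ConductivityField

        m = self._infarcted()
        out = attach_eht(m, EHTSpec(footprint=(20, 20), conductivity_fraction=0.10))
        cond = ConductivityField.from_model(out, eht_fraction=0.10)
        eht_el = (out.region[out.elements] == "EHT").all(axis=1)
        assert eht_el.any()
        assert np.allclose(cond.d_long[eht_el], 0.00013)
        assert np.allclose(cond.rho[eht_el], 1.0)  # isotropic graft

    def test_graft_is_purely_additive(self):
        from ehtsim.monodomain import assemble_operator

        m = self._infarcted()
        out = attach_eht(m, EHTSpec(footprint=(20, 20)))
        n_host = m.n_nodes
        K_host = assemble_operator(m).K
        K_coupled = assemble_operator(out).K
        # off-diagonal host-host couplings are untouched by the graft
        sub = K_coupled[:n_host, :n_host] - sp.diags(K_coupled.diagonal()[:n_host])
        ref = K_host - sp.diags(K_host.diagonal())
        assert abs(sub - ref).max() < 1e-12

    def test_footprint_clipped_with_warning(self):
        m = self._infarcted()
        with pytest.warns(UserWarning, match="clipped"):
            attach_eht(m, EHTSpec(footprint=(200, 200)))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            EHTSpec(conductivity_fraction=0.0)
        with pytest.raises(ValueError):
            EHTSpec(embed_depth=1.5, thickness=1.0)


class TestFibers:
    def test_constant_rule_all_equal(self):
        m = generate_fibers(build_sheet((5, 5), 1.0), "constant", direction=(0, 1))
        assert np.allclose(m.fiber, [0.0, 1.0])

    def test_rotating_rule_midwall_angle_zero(self):
        m = solve_layer_coordinates(build_sheet((10, 10), 0.5))
        m = generate_fibers(m, "rotating", angle_endo=-60, angle_epi=60)
        t_el = m.transmural_coord[m.elements].mean(axis=1)
        mid = np.abs(t_el - 0.5) < 0.03
        ang = np.rad2deg(np.arctan2(m.fiber[mid, 1], m.fiber[mid, 0]))
        assert np.abs(ang).max() < 8.0
        assert np.allclose(np.linalg.norm(m.fiber, axis=1), 1.0, atol=1e-9)


class TestPacingSites:
    def _model(self):
        m = build_sheet((60, 60), 1.0)
        m = label_infarct(m, InfarctSpec(center=(30, 30), sz_radius=8, bz_width=3))
        return excise_scar(m)

    def test_single_site_nonempty_viable(self):
        sites = select_pacing_sites(self._model(), 1)
        assert len(sites) == 1 and len(sites[0]) > 0

    def test_members_within_radius_of_seed(self):
        m = self._model()
        sites = select_pacing_sites(m, 3, radius=1.5)
        for s in sites:
            c = m.nodes[s][:, :2]
            anchor = c.mean(axis=0)
            assert np.linalg.norm(c - anchor, axis=1).max() <= 3.0

    def test_five_sites_equal_angular_spacing(self):
        m = self._model()
        sites = select_pacing_sites(m, 5)
        seeds = np.array([m.nodes[s][:, :2].mean(axis=0) for s in sites])
        ang = np.unwrap(np.sort(np.arctan2(seeds[:, 1] - 30, seeds[:, 0] - 30)))
        gaps = np.rad2deg(np.diff(ang))
        assert np.allclose(gaps, 72.0, atol=12.0)
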