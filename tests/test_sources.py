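import dataclasses

import numpy as np
import pytest

from osteotherm import acoustics as ac
from osteotherm import sources as src
from osteotherm.geometry import (FacetSet, GeometryParams, Tissue,
                                 build_tissue_map, inner_cortical_facet)


class TestDirectAbsorption:
    def test_zero_intensity_zero_source(self, tmap_1mm, medium, source_params):
        i = ac.IntensityField(np.zeros(tmap_1mm.shape), tmap_1mm.spacing_mm,
                              tmap_1mm.origin_mm)
        q = src.direct_absorption_source(i, tmap_1mm, source_params, medium, 1e6)
        assert np.all(q.q_w_m3 == 0)

    def test_unit_conversion_oracle(self, tmap_1mm, medium):
        # uniform I = 1e4 W/m^2, beta = 5.756 Np/m (0.5 dB/cm at 1 MHz)
        # -> q = 2 beta I = 1.151e5 W/m^3 in soft tissue
        params = src.SourceParams(tissue_absorption_np_m=5.756)
        i = ac.IntensityField(np.full(tmap_1mm.shape, 1.0e4),
                              tmap_1mm.spacing_mm, tmap_1mm.origin_mm)
        q = src.direct_absorption_source(i, tmap_1mm, params, medium, 1e6)
        gel = tmap_1mm.labels == int(Tissue.GEL)
        assert np.allclose(q.q_w_m3[gel], 2 * 5.756 * 1.0e4)
        assert q.q_w_m3[gel][0] == pytest.approx(1.151e5, rel=1e-3)

    def test_zero_in_bone(self, intensity_1mm, tmap_1mm, medium, source_params):
        q = src.direct_absorption_source(intensity_1mm, tmap_1mm, source_params,
                                         medium, 1e6)
        cort = tmap_1mm.labels == int(Tissue.CORTICAL)
        assert np.all(q.q_w_m3[cort] == 0)

    def test_max_at_focal_voxel(self, intensity_1mm, tmap_1mm, medium,
                                source_params):
        q = src.direct_absorption_source(intensity_1mm, tmap_1mm, source_params,
                                         medium, 1e6)
        idx = np.unravel_index(np.argmax(q.q_w_m3), q.q_w_m3.shape)
        soft_i = np.where(np.isin(tmap_1mm.labels, (1, 2, 4)),
                          intensity_1mm.data, 0.0)
        assert idx == np.unravel_index(np.argmax(soft_i), soft_i.shape)

    def test_default_beta_uses_absorbed_fraction(self, medium):
        p = src.SourceParams()
        expected = (p.absorption_fraction_of_attenuation
                    * ac.attenuation_np_per_m(medium, 1e6))
        assert p.beta_np_m(medium, 1e6) == pytest.approx(expected)


class TestOvenEffect:
    def test_power_bookkeeping_vs_direct_summation(self, intensity_1mm,
                                                   facet_1mm, tmap_1mm,
                                                   source_params):
        q = src.oven_effect_source(intensity_1mm, facet_1mm, source_params,
                                   tmap=tmap_1mm)
        # independent oracle: explicit loop over facet voxels
        p_inc = 0.0
        for (i, j, k), a in zip(facet_1mm.indices, facet_1mm.areas_mm2):
            p_inc += intensity_1mm.data[i, j, k] * a * 1e-6
        expected = source_params.cortical_absorption_fraction * p_inc
        assert q.total_power_w() == pytest.approx(expected, rel=5e-3)

    def test_uniform_deposition(self, intensity_1mm, facet_1mm, tmap_1mm,
                                source_params):
        q = src.oven_effect_source(intensity_1mm, facet_1mm, source_params,
                                   tmap=tmap_1mm)
        nz = q.q_w_m3[q.q_w_m3 > 0]
        assert nz.size > 0
        assert np.allclose(nz, nz[0])

    def test_deposit_only_in_cortical(self, intensity_1mm, facet_1mm, tmap_1mm,
                                      source_params):
        q = src.oven_effect_source(intensity_1mm, facet_1mm, source_params,
                                   tmap=tmap_1mm)
        outside_cortex = tmap_1mm.labels != int(Tissue.CORTICAL)
        assert np.all(q.q_w_m3[outside_cortex] == 0)

    def test_alpha_zero_gives_zero_source(self, intensity_1mm, facet_1mm,
                                          tmap_1mm):
        params = src.SourceParams(cortical_absorption_fraction=0.0)
        q = src.oven_effect_source(intensity_1mm, facet_1mm, params,
                                   tmap=tmap_1mm)
        assert np.all(q.q_w_m3 == 0)

    def test_empty_facet_warns_zero(self, intensity_1mm, source_params):
        empty = FacetSet(indices=np.empty((0, 3), dtype=int),
                         areas_mm2=np.empty(0), spacing_mm=1.0)
        with pytest.warns(UserWarning, match="empty"):
            q = src.oven_effect_source(intensity_1mm, empty, source_params)
        assert np.all(q.q_w_m3 == 0)

    def test_averaging_is_fixed_point(self, facet_1mm, tmap_1mm, intensity_1mm,
                                      source_params):
        # an intensity pattern already uniform on the facet yields the
        # same source as its facet-averaged version
        params = dataclasses.replace(source_params, redistribution="facet",
                                     deposition_depth_mm=1.0)
        uniform = ac.IntensityField(np.full(tmap_1mm.shape, 2.0e4),
                                    tmap_1mm.spacing_mm, tmap_1mm.origin_mm)
        q = src.oven_effect_source(uniform, facet_1mm, params, tmap=tmap_1mm)
        nz = q.q_w_m3[q.q_w_m3 > 0]
        mask = facet_1mm.mask(tmap_1mm.shape)
        assert np.count_nonzero(q.q_w_m3) == np.count_nonzero(mask)
        assert np.allclose(nz, nz[0])

    def test_rotation_invariance_full_ring(self, medium, source_params):
        """A full (uninterrupted) ring facet makes the oven source invariant
        under rotation of the intensity pattern about the bone axis."""
        geom = GeometryParams(cone_aperture_deg=1e-3, grid_spacing_mm=1.0,
                              domain_extent_mm=(20.0, 20.0, 20.0))
        tmap = build_tissue_map(geom)
        # full uninterrupted ring: every cortical voxel adjacent to the
        # cavity (built directly so the degenerate cone cannot bias it)
        from osteotherm.geometry import Tissue, _cavity_adjacency
        X, Y, Z = tmap.coordinate_grids()
        rho = np.broadcast_to(np.sqrt(Y**2 + Z**2), tmap.shape)
        gel = tmap.labels == int(Tissue.GEL)
        labels = tmap.labels.copy()
        labels[gel & (rho > geom.cavity_radius_mm)] = int(Tissue.CORTICAL)
        labels[gel & (rho <= geom.cavity_radius_mm)] = int(Tissue.MEDULLA)
        tmap.labels = labels
        n_faces = _cavity_adjacency(labels)
        ring = (labels == int(Tissue.CORTICAL)) & (n_faces > 0)
        idx = np.argwhere(ring)
        facet = FacetSet(indices=idx,
                         areas_mm2=n_faces[ring].astype(float)
                         * tmap.spacing_mm**2,
                         spacing_mm=tmap.spacing_mm)
        assert len(facet) > 0
        rng = np.random.default_rng(5)
        pattern = rng.random(tmap.shape)
        i1 = ac.IntensityField(pattern, tmap.spacing_mm, tmap.origin_mm)
        # rotate by 180 deg about the bone (x) axis: (y, z) -> (-y, -z)
        i2 = ac.IntensityField(pattern[:, ::-1, ::-1], tmap.spacing_mm,
                               tmap.origin_mm)
        q1 = src.oven_effect_source(i1, facet, source_params, tmap=tmap)
        q2 = src.oven_effect_source(i2, facet, source_params, tmap=tmap)
        assert q1.total_power_w() == pytest.approx(q2.total_power_w(), rel=1e-9)
        assert np.allclose(q1.q_w_m3, q2.q_w_m3)


class TestCombineAndBookkeeping:
    def test_identity(self, intensity_1mm, tmap_1mm, medium, source_params):
        q = src.direct_absorption_source(intensity_1mm, tmap_1mm, source_params,
                                         medium, 1e6)
        zero = src.HeatSourceMap(np.zeros_like(q.q_w_m3), q.spacing_mm,
                                 q.origin_mm)
        combined = src.combine_sources(q, zero)
        assert np.array_equal(combined.q_w_m3, q.q_w_m3)

    def test_linearity_of_totals(self, intensity_1mm, facet_1mm, tmap_1mm,
                                 medium, source_params):
        qa = src.direct_absorption_source(intensity_1mm, tmap_1mm,
                                          source_params, medium, 1e6)
        qb = src.oven_effect_source(intensity_1mm, facet_1mm, source_params,
                                    tmap=tmap_1mm)
        c = src.combine_sources(qa, qb)
        assert c.total_power_w() == pytest.approx(
            qa.total_power_w() + qb.total_power_w(), rel=1e-12)
        assert c.provenance == {"cortical", "tumoral"}

    def test_grid_mismatch_raises(self, intensity_1mm):
        a = src.HeatSourceMap(np.zeros((3, 3, 3)), 1.0, np.zeros(3))
        b = src.HeatSourceMap(np.zeros((4, 4, 4)), 1.0, np.zeros(3))
        with pytest.raises(ValueError, match="mismatched"):
            src.combine_sources(a, b)

    def test_cumulated_source_has_focal_max_and_cortical_ring(
            self, intensity_1mm, facet_1mm, tmap_1mm, medium, source_params):
        qa = src.direct_absorption_source(intensity_1mm, tmap_1mm,
                                          source_params, medium, 1e6)
        qb = src.oven_effect_source(intensity_1mm, facet_1mm, source_params,
                                    tmap=tmap_1mm)
        c = src.combine_sources(qa, qb)
        soft = np.isin(tmap_1mm.labels, (1, 2, 4))
        # soft-tissue maximum within 2 mm of the focal point (attenuation
        # shifts the |p| peak slightly pre-focally)
        soft_q = np.where(soft, c.q_w_m3, 0.0)
        idx = np.unravel_index(np.argmax(soft_q), soft_q.shape)
        pos = tmap_1mm.origin_mm + tmap_1mm.spacing_mm * np.array(idx)
        assert np.linalg.norm(pos - tmap_1mm.breakthrough_center_mm) <= 2.0
        # non-zero cortical ring
        cort = tmap_1mm.labels == int(Tissue.CORTICAL)
        assert np.count_nonzero(c.q_w_m3[cort] > 0) > 20

    def test_total_source_power_below_acoustic_power(
            self, intensity_1mm, facet_1mm, tmap_1mm, medium, source_params,
            transducer):
        qa = src.direct_absorption_source(intensity_1mm, tmap_1mm,
                                          source_params, medium, 1e6)
        qb = src.oven_effect_source(intensity_1mm, facet_1mm, source_params,
                                    tmap=tmap_1mm)
        total = src.combine_sources(qa, qb).total_power_w()
        assert total <= transducer.acoustic_power_w
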