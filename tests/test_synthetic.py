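"""Generator tests: deterministic layouts, field covariance, planted targets,
well subsampling."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from coexmap.errors import ConfigurationError
from coexmap.kriging import empirical_variogram, model_semivariance
from coexmap.synthetic import (
    SyntheticConfig,
    generate_domain,
    generate_gene_fields,
    generate_study,
    generate_target_map,
    subsample_wells,
    well_indices,
)


def cfg(**kw):
    base = dict(n_sites=27, n_genes=2, n_drivers=0, n_wells=9, seed=3)
    base.update(kw)
    return SyntheticConfig(**base)


class TestDomain:
    def test_cube_lattice_layout(self):
        # 8 sites at 1 mm spacing form a 2x2x2 cube of diameter sqrt(3)
        dom = generate_domain(cfg(n_sites=8, spacing_mm=1.0, n_wells=8))
        assert dom.n_sites == 8
        assert np.isclose(pdist(dom.coords).max(), np.sqrt(3.0))

    def test_lattice_matches_enumeration_oracle(self):
        dom = generate_domain(cfg(n_sites=27, spacing_mm=2.0))
        expected = {
            (2.0 * i, 2.0 * j, 2.0 * k)
            for i in range(3)
            for j in range(3)
            for k in range(3)
        }
        assert {tuple(c) for c in dom.coords} == expected

    def test_minimal_domain(self):
        # smallest usable study: 3 sites, empty off-lattice distance set
        dom = generate_domain(cfg(n_sites=3, n_wells=3))
        assert dom.n_sites == 3
        assert len(np.unique(dom.coords, axis=0)) == 3

    def test_ring_surface_on_sphere(self):
        dom = generate_domain(cfg(n_sites=50, geometry="ring_surface", n_wells=10))
        radii = np.linalg.norm(dom.coords, axis=1)
        assert np.allclose(radii, 70.0)
        assert dom.space == "surface"
        assert len(np.unique(dom.coords, axis=0)) == 50

    def test_unknown_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(geometry="moebius")


class TestFields:
    def test_zero_variance_limit(self):
        c = cfg(field_partial_sill=0.0, field_nugget=0.0)
        dom = generate_domain(c)
        fields = generate_gene_fields(dom, c)
        assert np.all(fields == 0.0)

    def test_long_range_near_constant(self):
        c = cfg(n_sites=216, field_nugget=0.0, field_range=1e5, n_wells=20)
        dom = generate_domain(c)
        fields = generate_gene_fields(dom, c)
        # far inside the correlation length the field barely varies in space
        assert fields.var(axis=1).mean() < 0.05 * c.field_partial_sill

    def test_empirical_semivariogram_matches_closed_form(self):
        c = SyntheticConfig(
            n_sites=512, spacing_mm=2.0, n_genes=1, n_drivers=0,
            field_nugget=0.5, field_partial_sill=2.0, field_range=5.0,
            n_wells=512, seed=11,
        )
        dom = generate_domain(c)
        fields = generate_gene_fields(dom, c)
        ss = subsample_wells(fields[0], dom, c, indices=np.arange(dom.n_sites))
        emp = empirical_variogram(ss, n_bins=6)
        expected = model_semivariance(
            emp.bin_centers, "exponential", c.field_nugget, c.field_partial_sill,
            c.field_range,
        )
        # Monte-Carlo tolerance: one realization, spatially correlated pairs
        assert np.all(np.abs(emp.semivariances - expected) < 0.6)
        assert np.corrcoef(emp.semivariances, expected)[0, 1] > 0.9

    def test_marginal_variance_matches_sill(self):
        c = SyntheticConfig(
            n_sites=125, spacing_mm=3.0, n_genes=400, n_drivers=0,
            field_nugget=0.5, field_partial_sill=1.5, field_range=8.0,
            n_wells=30, seed=5,
        )
        dom = generate_domain(c)
        fields = generate_gene_fields(dom, c)
        marginal = fields.var(axis=0, ddof=1).mean()  # across independent genes
        sill = c.field_nugget + c.field_partial_sill
        assert abs(marginal - sill) / sill < 0.10

    def test_reproducible_bit_identical(self):
        c = cfg(n_drivers=1)
        a = generate_study(c)
        b = generate_study(c)
        assert np.array_equal(a[1], b[1])
        assert np.array_equal(a[2].values, b[2].values)
        assert np.array_equal(a[4][0].values, b[4][0].values)

    def test_driver_coherence_induces_coexpression(self):
        c = SyntheticConfig(n_sites=343, n_genes=4, n_drivers=2, n_wells=20,
                            driver_coherence=0.95, seed=2)
        dom = generate_domain(c)
        f = generate_gene_fields(dom, c)
        assert np.corrcoef(f[0], f[1])[0, 1] > 0.7  # drivers share structure
        assert abs(np.corrcoef(f[2], f[3])[0, 1]) < 0.6  # non-drivers do not


class TestTarget:
    def test_single_driver_identity(self):
        c = cfg(n_drivers=1, noise_sd=0.0)
        dom = generate_domain(c)
        fields = generate_gene_fields(dom, c)
        target, drivers = generate_target_map(fields, dom, c)
        rho = stats.spearmanr(target.values, fields[0])[0]
        assert rho == pytest.approx(1.0)
        assert list(drivers) == [0]

    def test_negative_weight_reverses_ranks(self):
        c = cfg(n_drivers=1, driver_weights=[-1.0], noise_sd=0.0)
        dom = generate_domain(c)
        fields = generate_gene_fields(dom, c)
        target, _ = generate_target_map(fields, dom, c)
        assert stats.spearmanr(target.values, fields[0])[0] == pytest.approx(-1.0)

    def test_zero_drivers_gives_null_target(self):
        hits = 0
        for seed in range(10):
            c = SyntheticConfig(n_sites=1000, n_genes=2, n_drivers=0,
                                noise_sd=1.0, n_wells=10, seed=seed)
            dom = generate_domain(c)
            fields = generate_gene_fields(dom, c)
            target, drivers = generate_target_map(fields, dom, c)
            assert len(drivers) == 0
            if abs(stats.spearmanr(target.values, fields[0])[0]) < 0.2:
                hits += 1
        assert hits >= 9  # pure-noise target is uncorrelated with any gene


class TestWells:
    def test_exhaustive_covers_every_site(self):
        c = cfg(n_wells=27)
        dom = generate_domain(c)
        idx = well_indices(dom, c)
        assert sorted(idx) == list(range(27))

    def test_deterministic_given_seed(self):
        c = cfg(n_sites=1000, n_wells=3)
        dom = generate_domain(c)
        assert np.array_equal(well_indices(dom, c), well_indices(dom, c))

    def test_uniform_over_seeds(self):
        c0 = cfg(n_sites=30, n_wells=3)
        dom = generate_domain(c0)
        counts = np.zeros(30)
        n_rep = 4000
        for seed in range(n_rep):
            c = cfg(n_sites=30, n_wells=3, seed=seed)
            counts[well_indices(dom, c)] += 1
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_too_many_wells_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(n_sites=10, n_wells=11)

    def test_clustered_wells_concentrate(self):
        c_u = SyntheticConfig(n_sites=1000, n_genes=1, n_drivers=0, n_wells=100, seed=4)
        c_c = SyntheticConfig(n_sites=1000, n_genes=1, n_drivers=0, n_wells=100, seed=4,
                              clustered_wells=True, n_well_clusters=3)
        dom = generate_domain(c_u)
        spread_u = pdist(dom.coords[well_indices(dom, c_u)]).mean()
        spread_c = pdist(dom.coords[well_indices(dom, c_c)]).mean()
        assert spread_c < spread_u


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_sites": 0},
            {"n_genes": 0},
            {"n_drivers": 5, "n_genes": 3},
            {"driver_weights": [1.0, 2.0], "n_drivers": 1},
            {"noise_sd": -0.1},
            {"field_range": 0.0},
            {"n_wells": 2},
            {"driver_coherence": 1.5},
            {"field_family": "cubic"},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            cfg(**kw)

    def test_ground_truth_rsv(self):
        assert cfg(field_nugget=1.0, field_partial_sill=3.0).ground_truth_rsv == 75.0
        assert cfg(field_nugget=0.0).ground_truth_rsv == 100.0
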