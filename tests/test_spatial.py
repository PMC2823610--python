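import math

import numpy as np
import pytest

from geoassign.io_formats import MISSING, GenotypeTable, SampleRecord, SamplingSite
from geoassign.spatial import (
    AlleleRegistry,
    FrequencySurface,
    McmcConfig,
    Priors,
    SurfaceParams,
    covariance_matrix,
    fit_surfaces_mcmc,
    genotype_loglik,
    great_circle_km,
    krige_latent,
    latent_to_freq,
)

from .conftest import make_sites


def haversine_oracle(a, b, radius=6371.0):
    """Independent textbook haversine (written separately from the package)."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    term = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * radius * math.atan2(math.sqrt(term), math.sqrt(1 - term))


class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle_km((4.5, 9.0), (4.5, 9.0)) == 0.0

    def test_equatorial_antipodes(self):
        assert great_circle_km((0, 0), (0, 180)) == pytest.approx(math.pi * 6371.0)

    def test_against_oracle_on_published_pair(self):
        a, b = (5.69426, 10.98525), (4.79855, 9.2901)
        assert great_circle_km(a, b) == pytest.approx(haversine_oracle(a, b), rel=1e-6)

    def test_random_points_against_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            a = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            b = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            assert great_circle_km(a, b) == pytest.approx(haversine_oracle(a, b), rel=1e-9, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_km((91.0, 0.0), (0.0, 0.0))
        with pytest.raises(ValueError):
            great_circle_km((0.0, 0.0), (0.0, 181.0))


class TestCovariance:
    def test_diagonal_is_sill_plus_nugget(self):
        sites = make_sites([(5.0, 9.0), (6.0, 10.0)])
        c = covariance_matrix(sites, SurfaceParams(alpha=100.0, beta_sill=2.0, tau2=0.5))
        assert np.allclose(np.diag(c), 2.5)

    def test_monotone_decay_with_distance(self):
        sites = make_sites([(5.0, 9.0), (5.0, 10.0), (5.0, 12.0), (5.0, 16.0)])
        c = covariance_matrix(sites, SurfaceParams(alpha=150.0, beta_sill=1.0, tau2=0.0))
        assert c[0, 1] > c[0, 2] > c[0, 3] > 0.0

    def test_positive_definite_random_sites(self):
        rng = np.random.default_rng(0)
        sites = make_sites([(rng.uniform(2, 8), rng.uniform(8, 15)) for _ in range(10)])
        c = covariance_matrix(sites, SurfaceParams(alpha=120.0, beta_sill=1.0, tau2=0.05))
        assert np.linalg.eigvalsh(c).min() > 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SurfaceParams(alpha=-1.0, beta_sill=1.0)
        with pytest.raises(ValueError):
            SurfaceParams(alpha=1.0, beta_sill=0.0)


class TestLatentToFreq:
    def test_uniform_for_zero_latent(self):
        assert np.allclose(latent_to_freq(np.zeros(5)), 0.2)

    def test_shift_invariance(self):
        x = np.array([0.3, -1.2, 2.0])
        assert np.allclose(latent_to_freq(x), latent_to_freq(x + 7.5))

    def test_closed_form(self):
        assert np.allclose(latent_to_freq(np.array([0.0, math.log(2)])), [1 / 3, 2 / 3])

    def test_overflow_guarded(self):
        f = latent_to_freq(np.array([1e4, 0.0]))
        assert np.isfinite(f).all() and f.sum() == pytest.approx(1.0)


class TestGenotypeLoglik:
    def test_het_half_half(self):
        rec = SampleRecord("s", 1, ((120, 122),))
        assert genotype_loglik(rec, [{120: 0.5, 122: 0.5}]) == pytest.approx(math.log(0.5))

    def test_all_missing_is_zero(self):
        rec = SampleRecord("s", 1, ((MISSING, MISSING), (MISSING, MISSING)))
        assert genotype_loglik(rec, [{}, {}]) == 0.0

    def test_three_allele_het(self):
        rec = SampleRecord("s", 1, ((120, 124),))
        freqs = [{120: 0.2, 122: 0.3, 124: 0.5}]
        assert genotype_loglik(rec, freqs) == pytest.approx(math.log(2 * 0.2 * 0.5))

    def test_homozygote_squared(self):
        rec = SampleRecord("s", 1, ((120, 120),))
        assert genotype_loglik(rec, [{120: 0.3, 122: 0.7}]) == pytest.approx(2 * math.log(0.3))

    def test_haploid_contributes_p(self):
        rec = SampleRecord("s", 1, ((2,),))
        assert genotype_loglik(rec, [{2: 0.4}], ploidy=[1]) == pytest.approx(math.log(0.4))

    def test_locus_permutation_invariance(self):
        rec1 = SampleRecord("s", 1, ((120, 122), (130, 130)))
        rec2 = SampleRecord("s", 1, ((130, 130), (120, 122)))
        f1 = [{120: 0.4, 122: 0.6}, {130: 0.9, 132: 0.1}]
        assert genotype_loglik(rec1, f1) == pytest.approx(genotype_loglik(rec2, f1[::-1]))

    def test_monotone_in_observed_frequency(self):
        rec = SampleRecord("s", 1, ((120, 120),))
        lo = genotype_loglik(rec, [{120: 0.2, 122: 0.8}])
        hi = genotype_loglik(rec, [{120: 0.6, 122: 0.4}])
        assert hi > lo


def _single_site_table(n_a=12, n_b=4):
    samples = []
    calls = [100] * n_a + [102] * n_b
    for i in range(0, len(calls), 2):
        samples.append(SampleRecord(f"s{i}", 1, ((calls[i], calls[i + 1]),)))
    return GenotypeTable(("L1",), (2,), tuple(samples))


class TestMcmcFit:
    def test_single_site_posterior_mean(self):
        # flat-ish prior, 12/16 observed copies of allele 100: the posterior
        # mean should approximate the beta-binomial answer
        table = _single_site_table()
        sites = make_sites([(5.0, 10.0)])
        cfg = McmcConfig(thinning=2, burn_in=300, iterations=600, runs=2, seed=3)
        surf = fit_surfaces_mcmc(table, sites, cfg)
        freqs = np.array([np.exp(surf.log_freqs(d))[0, 0, 0] for d in range(surf.n_draws)])
        assert freqs.mean() == pytest.approx(12 / 16, abs=0.05)

    def test_frequencies_sum_to_one_every_draw(self):
        table = _single_site_table()
        sites = make_sites([(5.0, 10.0)])
        surf = fit_surfaces_mcmc(table, sites, McmcConfig(1, 50, 80, 1, seed=2))
        for d in range(surf.n_draws):
            f = np.exp(surf.log_freqs(d))
            assert np.allclose(f.sum(axis=1), 1.0, atol=1e-9)

    def test_bit_reproducible(self):
        table = _single_site_table()
        sites = make_sites([(5.0, 10.0)])
        cfg = McmcConfig(1, 50, 80, 2, seed=9)
        a = fit_surfaces_mcmc(table, sites, cfg)
        b = fit_surfaces_mcmc(table, sites, cfg)
        assert np.array_equal(a.latents, b.latents)
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.mus, b.mus)

    def test_identical_sites_difference_covers_zero(self):
        # two sites simulated with identical 50/50 frequencies: the posterior
        # of the cross-site frequency difference should cover 0 at 95% in
        # most replicates
        sites = make_sites([(3.0, 9.0), (7.0, 14.0)])
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            samples = []
            for s in (1, 2):
                for i in range(10):
                    pair = tuple(int(100 + 2 * rng.integers(0, 2)) for _ in range(2))
                    samples.append(SampleRecord(f"r{s}_{i}", s, (pair,)))
            table = GenotypeTable(("L1",), (2,), tuple(samples))
            surf = fit_surfaces_mcmc(
                table, sites, McmcConfig(1, 150, 300, 1, seed=500 + rep)
            )
            diffs = np.array(
                [np.exp(surf.log_freqs(d))[0, 0, 0] - np.exp(surf.log_freqs(d))[0, 0, 1] for d in range(surf.n_draws)]
            )
            lo, hi = np.quantile(diffs, [0.025, 0.975])
            hits += lo <= 0.0 <= hi
        assert hits >= int(0.9 * n_rep)

    def test_decorrelation_as_alpha_shrinks(self):
        # distant sites: latent draws decorrelate as the decay range drops
        sites = make_sites([(2.0, 9.0), (7.5, 15.0)])
        # data at site 1 only: the site-2 latent is driven by the spatial prior
        table = GenotypeTable(
            ("L1",),
            (2,),
            (SampleRecord("a", 1, ((100, 102),)),),
        )
        cors = []
        for alpha in (10.0, 500.0, 25000.0):
            priors = Priors(update_params=False, log_alpha_mean=math.log(alpha))
            surf = fit_surfaces_mcmc(
                table,
                sites,
                McmcConfig(2, 300, 800, 1, seed=21),
                priors=priors,
                init_params=SurfaceParams(alpha=alpha, beta_sill=1.0, tau2=0.01),
            )
            x = surf.latents[:, 0, 0, 0] - surf.mus[:, 0, 0]
            y = surf.latents[:, 0, 0, 1] - surf.mus[:, 0, 0]
            cors.append(np.corrcoef(x, y)[0, 1])
        assert cors[0] < cors[1] < cors[2]

    def test_acceptance_warning_structure(self):
        table = _single_site_table()
        sites = make_sites([(5.0, 10.0)])
        surf = fit_surfaces_mcmc(table, sites, McmcConfig(1, 50, 60, 1, seed=4))
        rates = surf.diagnostics["acceptance_rates"]
        assert len(rates) == 1 and 0.0 <= rates[0] <= 1.0

    def test_save_load_roundtrip(self, tmp_path):
        table = _single_site_table()
        sites = make_sites([(5.0, 10.0)])
        surf = fit_surfaces_mcmc(table, sites, McmcConfig(1, 40, 60, 1, seed=8))
        surf.save(tmp_path / "surface.npz")
        again = FrequencySurface.load(tmp_path / "surface.npz")
        assert np.array_equal(again.latents, surf.latents)
        assert again.registry.alleles == surf.registry.alleles
        assert again.sites == surf.sites


class TestKrige:
    def _surface(self, latents, mus, params, coords):
        sites = make_sites(coords)
        registry = AlleleRegistry(["L1"], [2], [[100, 102]])
        d, l, a, s = 1, 1, 2, len(coords)
        lat = np.zeros((d, l, registry.max_alleles, s))
        lat[0, 0, : latents.shape[0], :] = latents
        mu = np.zeros((d, l, registry.max_alleles))
        mu[0, 0, : mus.shape[0]] = mus
        return FrequencySurface(
            sites=sites,
            registry=registry,
            latents=lat,
            mus=mu,
            params=np.array([[params.alpha, params.beta_sill, params.tau2]]),
            run_index=np.zeros(1, dtype=int),
            config=McmcConfig(seed=0),
        )

    def test_interpolates_anchor_exactly_without_nugget(self):
        coords = [(5.0, 9.0), (6.0, 11.0), (4.0, 13.0)]
        latents = np.array([[1.0, -2.0, 0.5], [0.3, 0.7, -1.1]])
        surf = self._surface(latents, np.array([0.0, 0.0]), SurfaceParams(200.0, 1.0, 0.0), coords)
        out = krige_latent(surf, 0, coords[1])
        assert np.allclose(out[0, :2], latents[:, 1], atol=1e-8)

    def test_far_query_returns_mu(self):
        coords = [(5.0, 9.0), (5.5, 9.5)]
        latents = np.array([[1.0, -2.0], [0.3, 0.7]])
        mus = np.array([0.25, -0.5])
        surf = self._surface(latents, mus, SurfaceParams(5.0, 1.0, 0.01), coords)
        out = krige_latent(surf, 0, (-60.0, 120.0))
        assert np.allclose(out[0, :2], mus, atol=1e-6)

    def test_matches_direct_conditional_solve(self):
        coords = [(5.0, 9.0), (6.0, 11.0), (4.0, 13.0)]
        latents = np.array([[1.0, -2.0, 0.5], [0.3, 0.7, -1.1]])
        mus = np.array([0.2, -0.3])
        params = SurfaceParams(300.0, 1.3, 0.2)
        surf = self._surface(latents, mus, params, coords)
        q = (5.2, 10.7)
        out = krige_latent(surf, 0, q)
        # independent dense solve of the 3x3 conditional system
        c = covariance_matrix(surf.sites, params)
        k = np.array(
            [params.beta_sill * math.exp(-haversine_oracle(q, xy) / params.alpha) for xy in coords]
        )
        w = np.linalg.solve(c, k)
        for j in range(2):
            expected = mus[j] + w @ (latents[j] - mus[j])
            assert out[0, j] == pytest.approx(expected, rel=1e-9)

    def test_non_finite_query_rejected(self):
        coords = [(5.0, 9.0), (6.0, 11.0), (4.0, 13.0)]
        latents = np.zeros((2, 3))
        surf = self._surface(latents, np.zeros(2), SurfaceParams(200.0, 1.0, 0.1), coords)
        with pytest.raises(ValueError):
            krige_latent(surf, 0, (math.nan, 10.0))


class TestRegistry:
    def test_private_query_alleles_get_slots(self):
        ref = GenotypeTable(("L1",), (2,), (SampleRecord("a", 1, ((100, 100),)),))
        qry = GenotypeTable(("L1",), (2,), (SampleRecord("q", -1, ((104, 104),)),))
        reg = AlleleRegistry.from_tables(ref, qry)
        assert reg.alleles[0] == (100, 104)
        nq, _ = reg.query_counts(qry.samples[0])
        assert nq[0, 1] == 2.0

    def test_mismatched_panels_rejected(self):
        t1 = GenotypeTable(("L1",), (2,), ())
        t2 = GenotypeTable(("L2",), (2,), ())
        with pytest.raises(ValueError):
            AlleleRegistry.from_tables(t1, t2)


class TestParameterRecovery:
    def test_alpha_recovered_within_factor_three(self):
        # weakly identifiable: accept a factor-3 bracket in >=80% of replicates
        from geoassign.synthetic import LandscapeConfig, simulate_landscape

        alpha_true = 150.0
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = LandscapeConfig(
                n_sites=8,
                samples_per_site=5,
                n_loci=4,
                alleles_per_locus=4,
                alpha_true=alpha_true,
                barrier_shift=0.0,
                missing_rate=0.0,
                seed=900 + rep,
            )
            table, sites, _ = simulate_landscape(cfg)
            surf = fit_surfaces_mcmc(
                table, sites, McmcConfig(1, 150, 300, 1, seed=1300 + rep)
            )
            alpha_hat = float(np.median(surf.params[:, 0]))
            hits += alpha_true / 3 <= alpha_hat <= alpha_true * 3
        assert hits >= 8
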