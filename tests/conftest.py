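"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from geoassign.io_formats import GenotypeTable, SampleRecord, SamplingSite
from geoassign.spatial import McmcConfig
from geoassign.synthetic import LandscapeConfig, simulate_landscape


@pytest.fixture(scope="session")
def fast_mcmc() -> McmcConfig:
    """Small sampler schedule for unit tests."""
    return McmcConfig(thinning=1, burn_in=100, iterations=200, runs=2, seed=11)


@pytest.fixture(scope="session")
def tiny_mcmc() -> McmcConfig:
    return McmcConfig(thinning=1, burn_in=50, iterations=100, runs=1, seed=5)


@pytest.fixture(scope="session")
def small_landscape():
    """6 sites x 5 samples x 5 loci landscape with a strong barrier."""
    cfg = LandscapeConfig(
        n_sites=6,
        samples_per_site=5,
        n_loci=5,
        alleles_per_locus=4,
        barrier_shift=3.0,
        missing_rate=0.02,
        seed=42,
    )
    return simulate_landscape(cfg)


def make_sites(coords, zones=None) -> tuple[SamplingSite, ...]:
    zones = zones or ["North"] * len(coords)
    return tuple(
        SamplingSite(code=f"X{i + 1:02d}", index=i + 1, latitude=lat, longitude=lon, zone=z)
        for i, ((lat, lon), z) in enumerate(zip(coords, zones))
    )


def random_table(rng: np.random.Generator, n_samples=20, n_loci=5, n_alleles=4, n_sites=3) -> GenotypeTable:
    """Random well-formed diploid table for round-trip style tests."""
    samples = []
    for i in range(n_samples):
        alleles = []
        for _ in range(n_loci):
            if rng.random() < 0.1:
                alleles.append((-999, -999))
            else:
                pick = 100 + 2 * rng.integers(0, n_alleles, size=2)
                alleles.append((int(pick[0]), int(pick[1])))
        site = int(rng.integers(1, n_sites + 1)) if rng.random() > 0.2 else -1
        samples.append(SampleRecord(id=f"R{i:03d}", site_index=site, alleles=tuple(alleles)))
    return GenotypeTable(
        loci=tuple(f"L{j + 1}" for j in range(n_loci)),
        ploidy=(2,) * n_loci,
        samples=tuple(samples),
    )
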