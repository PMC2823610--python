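"""Synthetic georeferenced landscapes with barrier-structured frequencies.

Generates reference panels with the statistical structure the assignment
model assumes: spatially autocorrelated allele frequencies under the
exponential-decay covariance, a river-like barrier producing a mean shift
in the latent fields with a linear contact-zone taper, barrier-correlated
haplogroups, per-locus missingness, and unknown-origin query samples with
a withheld answer key.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    HAPLOGROUP_CODES,
    MISSING,
    NORTH,
    SOUTH,
    TRANSITION,
    GenotypeTable,
    SampleRecord,
    SamplingSite,
    write_scat_genotypes,
    write_sites,
)
from .spatial import SurfaceParams, covariance_matrix, latent_to_freq

__all__ = [
    "LandscapeConfig",
    "SyntheticTruth",
    "simulate_landscape",
    "sample_unknowns",
    "write_fixture_bundle",
]

_NORTH_HAPLOGROUPS = ("1a", "1b")
_SOUTH_HAPLOGROUPS = ("2a", "2b", "2c")


@dataclass(frozen=True)
class LandscapeConfig:
    n_sites: int = 10
    samples_per_site: int = 10
    n_loci: int = 10
    alleles_per_locus: int = 6
    alpha_true: float = 150.0
    beta_sill_true: float = 1.0
    tau2_true: float = 0.1
    lat_range: tuple[float, float] = (2.0, 7.5)
    lon_range: tuple[float, float] = (8.5, 14.5)
    #: Polyline (lat, lon) splitting the map into North (above) and South.
    barrier: tuple[tuple[float, float], ...] = ((4.6, 8.5), (4.6, 14.5))
    barrier_shift: float = 3.0
    transition_width: float = 100.0  # km
    missing_rate: float = 0.05
    haplogroup_fidelity: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        for p in (self.missing_rate, self.haplogroup_fidelity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.beta_sill_true, self.tau2_true) < 0 or self.alpha_true <= 0:
            raise ValueError("variance parameters must be non-negative, alpha positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth withheld from the assignment code paths."""

    site_freqs: np.ndarray  # (L, A, S)
    alleles: tuple[tuple[int, ...], ...]  # allele sizes per locus
    sites: tuple[SamplingSite, ...]
    sample_site: Mapping[str, str]  # sample id -> site code
    sample_haplogroup: Mapping[str, str]
    config: LandscapeConfig


def _barrier_lat(barrier: Sequence[tuple[float, float]], lon: float) -> float:
    """Latitude of the barrier polyline at ``lon`` (piecewise linear)."""
    pts = sorted(barrier, key=lambda p: p[1])
    if lon <= pts[0][1]:
        return pts[0][0]
    for (la1, lo1), (la2, lo2) in zip(pts, pts[1:]):
        if lon <= lo2:
            t = 0.0 if lo2 == lo1 else (lon - lo1) / (lo2 - lo1)
            return la1 + t * (la2 - la1)
    return pts[-1][0]


def _barrier_offset_km(cfg: LandscapeConfig, lat: float, lon: float) -> float:
    """Signed distance (km) north of the barrier, ~111 km per degree."""
    return (lat - _barrier_lat(cfg.barrier, lon)) * 111.0


def _ramp(signed_km: float, width_km: float) -> float:
    """0 on the south side, 1 on the north, linear across the contact zone."""
    if width_km <= 0:
        return 1.0 if signed_km >= 0 else 0.0
    t = signed_km / (width_km / 2.0)
    return float(np.clip((t + 1.0) / 2.0, 0.0, 1.0))


def _place_sites(cfg: LandscapeConfig, rng: np.random.Generator) -> tuple[SamplingSite, ...]:
    """Jittered-grid site placement so both barrier sides are populated."""
    n = cfg.n_sites
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    lat_lo, lat_hi = cfg.lat_range
    lon_lo, lon_hi = cfg.lon_range
    sites = []
    k = 0
    for r in range(rows):
        for c in range(cols):
            if k >= n:
                break
            lat = lat_lo + (r + 0.2 + 0.6 * rng.random()) * (lat_hi - lat_lo) / rows
            lon = lon_lo + (c + 0.2 + 0.6 * rng.random()) * (lon_hi - lon_lo) / cols
            offset = _barrier_offset_km(cfg, lat, lon)
            if offset > cfg.transition_width / 2.0:
                zone = NORTH
            elif offset < -cfg.transition_width / 2.0:
                zone = SOUTH
            else:
                zone = TRANSITION
            sites.append(
                SamplingSite(code=f"S{k + 1:02d}", index=k + 1, latitude=round(lat, 6), longitude=round(lon, 6), zone=zone)
            )
            k += 1
    return tuple(sites)


def simulate_landscape(
    cfg: LandscapeConfig,
) -> tuple[GenotypeTable, tuple[SamplingSite, ...], SyntheticTruth]:
    """Simulate a reference panel (genotypes, sites, withheld truth).

    Latent fields are multivariate-normal draws under the exponential
    decay covariance; one random-sign shift of magnitude
    ``barrier_shift`` per locus-allele is added north of the barrier,
    tapered linearly across ``transition_width``.  Genotypes follow HWE at
    each site's transformed frequencies; haplogroups track the barrier
    side with probability ``haplogroup_fidelity``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    sites = _place_sites(cfg, rng)
    L, A, S = cfg.n_loci, cfg.alleles_per_locus, cfg.n_sites
    alleles = tuple(tuple(100 + 2 * j for j in range(A)) for _ in range(L))

    if cfg.beta_sill_true > 0:
        params = SurfaceParams(cfg.alpha_true, cfg.beta_sill_true, cfg.tau2_true)
        cov = covariance_matrix(sites, params)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("degenerate landscape covariance") from exc
    else:
        chol = np.sqrt(cfg.tau2_true) * np.eye(S)

    ramps = np.array([_ramp(_barrier_offset_km(cfg, s.latitude, s.longitude), cfg.transition_width) for s in sites])
    # per locus, the shift raises one allele and lowers another north of the
    # barrier; a uniform sign would cancel under the softmax
    shift_pattern = np.zeros((L, A))
    for l in range(L):
        up, down = rng.choice(A, size=2, replace=False)
        shift_pattern[l, up] = 1.0
        shift_pattern[l, down] = -1.0
    latents = np.einsum("st,lat->las", chol, rng.standard_normal((L, A, S)))
    latents += cfg.barrier_shift * shift_pattern[:, :, None] * ramps[None, None, :]
    freqs = latent_to_freq(np.moveaxis(latents, 2, 1)).transpose(0, 2, 1)  # (L, A, S)

    samples = []
    sample_site: dict[str, str] = {}
    sample_hap: dict[str, str] = {}
    for s_idx, site in enumerate(sites):
        north_side = _barrier_offset_km(cfg, site.latitude, site.longitude) >= 0
        for i in range(cfg.samples_per_site):
            sid = f"{site.code}_{i + 1:03d}"
            geno = _draw_genotype(freqs[:, :, s_idx], alleles, cfg.missing_rate, rng)
            samples.append(SampleRecord(id=sid, site_index=site.index, alleles=geno))
            sample_site[sid] = site.code
            side = north_side if rng.random() < cfg.haplogroup_fidelity else not north_side
            pool = _NORTH_HAPLOGROUPS if side else _SOUTH_HAPLOGROUPS
            sample_hap[sid] = pool[rng.integers(len(pool))]

    table = GenotypeTable(
        loci=tuple(f"L{l + 1}" for l in range(L)),
        ploidy=(2,) * L,
        samples=tuple(samples),
    )
    truth = SyntheticTruth(
        site_freqs=freqs,
        alleles=alleles,
        sites=sites,
        sample_site=sample_site,
        sample_haplogroup=sample_hap,
        config=cfg,
    )
    return table, sites, truth


def _draw_genotype(
    site_freqs: np.ndarray,
    alleles: Sequence[Sequence[int]],
    missing_rate: float,
    rng: np.random.Generator,
) -> tuple[tuple[int, int], ...]:
    geno = []
    for l in range(site_freqs.shape[0]):
        if rng.random() < missing_rate:
            geno.append((MISSING, MISSING))
            continue
        p = site_freqs[l] / site_freqs[l].sum()
        pair = rng.choice(len(p), size=2, p=p)
        geno.append((alleles[l][pair[0]], alleles[l][pair[1]]))
    return tuple(geno)


def sample_unknowns(
    truth: SyntheticTruth, n_per_site: int, seed: int = 0
) -> tuple[GenotypeTable, dict[str, str]]:
    """Fresh unknown-origin queries drawn from each site's true frequencies.

    Returns the query table (site index -1) and the withheld answer key
    mapping query id to true site code.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    cfg = truth.config
    samples = []
    key: dict[str, str] = {}
    for s_idx, site in enumerate(truth.sites):
        for i in range(n_per_site):
            sid = f"U_{site.code}_{i + 1:03d}"
            geno = _draw_genotype(truth.site_freqs[:, :, s_idx], truth.alleles, cfg.missing_rate, rng)
            samples.append(SampleRecord(id=sid, site_index=-1, alleles=geno))
            key[sid] = site.code
    table = GenotypeTable(
        loci=tuple(f"L{l + 1}" for l in range(cfg.n_loci)),
        ploidy=(2,) * cfg.n_loci,
        samples=tuple(samples),
    )
    return table, key


def write_fixture_bundle(
    table: GenotypeTable,
    sites: Sequence[SamplingSite],
    truth: SyntheticTruth,
    path: str | Path,
    unknowns: GenotypeTable | None = None,
    answer_key: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write a complete plain-text fixture bundle under ``path``.

    Emits genotype, site, boundary-polygon, haplogroup and answer-key
    files; the bundle round-trips losslessly through the parsers.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    out["genotypes"] = path / "genotypes.txt"
    write_scat_genotypes(table, out["genotypes"])
    if unknowns is not None:
        out["unknowns"] = path / "unknowns.txt"
        write_scat_genotypes(unknowns, out["unknowns"])
    out["sites"] = path / "sites.txt"
    write_sites(sites, out["sites"])

    cfg = truth.config
    lat_lo, lat_hi = cfg.lat_range
    lon_lo, lon_hi = cfg.lon_range
    pad = 0.25
    box = [
        (lat_lo - pad, lon_lo - pad),
        (lat_lo - pad, lon_hi + pad),
        (lat_hi + pad, lon_hi + pad),
        (lat_hi + pad, lon_lo - pad),
        (lat_lo - pad, lon_lo - pad),
    ]
    out["boundary"] = path / "boundary.txt"
    with open(out["boundary"], "w", encoding="utf-8") as fh:
        for lat, lon in box:
            fh.write(f"{lat:.6f} {lon:.6f}\n")

    out["haplogroups"] = path / "haplogroups.tsv"
    with open(out["haplogroups"], "w", encoding="utf-8") as fh:
        fh.write("sample_id\thaplogroup\n")
        for sid in sorted(truth.sample_haplogroup):
            fh.write(f"{sid}\t{truth.sample_haplogroup[sid]}\n")

    if answer_key is not None:
        out["answer_key"] = path / "answer_key.tsv"
        with open(out["answer_key"], "w", encoding="utf-8") as fh:
            fh.write("sample_id\ttrue_site\n")
            for sid in sorted(answer_key):
                fh.write(f"{sid}\t{answer_key[sid]}\n")

    digest = hashlib.sha256()
    for name in sorted(out):
        digest.update(out[name].read_bytes())
    (path / "bundle.sha256").write_text(digest.hexdigest() + "\n")
    out["checksum"] = path / "bundle.sha256"
    return out
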