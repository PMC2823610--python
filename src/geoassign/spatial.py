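"""Spatially smoothed allele-frequency model.

Latent Gaussian fields over the reference sites, one per locus-allele,
with an exponential distance-decay covariance; a softmax transform maps
latents to allele frequencies, and a Metropolis-within-Gibbs sampler
produces posterior draws of the whole frequency surface.  Conditional
(kriging) interpolation extends each draw to arbitrary coordinates so
continuous assignment can evaluate likelihoods anywhere.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .io_formats import MISSING, GenotypeTable, SampleRecord, SamplingSite

__all__ = [
    "EARTH_RADIUS_KM",
    "SurfaceParams",
    "McmcConfig",
    "Priors",
    "AlleleRegistry",
    "FrequencySurface",
    "great_circle_km",
    "pairwise_great_circle_km",
    "covariance_matrix",
    "latent_to_freq",
    "genotype_loglik",
    "fit_surfaces_mcmc",
    "krige_latent",
]

EARTH_RADIUS_KM = 6371.0

_LOG2 = math.log(2.0)


def great_circle_km(a: Sequence[float], b: Sequence[float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) pairs."""
    lat1, lon1 = float(a[0]), float(a[1])
    lat2, lon2 = float(b[0]), float(b[1])
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90.0:
            raise ValueError(f"latitude {lat} out of range")
        if abs(lon) > 180.0:
            raise ValueError(f"longitude {lon} out of range")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def pairwise_great_circle_km(
    points_a: np.ndarray, points_b: np.ndarray
) -> np.ndarray:
    """Haversine distance matrix between two (n, 2) arrays of (lat, lon)."""
    pa = np.radians(np.atleast_2d(np.asarray(points_a, dtype=float)))
    pb = np.radians(np.atleast_2d(np.asarray(points_b, dtype=float)))
    phi1 = pa[:, 0][:, None]
    phi2 = pb[:, 0][None, :]
    dphi = phi2 - phi1
    dlam = pb[:, 1][None, :] - pa[:, 1][:, None]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


@dataclass(frozen=True)
class SurfaceParams:
    """Covariance parameters of the latent field.

    ``alpha`` is the decay range in km, ``beta_sill`` the covariance scale
    and ``tau2`` the nugget added on the diagonal.
    """

    alpha: float
    beta_sill: float
    tau2: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta_sill <= 0:
            raise ValueError("alpha and beta_sill must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler schedule: full-scale defaults mirror the published runs."""

    thinning: int = 500
    burn_in: int = 1000
    iterations: int = 2000
    runs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.thinning, self.burn_in, self.iterations, self.runs) < 1:
            raise ValueError("thinning, burn_in, iterations and runs must be positive")


@dataclass(frozen=True)
class Priors:
    """Hyperpriors for the surface fit (all log-scale normals except mu)."""

    mu_sd: float = 3.0
    log_alpha_mean: float = math.log(200.0)
    log_alpha_sd: float = 1.0
    log_beta_mean: float = 0.0
    log_beta_sd: float = 1.0
    log_tau2_mean: float = 0.0
    log_tau2_sd: float = 1.0
    update_params: bool = True  # False fixes alpha/beta/tau2 at their initial values


def covariance_matrix(
    sites: Sequence[SamplingSite] | np.ndarray, params: SurfaceParams
) -> np.ndarray:
    """Exponential-decay covariance with nugget over site coordinates.

    ``C[i, j] = beta_sill * exp(-d_ij / alpha) + tau2 * 1[i == j]`` with
    great-circle distances in km.
    """
    coords = _site_coords(sites)
    d = pairwise_great_circle_km(coords, coords)
    c = params.beta_sill * np.exp(-d / params.alpha)
    c[np.diag_indices_from(c)] += params.tau2
    return c


def _site_coords(sites: Sequence[SamplingSite] | np.ndarray) -> np.ndarray:
    if isinstance(sites, np.ndarray):
        return np.asarray(sites, dtype=float)
    return np.array([[s.latitude, s.longitude] for s in sites], dtype=float)


def latent_to_freq(latent: np.ndarray) -> np.ndarray:
    """Softmax transform, overflow-guarded; strictly positive, sums to 1."""
    x = np.asarray(latent, dtype=float)
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


class AlleleRegistry:
    """Per-locus allele inventories shared by reference and query samples.

    Every allele observed anywhere in the supplied tables gets a latent
    dimension at every site, so private alleles of queries never produce
    minus-infinity likelihoods.
    """

    def __init__(self, loci: Sequence[str], ploidy: Sequence[int], alleles: Sequence[Sequence[int]]):
        self.loci = tuple(loci)
        self.ploidy = tuple(ploidy)
        self.alleles = tuple(tuple(sorted(a)) for a in alleles)
        if not all(len(a) >= 1 for a in self.alleles):
            raise ValueError("every locus needs at least one observed allele")
        self._index = [
            {a: j for j, a in enumerate(locus_alleles)} for locus_alleles in self.alleles
        ]
        self.n_loci = len(self.loci)
        self.max_alleles = max(len(a) for a in self.alleles)
        # mask[l, a]: allele slot a exists at locus l
        self.mask = np.zeros((self.n_loci, self.max_alleles), dtype=bool)
        for l, locus_alleles in enumerate(self.alleles):
            self.mask[l, : len(locus_alleles)] = True

    @classmethod
    def from_tables(cls, *tables: GenotypeTable) -> "AlleleRegistry":
        base = tables[0]
        observed: list[set[int]] = [set() for _ in base.loci]
        for t in tables:
            if t.loci != base.loci or t.ploidy != base.ploidy:
                raise ValueError("tables disagree on the locus panel")
            for rec in t.samples:
                for i, pair in enumerate(rec.alleles):
                    observed[i].update(a for a in pair if a != MISSING)
        # a locus never typed anywhere still needs one dummy allele slot
        for i, s in enumerate(observed):
            if not s:
                s.add(1)
        return cls(base.loci, base.ploidy, [sorted(s) for s in observed])

    def site_counts(self, table: GenotypeTable, n_sites: int) -> np.ndarray:
        """Observed allele counts ``N[l, a, s]`` from georeferenced samples."""
        n = np.zeros((self.n_loci, self.max_alleles, n_sites), dtype=float)
        for rec in table.samples:
            if rec.unknown_origin:
                continue
            s = rec.site_index - 1
            if not 0 <= s < n_sites:
                raise ValueError(f"sample {rec.id!r}: site index {rec.site_index} out of range")
            for l, pair in enumerate(rec.alleles):
                for a in pair:
                    if a != MISSING:
                        n[l, self._index[l][a], s] += 1.0
        return n

    def query_counts(self, rec: SampleRecord) -> tuple[np.ndarray, float]:
        """Allele counts ``(L, A)`` for one sample plus the constant
        log-term (log 2 per heterozygous diploid locus)."""
        n = np.zeros((self.n_loci, self.max_alleles), dtype=float)
        const = 0.0
        for l, pair in enumerate(rec.alleles):
            calls = [a for a in pair if a != MISSING]
            if len(calls) != len(pair):
                continue  # partially/fully missing loci contribute nothing
            for a in calls:
                try:
                    n[l, self._index[l][a]] += 1.0
                except KeyError as exc:
                    raise KeyError(
                        f"allele {a} at locus {self.loci[l]!r} absent from registry"
                    ) from exc
            if len(calls) == 2 and calls[0] != calls[1]:
                const += _LOG2
        return n, const


def genotype_loglik(
    record: SampleRecord,
    freqs: Sequence[Mapping[int, float]],
    ploidy: Sequence[int] | None = None,
) -> float:
    """Log-probability of one sample's multilocus genotype.

    ``freqs[i]`` maps allele size to frequency at locus ``i``.  Diploid
    loci follow Hardy-Weinberg (p^2 / 2pq); haploid loci contribute
    ``log p``; loci with any missing call contribute 0.
    """
    if ploidy is None:
        ploidy = [len(p) for p in record.alleles]
    total = 0.0
    for i, pair in enumerate(record.alleles):
        if MISSING in pair:
            continue
        if ploidy[i] == 1:
            total += math.log(freqs[i][pair[0]])
        else:
            a, b = pair
            if a == b:
                total += 2.0 * math.log(freqs[i][a])
            else:
                total += _LOG2 + math.log(freqs[i][a]) + math.log(freqs[i][b])
    return total


@dataclass
class FrequencySurface:
    """Posterior draws of the latent frequency fields at the anchor sites."""

    sites: tuple[SamplingSite, ...]
    registry: AlleleRegistry
    latents: np.ndarray  # (D, L, A, S)
    mus: np.ndarray  # (D, L, A)
    params: np.ndarray  # (D, 3): alpha, beta_sill, tau2
    run_index: np.ndarray  # (D,)
    config: McmcConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.latents.shape[0]

    def draw_params(self, d: int) -> SurfaceParams:
        a, b, t = self.params[d]
        return SurfaceParams(alpha=float(a), beta_sill=float(b), tau2=float(t))

    def log_freqs(self, d: int) -> np.ndarray:
        """Log allele frequencies ``(L, A, S)`` for draw ``d`` (masked slots -inf)."""
        return _masked_log_softmax(self.latents[d], self.registry.mask)

    def site_freqs(self, d: int, site_index: int) -> list[dict[int, float]]:
        """Frequencies at 1-based ``site_index`` as per-locus allele->p dicts."""
        lf = self.log_freqs(d)[:, :, site_index - 1]
        out = []
        for l, alleles in enumerate(self.registry.alleles):
            out.append({a: float(np.exp(lf[l, j])) for j, a in enumerate(alleles)})
        return out

    def mean_log_freqs(self) -> np.ndarray:
        return np.mean([self.log_freqs(d) for d in range(self.n_draws)], axis=0)

    def save(self, path: str | Path) -> None:
        """Serialize draws (npz) plus a JSON manifest alongside."""
        path = Path(path)
        np.savez_compressed(
            path,
            latents=self.latents,
            mus=self.mus,
            params=self.params,
            run_index=self.run_index,
            site_coords=_site_coords(self.sites),
        )
        import hashlib

        digest = hashlib.sha256()
        for arr in (self.latents, self.mus, self.params, self.run_index):
            digest.update(np.ascontiguousarray(arr).tobytes())
        manifest = {
            "content_sha256": digest.hexdigest(),
            "seed": self.config.seed,
            "config": self.config.__dict__,
            "sites": [s.__dict__ for s in self.sites],
            "loci": list(self.registry.loci),
            "ploidy": list(self.registry.ploidy),
            "alleles": [list(a) for a in self.registry.alleles],
            "diagnostics": {k: v for k, v in self.diagnostics.items() if not isinstance(v, np.ndarray)},
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FrequencySurface":
        path = Path(path)
        data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        manifest = json.loads(path.with_suffix(".manifest.json").read_text())
        registry = AlleleRegistry(
            manifest["loci"], manifest["ploidy"], manifest["alleles"]
        )
        sites = tuple(SamplingSite(**s) for s in manifest["sites"])
        return cls(
            sites=sites,
            registry=registry,
            latents=data["latents"],
            mus=data["mus"],
            params=data["params"],
            run_index=data["run_index"],
            config=McmcConfig(**manifest["config"]),
            diagnostics=manifest.get("diagnostics", {}),
        )


def _masked_log_softmax(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Log-softmax over the allele axis of ``(L, A, S)`` with invalid slots -inf."""
    xm = np.where(mask[:, :, None], x, -np.inf)
    m = xm.max(axis=1, keepdims=True)
    e = np.exp(xm - m)  # exp(-inf) == 0 at masked slots
    return xm - (m + np.log(e.sum(axis=1, keepdims=True)))


def _loglik_per_locus(n: np.ndarray, logp: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood term per locus given counts and log-freqs."""
    lp = np.where(mask[:, :, None], logp, 0.0)
    return np.einsum("las,las->l", n, lp)


class _ChainState:
    """Mutable sampler state for one run (internal)."""

    def __init__(self, x, mu, params, dist, counts, mask, priors):
        self.x = x  # (L, A, S) latents, garbage at masked slots
        self.mu = mu  # (L, A)
        self.params = params
        self.dist = dist
        self.counts = counts
        self.mask = mask
        self.priors = priors
        self.refresh_cov()
        self.refresh_likelihood()

    def refresh_cov(self) -> None:
        c = self.params.beta_sill * np.exp(-self.dist / self.params.alpha)
        c[np.diag_indices_from(c)] += self.params.tau2
        sign, logdet = np.linalg.slogdet(c)
        if sign <= 0:
            raise np.linalg.LinAlgError("covariance not positive definite")
        self.cinv = np.linalg.inv(c)
        self.logdet = logdet

    def refresh_likelihood(self) -> None:
        self.logp = _masked_log_softmax(self.x, self.mask)
        self.ll = _loglik_per_locus(self.counts, self.logp, self.mask)

    def row_quads(self, x=None, mu=None) -> np.ndarray:
        """Prior quadratic forms per valid (locus, allele) row, (R,)."""
        x = self.x if x is None else x
        mu = self.mu if mu is None else mu
        v = (x - mu[:, :, None])[self.mask]  # (R, S)
        return np.einsum("rs,st,rt->r", v, self.cinv, v)


def fit_surfaces_mcmc(
    table: GenotypeTable,
    sites: Sequence[SamplingSite],
    cfg: McmcConfig,
    priors: Priors | None = None,
    registry: AlleleRegistry | None = None,
    init_params: SurfaceParams | None = None,
) -> FrequencySurface:
    """Posterior sampling of the allele-frequency surfaces.

    Metropolis-within-Gibbs: site-block random-walk proposals per
    locus-allele latent row (batched over loci, which are conditionally
    independent), elementwise random walks on the per-row means, and
    log-scale random walks on alpha, beta_sill and tau2.  Each run gets a
    deterministic child seed of ``cfg.seed``; ``cfg.iterations`` states are
    retained per run, keeping every ``cfg.thinning``-th proposal cycle
    after ``cfg.burn_in`` cycles.
    """
    sites = tuple(sites)
    if len(sites) < 1:
        raise ValueError("at least one site required")
    priors = priors or Priors()
    registry = registry or AlleleRegistry.from_tables(table)
    counts = registry.site_counts(table, len(sites))
    if not (counts.sum(axis=(0, 1)) > 0).sum() >= 1:
        raise ValueError("no typed reference samples at any site")

    coords = _site_coords(sites)
    dist = pairwise_great_circle_km(coords, coords)
    mask = registry.mask
    n_sites = len(sites)
    L, A = mask.shape
    init_params = init_params or SurfaceParams(
        alpha=math.exp(priors.log_alpha_mean),
        beta_sill=math.exp(priors.log_beta_mean),
        tau2=math.exp(priors.log_tau2_mean),
    )

    all_latents, all_mus, all_params, all_runs = [], [], [], []
    acc_rates = []
    rows_for_a = [np.nonzero(mask[:, a])[0] for a in range(A)]

    for run in range(cfg.runs):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(run,)))
        x0 = np.zeros((L, A, n_sites))
        mu0 = np.zeros((L, A))
        state = _ChainState(
            x0 + 0.1 * rng.standard_normal(x0.shape), mu0, init_params, dist, counts, mask, priors
        )
        lat, mus, pars = _run_chain(state, cfg, priors, rng, rows_for_a)
        all_latents.append(lat)
        all_mus.append(mus)
        all_params.append(pars)
        all_runs.append(np.full(len(lat), run))
        acc_rates.append(state.final_acc)

    acc = np.array(acc_rates)
    diag = {"acceptance_rates": acc.tolist()}
    if np.any(acc < 0.05) or np.any(acc > 0.95):
        warnings.warn(
            f"MCMC acceptance rates outside [0.05, 0.95]: {acc.round(3).tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    return FrequencySurface(
        sites=sites,
        registry=registry,
        latents=np.concatenate(all_latents),
        mus=np.concatenate(all_mus),
        params=np.concatenate(all_params),
        run_index=np.concatenate(all_runs),
        config=cfg,
        diagnostics=diag,
    )


def _run_chain(state: _ChainState, cfg: McmcConfig, priors: Priors, rng, rows_for_a):
    mask = state.mask
    L, A = mask.shape
    S = state.dist.shape[0]
    step_x = np.full(A, 0.5)
    step_mu = 0.5
    step_hyper = np.array([0.3, 0.3, 0.3])  # log alpha, log beta, log tau2
    acc_x = np.zeros(A)
    try_x = np.zeros(A)
    acc_total = 0.0
    try_total = 0.0

    total_cycles = cfg.burn_in + cfg.iterations * cfg.thinning
    keep_lat = np.empty((cfg.iterations, L, A, S))
    keep_mu = np.empty((cfg.iterations, L, A))
    keep_par = np.empty((cfg.iterations, 3))
    kept = 0

    quads = state.row_quads()  # cached prior quadratic forms (R,)
    row_locus = np.nonzero(mask)[0]  # locus id of each valid row
    # row lookup: for allele-step a, which rows of the (R,) layout are touched
    flat_index = np.full((L, A), -1, dtype=int)
    flat_index[mask] = np.arange(mask.sum())

    for cycle in range(total_cycles):
        in_burn = cycle < cfg.burn_in
        # --- latent rows, one allele slot at a time, batched over loci ---
        for a in range(A):
            rows = rows_for_a[a]
            if rows.size == 0:
                continue
            prop = state.x[rows, a, :] + step_x[a] * rng.standard_normal((rows.size, S))
            x_new = state.x[rows].copy()  # (n, A, S)
            x_new[:, a, :] = prop
            logp_new = _masked_log_softmax(x_new, mask[rows])
            ll_new = _loglik_per_locus(state.counts[rows], logp_new, mask[rows])
            v = prop - state.mu[rows, a][:, None]
            q_new = np.einsum("rs,st,rt->r", v, state.cinv, v)
            r_idx = flat_index[rows, a]
            log_acc = (ll_new - state.ll[rows]) - 0.5 * (q_new - quads[r_idx])
            accept = np.log(rng.random(rows.size)) < log_acc
            if accept.any():
                sel = rows[accept]
                state.x[sel, a, :] = prop[accept]
                state.logp[sel] = logp_new[accept]
                state.ll[sel] = ll_new[accept]
                quads[r_idx[accept]] = q_new[accept]
            try_x[a] += rows.size
            acc_x[a] += accept.sum()
            try_total += rows.size
            acc_total += accept.sum()

        # --- per-row means (elementwise, conditionally independent) ---
        mu_flat = state.mu[mask]
        prop_mu = mu_flat + step_mu * rng.standard_normal(mu_flat.size)
        x_rows = state.x[mask]  # (R, S)
        v_new = x_rows - prop_mu[:, None]
        q_new = np.einsum("rs,st,rt->r", v_new, state.cinv, v_new)
        dprior = -0.5 * (prop_mu**2 - mu_flat**2) / priors.mu_sd**2
        log_acc = -0.5 * (q_new - quads) + dprior
        accept = np.log(rng.random(mu_flat.size)) < log_acc
        if accept.any():
            mu_flat = np.where(accept, prop_mu, mu_flat)
            state.mu[mask] = mu_flat
            quads = np.where(accept, q_new, quads)

        # --- hyperparameters (log-scale random walks) ---
        if priors.update_params:
            quads = _update_hypers(state, quads, step_hyper, priors, rng)

        if in_burn and (cycle + 1) % 25 == 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                rate = np.where(try_x > 0, acc_x / np.maximum(try_x, 1), 0.3)
            step_x *= np.exp(np.clip(rate - 0.3, -0.5, 0.5))
            acc_x[:] = 0.0
            try_x[:] = 0.0

        if not in_burn and (cycle + 1 - cfg.burn_in) % cfg.thinning == 0 and kept < cfg.iterations:
            keep_lat[kept] = state.x
            keep_mu[kept] = state.mu
            keep_par[kept] = (state.params.alpha, state.params.beta_sill, state.params.tau2)
            kept += 1

    state.final_acc = acc_total / max(try_total, 1.0)
    return keep_lat[:kept], keep_mu[:kept], keep_par[:kept]


def _update_hypers(state: _ChainState, quads: np.ndarray, steps: np.ndarray, priors: Priors, rng):
    """Joint log-scale random-walk update of (alpha, beta_sill, tau2)."""
    n_rows = quads.size
    p = state.params
    cur = np.array([p.alpha, p.beta_sill, max(p.tau2, 0.0)])
    fixed_tau = p.tau2 <= 0  # tau2 == 0 stays fixed (log walk undefined)
    log_cur = np.log(np.where(cur > 0, cur, 1.0))
    log_new = log_cur + steps * rng.standard_normal(3)
    if fixed_tau:
        log_new[2] = log_cur[2]
    cand = SurfaceParams(
        alpha=math.exp(log_new[0]),
        beta_sill=math.exp(log_new[1]),
        tau2=0.0 if fixed_tau else math.exp(log_new[2]),
    )
    old_cinv, old_logdet, old_params = state.cinv, state.logdet, state.params
    state.params = cand
    try:
        state.refresh_cov()
    except np.linalg.LinAlgError:
        state.params, state.cinv, state.logdet = old_params, old_cinv, old_logdet
        return quads
    q_new = state.row_quads()
    means = np.array([priors.log_alpha_mean, priors.log_beta_mean, priors.log_tau2_mean])
    sds = np.array([priors.log_alpha_sd, priors.log_beta_sd, priors.log_tau2_sd])
    active = slice(0, 2) if fixed_tau else slice(0, 3)
    dprior = float(
        np.sum(-0.5 * ((log_new[active] - means[active]) / sds[active]) ** 2)
        - np.sum(-0.5 * ((log_cur[active] - means[active]) / sds[active]) ** 2)
    )
    log_acc = (
        -0.5 * (q_new.sum() - quads.sum())
        - 0.5 * n_rows * (state.logdet - old_logdet)
        + dprior
    )
    if math.log(rng.random()) < log_acc:
        return q_new
    state.params, state.cinv, state.logdet = old_params, old_cinv, old_logdet
    return quads


def krige_latent(
    surface: FrequencySurface, draw: int, query: Sequence[float]
) -> np.ndarray:
    """Conditional mean of the latent fields at ``query`` for one draw.

    Standard conditional-normal interpolation given the anchor latents
    under the draw's covariance; deterministic given the draw.  Returns
    the ``(L, A)`` latent matrix at the query point.
    """
    lat, lon = float(query[0]), float(query[1])
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ValueError("query coordinates must be finite")
    params = surface.draw_params(draw)
    coords = _site_coords(surface.sites)
    c = covariance_matrix(surface.sites, params)
    try:
        chol = cho_factor(c, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("anchor covariance is singular") from exc
    k = params.beta_sill * np.exp(
        -pairwise_great_circle_km(np.array([[lat, lon]]), coords)[0] / params.alpha
    )
    w = cho_solve(chol, k)  # (S,)
    mu = surface.mus[draw]  # (L, A)
    centered = surface.latents[draw] - mu[:, :, None]  # (L, A, S)
    return mu + centered @ w
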