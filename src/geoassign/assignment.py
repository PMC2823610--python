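"""Assignment of unknown-origin samples to sites (SAM) or coordinates (CAM).

SAM scores each reference site by the posterior-mean genotype
log-likelihood of the query under the fitted frequency surface and forms a
multi-run consensus.  CAM runs a Metropolis random walk over candidate
coordinates constrained to a boundary polygon, evaluating the query
likelihood at frequencies interpolated from the surface draws, and
summarises the pooled chain by a component-wise median plus weighted
confidence draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .io_formats import SampleRecord
from .spatial import (
    FrequencySurface,
    McmcConfig,
    _masked_log_softmax,
    pairwise_great_circle_km,
)

__all__ = [
    "BoundaryPolygon",
    "SamAssignment",
    "CamAssignment",
    "point_in_polygon",
    "sam_assign",
    "cam_assign",
    "median_point",
    "confidence_draws",
]


@dataclass(frozen=True)
class BoundaryPolygon:
    """Ordered (lat, lon) vertex list; closed implicitly if needed."""

    vertices: tuple[tuple[float, float], ...]
    _poly: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        verts = [tuple(map(float, v)) for v in self.vertices]
        if verts and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(set(verts)) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValueError("polygon is invalid (self-intersecting or degenerate)")
        object.__setattr__(self, "_poly", poly)
        object.__setattr__(self, "vertices", tuple(tuple(v) for v in verts))

    @property
    def shapely(self) -> Polygon:
        return self._poly

    def contains(self, lat: float, lon: float) -> bool:
        """Membership test; boundary points count as inside."""
        return bool(self._poly.covers(Point(lat, lon)))

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max)."""
        minx, miny, maxx, maxy = self._poly.bounds
        return minx, maxx, miny, maxy


def point_in_polygon(p: Sequence[float], poly: BoundaryPolygon) -> bool:
    """True when (lat, lon) point ``p`` lies inside or on ``poly``."""
    return poly.contains(float(p[0]), float(p[1]))


@dataclass(frozen=True)
class SamAssignment:
    """Per-site scores and multi-run consensus for one query sample."""

    sample_id: str
    site_codes: tuple[str, ...]
    mean_loglik: np.ndarray  # (S,) mean over all retained draws, all runs
    run_best: tuple[str, ...]  # best site code per run
    consensus_site: str
    agreement: int  # runs voting for the consensus site

    @property
    def mean_llr(self) -> float:
        """Consensus site's mean log-likelihood minus the best alternative's."""
        order = np.argsort(self.mean_loglik)[::-1]
        best, second = order[0], order[1] if len(order) > 1 else order[0]
        i = self.site_codes.index(self.consensus_site)
        rival = second if i == best else best
        return float(self.mean_loglik[i] - self.mean_loglik[rival])


@dataclass(frozen=True)
class CamAssignment:
    """Pooled coordinate chain and its median point estimate."""

    sample_id: str
    chain: np.ndarray  # (runs * iterations, 2) of (lat, lon)
    median_estimate: tuple[float, float]
    run_index: np.ndarray  # (runs * iterations,)
    acceptance_rates: tuple[float, ...]


def _query_scores(query: SampleRecord, surface: FrequencySurface) -> np.ndarray:
    """Per-draw, per-site log-likelihood matrix (D, S) for the query."""
    nq, const = surface.registry.query_counts(query)
    if nq.sum() == 0:
        raise ValueError(f"query {query.id!r} has no typed loci")
    mask = surface.registry.mask
    d, s = surface.n_draws, len(surface.sites)
    scores = np.empty((d, s))
    for i in range(d):
        lp = np.where(mask[:, :, None], surface.log_freqs(i), 0.0)
        scores[i] = np.einsum("las,la->s", lp, nq)
    return scores + const


def sam_assign(
    query: SampleRecord,
    surface: FrequencySurface,
    cfg: McmcConfig | None = None,
) -> SamAssignment:
    """Assign ``query`` to one of the surface's reference sites.

    Per run, the score of a site is the mean over that run's retained
    draws of the genotype log-likelihood at the site; the consensus is the
    majority of per-run best sites, ties broken by the highest mean
    log-likelihood across all runs.
    """
    del cfg  # the run structure is carried by the surface itself
    scores = _query_scores(query, surface)
    codes = tuple(s.code for s in surface.sites)
    runs = np.unique(surface.run_index)
    run_means = np.stack(
        [scores[surface.run_index == r].mean(axis=0) for r in runs]
    )  # (runs, S)
    run_best = tuple(codes[int(i)] for i in run_means.argmax(axis=1))
    mean_ll = scores.mean(axis=0)

    votes: dict[str, int] = {}
    for c in run_best:
        votes[c] = votes.get(c, 0) + 1
    top = max(votes.values())
    tied = [c for c, v in votes.items() if v == top]
    consensus = max(tied, key=lambda c: mean_ll[codes.index(c)])
    return SamAssignment(
        sample_id=query.id,
        site_codes=codes,
        mean_loglik=mean_ll,
        run_best=run_best,
        consensus_site=consensus,
        agreement=votes[consensus],
    )


class _DrawCache:
    """Per-draw quantities needed to evaluate the query likelihood anywhere."""

    def __init__(self, surface: FrequencySurface, nq: np.ndarray):
        self.typed = np.nonzero(nq.sum(axis=1) > 0)[0]
        self.nq = nq[self.typed]
        self.mask = surface.registry.mask[self.typed]
        coords = np.array([[s.latitude, s.longitude] for s in surface.sites])
        self.coords = coords
        self.surface = surface
        self._cache: dict[int, tuple] = {}

    def get(self, d: int):
        hit = self._cache.get(d)
        if hit is not None:
            return hit
        surf = self.surface
        alpha, beta, tau2 = surf.params[d]
        dist = pairwise_great_circle_km(self.coords, self.coords)
        c = beta * np.exp(-dist / alpha)
        c[np.diag_indices_from(c)] += tau2
        cinv = np.linalg.inv(c)
        mu = surf.mus[d][self.typed]  # (T, A)
        centered = surf.latents[d][self.typed] - mu[:, :, None]  # (T, A, S)
        entry = (float(alpha), float(beta), cinv, mu, centered)
        self._cache[d] = entry
        return entry

    def loglik(self, d: int, lat: float, lon: float) -> float:
        alpha, beta, cinv, mu, centered = self.get(d)
        dq = pairwise_great_circle_km(np.array([[lat, lon]]), self.coords)[0]
        k = beta * np.exp(-dq / alpha)
        w = cinv @ k
        latent = mu + centered @ w  # (T, A)
        lp = _masked_log_softmax(latent[:, :, None], self.mask)[:, :, 0]
        return float(np.sum(self.nq * np.where(self.mask, lp, 0.0)))


def cam_assign(
    query: SampleRecord,
    surface: FrequencySurface,
    boundary: BoundaryPolygon,
    cfg: McmcConfig | None = None,
    initial_step_deg: float = 0.5,
) -> CamAssignment:
    """Metropolis random walk over candidate origins inside ``boundary``.

    Proposals are spherical-Gaussian steps in degrees, rejected outright
    outside the polygon; the step size adapts toward 20-50% acceptance
    during burn-in and is frozen afterwards.  The surface posterior is
    consumed cyclically, one draw per proposal cycle.  The retained chain
    pools ``cfg.runs`` runs of ``cfg.iterations`` states each.
    """
    cfg = cfg or surface.config
    nq, const = surface.registry.query_counts(query)
    if nq.sum() == 0:
        raise ValueError(f"query {query.id!r} has no typed loci")
    del const  # constant in the target, irrelevant to the walk
    cache = _DrawCache(surface, nq)
    lat_min, lat_max, lon_min, lon_max = boundary.bounding_box()
    n_draws = surface.n_draws

    chains = []
    run_ids = []
    acc_rates = []
    for run in range(cfg.runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(run, 104729))
        )
        cur = None
        for _ in range(1000):
            cand = (
                rng.uniform(lat_min, lat_max),
                rng.uniform(lon_min, lon_max),
            )
            if boundary.contains(*cand):
                cur = cand
                break
        if cur is None:
            raise RuntimeError(
                "could not initialize CAM chain: no interior point in 1000 bounding-box draws"
            )
        step = initial_step_deg
        total = cfg.burn_in + cfg.iterations * cfg.thinning
        kept = np.empty((cfg.iterations, 2))
        n_kept = 0
        accepted = 0
        window_acc = 0
        window_n = 0
        cur_ll = None
        cur_draw = -1
        for cycle in range(total):
            d = cycle % n_draws
            if d != cur_draw:
                cur_ll = cache.loglik(d, *cur)
                cur_draw = d
            prop = (
                cur[0] + step * rng.standard_normal(),
                cur[1] + step * rng.standard_normal(),
            )
            window_n += 1
            if boundary.contains(*prop):
                prop_ll = cache.loglik(d, *prop)
                if math.log(rng.random()) < prop_ll - cur_ll:
                    cur, cur_ll = prop, prop_ll
                    accepted += 1
                    window_acc += 1
            in_burn = cycle < cfg.burn_in
            if in_burn and window_n >= 25:
                rate = window_acc / window_n
                if rate < 0.20:
                    step *= 0.7
                elif rate > 0.50:
                    step *= 1.4
                window_acc = 0
                window_n = 0
            if not in_burn and (cycle + 1 - cfg.burn_in) % cfg.thinning == 0 and n_kept < cfg.iterations:
                kept[n_kept] = cur
                n_kept += 1
        chains.append(kept[:n_kept])
        run_ids.append(np.full(n_kept, run))
        acc_rates.append(accepted / total)

    chain = np.concatenate(chains)
    return CamAssignment(
        sample_id=query.id,
        chain=chain,
        median_estimate=median_point(chain),
        run_index=np.concatenate(run_ids),
        acceptance_rates=tuple(acc_rates),
    )


def median_point(chain: np.ndarray) -> tuple[float, float]:
    """Component-wise median of a (n, 2) coordinate chain."""
    chain = np.asarray(chain, dtype=float)
    if chain.size == 0:
        raise ValueError("empty coordinate chain")
    return float(np.median(chain[:, 0])), float(np.median(chain[:, 1]))


def confidence_draws(chain: np.ndarray, n: int = 100, seed: int = 0) -> np.ndarray:
    """``n`` uniform with-replacement draws from the retained chain.

    The chain is already posterior-weighted, so uniform resampling yields
    probability-weighted confidence coordinates.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.size == 0:
        raise ValueError("empty coordinate chain")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(chain), size=n)
    return chain[idx]
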