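"""Evaluation suite for the assignment methods.

Leave-one-out cross-validation, confusion matrices with location/region
accuracies, empirical distance quantiles, zone containment of
estimate-to-truth segments, mtDNA concordance, and the negative-control
draw-fraction t-test.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import BoundaryPolygon, CamAssignment, cam_assign, point_in_polygon, sam_assign
from .io_formats import (
    HAPLOGROUP_CODES,
    NORTH,
    SOUTH,
    TRANSITION,
    UNKNOWN_HAPLOGROUP,
    GenotypeTable,
    SamplingSite,
)
from .spatial import AlleleRegistry, McmcConfig, Priors, fit_surfaces_mcmc, great_circle_km

__all__ = [
    "Assignment",
    "ConfusionMatrix",
    "ValidationReport",
    "loocv",
    "summarize_confusion",
    "distance_quantiles",
    "zone_containment",
    "mtdna_concordance",
    "negative_control_test",
    "haplogroup_region",
    "round_half_up_pct",
]

#: Haplogroup -> expected region side of the barrier.
_HAPLOGROUP_REGION = {"1a": NORTH, "1b": NORTH, "2a": SOUTH, "2b": SOUTH, "2c": SOUTH}


def haplogroup_region(label: str) -> str:
    """Region a haplogroup implies (1a/1b North, 2a/2b/2c South)."""
    try:
        return _HAPLOGROUP_REGION[label]
    except KeyError as exc:
        raise ValueError(f"no region mapping for haplogroup {label!r}") from exc


def round_half_up_pct(numerator: float, denominator: float) -> int:
    """Integer percent with half-up rounding (62.5 -> 63), as printed tables use."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator in percentage")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class Assignment:
    """One held-out or unknown sample's outcome."""

    sample_id: str
    true_site: str | None  # site code; None for genuine unknowns
    assigned_site: str | None  # SAM consensus code
    estimate: tuple[float, float] | None = None  # CAM median (lat, lon)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row = true site, column = assigned site, integer counts."""

    counts: pd.DataFrame
    location_accuracy: pd.Series  # per-row integer percent
    region_accuracy: pd.Series
    overall_location: int
    overall_region: int

    def __str__(self) -> str:  # printed in the familiar table layout
        out = self.counts.copy()
        out["Location%"] = self.location_accuracy
        out["Region%"] = self.region_accuracy
        return out.to_string()


@dataclass(frozen=True)
class ValidationReport:
    confusion: ConfusionMatrix | None
    distance_quantiles_km: dict[float, float] | None
    zone_containment_pct: int | None
    concordance_pct: int | None
    negative_control: tuple[float, float, float] | None  # (t, df, p)

    def to_text(self) -> str:
        lines = ["# validation report"]
        if self.confusion is not None:
            lines += ["", "## SAM confusion matrix", str(self.confusion),
                      f"overall location accuracy: {self.confusion.overall_location}%",
                      f"overall region accuracy: {self.confusion.overall_region}%"]
        if self.distance_quantiles_km is not None:
            lines += ["", "## CAM distance quantiles (km)"]
            lines += [f"  {int(q * 100)}%: {v:.1f}" for q, v in sorted(self.distance_quantiles_km.items())]
        if self.zone_containment_pct is not None:
            lines.append(f"zone containment: {self.zone_containment_pct}%")
        if self.concordance_pct is not None:
            lines.append(f"mtDNA concordance: {self.concordance_pct}%")
        if self.negative_control is not None:
            t, df, p = self.negative_control
            lines.append(f"negative control: t={t:.3f} df={df:.1f} p={p:.3g}")
        return "\n".join(lines) + "\n"


def _sample_seed(base_seed: int, sample_id: str) -> int:
    """Order-independent per-sample seed derived from the id."""
    return (base_seed << 32) ^ zlib.crc32(sample_id.encode())


def loocv(
    table: GenotypeTable,
    sites: Sequence[SamplingSite],
    method: str,
    cfg: McmcConfig,
    priors: Priors | None = None,
    boundary: BoundaryPolygon | None = None,
    sample_ids: Iterable[str] | None = None,
) -> list[Assignment]:
    """Leave-one-out cross-validation over the georeferenced samples.

    Each selected sample is held out, the surfaces are refitted without
    it, and it is reassigned by ``method`` ("SAM" or "CAM").  A site
    emptied by the hold-out keeps its coordinates and simply contributes
    no data.  Per-sample seeds derive from the sample id, so results do
    not depend on dataset ordering.
    """
    method = method.upper()
    if method not in ("SAM", "CAM"):
        raise ValueError("method must be 'SAM' or 'CAM'")
    if method == "CAM" and boundary is None:
        raise ValueError("CAM cross-validation needs a boundary polygon")
    if len(sites) < 2:
        raise ValueError("at least two sites required")
    registry = AlleleRegistry.from_tables(table)
    code_of = {s.index: s.code for s in sites}
    wanted = set(sample_ids) if sample_ids is not None else None

    results = []
    for rec in table.samples:
        if rec.unknown_origin:
            continue
        if wanted is not None and rec.id not in wanted:
            continue
        sub = table.drop(rec.id)
        cfg_i = replace(cfg, seed=_sample_seed(cfg.seed, rec.id))
        surface = fit_surfaces_mcmc(sub, sites, cfg_i, priors=priors, registry=registry)
        true_code = code_of[rec.site_index]
        if method == "SAM":
            sam = sam_assign(rec, surface)
            results.append(Assignment(rec.id, true_code, sam.consensus_site))
        else:
            cam = cam_assign(rec, surface, boundary, cfg_i)
            results.append(Assignment(rec.id, true_code, None, cam.median_estimate))
    results.sort(key=lambda a: a.sample_id)
    return results


def summarize_confusion(
    assignments: Iterable[Assignment],
    sites: Sequence[SamplingSite],
    transition_region: str = NORTH,
    overall_denominator: int | None = None,
) -> ConfusionMatrix:
    """Confusion matrix plus per-row and overall accuracies.

    Region scoring maps Transition-zone sites to ``transition_region``.
    ``overall_denominator`` overrides the matrix total in the *overall*
    percentages only, for comparison against reports whose stated sample
    count differs from their tabulated assignment count; per-row
    accuracies always use row sums.
    """
    codes = [s.code for s in sites]
    region = {s.code: s.region(transition_region) for s in sites}
    counts = pd.DataFrame(0, index=codes, columns=codes, dtype=int)
    for a in assignments:
        if a.true_site not in region or a.assigned_site not in region:
            raise ValueError(f"assignment references unknown site: {a}")
        counts.loc[a.true_site, a.assigned_site] += 1

    loc_acc = {}
    reg_acc = {}
    diag_total = 0
    region_total = 0
    grand = int(counts.to_numpy().sum())
    for code in codes:
        row = counts.loc[code]
        n = int(row.sum())
        if n == 0:
            loc_acc[code] = 0
            reg_acc[code] = 0
            continue
        good_loc = int(row[code])
        good_reg = int(sum(v for c, v in row.items() if region[c] == region[code]))
        loc_acc[code] = round_half_up_pct(good_loc, n)
        reg_acc[code] = round_half_up_pct(good_reg, n)
        diag_total += good_loc
        region_total += good_reg
    denom = overall_denominator if overall_denominator is not None else grand
    return ConfusionMatrix(
        counts=counts,
        location_accuracy=pd.Series(loc_acc),
        region_accuracy=pd.Series(reg_acc),
        overall_location=round_half_up_pct(diag_total, denom),
        overall_region=round_half_up_pct(region_total, denom),
    )


def distance_quantiles(
    estimates: Mapping[str, tuple[float, float]],
    truths: Mapping[str, tuple[float, float]],
    probs: Sequence[float] = (0.3, 0.5, 0.8),
) -> dict[float, float]:
    """Empirical-CDF-inverted error quantiles in km.

    The quantile at ``q`` is the smallest observed error ``e`` such that
    the fraction of errors <= ``e`` reaches ``q`` (no interpolation).
    """
    shared = sorted(set(estimates) & set(truths))
    if not shared:
        raise ValueError("no shared sample ids between estimates and truths")
    errors = np.sort([great_circle_km(estimates[i], truths[i]) for i in shared])
    n = len(errors)
    out = {}
    for q in probs:
        if not 0.0 < q <= 1.0:
            raise ValueError(f"quantile prob {q} outside (0, 1]")
        out[q] = float(errors[math.ceil(q * n) - 1])
    return out


def zone_containment(
    estimate: Sequence[float],
    truth: Sequence[float],
    zone_polygons: Mapping[str, BoundaryPolygon],
    n_points: int = 101,
) -> bool:
    """True when the estimate-to-truth segment stays in the truth's zone.

    The great-circle segment is sampled at ``n_points`` evenly spaced
    points (spherical interpolation) and every point must fall inside the
    single zone polygon containing the truth.
    """
    home = [z for z, poly in zone_polygons.items() if point_in_polygon(truth, poly)]
    if len(home) != 1:
        raise ValueError(f"truth point lies in {len(home)} zones, expected exactly 1")
    poly = zone_polygons[home[0]]
    for lat, lon in _great_circle_points(truth, estimate, n_points):
        if not poly.contains(lat, lon):
            return False
    return True


def _great_circle_points(a: Sequence[float], b: Sequence[float], n: int) -> np.ndarray:
    """Spherical linear interpolation between two (lat, lon) points."""

    def to_xyz(p):
        phi, lam = math.radians(p[0]), math.radians(p[1])
        return np.array([math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)])

    va, vb = to_xyz(a), to_xyz(b)
    dot = float(np.clip(va @ vb, -1.0, 1.0))
    omega = math.acos(dot)
    ts = np.linspace(0.0, 1.0, n)
    if omega < 1e-12:
        pts = np.tile(va, (n, 1))
    else:
        pts = (
            np.sin((1 - ts)[:, None] * omega) * va[None, :] + np.sin(ts[:, None] * omega) * vb[None, :]
        ) / math.sin(omega)
    lat = np.degrees(np.arcsin(np.clip(pts[:, 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(pts[:, 1], pts[:, 0]))
    return np.column_stack([lat, lon])


def mtdna_concordance(
    assigned_region: Mapping[str, str],
    haplogroups: Mapping[str, str],
    include_transition: bool = False,
) -> tuple[int, dict[str, int]]:
    """Percent agreement between haplogroup-implied and assigned regions.

    Samples with unknown haplogroups are skipped.  Transition-region
    assignments are excluded from the default tally; with
    ``include_transition`` they count as discordant (a transition
    assignment matches neither haplogroup side).  Returns the headline
    percent plus a detail dict with both tallies.
    """
    shared = sorted(set(assigned_region) & set(haplogroups))
    usable = [i for i in shared if haplogroups[i] != UNKNOWN_HAPLOGROUP]
    if not usable:
        raise ValueError("no samples with known haplogroups to compare")
    concordant = 0
    n_excl = 0
    concordant_incl = 0
    n_incl = 0
    for i in usable:
        expected = haplogroup_region(haplogroups[i])
        got = assigned_region[i]
        n_incl += 1
        if got == expected:
            concordant_incl += 1
        if got == TRANSITION:
            continue
        n_excl += 1
        concordant += got == expected
    detail = {
        "concordant_excluding_transition": concordant,
        "n_excluding_transition": n_excl,
        "concordant_including_transition": concordant_incl,
        "n_including_transition": n_incl,
    }
    if include_transition:
        return round_half_up_pct(concordant_incl, n_incl), detail
    if n_excl == 0:
        raise ValueError("all assignments fell in the transition zone")
    return round_half_up_pct(concordant, n_excl), detail


def negative_control_test(
    test_fractions: Sequence[float], control_fractions: Sequence[float]
) -> tuple[float, float, float]:
    """Welch two-sample t-test on per-sample draw fractions.

    Compares the fraction of coordinate draws falling inside a target
    subregion between a test group and a negative-control group.
    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    x = np.asarray(test_fractions, dtype=float)
    y = np.asarray(control_fractions, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least two samples")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def draw_fraction_inside(chain: np.ndarray, poly: BoundaryPolygon) -> float:
    """Fraction of chain coordinates inside ``poly`` (negative-control input)."""
    chain = np.asarray(chain, dtype=float)
    return float(np.mean([poly.contains(lat, lon) for lat, lon in chain]))


def distance_to_polygons(
    point: Sequence[float],
    polygons: Iterable[BoundaryPolygon],
    boundary_samples: int = 50,
) -> float:
    """Great-circle km from ``point`` to the nearest polygon (0 if inside).

    Generic hook for 'inside or within X km of a protected area' style
    queries; the caller supplies the polygon set.  Boundary distance is
    approximated by sampling each edge at ``boundary_samples`` points.
    """
    best = math.inf
    found = False
    for poly in polygons:
        found = True
        if point_in_polygon(point, poly):
            return 0.0
        verts = list(poly.vertices)
        for (a_lat, a_lon), (b_lat, b_lon) in zip(verts, verts[1:] + verts[:1]):
            for t in np.linspace(0.0, 1.0, boundary_samples):
                edge_pt = (a_lat + t * (b_lat - a_lat), a_lon + t * (b_lon - a_lon))
                best = min(best, great_circle_km(point, edge_pt))
    if not found:
        raise ValueError("no polygons supplied")
    return best
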