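"""Harvest-threshold sensitivity analysis.

The feasibility question is threshold-based: for each demographic parameter
(egg survival, juvenile survival, adult survival, fecundity), how far can it
be reduced — all other parameters held constant — before the intrinsic rate
of increase ``r = ln(lambda)`` turns negative?  The threshold (``r_min``
value) is where ``lambda = 1``, equivalently where the reproductive loop
product balances the stay probabilities:

    F G1 G2 = (1 - P1)(1 - P2)

The percent margin ``100 (predicted - threshold) / predicted`` is the
proportional harvest headroom for that parameter.  Uncertainty bands around
the swept r-curves come from jackknife randomizations that redraw the
non-focal parameters from the spread of species-level values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import (
    ConventionFlags,
    DemographicParams,
    build_matrix,
    dominant_lambda,
    elasticities,
    with_survival,
)

__all__ = [
    "FOCAL_PARAMETERS",
    "SweepResult",
    "HarvestMargins",
    "default_grid",
    "sweep",
    "r_min",
    "margins",
    "jackknife_bands",
    "convention_search",
    "round_half_away",
]

FOCAL_PARAMETERS = (
    "egg_survival",
    "juvenile_survival",
    "adult_survival",
    "fecundity",
)

_PARAM_ATTR = {
    "egg_survival": "p_egg",
    "juvenile_survival": "p_juv",
    "adult_survival": "p_adult",
    "fecundity": "fecundity",
}


def _r_at(
    params: DemographicParams,
    focal: str,
    value: float,
    conv: ConventionFlags,
) -> float:
    """r with the focal parameter set to *value* (others fixed).

    A fecundity of exactly 0 breaks the reproductive loop; the growth rate is
    then set by persistence alone, ``r = ln max(P1, P2)`` (the cubic's largest
    root with zero constant term), handled as an explicit limit.
    """
    p = with_survival(params, focal, value, conv)
    if focal == "fecundity" and value == 0.0:
        q = with_survival(params, focal, 1e-12, conv)
        A = build_matrix(q, conv)
        return math.log(max(A.P1, A.P2))
    A = build_matrix(p, conv)
    return math.log(dominant_lambda(A))


def default_grid(
    params: DemographicParams, focal: str, n: int = 200
) -> np.ndarray:
    """Default sweep grid: survivals over (0.01, 0.99), fecundity over
    (0, 1.5x the current value)."""
    if focal == "fecundity":
        return np.linspace(0.0, 1.5 * params.fecundity, n)
    return np.linspace(0.01, 0.99, n)


@dataclass
class SweepResult:
    """r as a function of one demographic parameter.

    ``band_lo``/``band_hi`` are pointwise 95% prediction limits of jackknifed
    r draws; ``ci_lo``/``ci_hi`` the 95% confidence limits of the mean r.
    All bands are None until :func:`jackknife_bands` fills them in.
    """

    focal: str
    grid: np.ndarray
    r: np.ndarray
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None


def sweep(
    params: DemographicParams,
    focal: str,
    grid: np.ndarray | None = None,
    conventions: ConventionFlags | None = None,
) -> SweepResult:
    """Compute r over a grid of one focal parameter, others held constant.

    Under the coupling convention, an adult-survival sweep re-derives
    juvenile survival by the 13%-less rule at every grid point.
    """
    if focal not in FOCAL_PARAMETERS:
        raise ValueError(
            f"focal must be one of {FOCAL_PARAMETERS}, got {focal!r}"
        )
    conv = conventions or ConventionFlags()
    if grid is None:
        grid = default_grid(params, focal)
    grid = np.asarray(grid, dtype=float)
    r = np.array([_r_at(params, focal, g, conv) for g in grid])
    return SweepResult(focal=focal, grid=grid, r=r)


def r_min(
    params: DemographicParams,
    focal: str,
    tol: float = 1e-6,
    conventions: ConventionFlags | None = None,
    domain: tuple[float, float] | None = None,
) -> float | None:
    """Threshold value of the focal parameter at which r crosses zero.

    Bisection on the monotone map focal -> r.  Returns None when r does not
    change sign over the domain ("no finite threshold"): either the
    population declines even at the domain's upper bound, or it grows
    throughout.
    """
    if focal not in FOCAL_PARAMETERS:
        raise ValueError(f"unknown focal parameter {focal!r}")
    conv = conventions or ConventionFlags()
    if domain is None:
        if focal == "fecundity":
            domain = (0.0, max(10.0 * params.fecundity, 100.0))
        else:
            domain = (1e-3, 1.0 - 1e-9)
    lo, hi = domain
    r_lo = _r_at(params, focal, lo, conv)
    r_hi = _r_at(params, focal, hi, conv)
    if r_lo > 0.0 or r_hi < 0.0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _r_at(params, focal, mid, conv) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (report convention)."""
    return int(math.floor(abs(x) + 0.5) * math.copysign(1.0, x))


@dataclass
class HarvestMargins:
    """Percent reduction each parameter can absorb before r < 0."""

    predicted: dict[str, float]
    threshold: dict[str, float | None]
    margin_percent: dict[str, int | None]


def margins(
    predicted: dict[str, float],
    thresholds: dict[str, float | None],
) -> HarvestMargins:
    """Percent margins 100*(predicted - threshold)/predicted per parameter.

    Reported margins are rounded to the nearest integer, half away from
    zero.  A parameter without a finite threshold gets margin None.
    """
    out: dict[str, int | None] = {}
    for name, pred in predicted.items():
        if pred == 0:
            raise ValueError(f"predicted value for {name} is zero")
        thr = thresholds.get(name)
        if thr is None:
            out[name] = None
        else:
            out[name] = round_half_away(100.0 * (pred - thr) / pred)
    return HarvestMargins(
        predicted=dict(predicted), threshold=dict(thresholds),
        margin_percent=out,
    )


def zone_margins(
    params: DemographicParams,
    conventions: ConventionFlags | None = None,
) -> HarvestMargins:
    """Thresholds and margins for all four focal parameters of one zone."""
    conv = conventions or ConventionFlags()
    predicted = {f: getattr(params, _PARAM_ATTR[f]) for f in FOCAL_PARAMETERS}
    thresholds = {
        f: r_min(params, f, conventions=conv) for f in FOCAL_PARAMETERS
    }
    return margins(predicted, thresholds)


def jackknife_bands(
    species_values: dict[str, np.ndarray],
    params: DemographicParams,
    focal: str,
    grid: np.ndarray | None = None,
    n_iter: int = 500,
    seed: int | np.random.Generator = 0,
    conventions: ConventionFlags | None = None,
    min_species: int = 5,
) -> SweepResult:
    """Jackknife uncertainty bands around a swept r-curve.

    Each iteration redraws every non-focal resampled parameter uniformly from
    the [2.5th, 97.5th] percentile range of its zone species-level values —
    fecundity and adult survival are resampled; juvenile survival is derived
    from the drawn adult survival by the 13%-less rule; egg survival stays at
    its fixed default.  r is recomputed over the grid per iteration.  The
    prediction band is the pointwise 2.5/97.5 percentile of r draws; the
    confidence band is mean r +/- 1.96 SD/sqrt(n_iter).

    *species_values* maps ``"fecundity"`` and ``"adult_survival"`` to arrays
    of species-level values for the zone.
    """
    conv = conventions or ConventionFlags()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if grid is None:
        grid = default_grid(params, focal)
    grid = np.asarray(grid, dtype=float)

    resampled = [
        p for p in ("fecundity", "adult_survival") if p != focal
    ]
    ranges: dict[str, tuple[float, float]] = {}
    for name in resampled:
        vals = np.asarray(species_values.get(name, ()), dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < min_species:
            raise ValueError(
                f"need >= {min_species} species values to resample "
                f"{name!r}, got {vals.size}"
            )
        ranges[name] = tuple(np.percentile(vals, [2.5, 97.5]))

    draws = np.empty((n_iter, grid.size))
    for i in range(n_iter):
        p = params
        for name in resampled:
            lo, hi = ranges[name]
            value = rng.uniform(lo, hi)
            if name == "adult_survival":
                value = min(value, 1.0 - 1e-9)
            p = with_survival(p, name, value, conv)
        draws[i] = [_r_at(p, focal, g, conv) for g in grid]

    point = np.array([_r_at(params, focal, g, conv) for g in grid])
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    mean = draws.mean(axis=0)
    half = 1.96 * draws.std(axis=0, ddof=1) / math.sqrt(n_iter)
    return SweepResult(
        focal=focal,
        grid=grid,
        r=point,
        band_lo=lo,
        band_hi=hi,
        ci_lo=mean - half,
        ci_hi=mean + half,
    )


# ---------------------------------------------------------------------------
# Convention-search diagnostic
# ---------------------------------------------------------------------------

_ELASTICITY_KEYS = (
    ("egg_survival", "egg_survival"),
    ("juvenile_P", "juvenile_P"),
    ("juvenile_G", "juvenile_G"),
    ("adult_survival", "adult_survival"),
    ("fecundity", "fecundity"),
)

_RMIN_KEYS = ("egg_survival", "juvenile_survival", "adult_survival", "fecundity")


def _all_conventions() -> list[ConventionFlags]:
    out = []
    for d_inc in (True, False):
        for ff in (0.5, 1.0):
            for couple in (True, False):
                out.append(
                    ConventionFlags(
                        d_juv_includes_egg=d_inc,
                        female_fraction=ff,
                        couple_juvenile=couple,
                    )
                )
    return out


def convention_search(
    zone_inputs: dict[str, dict[str, float]],
    targets: dict[str, dict[str, dict[str, float]]],
) -> dict:
    """Rank the 8 candidate convention combinations against reference tables.

    *zone_inputs* maps zone name -> {adult_survival, age_maturity, fecundity}
    (the predicted trait medians feeding the matrix).  *targets* maps zone ->
    {"elasticity": {...}, "r_min": {...}} with published reference cells.
    For each convention the per-zone elasticities and r-min thresholds are
    computed and compared cell-by-cell; conventions are ranked by total
    absolute deviation.  A missing threshold (no sign change) contributes the
    deviation between the reference cell and the domain edge.  The diagnostic
    never asserts an exact match — it reports which convention comes closest
    and how far off every cell is.
    """
    report: list[dict] = []
    for conv in _all_conventions():
        total = 0.0
        cells: dict[str, dict[str, dict[str, float | None]]] = {}
        for zone, inp in zone_inputs.items():
            params = DemographicParams.from_traits(
                p_adult=inp["adult_survival"],
                age_maturity=inp["age_maturity"],
                fecundity=inp["fecundity"],
                conventions=conv,
            )
            A = build_matrix(params, conv)
            el = elasticities(A)
            el_map = {
                "egg_survival": el.egg_survival,
                "juvenile_P": el.juvenile_P,
                "juvenile_G": el.juvenile_G,
                "adult_survival": el.adult_survival,
                "fecundity": el.fecundity,
            }
            zone_cells: dict[str, dict[str, float | None]] = {
                "elasticity": {},
                "r_min": {},
            }
            for key, _ in _ELASTICITY_KEYS:
                ref = targets[zone]["elasticity"][key]
                got = el_map[key]
                zone_cells["elasticity"][key] = got
                total += abs(got - ref)
            for key in _RMIN_KEYS:
                ref = targets[zone]["r_min"][key]
                thr = r_min(params, key, conventions=conv)
                zone_cells["r_min"][key] = thr
                got = thr if thr is not None else (
                    1.0 if key != "fecundity" else 0.0
                )
                total += abs(got - ref)
            cells[zone] = zone_cells
        report.append(
            {
                "convention": {
                    "d_juv_includes_egg": conv.d_juv_includes_egg,
                    "female_fraction": conv.female_fraction,
                    "couple_juvenile": conv.couple_juvenile,
                },
                "total_abs_deviation": total,
                "cells": cells,
            }
        )
    report.sort(key=lambda rec: rec["total_abs_deviation"])
    return {"ranking": report, "best": report[0]["convention"]}
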