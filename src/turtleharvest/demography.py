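"""Stage-structured matrix population model for freshwater turtles.

The life cycle has three stages — egg, juvenile, adult — projected annually
with a Lefkovitch matrix

    A = [[0,  0,  F ],
         [G1, P1, 0 ],
         [0,  G2, P2]]

where ``P`` is the annual probability of surviving and remaining in a stage,
``G`` the annual probability of surviving and advancing, and ``F`` the annual
fecundity (female eggs per adult female per year).  ``P`` and ``G`` follow the
stationary age-within-stage parameterization from a stage's annual survival
``p`` and duration ``d`` (years):

    P = p (1 - p^(d-1)) / (1 - p^d)
    G = p^d (1 - p) / (1 - p^d)

which satisfy the algebraic identity ``P + G = p`` for all valid inputs.  The
adult stage is terminal (infinite duration), so ``P_adult = p_adult`` and
there is no transition out of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConventionFlags",
    "DemographicParams",
    "StageMatrix",
    "EigenSystem",
    "ElasticityTable",
    "stage_params",
    "build_matrix",
    "eigen_analysis",
    "dominant_lambda",
    "elasticities",
    "project",
    "DEFAULT_INITIAL_PROPORTIONS",
]

#: Stable-stage proportions (egg, juvenile, adult) used as the default start
#: of a projection, with a total initial population of 1000 individuals.
DEFAULT_INITIAL_PROPORTIONS = np.array([0.544, 0.401, 0.055])

STAGE_LABELS = ("egg", "juvenile", "adult")


@dataclass(frozen=True)
class ConventionFlags:
    """Modelling conventions the source material leaves unstated.

    Parameters
    ----------
    d_juv_includes_egg
        If True (default), the juvenile stage duration is
        ``age_maturity - d_egg``: maturation age counts the year spent in the
        egg stage.  If False, ``d_juv = age_maturity``.
    female_fraction
        Fraction of eggs that are female; multiplies fecundity in the matrix.
        0.5 reflects an even primary sex ratio in a female-only model.
    couple_juvenile
        If True (default), juvenile survival is re-derived from adult survival
        by the 13%-less rule (``p_juv = 0.87 p_adult``) whenever adult survival
        is varied in a sweep or resampled in a jackknife draw.
    """

    d_juv_includes_egg: bool = True
    female_fraction: float = 0.5
    couple_juvenile: bool = True

    def d_juv(self, age_maturity: float, d_egg: float = 1.0) -> float:
        d = age_maturity - d_egg if self.d_juv_includes_egg else age_maturity
        if d <= 0:
            raise ValueError(
                f"juvenile duration {d} <= 0 for age_maturity={age_maturity}"
            )
        return d


@dataclass
class DemographicParams:
    """Inputs of the three-stage projection matrix.

    Survivals are annual probabilities, durations in years, fecundity in eggs
    per female per year (clutch size x clutch frequency, both sexes).
    """

    p_egg: float = 0.2
    p_juv: float = 0.75
    p_adult: float = 0.85
    d_egg: float = 1.0
    d_juv: float = 7.0
    fecundity: float = 14.0
    female_fraction: float = 0.5
    juvenile_factor: float = 0.87

    def validate(self) -> None:
        for name in ("p_egg", "p_juv", "p_adult"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        for name in ("d_egg", "d_juv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fecundity < 0:
            raise ValueError("fecundity must be >= 0")
        if not 0.0 < self.female_fraction <= 1.0:
            raise ValueError("female_fraction outside (0, 1]")

    @classmethod
    def from_traits(
        cls,
        *,
        p_adult: float,
        age_maturity: float,
        fecundity: float,
        p_egg: float = 0.2,
        conventions: ConventionFlags | None = None,
    ) -> "DemographicParams":
        """Derive matrix inputs from zone-level trait medians.

        Juvenile survival is 13% less than adult survival; the egg stage lasts
        one census year; juvenile duration follows the stage-duration
        convention in *conventions*.
        """
        conv = conventions or ConventionFlags()
        return cls(
            p_egg=p_egg,
            p_juv=0.87 * p_adult,
            p_adult=p_adult,
            d_egg=1.0,
            d_juv=conv.d_juv(age_maturity),
            fecundity=fecundity,
            female_fraction=conv.female_fraction,
        )


def stage_params(p: float, d: float) -> tuple[float, float]:
    """Annual stay (P) and advance (G) probabilities for one stage.

    ``P = p (1 - p^(d-1)) / (1 - p^d)`` and ``G = p^d (1 - p) / (1 - p^d)``.
    As ``p -> 1`` both expressions tend to 0/0; the continuous limits
    ``P -> p (d-1)/d`` and ``G -> p/d`` are used within 1e-9 of the pole.
    Durations need not be integers.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"survival p={p} outside (0, 1)")
    if d <= 0:
        raise ValueError(f"duration d={d} must be > 0")
    if abs(1.0 - p) < 1e-9:
        return p * (d - 1.0) / d, p / d
    pd = p**d
    denom = 1.0 - pd
    P = p * (1.0 - p ** (d - 1.0)) / denom
    G = pd * (1.0 - p) / denom
    return P, G


@dataclass
class StageMatrix:
    """3x3 projection matrix with the egg/juvenile/adult zero pattern."""

    F: float
    G1: float
    P1: float
    G2: float
    P2: float
    labels: tuple[str, str, str] = STAGE_LABELS

    def __post_init__(self) -> None:
        for name in ("F", "G1", "P1", "G2", "P2"):
            if getattr(self, name) < 0:
                raise ValueError(f"matrix entry {name} < 0")
        for name in ("G1", "P1", "G2", "P2"):
            if getattr(self, name) > 1:
                raise ValueError(f"probability entry {name} > 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [0.0, 0.0, self.F],
                [self.G1, self.P1, 0.0],
                [0.0, self.G2, self.P2],
            ]
        )

    @property
    def loop_product(self) -> float:
        """Product F*G1*G2 around the single reproductive loop."""
        return self.F * self.G1 * self.G2


def build_matrix(
    params: DemographicParams, conventions: ConventionFlags | None = None
) -> StageMatrix:
    """Assemble the projection matrix from demographic parameters.

    Egg and juvenile rows use the stationary age-within-stage equations; the
    adult stage is terminal so ``P2 = p_adult``.  Fecundity enters as
    ``F = female_fraction * fecundity`` (the matrix tracks females only).
    The *conventions* argument overrides ``params.female_fraction`` when
    given, so one parameter set can be evaluated under several conventions.
    """
    params.validate()
    ff = (
        conventions.female_fraction
        if conventions is not None
        else params.female_fraction
    )
    # The layout has no egg-stay cell: with the default one-year egg stage
    # the stay probability is exactly 0, so only G leaves the egg row.
    _, G1 = stage_params(params.p_egg, params.d_egg)
    P1, G2 = stage_params(params.p_juv, params.d_juv)
    return StageMatrix(
        F=ff * params.fecundity, G1=G1, P1=P1, G2=G2, P2=params.p_adult
    )


@dataclass
class EigenSystem:
    """Dominant eigen-structure of a projection matrix.

    ``lam`` is the dominant eigenvalue (annual multiplication rate),
    ``r = ln(lam)`` the intrinsic rate of increase, ``w`` the stable stage
    distribution (sums to 1) and ``v`` the reproductive values (scaled so
    ``<v, w> = 1``).
    """

    lam: float
    r: float
    w: np.ndarray
    v: np.ndarray


def _require_irreducible(A: StageMatrix) -> None:
    for name in ("F", "G1", "G2"):
        if getattr(A, name) <= 0:
            raise ValueError(
                f"reducible life cycle: loop entry {name} is zero, the "
                "egg->juvenile->adult->egg loop is broken"
            )


def eigen_analysis(
    A: StageMatrix, tol: float = 1e-12, max_iter: int = 100_000
) -> EigenSystem:
    """Dominant eigenpair by power iteration on A (right) and A^T (left).

    The matrix is nonnegative and, with a complete reproductive loop,
    irreducible, so the Perron root is simple and power iteration converges.
    """
    _require_irreducible(A)
    M = A.as_array()
    w = np.full(3, 1.0 / 3.0)
    v = np.full(3, 1.0 / 3.0)
    lam = 1.0
    for _ in range(max_iter):
        w_new = M @ w
        lam = w_new.sum()
        w_new /= lam
        v_new = M.T @ v
        v_new /= v_new.sum()
        if (
            np.abs(w_new - w).max() < tol
            and np.abs(v_new - v).max() < tol
        ):
            w, v = w_new, v_new
            break
        w, v = w_new, v_new
    else:
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(last lambda {lam})"
        )
    v = v / (v @ w)
    return EigenSystem(lam=float(lam), r=float(np.log(lam)), w=w, v=v)


def dominant_lambda(A: StageMatrix) -> float:
    """Dominant eigenvalue via the characteristic cubic.

    The characteristic polynomial of the stage matrix is
    ``lam^3 - (P1+P2) lam^2 + P1 P2 lam - F G1 G2``; its largest real root is
    the Perron root.  This closed-form route is much cheaper than iterating
    and is used in sweeps; ``eigen_analysis`` is the independent iterative
    route (the two agree to ~1e-10 and are cross-checked in the test suite).
    """
    _require_irreducible(A)
    roots = np.roots([1.0, -(A.P1 + A.P2), A.P1 * A.P2, -A.loop_product])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return float(real.max())


@dataclass
class ElasticityTable:
    """Elasticities of lambda to the five labeled matrix entries.

    Rows follow the conventional reporting order: egg survival (G1),
    juvenile stay (P1), juvenile graduation (G2), adult survival (P2),
    annual fecundity (F).  For this single-loop life cycle the loop entries
    share one elasticity: e(F) = e(G1) = e(G2).
    """

    egg_survival: float
    juvenile_P: float
    juvenile_G: float
    adult_survival: float
    fecundity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Egg survival": self.egg_survival,
            "Juvenile P": self.juvenile_P,
            "Juvenile G": self.juvenile_G,
            "Adult survival": self.adult_survival,
            "Annual fecundity": self.fecundity,
        }

    @property
    def total(self) -> float:
        return (
            self.egg_survival
            + self.juvenile_P
            + self.juvenile_G
            + self.adult_survival
            + self.fecundity
        )


def elasticities(A: StageMatrix) -> ElasticityTable:
    """Elasticity of lambda to each nonzero matrix entry.

    Sensitivity ``s_ij = v_i w_j / <v, w>`` and elasticity
    ``e_ij = (a_ij / lambda) s_ij``; elasticities over all entries sum to 1.
    """
    es = eigen_analysis(A)
    M = A.as_array()
    S = np.outer(es.v, es.w) / (es.v @ es.w)
    E = (M / es.lam) * S
    return ElasticityTable(
        egg_survival=float(E[1, 0]),
        juvenile_P=float(E[1, 1]),
        juvenile_G=float(E[2, 1]),
        adult_survival=float(E[2, 2]),
        fecundity=float(E[0, 2]),
    )


def project(
    A: StageMatrix, n0: np.ndarray | None = None, T: int = 100
) -> np.ndarray:
    """Project stage abundances forward T years; returns a (T+1, 3) array.

    Default initial vector is 1000 individuals split by the stable-stage
    proportions (0.544, 0.401, 0.055).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    if n0 is None:
        n0 = 1000.0 * DEFAULT_INITIAL_PROPORTIONS
    n0 = np.asarray(n0, dtype=float)
    if n0.shape != (3,):
        raise ValueError("n0 must have shape (3,)")
    if (n0 < 0).any():
        raise ValueError("n0 entries must be nonnegative")
    M = A.as_array()
    out = np.empty((T + 1, 3))
    out[0] = n0
    for t in range(T):
        out[t + 1] = M @ out[t]
    return out


def with_survival(
    params: DemographicParams,
    focal: str,
    value: float,
    conventions: ConventionFlags | None = None,
) -> DemographicParams:
    """Copy *params* with one focal parameter replaced.

    When adult survival is the focal parameter and the coupling convention is
    active, juvenile survival is re-derived as ``juvenile_factor * value``.
    """
    conv = conventions or ConventionFlags()
    if focal == "egg_survival":
        return replace(params, p_egg=value)
    if focal == "juvenile_survival":
        return replace(params, p_juv=value)
    if focal == "adult_survival":
        if conv.couple_juvenile:
            return replace(
                params, p_adult=value, p_juv=params.juvenile_factor * value
            )
        return replace(params, p_adult=value)
    if focal == "fecundity":
        return replace(params, fecundity=value)
    raise ValueError(
        f"unknown focal parameter {focal!r}; expected one of egg_survival, "
        "juvenile_survival, adult_survival, fecundity"
    )
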