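"""Fiber architecture, anisotropic conductivity and analytic wavespeed.

The myometrium has no global fiber order, but fibers in localized patches
share an orientation.  This module emulates that structure by partitioning
the uterine surface into contiguous regions (25 by default, seeded at least
4 cm apart), drawing one fiber angle per region from N(0, pi/4), and turning
each angle into a unit tangent direction ``a3`` via an orthonormal tangent
basis at every element.  Conductivity is transversely isotropic about
``a3``:

    G = (sigma_l - sigma_t) a3 a3^T + sigma_t I,

with separate intra/extracellular pairs related by the equal-anisotropy
ratio ``Gi' = zeta Ge'`` that underlies the monodomain reduction.

The analytic front speed of the bursting-type wave follows from freezing the
recovery variable at rest and reading the resulting scalar bistable
reaction-diffusion equation against its classical traveling-wave solution:

    c = |r1 - 2 r2 + r3| / c_m * sqrt(k sigma_el zeta / (2 eps1 a_m (zeta+1)))

where ``r1 <= r2 <= r3`` are the roots of the rest-state cubic.  When the
supplied resting potential is the model's own rest value it is itself a root
of that cubic, so all three roots are real; a rounded rest value can push
the cubic past its fold and produce a complex pair, in which case the
configured root policy decides how to proceed (see
:func:`wavespeed_analytic`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from uteromag.cell_dynamics import FHNParams, resting_potential

__all__ = [
    "FiberRegionPartition",
    "FiberField",
    "ConductivityTensorPair",
    "WavespeedInputs",
    "WavespeedResult",
    "partition_regions",
    "sample_fiber_angles",
    "fiber_orientation",
    "build_fiber_field",
    "conductivity_tensor",
    "conductivity_tensors",
    "resting_recovery",
    "wavespeed_analytic",
]

_POLAR_TOL = 1e-8


@dataclass(frozen=True)
class FiberRegionPartition:
    """Assignment of every surface element to one of ``n`` seeded regions."""

    seed_points: np.ndarray          # (n_regions, 3) seed element centroids
    seed_elements: np.ndarray        # (n_regions,) element indices of seeds
    region_of_element: np.ndarray    # (n_elements,) region ids 0..n-1
    min_separation: float
    rng_seed: int | None

    @property
    def n_regions(self) -> int:
        return len(self.seed_points)

    def __post_init__(self) -> None:
        n = len(self.seed_points)
        if self.region_of_element.min() < 0 or self.region_of_element.max() >= n:
            raise ValueError("element region ids out of range")


@dataclass(frozen=True)
class FiberField:
    """Per-element fiber angle and unit direction on a surface mesh."""

    alpha: np.ndarray       # (n_elements,) angle to the vertical tangent (rad)
    a3: np.ndarray          # (n_elements, 3) unit fiber directions
    distribution: str = "fixed"

    def __post_init__(self) -> None:
        if len(self.alpha) != len(self.a3):
            raise ValueError("alpha and a3 must have matching length")
        norms = np.linalg.norm(self.a3, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("fiber directions must be unit vectors")


@dataclass(frozen=True)
class ConductivityTensorPair:
    """Intra/extracellular tensors sharing the fiber eigenvector."""

    Gi: np.ndarray
    Ge: np.ndarray
    sigma_il: float
    sigma_it: float
    sigma_el: float
    sigma_et: float


@dataclass(frozen=True)
class WavespeedInputs:
    """Tissue-scale parameters entering the analytic wavespeed."""

    params: FHNParams = field(default_factory=FHNParams)
    zeta: float = 0.518
    a_m: float = 575870.0
    sigma_el: float = 0.68
    v_mr: float = -0.056

    def __post_init__(self) -> None:
        if self.zeta <= 0 or self.a_m <= 0 or self.sigma_el <= 0:
            raise ValueError("zeta, a_m and sigma_el must be positive")


@dataclass(frozen=True)
class WavespeedResult:
    """Speed plus root diagnostics: which root-handling path produced it."""

    speed: float
    roots: np.ndarray
    path: str               # "real_roots" | "consistent_rest" | "real_parts"
    v_mr_used: float

    def __float__(self) -> float:
        return self.speed


def partition_regions(
    mesh,
    n_regions: int = 25,
    min_sep: float = 0.04,
    rng_seed: int | None = None,
    max_failures: int = 2000,
    max_restarts: int = 20,
) -> FiberRegionPartition:
    """Partition a surface into ``n_regions`` by separated random seeds.

    Seed elements are drawn uniformly at random; a candidate closer than
    ``min_sep`` (Euclidean, in meters) to an accepted seed is resampled.
    Every element then joins the region of its nearest seed, which keeps the
    regions contiguous on smooth meshes.
    """
    centroids = mesh.element_centroids
    n_elem = len(centroids)
    if n_regions < 1:
        raise ValueError("need at least one region")
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_restarts):
        seeds: list[int] = []
        failures = 0
        while len(seeds) < n_regions and failures < max_failures:
            cand = int(rng.integers(n_elem))
            if seeds:
                d = np.linalg.norm(
                    centroids[seeds] - centroids[cand], axis=1
                ).min()
                if d < min_sep:
                    failures += 1
                    continue
            seeds.append(cand)
        if len(seeds) == n_regions:
            seed_pts = centroids[seeds]
            d = np.linalg.norm(
                centroids[:, None, :] - seed_pts[None, :, :], axis=2
            )
            region = np.argmin(d, axis=1)
            return FiberRegionPartition(
                seed_points=seed_pts,
                seed_elements=np.asarray(seeds),
                region_of_element=region,
                min_separation=min_sep,
                rng_seed=rng_seed,
            )
    raise RuntimeError(
        f"could not place {n_regions} seeds at separation >= {min_sep} m "
        f"after {max_restarts} restarts; the surface is too small or the "
        "separation too large"
    )


def sample_fiber_angles(
    partition: FiberRegionPartition,
    sd: float = math.pi / 4,
    rng_seed: int | None = None,
) -> np.ndarray:
    """One angle per region from N(0, sd); 0 means fibers run vertically."""
    rng = np.random.default_rng(rng_seed)
    return rng.normal(0.0, sd, size=partition.n_regions)


def fiber_orientation(normal: np.ndarray, alpha) -> np.ndarray:
    """Unit fiber direction at angle ``alpha`` in the tangent plane.

    With surface normal ``n = (nx, ny, nz)`` and ``s = sqrt(nx^2 + nz^2)``,
    the tangent basis is ``t1 = (nx ny, -s^2, nz ny)/s`` (steepest vertical
    descent; the vertical axis is y) and ``t2 = (-nz, 0, nx)/s`` (horizontal
    tangent); the fiber is ``a3 = cos(alpha) t1 + sin(alpha) t2``.  Where the
    normal is (anti)parallel to y the basis degenerates and a fixed fallback
    pair ``t1=(1,0,0), t2=(0,0,1)`` is used.
    """
    n = np.atleast_2d(np.asarray(normal, float))
    alpha = np.broadcast_to(np.asarray(alpha, float), n.shape[:-1]).ravel()
    s = np.sqrt(n[:, 0] ** 2 + n[:, 2] ** 2)
    polar = s < _POLAR_TOL
    s_safe = np.where(polar, 1.0, s)
    t1 = np.stack(
        [n[:, 0] * n[:, 1], -(s ** 2), n[:, 2] * n[:, 1]], axis=1
    ) / s_safe[:, None]
    t2 = np.stack([-n[:, 2], np.zeros(len(n)), n[:, 0]], axis=1) / s_safe[:, None]
    t1[polar] = [1.0, 0.0, 0.0]
    t2[polar] = [0.0, 0.0, 1.0]
    a3 = np.cos(alpha)[:, None] * t1 + np.sin(alpha)[:, None] * t2
    if np.asarray(normal).ndim == 1:
        return a3[0]
    return a3


def build_fiber_field(
    mesh,
    partition: FiberRegionPartition | None = None,
    region_angles: np.ndarray | None = None,
    fixed_angle: float | None = None,
) -> FiberField:
    """Per-element fiber field, either region-random or fixed-angle.

    Exactly one of (``partition`` + ``region_angles``) or ``fixed_angle``
    must be given.
    """
    normals = mesh.element_normals
    if fixed_angle is not None:
        if partition is not None or region_angles is not None:
            raise ValueError("give either fixed_angle or a partition, not both")
        alpha = np.full(len(normals), float(fixed_angle))
        dist = "fixed"
    else:
        if partition is None or region_angles is None:
            raise ValueError("random field needs partition and region_angles")
        alpha = np.asarray(region_angles, float)[partition.region_of_element]
        dist = "region_normal"
    a3 = fiber_orientation(normals, alpha)
    return FiberField(alpha=alpha, a3=a3, distribution=dist)


def conductivity_tensor(a3: np.ndarray, sigma_l: float, sigma_t: float) -> np.ndarray:
    """Transversely isotropic tensor ``(s_l - s_t) a3 a3^T + s_t I``."""
    if sigma_l <= 0 or sigma_t <= 0:
        raise ValueError("conductivities must be positive")
    a3 = np.asarray(a3, float)
    single = a3.ndim == 1
    a3 = np.atleast_2d(a3)
    G = (sigma_l - sigma_t) * np.einsum("ei,ej->eij", a3, a3) + sigma_t * np.eye(3)
    return G[0] if single else G


def conductivity_tensors(
    fibers: FiberField,
    sigma_el: float = 0.68,
    zeta: float = 0.518,
    transverse_ratio: float = 0.2,
) -> ConductivityTensorPair:
    """Extra/intracellular tensor fields from the published scalars.

    Only the extracellular longitudinal conductivity and the anisotropy
    ratio are published; the transverse values default to
    ``transverse_ratio`` times the longitudinal, and the intracellular
    tensors follow from the equal-anisotropy-ratio assumption
    ``Gi' = zeta Ge'``.
    """
    sigma_et = transverse_ratio * sigma_el
    Ge = conductivity_tensor(fibers.a3, sigma_el, sigma_et)
    return ConductivityTensorPair(
        Gi=zeta * Ge,
        Ge=Ge,
        sigma_il=zeta * sigma_el,
        sigma_it=zeta * sigma_et,
        sigma_el=sigma_el,
        sigma_et=sigma_et,
    )


def resting_recovery(params: FHNParams, v_mr: float) -> float:
    """Rest value of the recovery variable, ``(beta v_mr + delta)/gamma``."""
    return (params.beta * v_mr + params.delta) / params.gamma


def _front_cubic_roots(params: FHNParams, v_mr: float) -> np.ndarray:
    """Roots of ``(v-v1)(v2-v)(v-v3) - (beta v_mr + delta)/(k gamma)``."""
    offset = (params.beta * v_mr + params.delta) / (params.k * params.gamma)
    # (v-v1)(v2-v)(v-v3) = -(v-v1)(v-v2)(v-v3)
    coeffs = -np.polynomial.polynomial.polyfromroots(
        [params.v1, params.v2, params.v3]
    )
    coeffs[0] -= offset
    return np.roots(coeffs[::-1])


def wavespeed_analytic(
    inputs: WavespeedInputs | None = None,
    root_policy: str = "auto",
    **kwargs,
) -> WavespeedResult:
    """Analytic front speed along the fiber direction (m/s).

    ``root_policy``:

    * ``"auto"`` (default) -- use the three real roots when the cubic has
      them; otherwise recompute with the model's own resting potential, for
      which the cubic provably has a real root at rest (path
      ``"consistent_rest"``); fall back to real parts only if even that
      leaves a complex pair.
    * ``"strict"`` -- error unless all three roots are real.
    * ``"real_parts"`` -- always sort the real parts of the roots.

    The returned diagnostics record the path actually taken and the resting
    potential used.
    """
    if inputs is None:
        inputs = WavespeedInputs(**kwargs)
    elif kwargs:
        raise TypeError("pass either a WavespeedInputs or keyword fields")
    p = inputs.params

    def speed_from(roots: np.ndarray) -> float:
        r = np.sort(roots.real)
        dv = abs(r[0] - 2.0 * r[1] + r[2])
        return dv / p.c_m * math.sqrt(
            p.k * inputs.sigma_el * inputs.zeta
            / (2.0 * p.eps1 * inputs.a_m * (inputs.zeta + 1.0))
        )

    roots = _front_cubic_roots(p, inputs.v_mr)
    all_real = bool(np.all(np.abs(roots.imag) < 1e-9))
    if all_real:
        return WavespeedResult(speed_from(roots), roots.real, "real_roots", inputs.v_mr)
    if root_policy == "strict":
        raise ArithmeticError(
            "front cubic has a complex root pair for the supplied v_mr; "
            "use the model resting potential or the real_parts policy"
        )
    if root_policy == "auto":
        v_rest = resting_potential(p)
        roots2 = _front_cubic_roots(p, v_rest)
        if np.all(np.abs(roots2.imag) < 1e-9):
            return WavespeedResult(
                speed_from(roots2), roots2.real, "consistent_rest", v_rest
            )
    return WavespeedResult(speed_from(roots), roots.real, "real_parts", inputs.v_mr)
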