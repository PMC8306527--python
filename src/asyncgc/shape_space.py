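"""4-D shape-space representation of BCR/epitope affinity.

B cell receptors and epitopes live on a small 4-dimensional integer lattice
(default 0..9 per axis). The Euclidean distance between a B cell's position
and an epitope's optimal position encodes binding affinity through a Gaussian
kernel, somatic hypermutation is a nearest-neighbor step, and antigens with
several unrelated epitopes are represented by several optimal positions far
apart on the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

DIM = 4
#: Number of lattice values per axis (coordinates run 0 .. BOUND-1).
DEFAULT_BOUND = 10
#: Width of the Gaussian affinity kernel, in lattice units.
DEFAULT_GAMMA = 2.8
#: Minimum Euclidean distance of random (naive) founders from every optimum.
DEFAULT_MIN_FOUNDER_DISTANCE = 5.0
#: Minimum pairwise distance between optima of unrelated epitopes.
DEFAULT_EPITOPE_SEPARATION = 6.0


class ShapeSpaceError(ValueError):
    """Raised for malformed positions, epitopes or founder specifications."""


def as_position(
    coords: Sequence[int], bound: Optional[int] = DEFAULT_BOUND
) -> np.ndarray:
    """Validate and return a shape-space position as an int array of length 4.

    ``bound=None`` skips the upper-bound check (used for epitope optima,
    whose lattice is fixed by the simulation parameters, not at construction).
    """
    arr = np.asarray(coords)
    if arr.shape != (DIM,):
        raise ShapeSpaceError(
            f"shape-space position must have exactly {DIM} coordinates, "
            f"got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise ShapeSpaceError("shape-space coordinates must be integers")
        arr = arr.astype(np.int64)
    if np.any(arr < 0) or (bound is not None and np.any(arr >= bound)):
        raise ShapeSpaceError(
            f"coordinates {arr.tolist()} outside lattice bounds [0, {bound - 1}]"
        )
    return arr.astype(np.int64)


@dataclass(frozen=True)
class Epitope:
    """One antigenic determinant: an optimal lattice position and its share
    of the total antigen loaded on FDCs."""

    optimum: np.ndarray
    abundance_fraction: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "optimum", as_position(self.optimum, bound=None))
        if not (0.0 <= self.abundance_fraction <= 1.0):
            raise ShapeSpaceError(
                f"abundance fraction {self.abundance_fraction} not in [0, 1]"
            )


def validate_epitopes(
    epitopes: Sequence[Epitope],
    min_separation: float = DEFAULT_EPITOPE_SEPARATION,
    bound: Optional[int] = None,
) -> None:
    """Check abundance fractions sum to 1, optima are mutually unrelated and
    (when ``bound`` is given) lie on the configured lattice."""
    if len(epitopes) == 0:
        raise ShapeSpaceError("at least one epitope is required")
    if bound is not None:
        for e in epitopes:
            as_position(e.optimum, bound=bound)
    total = sum(e.abundance_fraction for e in epitopes)
    if abs(total - 1.0) > 1e-9:
        raise ShapeSpaceError(f"epitope abundance fractions sum to {total}, not 1")
    for i, a in enumerate(epitopes):
        for b in epitopes[i + 1 :]:
            d = float(np.linalg.norm(a.optimum - b.optimum))
            if d < min_separation:
                raise ShapeSpaceError(
                    f"epitope optima {a.optimum.tolist()} and {b.optimum.tolist()} "
                    f"are {d:.2f} apart; unrelated epitopes require >= {min_separation}"
                )


FounderMode = Literal["random", "epitope_specific"]


@dataclass(frozen=True)
class FounderSpec:
    """How founder (seeder) B cell positions are drawn.

    ``random`` founders are naive: uniform over the lattice subject to a
    minimum distance from every epitope optimum. ``epitope_specific`` founders
    sit on the lattice shell at a given rounded distance from one epitope's
    optimum (distance 0 reproduces the optimum itself).
    """

    mode: FounderMode = "random"
    target_epitope: Optional[int] = None
    distance_from_optimum: int = 5
    min_random_distance: float = DEFAULT_MIN_FOUNDER_DISTANCE

    def __post_init__(self) -> None:
        if self.mode not in ("random", "epitope_specific"):
            raise ShapeSpaceError(f"unknown founder mode {self.mode!r}")
        if self.mode == "epitope_specific" and self.target_epitope is None:
            raise ShapeSpaceError(
                "epitope_specific founder spec requires a target_epitope index"
            )
        if self.distance_from_optimum < 0:
            raise ShapeSpaceError("founder distance must be >= 0")


def affinity(
    p: Sequence[int],
    epitope: Epitope,
    gamma: float = DEFAULT_GAMMA,
    bound: int = DEFAULT_BOUND,
) -> float:
    """Gaussian affinity exp(-d^2/gamma^2) of a position for one epitope.

    Equals 1 exactly at the optimum and decreases strictly with Euclidean
    distance d in the lattice.
    """
    arr = as_position(p, bound=bound)
    d2 = float(np.sum((arr - epitope.optimum) ** 2))
    return float(np.exp(-d2 / gamma**2))


def affinity_many(
    positions: np.ndarray, optimum: np.ndarray, gamma: float = DEFAULT_GAMMA
) -> np.ndarray:
    """Vectorized affinity of an (n, 4) position block for one optimum."""
    d2 = np.sum((positions.astype(np.int64) - optimum) ** 2, axis=1)
    return np.exp(-d2 / gamma**2)


def operative_affinity(
    p: Sequence[int], epitopes: Sequence[Epitope], gamma: float = DEFAULT_GAMMA
) -> float:
    """A cell's operative affinity for a multi-epitope antigen: the maximum
    single-epitope affinity."""
    return max(affinity(p, e, gamma=gamma) for e in epitopes)


def mutate(
    p: Sequence[int],
    mutation_prob: float,
    rng: np.random.Generator,
    bound: int = DEFAULT_BOUND,
) -> np.ndarray:
    """Somatic hypermutation: with probability ``mutation_prob`` move one
    coordinate by +-1 (uniform over the 8 signed axis moves, re-drawn while
    the move would leave the lattice); otherwise return the position unchanged.
    """
    if not (0.0 <= mutation_prob <= 1.0):
        raise ShapeSpaceError(f"mutation probability {mutation_prob} not in [0, 1]")
    arr = as_position(p, bound=bound)
    if rng.random() >= mutation_prob:
        return arr.copy()
    while True:
        move = rng.integers(0, 2 * DIM)
        axis, sign = divmod(move, 2)
        new = arr.copy()
        new[axis] += 1 if sign else -1
        if 0 <= new[axis] < bound:
            return new


def mutate_many(
    positions: np.ndarray,
    mutation_prob: float,
    rng: np.random.Generator,
    bound: int = DEFAULT_BOUND,
) -> np.ndarray:
    """Vectorized :func:`mutate` applied independently to each row in place
    of a fresh copy. Out-of-bounds moves are re-drawn, matching the scalar op.
    """
    out = positions.copy()
    n = out.shape[0]
    if n == 0:
        return out
    hit = np.nonzero(rng.random(n) < mutation_prob)[0]
    while hit.size:
        moves = rng.integers(0, 2 * DIM, size=hit.size)
        axis = moves // 2
        step = np.where(moves % 2 == 1, 1, -1)
        newval = out[hit, axis] + step
        ok = (newval >= 0) & (newval < bound)
        ok_idx = hit[ok]
        out[ok_idx, axis[ok]] = newval[ok]
        hit = hit[~ok]  # re-draw the move for cells that fell off the lattice
    return out


def _all_lattice_points(bound: int) -> np.ndarray:
    grids = np.meshgrid(*([np.arange(bound)] * DIM), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def enumerate_shell(
    optimum: np.ndarray, distance: int, bound: int = DEFAULT_BOUND
) -> np.ndarray:
    """All lattice points whose Euclidean distance from ``optimum`` rounds to
    ``distance``. Raises if the shell is empty."""
    pts = _all_lattice_points(bound)
    d = np.sqrt(np.sum((pts - np.asarray(optimum)) ** 2, axis=1))
    shell = pts[np.round(d).astype(int) == int(distance)]
    if shell.shape[0] == 0:
        raise ShapeSpaceError(
            f"no lattice point at rounded distance {distance} from "
            f"{np.asarray(optimum).tolist()} within bounds [0, {bound - 1}]"
        )
    return shell


def sample_founder(
    spec: FounderSpec,
    epitopes: Sequence[Epitope],
    rng: np.random.Generator,
    bound: int = DEFAULT_BOUND,
) -> np.ndarray:
    """Draw one founder-cell position according to ``spec``."""
    return sample_founders(1, spec, epitopes, rng, bound=bound)[0]


def founder_candidates(
    spec: FounderSpec, epitopes: Sequence[Epitope], bound: int = DEFAULT_BOUND
) -> np.ndarray:
    """Lattice points a founder spec may draw from (uniformly)."""
    if len(epitopes) == 0:
        raise ShapeSpaceError("founder sampling requires at least one epitope")
    if spec.mode == "epitope_specific":
        target = epitopes[spec.target_epitope]
        return enumerate_shell(target.optimum, spec.distance_from_optimum, bound)
    # random mode: uniform over points at >= min_random_distance from every optimum
    pts = _all_lattice_points(bound)
    ok = np.ones(pts.shape[0], dtype=bool)
    for e in epitopes:
        d = np.sqrt(np.sum((pts - e.optimum) ** 2, axis=1))
        ok &= d >= spec.min_random_distance
    candidates = pts[ok]
    if candidates.shape[0] == 0:
        raise ShapeSpaceError(
            f"no lattice point is >= {spec.min_random_distance} from every "
            "epitope optimum; relax min_random_distance or the epitope layout"
        )
    return candidates


def sample_founders(
    n: int,
    spec: FounderSpec,
    epitopes: Sequence[Epitope],
    rng: np.random.Generator,
    bound: int = DEFAULT_BOUND,
    candidates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw ``n`` founder positions as an (n, 4) array.

    Pass a precomputed ``candidates`` array (from :func:`founder_candidates`)
    to avoid re-enumerating the lattice on repeated draws.
    """
    if candidates is None:
        candidates = founder_candidates(spec, epitopes, bound)
    idx = rng.integers(0, candidates.shape[0], size=n)
    return candidates[idx].copy()
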