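"""The dynamic-distance collective variable.

A single scalar coordinate built from a set of non-overlapping atom
pairs (no atom may appear in two pairs).  With pair reduced masses
``μij = mi·mj/(mi+mj)`` and their sum ``μ* = Σ μij``,

    D = sqrt( Σ_pairs (μij/μ*) · |ri − rj|² )

i.e. a reduced-mass-weighted root-mean-square over the pair distances.
Holding D fixed during MD controls the collective hydrogen-bond /
coordination-bond structure while letting individual pairs trade
distance.  The square in the defining sum is the squared Euclidean norm
of the pair vector — the only reading that yields a scalar with
distance units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import reduced_mass


@dataclass
class DynamicDistanceSpec:
    """The pair set entering the dynamic distance.

    Parameters
    ----------
    pairs
        (n_pairs, 2) integer atom indices.  Pairs must be
        non-overlapping: no atom index may occur twice in the whole set.
    mu_ij
        Reduced mass of each pair, amu.
    variant_name
        Which selection convention produced the set: ``"EQUI"`` (all
        inter-base hydrogen bonds of regular pairs), ``"DNA"`` (one
        N···H bond per regular pair plus the two Hg-bridged N···O
        distances), ``"ISO"`` (only the two N···O distances of the
        modified pair) or a free-form tag.
    labels
        Optional human-readable name per pair (e.g. ``"T7:H3--A20:N1"``).
    """

    pairs: np.ndarray
    mu_ij: np.ndarray
    variant_name: str = "CUSTOM"
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        self.mu_ij = np.asarray(self.mu_ij, dtype=float).ravel()
        if len(self.pairs) == 0:
            raise ValueError("dynamic distance requires at least one atom pair")
        if len(self.mu_ij) != len(self.pairs):
            raise ValueError("mu_ij and pairs length mismatch")
        if np.any(self.mu_ij <= 0):
            raise ValueError("all pair reduced masses must be strictly positive")
        flat = self.pairs.ravel()
        if len(np.unique(flat)) != len(flat):
            raise ValueError(
                "pairs overlap: an atom index occurs in more than one pair"
            )

    @property
    def mu_star(self) -> float:
        """Sum of all pair reduced masses, amu."""
        return float(self.mu_ij.sum())

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_masses(
        cls,
        pairs,
        masses: np.ndarray,
        variant_name: str = "CUSTOM",
        labels: list[str] | None = None,
    ) -> "DynamicDistanceSpec":
        """Build a spec from atom index pairs and per-atom masses."""
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        masses = np.asarray(masses, dtype=float)
        mu = np.array(
            [reduced_mass(masses[i], masses[j]) for i, j in pairs], dtype=float
        )
        return cls(pairs, mu, variant_name, labels or [])


def pair_vectors(spec: DynamicDistanceSpec, positions: np.ndarray) -> np.ndarray:
    """(n_pairs, 3) array of ri − rj for each pair."""
    positions = np.asarray(positions, dtype=float)
    return positions[spec.pairs[:, 0]] - positions[spec.pairs[:, 1]]


def pair_distances(spec: DynamicDistanceSpec, positions: np.ndarray) -> np.ndarray:
    """Euclidean distance of each pair, Å."""
    return np.linalg.norm(pair_vectors(spec, positions), axis=1)


def dynamic_distance(spec: DynamicDistanceSpec, positions: np.ndarray) -> float:
    """Evaluate the dynamic distance D (Å) on a configuration.

    ``positions`` is an (N, 3) array; any ``Configuration``-like object
    with a ``positions`` attribute is also accepted.
    """
    positions = _coords(positions)
    d2 = np.einsum("ij,ij->i", *(2 * (pair_vectors(spec, positions),)))
    return float(np.sqrt(np.dot(spec.mu_ij, d2) / spec.mu_star))


def dynamic_distance_gradient(
    spec: DynamicDistanceSpec, positions: np.ndarray
) -> np.ndarray:
    """Analytic gradient ∂D/∂r, shape (N, 3).

    For atom i of pair (i, j):  ∂D/∂ri = (μij / (μ*·D)) · (ri − rj),
    and the negative of that for atom j.  Atoms in no pair get zero.
    Raises if D = 0, where the gradient is singular.
    """
    positions = _coords(positions)
    D = dynamic_distance(spec, positions)
    if D <= 0.0:
        raise ValueError("dynamic distance is zero: gradient is singular")
    vec = pair_vectors(spec, positions)
    w = (spec.mu_ij / (spec.mu_star * D))[:, None] * vec
    grad = np.zeros_like(positions)
    grad[spec.pairs[:, 0]] += w
    grad[spec.pairs[:, 1]] -= w
    return grad


def per_pair_contributions(
    spec: DynamicDistanceSpec, positions: np.ndarray
) -> np.ndarray:
    """Each pair's additive share (μij/μ*)·dij² of D², Å²."""
    positions = _coords(positions)
    d = pair_distances(spec, positions)
    return spec.mu_ij / spec.mu_star * d**2


def _coords(obj) -> np.ndarray:
    if hasattr(obj, "positions"):
        obj = obj.positions
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("positions must be an (N, 3) array")
    return arr
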