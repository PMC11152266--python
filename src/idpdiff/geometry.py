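"""Exact geometric primitives over Cα traces.

All lengths are in Å.  A conformation is an ``(L, 3)`` coordinate array, an
ensemble stacks ``N`` of them as ``(N, L, 3)`` tied to a one-letter amino
acid sequence.  The α torsion angle of residue ``i`` is the signed dihedral
defined by Cα atoms ``i, i+1, i+2, i+3`` (IUPAC convention: looking along
the central virtual bond, clockwise rotation of the far bond is positive);
right-handed helical geometry clusters near +50…60°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: canonical three-letter residue names for PDB output
AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA_ONE = {v: k for k, v in AA_THREE.items()}


class InvalidInputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


@dataclass(frozen=True)
class Sequence:
    """One-letter amino-acid string; needs L ≥ 4 for at least one α torsion."""

    letters: str

    def __post_init__(self):
        if len(self.letters) < 4:
            raise InvalidInputError("sequence must have at least 4 residues")
        bad = set(self.letters) - set(AA_ALPHABET)
        if bad:
            raise InvalidInputError(f"non-canonical residue letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.letters)

    @property
    def indices(self) -> np.ndarray:
        return np.array([AA_INDEX[a] for a in self.letters], dtype=np.int64)


@dataclass
class Ensemble:
    """Ordered collection of conformations sharing one sequence."""

    sequence: Sequence
    coords: np.ndarray  # (N, L, 3) Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidInputError("ensemble coords must have shape (N, L, 3)")
        if self.coords.shape[0] < 1:
            raise InvalidInputError("ensemble must contain at least one member")
        if self.coords.shape[1] != len(self.sequence):
            raise InvalidInputError(
                f"coordinate length {self.coords.shape[1]} does not match "
                f"sequence length {len(self.sequence)}"
            )
        if not np.isfinite(self.coords).all():
            raise InvalidInputError("non-finite coordinates")

    @property
    def n_members(self) -> int:
        return self.coords.shape[0]

    @property
    def length(self) -> int:
        return self.coords.shape[1]

    def subset(self, idx) -> "Ensemble":
        return Ensemble(self.sequence, self.coords[idx])


def _check_conf(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.ndim != 3 or coords.shape[-1] != 3:
        raise InvalidInputError("coordinates must have shape (L, 3) or (N, L, 3)")
    if not np.isfinite(coords).all():
        raise InvalidInputError("non-finite coordinates")
    return coords


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """All Cα-Cα Euclidean distances; d_ij = ‖x_i − x_j‖.

    Accepts ``(L, 3)`` or a batch ``(N, L, 3)``; returns ``(L, L)`` or
    ``(N, L, L)``.  There are L(L−1)/2 unique off-diagonal pairs.
    """
    batch = np.asarray(coords).ndim == 3
    c = _check_conf(coords)
    diff = c[:, :, None, :] - c[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return d if batch else d[0]


def alpha_torsions(coords: np.ndarray, degrees: bool = True) -> np.ndarray:
    """Signed dihedrals over consecutive Cα quadruples; length L−3 per chain.

    Accepts ``(L, 3)`` or ``(N, L, 3)``.  Raises on chains shorter than 4
    residues or on degenerate (collinear) quadruples.
    """
    batch = np.asarray(coords).ndim == 3
    c = _check_conf(coords)
    if c.shape[1] < 4:
        raise InvalidInputError("alpha torsions require at least 4 residues")
    b0 = c[:, 1:-2] - c[:, :-3]
    b1 = c[:, 2:-1] - c[:, 1:-2]
    b2 = c[:, 3:] - c[:, 2:-1]
    u = np.cross(b0, b1)
    v = np.cross(b1, b2)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if (nu < 1e-9).any() or (nv < 1e-9).any():
        raise InvalidInputError("undefined dihedral: three consecutive collinear atoms")
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = (u * v).sum(axis=-1)
    y = (np.cross(u, v) * b1n).sum(axis=-1)
    ang = np.arctan2(y, x)
    if degrees:
        ang = np.degrees(ang)
    return ang if batch else ang[0]


def torsion_unit_vectors(coords: np.ndarray) -> np.ndarray:
    """(cos α, sin α) pairs, shape ``(…, L−3, 2)``."""
    ang = alpha_torsions(coords, degrees=False)
    return np.stack([np.cos(ang), np.sin(ang)], axis=-1)


def radius_of_gyration(coords: np.ndarray) -> np.ndarray | float:
    """Unweighted Cα radius of gyration: √(mean‖x_i − x̄‖²), Å."""
    batch = np.asarray(coords).ndim == 3
    c = _check_conf(coords)
    centered = c - c.mean(axis=1, keepdims=True)
    rg = np.sqrt((centered**2).sum(axis=-1).mean(axis=-1))
    return rg if batch else float(rg[0])


def contact_frequencies(ens: Ensemble, threshold: float = 8.0) -> np.ndarray:
    """Fraction of members with d_ij strictly below ``threshold`` (Å).

    The diagonal is 1 by convention.  Strict inequality makes boundary
    behaviour deterministic: a pair sitting exactly at the threshold never
    counts as a contact.
    """
    d = pairwise_distances(ens.coords)
    p = (d < threshold).mean(axis=0)
    np.fill_diagonal(p, 1.0)
    return p


def log_contact_map(p: np.ndarray, n_members: int) -> np.ndarray:
    """log10 contact probabilities with a floor of 1/(10·N) for zeros."""
    floor = 1.0 / (10.0 * n_members)
    return np.log10(np.maximum(p, floor))


def rigid_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    """Apply a proper rigid transform; improper rotations are rejected."""
    c = np.asarray(coords, dtype=np.float64)
    R = np.asarray(rotation, dtype=np.float64)
    t = np.asarray(translation, dtype=np.float64)
    if R.shape != (3, 3):
        raise InvalidInputError("rotation must be a 3x3 matrix")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
        raise InvalidInputError("rotation must be proper (orthogonal, det +1)")
    return c @ R.T + t


def mirror(coords: np.ndarray) -> np.ndarray:
    """Reflect through the xy-plane: preserves distances, negates torsions."""
    c = np.asarray(coords, dtype=np.float64).copy()
    c[..., 2] *= -1.0
    return c


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1.0
    return Q


def n_pairs(L: int) -> int:
    return L * (L - 1) // 2


def n_torsions(L: int) -> int:
    return L - 3
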