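"""Synthetic Cα ensembles emulating implicit-solvent sampling of short IDRs.

Real training corpora for ensemble generators come from large-scale
simulations; this module provides a stand-in with the same essential
statistical structure so the full pipeline is exercisable on a desk:

* chains of 8–60 residues with a fixed 3.8 Å consecutive Cα-Cα virtual bond;
* chirally biased α torsions — the helical mode sits at +52° (right-handed),
  inside the +50…60° window characteristic of helical backbone geometry;
* sequence dependence via per-letter helix propensities, so different
  sequences produce measurably different torsion and contact statistics;
* optional two-state (compact helical vs. extended) mixtures producing
  bimodal radius-of-gyration distributions with a controllable weight.

Chains are built in internal coordinates (NeRF-style placement from bond
length, pseudo bond angle and torsion), giving exact control over the
features the autoencoder must reconstruct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AA_ALPHABET, Ensemble, InvalidInputError, Sequence

#: default per-letter helix propensities (probability that a torsion drawn
#: at a residue of this type comes from the helical mode)
DEFAULT_HELIX_PROPENSITY = {
    **{a: 0.85 for a in "ALMEKQR"},
    **{a: 0.45 for a in "IWFSTVCHNDY"},
    **{a: 0.05 for a in "GP"},
}

MIN_LENGTH = 8
MAX_LENGTH = 60


@dataclass
class ToyModelSpec:
    """Parameters of the toy conformational model.

    ``two_state_weight`` is the probability that a chain is drawn from the
    extended state rather than the propensity-driven compact state; 0 turns
    the switch off.  Angles in degrees, lengths in Å.
    """

    bond_length: float = 3.8
    helix_propensity: dict = field(default_factory=lambda: dict(DEFAULT_HELIX_PROPENSITY))
    helix_torsion_mean: float = 52.0
    helix_torsion_sd: float = 8.0
    helix_bond_angle_mean: float = 91.0
    helix_bond_angle_sd: float = 4.0
    coil_torsion_modes: tuple = ((-120.0, 35.0, 0.5), (120.0, 35.0, 0.5))
    coil_bond_angle_mean: float = 120.0
    coil_bond_angle_sd: float = 12.0
    extended_torsion_mean: float = 180.0
    extended_torsion_sd: float = 12.0
    extended_bond_angle_mean: float = 135.0
    extended_bond_angle_sd: float = 5.0
    two_state_weight: float = 0.0
    excluded_volume_cutoff: float | None = None  # Å; None disables resampling
    max_retries: int = 50

    def __post_init__(self):
        if not 0.0 <= self.two_state_weight <= 1.0:
            raise InvalidInputError("two_state_weight must be in [0, 1]")
        if self.bond_length <= 0:
            raise InvalidInputError("bond length must be positive")
        for v in self.helix_propensity.values():
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError("helix propensities must be in [0, 1]")


def generate_toy_sequence(length: int, seed: int,
                          composition: dict | None = None) -> Sequence:
    """Reproducible random sequence over the canonical 20-letter alphabet.

    ``composition`` maps letters to relative weights (default uniform).
    Lengths outside the 8–60 residue regime of the toy corpus are rejected.
    """
    if not MIN_LENGTH <= length <= MAX_LENGTH:
        raise InvalidInputError(
            f"length {length} outside supported range [{MIN_LENGTH}, {MAX_LENGTH}]"
        )
    rng = np.random.default_rng(seed)
    letters = list(AA_ALPHABET)
    if composition:
        w = np.array([composition.get(a, 0.0) for a in letters], dtype=np.float64)
        if w.sum() <= 0:
            raise InvalidInputError("composition weights must have positive mass")
    else:
        w = np.ones(len(letters))
    w = w / w.sum()
    picks = rng.choice(len(letters), size=length, p=w)
    return Sequence("".join(letters[i] for i in picks))


def _nerf_extend(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                 bond: float, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Place the next atom D from frame atoms A, B, C (batched).

    ``theta`` is the B-C-D pseudo bond angle, ``phi`` the A-B-C-D torsion,
    both in radians.
    """
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ],
        axis=-1,
    )
    frame = np.stack([bc, m, n], axis=-1)  # columns
    return c + np.einsum("...ij,...j->...i", frame, d_local)


def _sample_coil_torsions(rng: np.random.Generator, spec: ToyModelSpec,
                          size: int) -> np.ndarray:
    modes = spec.coil_torsion_modes
    weights = np.array([m[2] for m in modes], dtype=np.float64)
    weights /= weights.sum()
    which = rng.choice(len(modes), size=size, p=weights)
    means = np.array([m[0] for m in modes])[which]
    sds = np.array([m[1] for m in modes])[which]
    return rng.normal(means, sds)


def _build_chains(seq: Sequence, n: int, spec: ToyModelSpec,
                  rng: np.random.Generator) -> np.ndarray:
    L = len(seq)
    b = spec.bond_length
    extended = rng.random(n) < spec.two_state_weight

    # per-chain, per-step bond angles and torsions (degrees)
    thetas = np.empty((n, L - 2))
    phis = np.empty((n, L - 3))
    prop = np.array([spec.helix_propensity.get(a, 0.45) for a in seq.letters])
    for j in range(L - 3):
        helical = rng.random(n) < prop[j]
        phi = np.where(
            helical,
            rng.normal(spec.helix_torsion_mean, spec.helix_torsion_sd, n),
            _sample_coil_torsions(rng, spec, n),
        )
        theta = np.where(
            helical,
            rng.normal(spec.helix_bond_angle_mean, spec.helix_bond_angle_sd, n),
            rng.normal(spec.coil_bond_angle_mean, spec.coil_bond_angle_sd, n),
        )
        phi_ext = rng.normal(spec.extended_torsion_mean, spec.extended_torsion_sd, n)
        theta_ext = rng.normal(spec.extended_bond_angle_mean,
                               spec.extended_bond_angle_sd, n)
        phis[:, j] = np.where(extended, phi_ext, phi)
        # atom j+3 is placed with torsion slot j and bond-angle slot j+1
        thetas[:, j + 1] = np.where(extended, theta_ext, theta)
    # bond angle for the very first placement step (atom 2)
    helical0 = rng.random(n) < prop[0]
    theta0 = np.where(
        helical0,
        rng.normal(spec.helix_bond_angle_mean, spec.helix_bond_angle_sd, n),
        rng.normal(spec.coil_bond_angle_mean, spec.coil_bond_angle_sd, n),
    )
    thetas[:, 0] = np.where(
        extended,
        rng.normal(spec.extended_bond_angle_mean, spec.extended_bond_angle_sd, n),
        theta0,
    )

    coords = np.zeros((n, L, 3))
    coords[:, 1, 0] = b
    th = np.radians(thetas[:, 0])
    coords[:, 2, 0] = b - b * np.cos(th)
    coords[:, 2, 1] = b * np.sin(th)
    for j in range(3, L):
        coords[:, j] = _nerf_extend(
            coords[:, j - 3],
            coords[:, j - 2],
            coords[:, j - 1],
            b,
            np.radians(thetas[:, j - 2]),
            np.radians(phis[:, j - 3]),
        )
    return coords


def _has_overlap(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Per-chain flag: any non-neighbor pair closer than ``cutoff``."""
    n, L, _ = coords.shape
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    i, j = np.triu_indices(L, 2)  # skip consecutive pairs
    return (d[:, i, j] < cutoff).any(axis=-1)


def sample_toy_ensemble(seq: Sequence, n: int, spec: ToyModelSpec,
                        seed: int = 0) -> Ensemble:
    """Draw ``n`` chains for ``seq`` from the toy model; reproducible by seed."""
    if n < 1:
        raise InvalidInputError("ensemble size must be at least 1")
    rng = np.random.default_rng(seed)
    coords = _build_chains(seq, n, spec, rng)
    if spec.excluded_volume_cutoff is not None:
        for _ in range(spec.max_retries):
            bad = _has_overlap(coords, spec.excluded_volume_cutoff)
            if not bad.any():
                break
            coords[bad] = _build_chains(seq, int(bad.sum()), spec, rng)
        else:
            raise RuntimeError(
                "excluded-volume resampling exceeded retry budget "
                f"({spec.max_retries}); loosen the cutoff or the model"
            )
    return Ensemble(seq, coords)


@dataclass
class FixtureSuite:
    """A train/validation/test split of toy systems."""

    train: list  # list[Ensemble]
    val: list
    test: list


def default_fixture_suite(seed: int = 0, n_train: int = 40, n_val: int = 5,
                          n_test: int = 5, n_frames: int = 1000,
                          length_range: tuple = (10, 30),
                          spec: ToyModelSpec | None = None) -> FixtureSuite:
    """Generate the default toy corpus: 40/5/5 systems, 1,000 frames each.

    Sequence lengths are drawn uniformly from ``length_range``; each system
    gets its own derived seed so the suite is exactly regenerable.
    """
    spec = spec or ToyModelSpec()
    rng = np.random.default_rng(seed)
    out = []
    for count in (n_train, n_val, n_test):
        group = []
        for _ in range(count):
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            sseed = int(rng.integers(0, 2**31 - 1))
            seq = generate_toy_sequence(L, sseed)
            group.append(sample_toy_ensemble(seq, n_frames, spec, seed=sseed + 1))
        out.append(group)
    return FixtureSuite(*out)
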