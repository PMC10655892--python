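"""Deterministic miniature structures used throughout the test suite."""

from __future__ import annotations

import numpy as np

from .topology import (
    ChromosomeTopology,
    build_uniform_bottlebrush,
    initial_bottlebrush_coords,
)

FIXTURE_NAMES = ("tiny_bbp", "tiny_sac", "helix", "rod", "blob")


def helix_coords(
    n: int = 100,
    radius: float = 2.0,
    pitch: float = 3.0,
    points_per_turn: int = 10,
) -> np.ndarray:
    """Ideal helix; tangent correlations follow a known closed form."""
    theta = 2.0 * np.pi * np.arange(n) / points_per_turn
    z = pitch * np.arange(n) / points_per_turn
    return np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), z], axis=1
    )


def rod_coords(n: int = 50, spacing: float = 1.1) -> np.ndarray:
    """Collinear beads along z: zero acylindricity, zero width."""
    pos = np.zeros((n, 3))
    pos[:, 2] = spacing * np.arange(n)
    return pos


def blob_coords(n: int = 200, sigma: float = 3.0, seed: int = 7) -> np.ndarray:
    """Isotropic Gaussian cloud (spherical reference shape)."""
    return sigma * np.random.default_rng(seed).standard_normal((n, 3))


def cylinder_shell_coords(
    n: int = 2000, radius: float = 4.0, length: float = 40.0, seed: int = 11
) -> np.ndarray:
    """Points uniform on a cylindrical shell: lambda1 = lambda2 < lambda3."""
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    z = rng.uniform(-length / 2.0, length / 2.0, n)
    return np.stack([radius * np.cos(phi), radius * np.sin(phi), z], axis=1)


def sphere_shell_coords(n: int = 2000, radius: float = 5.0,
                        seed: int = 13) -> np.ndarray:
    """Points uniform on a sphere: lambda1 = lambda2 = lambda3."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    return radius * v / np.linalg.norm(v, axis=1, keepdims=True)


def wormlike_chain_coords(
    n: int,
    k_bend: float = 3.0,
    bond_length: float = 1.1,
    seed: int = 0,
) -> np.ndarray:
    """Equilibrium-statistics worm-like chain sample.

    Successive bond directions differ by angles drawn from the
    Boltzmann weight of the discrete Kratky-Porod energy,
    ``p(cos a) ~ exp(k cos a)``, giving ``<cos a> = coth(k) - 1/k``.
    Used as a pre-equilibrated start for free-chain runs (a straight
    rod would need the full Rouse time to forget its orientation).
    """
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    t = np.array([0.0, 0.0, 1.0])
    for i in range(1, n):
        u = rng.uniform()
        cos_a = 1.0 + np.log(u + (1 - u) * np.exp(-2 * k_bend)) / k_bend
        sin_a = np.sqrt(max(0.0, 1.0 - cos_a * cos_a))
        phi = rng.uniform(0.0, 2.0 * np.pi)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(t @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(t, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        t = cos_a * t + sin_a * (np.cos(phi) * e1 + np.sin(phi) * e2)
        t /= np.linalg.norm(t)
        pos[i] = pos[i - 1] + bond_length * t
    return pos


def make_fixture(name: str) -> tuple[ChromosomeTopology | None, np.ndarray]:
    """Named (topology, coordinates) fixtures; topology may be None."""
    if name == "tiny_bbp":
        topo = build_uniform_bottlebrush(10, 10)
        return topo, initial_bottlebrush_coords(topo, seed=42)
    if name == "tiny_sac":
        # compact cylinder arrangement of a 10-loop bottlebrush: anchors
        # stacked densely on the axis, loop beads on a surrounding shell
        topo = build_uniform_bottlebrush(10, 10)
        pos = np.empty((topo.n_beads, 3))
        for k, (anchor, L) in enumerate(topo.loop_table):
            z = 0.8 * k
            pos[anchor] = (0.0, 0.0, z)
            theta = 2.0 * np.pi * np.arange(1, L) / (L - 1)
            pos[anchor + 1 : anchor + L] = np.stack(
                [2.0 * np.cos(theta + k), 2.0 * np.sin(theta + k),
                 np.full(L - 1, z)], axis=1
            )
        return topo, pos
    if name == "helix":
        return None, helix_coords()
    if name == "rod":
        return None, rod_coords()
    if name == "blob":
        return None, blob_coords()
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
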