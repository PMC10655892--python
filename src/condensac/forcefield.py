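"""Potential-energy terms and the species-pair interaction table.

Energy terms (reduced units, energies in kBT, lengths in sigma):

* soft repulsion between non-bonded polymer beads,
  ``U = A (1 + cos(pi r / r_c))`` with ``r_c = 2^(1/6)``.  The bounded
  amplitude ``A`` encodes topoisomerase II activity: at ``A = 1`` thermal
  fluctuations let chromatin strands pass through one another, at
  ``A = 100`` strand passage is effectively forbidden.
* harmonic chain bonds ``U = K (r - r0)^2`` (K = 100, r0 = 1.1).
* Kratky-Porod bending ``U = K_BEND (1 + cos phi)`` at each interior bead,
  ``phi`` the interior angle (K_BEND = 3, persistence length ~3 sigma).
* loop-closure ("looping condensin") springs ``U = K_bb (r - r1)^2``
  (K_bb = 100, r1 = 1.8); the same term is reused for centromere springs.
* truncated Lennard-Jones between bridges and the polymer: eps = 3 for
  generic chromatin, eps = 8 for loop anchors, both attractive with
  cutoff 1.8 and energy-shifted to zero there; bridge-bridge is purely
  repulsive WCA with eps = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import ANCHOR, BRIDGE, CHROMATIN, ChromosomeTopology

RC_SOFT = 2.0 ** (1.0 / 6.0)
WCA_CUT = 2.0 ** (1.0 / 6.0)
ATTRACTIVE_CUT = 1.8

KIND_SOFT = 0
KIND_LJ = 1


class OverlapError(ValueError):
    """Raised when a diverging pair distance (r = 0) is evaluated."""


# ---------------------------------------------------------------------------
# scalar potential terms (reference implementations; numpy-broadcastable)

def soft_pair(r, A: float, rc: float = RC_SOFT):
    """Bounded soft repulsion; returns (energy, scalar force -dU/dr).

    U(0) = 2A, U(rc/2) = A, U(r >= rc) = 0; both U and F are continuous
    at the cutoff.  Because U is bounded by 2A, strands can cross.
    """
    r = np.asarray(r, dtype=float)
    inside = r <= rc
    u = np.where(inside, A * (1.0 + np.cos(np.pi * r / rc)), 0.0)
    f = np.where(inside, A * np.pi / rc * np.sin(np.pi * r / rc), 0.0)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def harmonic_bond(r, K: float, rest: float):
    """Harmonic bond U = K (r - rest)^2; returns (energy, force -dU/dr)."""
    r = np.asarray(r, dtype=float)
    u = K * (r - rest) ** 2
    f = -2.0 * K * (r - rest)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def kratky_porod(phi, K_BEND: float):
    """Bending energy U = K (1 + cos phi) at interior angle phi.

    A straight chain (phi = pi) is the minimum; a hairpin (phi = 0)
    costs 2 K.  Returns (energy, torque -dU/dphi).
    """
    phi = np.asarray(phi, dtype=float)
    u = K_BEND * (1.0 + np.cos(phi))
    tau = K_BEND * np.sin(phi)
    if u.ndim == 0:
        return float(u), float(tau)
    return u, tau


def lj_cut(r, epsilon: float, cutoff: float, shifted: bool = True):
    """Truncated 12-6 Lennard-Jones; returns (energy, force -dU/dr).

    If ``shifted`` the potential is raised so U(cutoff) = 0.  With
    cutoff = 2^(1/6) and shifting this is the WCA purely repulsive form.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise OverlapError("pair distance must be positive")
    inside = r <= cutoff
    sr6 = np.where(inside, (1.0 / r) ** 6, 0.0)
    u = 4.0 * epsilon * (sr6 * sr6 - sr6)
    f = np.where(inside, 24.0 * epsilon * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    if shifted:
        sc6 = (1.0 / cutoff) ** 6
        u = u - 4.0 * epsilon * (sc6 * sc6 - sc6)
    u = np.where(inside, u, 0.0)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


# ---------------------------------------------------------------------------
# force field assembly

@dataclass
class ForceField:
    """Bonded parameters plus the 3x3 species-pair interaction table."""

    A: float = 10.0
    rc_soft: float = RC_SOFT
    K: float = 100.0
    r0: float = 1.1
    K_BEND: float = 3.0
    K_backbone: float = 100.0
    r1: float = 1.8
    eps_weak: float = 3.0
    eps_strong: float = 8.0
    eps_bridge_bridge: float = 1.0
    attractive: bool = True   # False during the pre-bridging steric phase
    # derived pair table (species x species), filled in __post_init__
    pair_kind: np.ndarray = field(init=False, repr=False)
    pair_eps: np.ndarray = field(init=False, repr=False)
    pair_cut: np.ndarray = field(init=False, repr=False)
    pair_shift: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        kind = np.zeros((3, 3), dtype=np.int64)
        eps = np.zeros((3, 3))
        cut = np.zeros((3, 3))
        # chromatin/anchor family: soft potential with amplitude A
        for a in (CHROMATIN, ANCHOR):
            for b in (CHROMATIN, ANCHOR):
                kind[a, b] = KIND_SOFT
                eps[a, b] = self.A
                cut[a, b] = self.rc_soft
        # bridge - polymer
        if self.attractive:
            bc = (self.eps_weak, ATTRACTIVE_CUT)
            ba = (self.eps_strong, ATTRACTIVE_CUT)
        else:
            bc = (1.0, WCA_CUT)
            ba = (1.0, WCA_CUT)
        for sp, (e, c) in ((CHROMATIN, bc), (ANCHOR, ba)):
            kind[BRIDGE, sp] = kind[sp, BRIDGE] = KIND_LJ
            eps[BRIDGE, sp] = eps[sp, BRIDGE] = e
            cut[BRIDGE, sp] = cut[sp, BRIDGE] = c
        kind[BRIDGE, BRIDGE] = KIND_LJ
        eps[BRIDGE, BRIDGE] = self.eps_bridge_bridge
        cut[BRIDGE, BRIDGE] = WCA_CUT
        # LJ energy shift so U(cutoff) = 0 on every LJ entry
        shift = np.zeros((3, 3))
        lj = kind == KIND_LJ
        with np.errstate(divide="ignore"):
            sc6 = np.where(lj, (1.0 / np.where(cut > 0, cut, 1.0)) ** 6, 0.0)
        shift[lj] = (4.0 * eps * (sc6 * sc6 - sc6))[lj]
        self.pair_kind, self.pair_eps = kind, eps
        self.pair_cut, self.pair_shift = cut, shift

    @property
    def max_cutoff(self) -> float:
        return float(max(self.pair_cut.max(), self.rc_soft))

    def pair_energy_force(self, r: float, sa: int, sb: int):
        """Energy and scalar force of one non-bonded pair by species."""
        if self.pair_kind[sa, sb] == KIND_SOFT:
            return soft_pair(r, self.pair_eps[sa, sb], self.pair_cut[sa, sb])
        u, f = lj_cut(r, self.pair_eps[sa, sb], self.pair_cut[sa, sb], shifted=False)
        if r <= self.pair_cut[sa, sb]:
            u -= self.pair_shift[sa, sb]
        return u, f

    def steric(self) -> "ForceField":
        """Copy with bridge-polymer attraction replaced by pure sterics."""
        return ForceField(
            A=self.A, K=self.K, r0=self.r0, K_BEND=self.K_BEND,
            K_backbone=self.K_backbone, r1=self.r1, eps_weak=self.eps_weak,
            eps_strong=self.eps_strong,
            eps_bridge_bridge=self.eps_bridge_bridge, attractive=False,
        )


def bonded_arrays(topo: ChromosomeTopology, ff: ForceField):
    """Flatten all bonds (chain, loop, centromere) into kernel arrays.

    Returns (bond_pairs (m,2), bond_K (m,), bond_rest (m,)).
    """
    pairs = [topo.chain_bonds, topo.loop_springs, topo.centromere_springs]
    ks = [
        np.full(len(topo.chain_bonds), ff.K),
        np.full(len(topo.loop_springs), ff.K_backbone),
        np.full(len(topo.centromere_springs), ff.K_backbone),
    ]
    rests = [
        np.full(len(topo.chain_bonds), ff.r0),
        np.full(len(topo.loop_springs), ff.r1),
        np.full(len(topo.centromere_springs), ff.r1),
    ]
    return (
        np.concatenate(pairs).astype(np.int64).reshape(-1, 2),
        np.concatenate(ks),
        np.concatenate(rests),
    )


def exclusion_csr(topo: ChromosomeTopology, n_total: int):
    """Per-particle CSR lists of directly bonded partners (excluded pairs)."""
    pairs = np.concatenate(
        [topo.chain_bonds, topo.loop_springs, topo.centromere_springs]
    ).reshape(-1, 2)
    adj: list[list[int]] = [[] for _ in range(n_total)]
    for i, j in pairs:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    indptr = np.zeros(n_total + 1, dtype=np.int64)
    for i, lst in enumerate(adj):
        indptr[i + 1] = indptr[i] + len(lst)
    indices = np.empty(indptr[-1], dtype=np.int64)
    for i, lst in enumerate(adj):
        indices[indptr[i] : indptr[i + 1]] = sorted(lst)
    return indptr, indices


def total_energy(
    positions: np.ndarray,
    topology: ChromosomeTopology,
    ff: ForceField,
    n_bridges: int = 0,
    box: float = 0.0,
) -> dict:
    """Brute-force O(N^2) energy decomposition (reference implementation).

    Returns a dict with keys soft, bonds, angles, loop_springs, pair_lj.
    Directly bonded pairs are excluded from the non-bonded terms.  With
    ``box > 0`` the minimum-image convention is applied to non-bonded
    distances.
    """
    n = positions.shape[0]
    if n != topology.n_beads + n_bridges:
        raise ValueError(
            f"positions has {n} rows, expected {topology.n_beads + n_bridges}"
        )
    species = topology.species_with_bridges(n_bridges)
    out = {"soft": 0.0, "bonds": 0.0, "angles": 0.0, "loop_springs": 0.0,
           "pair_lj": 0.0}
    if n < 2:
        out["total"] = 0.0
        return out

    excluded = set()
    for arr in (topology.chain_bonds, topology.loop_springs,
                topology.centromere_springs):
        for i, j in arr:
            excluded.add((min(i, j), max(i, j)))

    for i in range(n - 1):
        d = positions[i + 1 :] - positions[i]
        if box > 0:
            d -= box * np.round(d / box)
        r = np.sqrt((d * d).sum(axis=1))
        for k, rij in enumerate(r):
            j = i + 1 + k
            if (i, j) in excluded:
                continue
            sa, sb = int(species[i]), int(species[j])
            if ff.pair_cut[sa, sb] <= 0 or rij > ff.pair_cut[sa, sb]:
                continue
            u, _ = ff.pair_energy_force(float(rij), sa, sb)
            if ff.pair_kind[sa, sb] == KIND_SOFT:
                out["soft"] += u
            else:
                out["pair_lj"] += u

    def _bond_sum(pairs, K, rest):
        if len(pairs) == 0:
            return 0.0
        d = positions[pairs[:, 1]] - positions[pairs[:, 0]]
        r = np.sqrt((d * d).sum(axis=1))
        return float((K * (r - rest) ** 2).sum())

    out["bonds"] = _bond_sum(topology.chain_bonds, ff.K, ff.r0)
    out["loop_springs"] = _bond_sum(topology.loop_springs, ff.K_backbone, ff.r1) + \
        _bond_sum(topology.centromere_springs, ff.K_backbone, ff.r1)

    if len(topology.angle_triplets):
        tri = topology.angle_triplets
        b1 = positions[tri[:, 1]] - positions[tri[:, 0]]
        b2 = positions[tri[:, 2]] - positions[tri[:, 1]]
        c = (b1 * b2).sum(axis=1) / (
            np.linalg.norm(b1, axis=1) * np.linalg.norm(b2, axis=1)
        )
        out["angles"] = float((ff.K_BEND * (1.0 - np.clip(c, -1.0, 1.0))).sum())

    out["total"] = sum(v for k, v in out.items() if k != "total")
    return out


def lammps_coefficients(ff: ForceField) -> str:
    """Pair/bond/angle coefficients in LAMMPS input syntax (cross-checking).

    Species types are 1 = chromatin, 2 = anchor, 3 = bridge; bond types
    1 = chain, 2 = loop spring, 3 = centromere; angle type 1.
    """
    lines = [
        "# pair_style hybrid soft/cut + lj/cut (energies kBT, lengths sigma)",
        f"pair_coeff 1 1 soft {ff.A:.6g} {ff.rc_soft:.6f}",
        f"pair_coeff 1 2 soft {ff.A:.6g} {ff.rc_soft:.6f}",
        f"pair_coeff 2 2 soft {ff.A:.6g} {ff.rc_soft:.6f}",
    ]
    if ff.attractive:
        lines += [
            f"pair_coeff 1 3 lj/cut {ff.eps_weak:.6g} 1.0 {ATTRACTIVE_CUT:.6f}",
            f"pair_coeff 2 3 lj/cut {ff.eps_strong:.6g} 1.0 {ATTRACTIVE_CUT:.6f}",
        ]
    else:
        lines += [
            f"pair_coeff 1 3 lj/cut 1.0 1.0 {WCA_CUT:.6f}",
            f"pair_coeff 2 3 lj/cut 1.0 1.0 {WCA_CUT:.6f}",
        ]
    lines += [
        f"pair_coeff 3 3 lj/cut {ff.eps_bridge_bridge:.6g} 1.0 {WCA_CUT:.6f}",
        "pair_modify shift yes",
        f"bond_coeff 1 {ff.K:.6g} {ff.r0:.6g}",
        f"bond_coeff 2 {ff.K_backbone:.6g} {ff.r1:.6g}",
        f"bond_coeff 3 {ff.K_backbone:.6g} {ff.r1:.6g}",
        f"angle_coeff 1 {ff.K_BEND:.6g}",
    ]
    return "\n".join(lines) + "\n"
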