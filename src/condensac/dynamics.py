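"""Underdamped Langevin dynamics with neighbor-listed force evaluation.

The equation of motion for every bead (polymer and bridge alike) is

    m d2r/dt2 = -grad U - gamma dr/dt + sqrt(2 kBT gamma) eta(t),

with ``m = gamma = kBT = 1`` in reduced units so that the inertial,
velocity-decorrelation and Brownian times coincide.  The integrator is
the BAOAB splitting of the Langevin equation: a symplectic
velocity-Verlet core with the friction/noise (Ornstein-Uhlenbeck) step
applied between the two drift half-steps.  At ``gamma = 0`` it reduces
exactly to velocity Verlet.  The default time step is ``dt = 0.01``.

Positions are kept unwrapped at all times; periodic boundary conditions
enter only through the minimum-image convention in non-bonded distances
(bonded terms use raw displacements, which is exact as long as the box
is larger than twice any bonded extension).  Non-bonded pairs come from
a Verlet list built on a cell grid and rebuilt whenever any particle has
moved more than half the skin since the last build.

All randomness in a run derives from a single integer seed; execution is
single-threaded, so trajectories are bit-identical across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .forcefield import ForceField, bonded_arrays, exclusion_csr
from .topology import ChromosomeTopology

DEFAULT_SKIN = 0.6  # Verlet-list skin; near-optimal from dense-phase profiling
FORCE_CAP = 1.0e3  # cap on pair LJ force magnitude; tames start-up overlaps


class IntegrationError(RuntimeError):
    """Non-finite coordinate or force encountered; carries the bad frame."""

    def __init__(self, message: str, frame: np.ndarray | None = None):
        super().__init__(message)
        self.frame = frame


@dataclass
class SimulationState:
    """Instantaneous mechanical state of the system."""

    positions: np.ndarray          # (n, 3) sigma, unwrapped
    velocities: np.ndarray         # (n, 3)
    box: float                     # cubic side (sigma); 0 = free space
    time: float = 0.0              # elapsed tau_B
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )

    @classmethod
    def create(
        cls,
        positions: np.ndarray,
        box: float,
        seed: int,
        kBT: float = 1.0,
    ) -> "SimulationState":
        """Initial state with Maxwell-Boltzmann velocities."""
        rng = np.random.default_rng(seed)
        vel = rng.normal(0.0, np.sqrt(kBT), size=positions.shape)
        return cls(
            positions=np.array(positions, dtype=np.float64),
            velocities=vel,
            box=float(box),
            rng=rng,
        )

    def chunk_seed(self) -> int:
        """Next sub-seed for a kernel invocation (deterministic stream)."""
        return int(self.rng.integers(2**31 - 1))


@dataclass
class Trajectory:
    """Time-ordered snapshots of unwrapped coordinates."""

    frames: np.ndarray             # (n_frames, n, 3)
    times: np.ndarray              # (n_frames,) tau_B
    species: np.ndarray            # (n,) int8
    box: float
    kinetic: np.ndarray | None = None  # (n_frames,) kinetic energy

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def concatenate(self, other: "Trajectory") -> "Trajectory":
        return Trajectory(
            frames=np.concatenate([self.frames, other.frames]),
            times=np.concatenate([self.times, other.times]),
            species=self.species,
            box=self.box,
            kinetic=None
            if self.kinetic is None or other.kinetic is None
            else np.concatenate([self.kinetic, other.kinetic]),
        )


@dataclass
class PullingConfig:
    """Constant equal-and-opposite end forces for micromanipulation runs."""

    force_magnitude: float         # kBT/sigma
    bead_a: int
    bead_b: int
    extension_phase: float = 0.0   # tau_B
    relaxation_phase: float = 0.0

    def __post_init__(self) -> None:
        # negative indices are a sentinel for "use the terminal anchors"
        if self.bead_a == self.bead_b and self.bead_a >= 0:
            raise ValueError("bead_a and bead_b must differ")
        if self.extension_phase < 0 or self.relaxation_phase < 0:
            raise ValueError("phase durations must be >= 0")


def apply_end_forces(state: SimulationState, pulling: PullingConfig) -> np.ndarray:
    """External force field: +F on bead_a, -F on bead_b along their axis.

    The direction is the current line joining the two beads (re-evaluated
    every step inside the integrator); the net external force is zero.
    """
    n = state.positions.shape[0]
    out = np.zeros((n, 3))
    d = state.positions[pulling.bead_a] - state.positions[pulling.bead_b]
    r = np.linalg.norm(d)
    if r > 0:
        u = d / r
        out[pulling.bead_a] = pulling.force_magnitude * u
        out[pulling.bead_b] = -pulling.force_magnitude * u
    return out


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True, inline="always")
def _min_image(d, box):
    if box > 0.0:
        return d - box * np.floor(d / box + 0.5)
    return d


MAX_CELLS_DIM = 128


@njit(cache=True)
def _build_pairs(pos, box, rlist, species, cutsk2, excl_ptr, excl_idx,
                 pi_arr, pj_arr, head, nxt, cellx, celly, cellz):
    """Fill the candidate pair arrays, split by interaction kind.

    Soft (polymer-polymer) candidates are packed at the front of the
    arrays and Lennard-Jones (bridge-involving) candidates immediately
    after them; returns (n_soft, n_lj), or (-1, -1) on overflow.

    ``rlist`` (max cutoff + skin) sets the cell size; each candidate is
    kept only if within its own species-pair cutoff + skin (``cutsk2``,
    squared), which keeps the list small when cutoffs differ by species.

    ``head`` is a caller-owned cell table that must be all -1 on entry;
    it is restored to -1 (touched cells only) before returning, so
    repeated rebuilds never pay for clearing the mostly-empty grid.
    """
    n = pos.shape[0]
    cap = pi_arr.shape[0]
    n_soft = 0
    n_lj = 0
    # scalar prefilter bound: rejects most candidates before the
    # species loads and 2D table lookup
    max_cutsk2 = cutsk2[0, 0]
    for a in range(3):
        for b in range(3):
            if cutsk2[a, b] > max_cutsk2:
                max_cutsk2 = cutsk2[a, b]

    if box > 0.0:
        ncd = int(box / rlist)
        periodic = True
        ox = oy = oz = 0.0
        ex = ey = ez = box
    else:
        periodic = False
        ox, oy, oz = pos[0, 0], pos[0, 1], pos[0, 2]
        ex = ey = ez = 0.0
        mx, my, mz = ox, oy, oz
        for i in range(n):
            if pos[i, 0] < ox:
                ox = pos[i, 0]
            elif pos[i, 0] > mx:
                mx = pos[i, 0]
            if pos[i, 1] < oy:
                oy = pos[i, 1]
            elif pos[i, 1] > my:
                my = pos[i, 1]
            if pos[i, 2] < oz:
                oz = pos[i, 2]
            elif pos[i, 2] > mz:
                mz = pos[i, 2]
        ex, ey, ez = mx - ox + 1e-9, my - oy + 1e-9, mz - oz + 1e-9
        ncd = int(max(ex, ey, ez) / rlist)

    use_cells = ncd >= 3 and n > 256

    if not use_cells:
        # brute-force enumeration (small or dense-box systems)
        for i in range(n - 1):
            e0, e1 = excl_ptr[i], excl_ptr[i + 1]
            for j in range(i + 1, n):
                dx = _min_image(pos[i, 0] - pos[j, 0], box)
                dy = _min_image(pos[i, 1] - pos[j, 1], box)
                dz = _min_image(pos[i, 2] - pos[j, 2], box)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > cutsk2[species[i], species[j]]:
                    continue
                skip = False
                for e in range(e0, e1):
                    if excl_idx[e] == j:
                        skip = True
                        break
                if skip:
                    continue
                if n_soft + n_lj >= cap:
                    return -1, -1
                if species[i] < 2 and species[j] < 2:
                    pi_arr[n_soft] = i
                    pj_arr[n_soft] = j
                    n_soft += 1
                else:
                    n_lj += 1
                    pi_arr[cap - n_lj] = i
                    pj_arr[cap - n_lj] = j
        if n_soft + 2 * n_lj > cap:  # segments would overlap when packing
            return -1, -1
        for k in range(n_lj):
            pi_arr[n_soft + k] = pi_arr[cap - 1 - k]
            pj_arr[n_soft + k] = pj_arr[cap - 1 - k]
        return n_soft, n_lj

    # cell grid, cell size >= rlist
    if periodic:
        ncx = ncy = ncz = min(ncd, MAX_CELLS_DIM)
        cx = cy = cz = box / ncx
    else:
        ncx = min(max(1, int(ex / rlist)), MAX_CELLS_DIM)
        ncy = min(max(1, int(ey / rlist)), MAX_CELLS_DIM)
        ncz = min(max(1, int(ez / rlist)), MAX_CELLS_DIM)
        cx, cy, cz = ex / ncx, ey / ncy, ez / ncz

    for i in range(n):
        x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
        if periodic:
            x -= box * np.floor(x / box)
            y -= box * np.floor(y / box)
            z -= box * np.floor(z / box)
            ix = min(int(x / cx), ncx - 1)
            iy = min(int(y / cy), ncy - 1)
            iz = min(int(z / cz), ncz - 1)
        else:
            ix = min(int((x - ox) / cx), ncx - 1)
            iy = min(int((y - oy) / cy), ncy - 1)
            iz = min(int((z - oz) / cz), ncz - 1)
        cellx[i], celly[i], cellz[i] = ix, iy, iz
        c = (ix * ncy + iy) * ncz + iz
        nxt[i] = head[c]
        head[c] = i

    # 13 half-space neighbour offsets (plus intra-cell pairs); iterating
    # over particles, not cells, keeps the cost independent of box size
    n_offs = 13
    offs = np.array(
        [
            (1, 0, 0), (-1, 1, 0), (0, 1, 0), (1, 1, 0),
            (-1, -1, 1), (0, -1, 1), (1, -1, 1), (-1, 0, 1),
            (0, 0, 1), (1, 0, 1), (-1, 1, 1), (0, 1, 1), (1, 1, 1),
        ],
        dtype=np.int64,
    )

    for i in range(n):
        ix, iy, iz = cellx[i], celly[i], cellz[i]
        # intra-cell: particles after i in this cell's linked list
        j = nxt[i]
        while j != -1:
            a, b = (i, j) if i < j else (j, i)
            dx = _min_image(pos[a, 0] - pos[b, 0], box)
            dy = _min_image(pos[a, 1] - pos[b, 1], box)
            dz = _min_image(pos[a, 2] - pos[b, 2], box)
            r2ab = dx * dx + dy * dy + dz * dz
            if r2ab <= max_cutsk2 and \
                    r2ab <= cutsk2[species[a], species[b]]:
                skip = False
                for e in range(excl_ptr[a], excl_ptr[a + 1]):
                    if excl_idx[e] == b:
                        skip = True
                        break
                if not skip:
                    if n_soft + n_lj < cap:
                        if species[a] < 2 and species[b] < 2:
                            pi_arr[n_soft] = a
                            pj_arr[n_soft] = b
                            n_soft += 1
                        else:
                            n_lj += 1
                            pi_arr[cap - n_lj] = a
                            pj_arr[cap - n_lj] = b
                    else:
                        n_soft += 1  # poison: forces overflow signal
            j = nxt[j]
        for o in range(n_offs):
            jx = ix + offs[o, 0]
            jy = iy + offs[o, 1]
            jz = iz + offs[o, 2]
            if periodic:
                jx %= ncx
                jy %= ncy
                jz %= ncz
            else:
                if jx < 0 or jx >= ncx or jy < 0 or jy >= ncy \
                        or jz < 0 or jz >= ncz:
                    continue
            c2 = (jx * ncy + jy) * ncz + jz
            j = head[c2]
            while j != -1:
                a, b = (i, j) if i < j else (j, i)
                dx = _min_image(pos[a, 0] - pos[b, 0], box)
                dy = _min_image(pos[a, 1] - pos[b, 1], box)
                dz = _min_image(pos[a, 2] - pos[b, 2], box)
                r2ab = dx * dx + dy * dy + dz * dz
                if r2ab <= max_cutsk2 and \
                        r2ab <= cutsk2[species[a], species[b]]:
                    skip = False
                    for e in range(excl_ptr[a], excl_ptr[a + 1]):
                        if excl_idx[e] == b:
                            skip = True
                            break
                    if not skip:
                        if n_soft + n_lj < cap:
                            if species[a] < 2 and species[b] < 2:
                                pi_arr[n_soft] = a
                                pj_arr[n_soft] = b
                                n_soft += 1
                            else:
                                n_lj += 1
                                pi_arr[cap - n_lj] = a
                                pj_arr[cap - n_lj] = b
                        else:
                            n_soft += 1  # poison: forces overflow signal
                j = nxt[j]
    # restore the caller-owned cell table to all -1 (touched cells only)
    for i in range(n):
        head[(cellx[i] * ncy + celly[i]) * ncz + cellz[i]] = -1
    if n_soft + 2 * n_lj > cap:  # overflow, or segments would overlap
        return -1, -1
    for k in range(n_lj):
        pi_arr[n_soft + k] = pi_arr[cap - 1 - k]
        pj_arr[n_soft + k] = pj_arr[cap - 1 - k]
    return n_soft, n_lj


@njit(cache=True)
def _sort_pairs(pi_arr, pj_arr, count, n):
    """Counting sort of the pair list by first index (cache locality)."""
    cnt = np.zeros(n + 1, dtype=np.int64)
    for p in range(count):
        cnt[pi_arr[p] + 1] += 1
    for i in range(n):
        cnt[i + 1] += cnt[i]
    out_i = np.empty(count, dtype=np.int64)
    out_j = np.empty(count, dtype=np.int64)
    for p in range(count):
        i = pi_arr[p]
        k = cnt[i]
        out_i[k] = i
        out_j[k] = pj_arr[p]
        cnt[i] = k + 1
    pi_arr[:count] = out_i
    pj_arr[:count] = out_j


@njit(cache=True, inline="always")
def _sin_0_pi(x):
    """sin(x) for x in [0, pi] via an even polynomial in (x - pi/2).

    Max error ~5e-7; used only on the production force path where the
    exact-trig cost dominates the soft-pair loop.
    """
    s = x - 1.5707963267948966
    s2 = s * s
    return 1.0 + s2 * (-0.5 + s2 * (4.1666666666666664e-02 + s2 * (
        -1.3888888888888889e-03 + s2 * (2.4801587301587302e-05
                                        - s2 * 2.7557319223985893e-07))))


@njit(cache=True)
def _compute_forces(
    pos, box, species, forces,
    pi_arr, pj_arr, n_soft, n_lj,
    kind, eps, cut2, shift, rc_soft,
    bonds, bond_K, bond_rest,
    angles, k_bend,
    ext_f, pull_a, pull_b, pull_F, fcap,
    want_pe,
):
    """Total force into ``forces``; returns potential energy.

    With ``want_pe == 0`` the pair-energy accumulation is skipped (the
    integrator needs only forces); the returned value is then 0.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = ext_f[i, 0]
        forces[i, 1] = ext_f[i, 1]
        forces[i, 2] = ext_f[i, 2]
    pe = 0.0

    pi_over_rc = np.pi / rc_soft
    # soft (polymer-polymer) pairs: shared amplitude and cutoff
    A_soft = eps[0, 0]
    c2_soft = cut2[0, 0]
    for p in range(n_soft):
        i, j = pi_arr[p], pj_arr[p]
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2_soft or r2 < 1e-24:
            continue
        r = np.sqrt(r2)
        x = pi_over_rc * r
        if want_pe != 0:
            pe += A_soft * (1.0 + np.cos(x))
            fmag = A_soft * pi_over_rc * np.sin(x)
        else:
            fmag = A_soft * pi_over_rc * _sin_0_pi(x)
        fr = fmag / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz
    # bridge-involving pairs: truncated shifted Lennard-Jones
    for p in range(n_soft, n_soft + n_lj):
        i, j = pi_arr[p], pj_arr[p]
        si, sj = species[i], species[j]
        c2 = cut2[si, sj]
        dx = _min_image(pos[i, 0] - pos[j, 0], box)
        dy = _min_image(pos[i, 1] - pos[j, 1], box)
        dz = _min_image(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2 or r2 < 1e-24:
            continue
        e = eps[si, sj]
        sr2 = 1.0 / r2
        sr6 = sr2 * sr2 * sr2
        if want_pe != 0:
            pe += 4.0 * e * (sr6 * sr6 - sr6) - shift[si, sj]
        r = np.sqrt(r2)
        fmag = 24.0 * e * (2.0 * sr6 * sr6 - sr6) / r
        if fmag > fcap:
            fmag = fcap
        elif fmag < -fcap:
            fmag = -fcap
        fr = fmag / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz

    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        dr = r - bond_rest[b]
        pe += bond_K[b] * dr * dr
        fr = -2.0 * bond_K[b] * dr / r
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz

    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        inv = 1.0 / (n1 * n2)
        c = (b1x * b2x + b1y * b2y + b1z * b2z) * inv
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        pe += k_bend * (1.0 - c)
        # dE/dr = -K dc/dr;  dc/db1 = b2/(n1 n2) - c b1/n1^2, similarly b2
        g1x = b2x * inv - c * b1x / (n1 * n1)
        g1y = b2y * inv - c * b1y / (n1 * n1)
        g1z = b2z * inv - c * b1z / (n1 * n1)
        g2x = b1x * inv - c * b2x / (n2 * n2)
        g2y = b1y * inv - c * b2y / (n2 * n2)
        g2z = b1z * inv - c * b2z / (n2 * n2)
        # F_i = -dE/dr_i = -K dc/db1 ; F_k = +K dc/db2 ... with signs:
        fix = -k_bend * g1x
        fiy = -k_bend * g1y
        fiz = -k_bend * g1z
        fkx = k_bend * g2x
        fky = k_bend * g2y
        fkz = k_bend * g2z
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    if pull_a >= 0 and pull_b >= 0 and pull_F != 0.0:
        dx = pos[pull_a, 0] - pos[pull_b, 0]
        dy = pos[pull_a, 1] - pos[pull_b, 1]
        dz = pos[pull_a, 2] - pos[pull_b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 1e-12:
            fr = pull_F / r
            forces[pull_a, 0] += fr * dx
            forces[pull_a, 1] += fr * dy
            forces[pull_a, 2] += fr * dz
            forces[pull_b, 0] -= fr * dx
            forces[pull_b, 1] -= fr * dy
            forces[pull_b, 2] -= fr * dz

    return pe


@njit(cache=True)
def _run_kernel(
    pos, vel, species, box,
    bonds, bond_K, bond_rest, angles, k_bend,
    excl_ptr, excl_idx,
    kind, eps, cut2, shift, rc_soft,
    ext_f, pull_a, pull_b, pull_F, fcap,
    dt, gamma, kBT,
    n_steps, stride, seed, skin, rlist,
    frames, frame_steps, ke_out,
):
    """Advance ``n_steps`` of BAOAB Langevin dynamics.

    Snapshots go into ``frames`` every ``stride`` steps.  Returns
    (n_frames_written, status) with status 0 = ok, 1 = non-finite.
    """
    # xorshift64* noise stream: cheap, seedable, single-threaded
    rng = (np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)) | np.uint64(1)
    n = pos.shape[0]
    cutsk2 = (np.sqrt(cut2) + skin) ** 2
    # caller-owned cell-grid work arrays, reused across every rebuild
    ncd = min(max(int(box / rlist), 1) if box > 0.0 else MAX_CELLS_DIM,
              MAX_CELLS_DIM)
    head = np.full(ncd * ncd * ncd, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cellx = np.empty(n, dtype=np.int64)
    celly = np.empty(n, dtype=np.int64)
    cellz = np.empty(n, dtype=np.int64)
    cap = 96 * n + 1024
    pi_arr = np.empty(cap, dtype=np.int64)
    pj_arr = np.empty(cap, dtype=np.int64)
    n_soft, n_lj = _build_pairs(pos, box, rlist, species, cutsk2,
                                excl_ptr, excl_idx, pi_arr, pj_arr,
                                head, nxt, cellx, celly, cellz)
    while n_soft < 0:
        cap *= 2
        pi_arr = np.empty(cap, dtype=np.int64)
        pj_arr = np.empty(cap, dtype=np.int64)
        n_soft, n_lj = _build_pairs(pos, box, rlist, species, cutsk2,
                                    excl_ptr, excl_idx, pi_arr, pj_arr,
                                    head, nxt, cellx, celly, cellz)
    _sort_pairs(pi_arr, pj_arr, n_soft, n)
    pos0 = pos.copy()
    forces = np.zeros((n, 3))
    _compute_forces(
        pos, box, species, forces, pi_arr, pj_arr, n_soft, n_lj,
        kind, eps, cut2, shift, rc_soft,
        bonds, bond_K, bond_rest, angles, k_bend,
        ext_f, pull_a, pull_b, pull_F, fcap, 0,
    )
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kBT)
    half = 0.5 * dt
    nframe = 0

    s12 = np.uint64(12)
    s25 = np.uint64(25)
    s27 = np.uint64(27)
    s11 = np.uint64(11)
    mult = np.uint64(2685821657736338717)
    inv53 = 1.0 / 9007199254740992.0
    noise = np.empty(3 * n)
    for step in range(n_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * forces[i, d]
                pos[i, d] += half * vel[i, d]
        if c2 > 0.0:
            # thermostat noise: variance-matched uniform deviates
            # (sqrt(3) * U[-1,1]) from a xorshift64* stream.  Over the
            # ~1/(gamma*dt) kicks of one relaxation time the velocity
            # becomes Gaussian by the CLT while the first two moments
            # are exact (standard Langevin-thermostat practice).  The
            # serial RNG recurrence lives in its own pass so the
            # integration sweeps stay vectorisable.
            for k in range(3 * n):
                rng ^= rng >> s12
                rng ^= rng << s25
                rng ^= rng >> s27
                u = np.float64((rng * mult) >> s11) * inv53
                noise[k] = 3.4641016151377544 * (u - 0.5)
            for i in range(n):
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + c2 * noise[3 * i + d]
        for i in range(n):
            for d in range(3):
                pos[i, d] += half * vel[i, d]
        # two-largest-displacement criterion: a pair can close the skin
        # gap at most by the sum of its two displacements, so a rebuild
        # is needed only once max1 + max2 exceeds the skin
        m1 = 0.0
        m2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - pos0[i, 0]
            dy = pos[i, 1] - pos0[i, 1]
            dz = pos[i, 2] - pos0[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > m1:
                m2 = m1
                m1 = d2
            elif d2 > m2:
                m2 = d2
        if np.sqrt(m1) + np.sqrt(m2) > skin:
            n_soft, n_lj = _build_pairs(pos, box, rlist, species, cutsk2,
                                        excl_ptr, excl_idx, pi_arr, pj_arr,
                                        head, nxt, cellx, celly, cellz)
            while n_soft < 0:
                cap *= 2
                pi_arr = np.empty(cap, dtype=np.int64)
                pj_arr = np.empty(cap, dtype=np.int64)
                n_soft, n_lj = _build_pairs(pos, box, rlist, species,
                                            cutsk2, excl_ptr, excl_idx,
                                            pi_arr, pj_arr,
                                            head, nxt, cellx, celly, cellz)
            _sort_pairs(pi_arr, pj_arr, n_soft, n)
            pos0[:, :] = pos
        _compute_forces(
            pos, box, species, forces, pi_arr, pj_arr, n_soft, n_lj,
            kind, eps, cut2, shift, rc_soft,
            bonds, bond_K, bond_rest, angles, k_bend,
            ext_f, pull_a, pull_b, pull_F, fcap, 0,
        )
        for i in range(n):
            for d in range(3):
                vel[i, d] += half * forces[i, d]
        if stride > 0 and (step + 1) % stride == 0 and nframe < frames.shape[0]:
            ke = 0.0
            ok = True
            for i in range(n):
                for d in range(3):
                    v = vel[i, d]
                    ke += 0.5 * v * v
                    if not np.isfinite(pos[i, d]):
                        ok = False
            frames[nframe] = pos
            frame_steps[nframe] = step + 1
            ke_out[nframe] = ke
            nframe += 1
            if not ok:
                return nframe, 1
    if not np.isfinite(pos).all():
        return nframe, 1
    return nframe, 0


# ---------------------------------------------------------------------------
# python driver

def neighbor_pairs(
    positions: np.ndarray,
    box: float,
    cutoff: float,
    skin: float = DEFAULT_SKIN,
    exclusions: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Candidate pair list (superset of all pairs within ``cutoff``).

    Returns an (m, 2) integer array.  Raises if the periodic box is too
    small for the minimum-image convention at this cutoff.
    """
    rlist = cutoff + skin
    if box > 0 and rlist > box / 2.0:
        raise ValueError(
            f"cutoff+skin {rlist:.3f} exceeds half box {box / 2.0:.3f} "
            "(minimum-image violation)"
        )
    n = positions.shape[0]
    if exclusions is None:
        excl_ptr = np.zeros(n + 1, dtype=np.int64)
        excl_idx = np.empty(0, dtype=np.int64)
    else:
        excl_ptr, excl_idx = exclusions
    cap = max(128 * n, 4096)
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    species0 = np.zeros(n, dtype=np.int8)
    cutsk2 = np.full((3, 3), rlist * rlist)
    while True:
        pi_arr = np.empty(cap, dtype=np.int64)
        pj_arr = np.empty(cap, dtype=np.int64)
        ncd = min(max(int(box / rlist), 1) if box > 0
                  else MAX_CELLS_DIM, MAX_CELLS_DIM)
        head = np.full(ncd * ncd * ncd, -1, dtype=np.int64)
        work = np.empty(n, dtype=np.int64)
        ns, nl = _build_pairs(pos, float(box), float(rlist), species0,
                              cutsk2, excl_ptr, excl_idx, pi_arr, pj_arr,
                              head, work.copy(), work.copy(), work.copy(),
                              work.copy())
        if ns >= 0:
            count = ns + nl
            return np.stack([pi_arr[:count], pj_arr[:count]], axis=1)
        cap *= 2


def _kernel_inputs(topology: ChromosomeTopology, ff: ForceField, n_total: int):
    bonds, bond_K, bond_rest = bonded_arrays(topology, ff)
    excl_ptr, excl_idx = exclusion_csr(topology, n_total)
    cut2 = ff.pair_cut**2
    return bonds, bond_K, bond_rest, excl_ptr, excl_idx, cut2


def langevin_run(
    state: SimulationState,
    topology: ChromosomeTopology,
    ff: ForceField,
    n_steps: int,
    dt: float = 0.01,
    gamma: float = 1.0,
    kBT: float = 1.0,
    stride: int = 0,
    pulling: PullingConfig | None = None,
    external_forces: np.ndarray | None = None,
    skin: float = DEFAULT_SKIN,
    force_cap: float = FORCE_CAP,
) -> Trajectory:
    """Advance the state in place by ``n_steps``; return sampled snapshots.

    ``stride = 0`` records only the final frame.  ``pulling`` applies
    constant opposite forces to two beads along their joining line,
    re-evaluated every step.  ``external_forces`` adds a static per-bead
    force field.
    """
    n = state.positions.shape[0]
    species = topology.species_with_bridges(n - topology.n_beads)
    if species.shape[0] != n:
        raise ValueError("state size inconsistent with topology")
    bonds, bond_K, bond_rest, excl_ptr, excl_idx, cut2 = _kernel_inputs(
        topology, ff, n
    )
    ext_f = (
        np.zeros((n, 3))
        if external_forces is None
        else np.ascontiguousarray(external_forces, dtype=np.float64)
    )
    pull_a, pull_b, pull_F = -1, -1, 0.0
    if pulling is not None:
        pull_a, pull_b = pulling.bead_a, pulling.bead_b
        pull_F = pulling.force_magnitude

    record_stride = stride if stride > 0 else n_steps
    n_frames = n_steps // record_stride if n_steps > 0 else 0
    frames = np.empty((max(n_frames, 1), n, 3))
    frame_steps = np.zeros(max(n_frames, 1), dtype=np.int64)
    ke = np.zeros(max(n_frames, 1))

    rlist = ff.max_cutoff + skin
    if state.box > 0 and rlist > state.box / 2.0:
        raise ValueError("box too small for cutoff (minimum image violation)")

    nframe, status = _run_kernel(
        state.positions, state.velocities, species, state.box,
        bonds, bond_K, bond_rest,
        np.ascontiguousarray(topology.angle_triplets), ff.K_BEND,
        excl_ptr, excl_idx,
        ff.pair_kind, ff.pair_eps, cut2, ff.pair_shift, ff.rc_soft,
        ext_f, pull_a, pull_b, pull_F, force_cap,
        dt, gamma, kBT,
        n_steps, record_stride, state.chunk_seed(), skin, rlist,
        frames, frame_steps, ke,
    )
    if status != 0:
        raise IntegrationError(
            f"non-finite coordinates after step {frame_steps[max(nframe - 1, 0)]}",
            frame=frames[max(nframe - 1, 0)],
        )
    t0 = state.time
    state.time += n_steps * dt
    if nframe == 0:
        # no full stride elapsed: report the final state as a single frame
        frames[0] = state.positions
        frame_steps[0] = n_steps
        ke[0] = 0.5 * float((state.velocities**2).sum())
        nframe = 1
    return Trajectory(
        frames=frames[:nframe].copy(),
        times=t0 + frame_steps[:nframe] * dt,
        species=species,
        box=state.box,
        kinetic=ke[:nframe].copy(),
    )


def nonbonded_energy(
    positions: np.ndarray,
    species: np.ndarray,
    box: float,
    ff: ForceField,
    exclusions: tuple[np.ndarray, np.ndarray],
) -> float:
    """Non-bonded energy through the neighbor-list path (for validation)."""
    pairs = neighbor_pairs(positions, box, ff.max_cutoff, exclusions=exclusions)
    pos = np.asarray(positions, dtype=np.float64)
    total = 0.0
    for i, j in pairs:
        d = pos[i] - pos[j]
        if box > 0:
            d -= box * np.round(d / box)
        r = float(np.sqrt((d * d).sum()))
        si, sj = int(species[i]), int(species[j])
        if ff.pair_cut[si, sj] <= 0 or r > ff.pair_cut[si, sj]:
            continue
        u, _ = ff.pair_energy_force(r, si, sj)
        total += u
    return total


def compute_forces_energy(
    positions: np.ndarray,
    topology: ChromosomeTopology,
    ff: ForceField,
    box: float = 0.0,
    pulling: PullingConfig | None = None,
    external_forces: np.ndarray | None = None,
    force_cap: float = 1.0e30,
) -> tuple[np.ndarray, float]:
    """One-shot force/energy evaluation through the production kernel."""
    n = positions.shape[0]
    species = topology.species_with_bridges(n - topology.n_beads)
    bonds, bond_K, bond_rest, excl_ptr, excl_idx, cut2 = _kernel_inputs(
        topology, ff, n
    )
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    pairs = neighbor_pairs(
        pos, box, ff.max_cutoff, exclusions=(excl_ptr, excl_idx)
    )
    ext_f = (
        np.zeros((n, 3))
        if external_forces is None
        else np.asarray(external_forces, dtype=np.float64)
    )
    pull_a, pull_b, pull_F = -1, -1, 0.0
    if pulling is not None:
        pull_a, pull_b = pulling.bead_a, pulling.bead_b
        pull_F = pulling.force_magnitude
    forces = np.zeros((n, 3))
    is_soft = (species[pairs[:, 0]] < 2) & (species[pairs[:, 1]] < 2)
    ordered = np.concatenate([pairs[is_soft], pairs[~is_soft]])
    pe = _compute_forces(
        pos, float(box), species, forces,
        np.ascontiguousarray(ordered[:, 0]),
        np.ascontiguousarray(ordered[:, 1]),
        int(is_soft.sum()), int((~is_soft).sum()),
        ff.pair_kind, ff.pair_eps, cut2, ff.pair_shift, ff.rc_soft,
        bonds, bond_K, bond_rest,
        np.ascontiguousarray(topology.angle_triplets), ff.K_BEND,
        ext_f, pull_a, pull_b, pull_F, force_cap, 1,
    )
    return forces, float(pe)
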