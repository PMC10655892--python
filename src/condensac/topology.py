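"""Bottlebrush chromosome topologies and their perturbations.

A prometaphase chromosome is modelled as a chain of beads arranged into
consecutive chromatin loops.  Each loop is held closed by a "looping
condensin", a harmonic spring connecting the loop anchor bead ``i`` to the
chromatin bead immediately preceding the next anchor along the chain
(``j = i + L - 1`` for a loop of ``L`` beads).  The ordered anchors form
the chromosome backbone.  Loops are back-to-back with no linker beads:
the next anchor is ``j + 1``.

Bead species: 0 = generic chromatin, 1 = loop anchor, 2 = bridging
condensin (diffusing particle, not part of the chain).  Indexing is
0-based and contiguous per chromatid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import MIN_LOOP_BEADS, RunConfig

CHROMATIN, ANCHOR, BRIDGE = 0, 1, 2
SPECIES_NAMES = {CHROMATIN: "chromatin", ANCHOR: "anchor", BRIDGE: "bridge"}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}


class TopologyError(ValueError):
    pass


@dataclass
class ChromosomeTopology:
    """Connectivity of one or two bottlebrush chromatids.

    Arrays index polymer beads only; bridging condensins are appended
    after the polymer when a simulation system is assembled.
    """

    species: np.ndarray            # (n_beads,) int8, CHROMATIN or ANCHOR
    chain_bonds: np.ndarray        # (n-1 per chromatid, 2) int64, (i, i+1)
    loop_springs: np.ndarray       # (k, 2) int64, (anchor, closing bead)
    angle_triplets: np.ndarray     # (m, 3) int64, consecutive chain triplets
    loop_table: np.ndarray         # (k, 2) int64, (anchor index, length in beads)
    centromere_springs: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64)
    )
    n_chromatids: int = 1

    @property
    def n_beads(self) -> int:
        return self.species.shape[0]

    @property
    def beads_per_chromatid(self) -> int:
        return self.n_beads // self.n_chromatids

    @property
    def anchors(self) -> np.ndarray:
        """Backbone bead indices: the ordered loop anchors."""
        return np.flatnonzero(self.species == ANCHOR)

    def validate(self) -> None:
        n = self.n_beads
        for name in ("chain_bonds", "loop_springs", "angle_triplets",
                     "centromere_springs"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise TopologyError(f"{name} indexes outside [0, {n})")
        per = self.beads_per_chromatid
        if self.loop_springs.size:
            if np.any(self.loop_springs[:, 0] // per != self.loop_springs[:, 1] // per):
                raise TopologyError("loop spring crosses a chromatid boundary")

    def species_with_bridges(self, n_bridges: int) -> np.ndarray:
        """Full species array for polymer beads followed by bridges."""
        return np.concatenate(
            [self.species, np.full(n_bridges, BRIDGE, dtype=np.int8)]
        )


def _wire_chromatid(loop_lengths: np.ndarray) -> ChromosomeTopology:
    """Assemble one chromatid from a vector of loop lengths (beads)."""
    loop_lengths = np.asarray(loop_lengths, dtype=np.int64)
    if np.any(loop_lengths < MIN_LOOP_BEADS):
        raise TopologyError(f"loops must be >= {MIN_LOOP_BEADS} beads")
    n = int(loop_lengths.sum())
    anchors = np.concatenate([[0], np.cumsum(loop_lengths)[:-1]])
    species = np.zeros(n, dtype=np.int8)
    species[anchors] = ANCHOR
    closing = anchors + loop_lengths - 1
    loop_springs = np.stack([anchors, closing], axis=1)
    idx = np.arange(n - 1, dtype=np.int64)
    chain_bonds = np.stack([idx, idx + 1], axis=1)
    mid = np.arange(1, n - 1, dtype=np.int64)
    angle_triplets = np.stack([mid - 1, mid, mid + 1], axis=1)
    loop_table = np.stack([anchors, loop_lengths], axis=1)
    topo = ChromosomeTopology(
        species=species,
        chain_bonds=chain_bonds,
        loop_springs=loop_springs,
        angle_triplets=angle_triplets,
        loop_table=loop_table,
    )
    topo.validate()
    return topo


def build_uniform_bottlebrush(n_loops: int, loop_beads: int) -> ChromosomeTopology:
    """Bottlebrush with ``n_loops`` identical loops of ``loop_beads`` beads."""
    if n_loops < 1:
        raise TopologyError("n_loops must be >= 1")
    return _wire_chromatid(np.full(n_loops, loop_beads, dtype=np.int64))


def build_poisson_bottlebrush(
    n_loops: int,
    mean_loop_beads: float,
    min_loop: int = MIN_LOOP_BEADS,
    seed: int = 0,
    total_beads: int | None = None,
    total_tol: float = 0.01,
) -> ChromosomeTopology:
    """Bottlebrush with Poisson-distributed loop lengths.

    Loop lengths are i.i.d. Poisson(``mean_loop_beads``) conditioned on
    being at least ``min_loop`` beads (resampled below the floor).

    With ``total_beads`` the whole length vector is redrawn until the
    total genomic content matches to within ``total_tol`` (closest draw
    kept after 200 attempts).  Matched totals make paired comparisons
    against uniform-loop chromosomes measure the loop-statistics
    effect rather than sample-size noise — the variable-loop chromosome
    represents the same chromosome with its loops redrawn.
    """
    if mean_loop_beads < min_loop:
        raise TopologyError("mean_loop_beads must be >= min_loop")
    rng = np.random.default_rng(seed)

    def draw_lengths() -> np.ndarray:
        lengths = np.empty(n_loops, dtype=np.int64)
        todo = np.arange(n_loops)
        while todo.size:
            draw = rng.poisson(mean_loop_beads, size=todo.size)
            ok = draw >= min_loop
            lengths[todo[ok]] = draw[ok]
            todo = todo[~ok]
        return lengths

    lengths = draw_lengths()
    if total_beads is not None:
        best, best_err = lengths, abs(int(lengths.sum()) - total_beads)
        attempts = 0
        while best_err > total_tol * total_beads and attempts < 200:
            lengths = draw_lengths()
            err = abs(int(lengths.sum()) - total_beads)
            if err < best_err:
                best, best_err = lengths, err
            attempts += 1
        lengths = best
    return _wire_chromatid(lengths)


def build_linear_chain(n_beads: int, anchor_every: int = 0) -> ChromosomeTopology:
    """Unlooped control chain: no loop springs, optional periodic anchors.

    With ``anchor_every > 0``, every that-many-th bead is tagged a
    high-affinity site even though no looping springs exist — the
    no-loop control used to show that the bottlebrush is required for
    the mitotic contact-probability scaling.
    """
    species = np.zeros(n_beads, dtype=np.int8)
    if anchor_every > 0:
        species[::anchor_every] = ANCHOR
    idx = np.arange(n_beads - 1, dtype=np.int64)
    mid = np.arange(1, n_beads - 1, dtype=np.int64)
    topo = ChromosomeTopology(
        species=species,
        chain_bonds=np.stack([idx, idx + 1], axis=1),
        loop_springs=np.empty((0, 2), dtype=np.int64),
        angle_triplets=np.stack([mid - 1, mid, mid + 1], axis=1),
        loop_table=np.empty((0, 2), dtype=np.int64),
    )
    topo.validate()
    return topo


def build_sister_chromatids(
    base: ChromosomeTopology,
    centromere_loops: tuple[int, int],
    n_springs: int,
) -> ChromosomeTopology:
    """Two copies of ``base`` joined by springs at the centromere.

    ``centromere_loops`` is a half-open range of loop indices defining
    the centromeric region; ``n_springs`` harmonic springs pair
    homologous beads (i, i + n_beads) evenly spread over that region.
    """
    if base.n_chromatids != 1:
        raise TopologyError("base must be a single chromatid")
    lo, hi = centromere_loops
    if not (0 <= lo < hi <= base.loop_table.shape[0]):
        raise TopologyError("centromere loop range outside loop table")
    n = base.n_beads
    first = int(base.loop_table[lo, 0])
    last = int(base.loop_table[hi - 1, 0] + base.loop_table[hi - 1, 1])
    if n_springs > 0:
        beads = np.unique(
            np.linspace(first, last - 1, n_springs).round().astype(np.int64)
        )
        centromere = np.stack([beads, beads + n], axis=1)
    else:
        centromere = np.empty((0, 2), dtype=np.int64)
    topo = ChromosomeTopology(
        species=np.concatenate([base.species, base.species]),
        chain_bonds=np.concatenate([base.chain_bonds, base.chain_bonds + n]),
        loop_springs=np.concatenate([base.loop_springs, base.loop_springs + n]),
        angle_triplets=np.concatenate([base.angle_triplets, base.angle_triplets + n]),
        loop_table=np.concatenate(
            [base.loop_table, base.loop_table + np.array([n, 0])]
        ),
        centromere_springs=centromere,
        n_chromatids=2,
    )
    topo.validate()
    return topo


@dataclass
class ScenarioSpec:
    """Perturbation recipe for knockout / fragile-site simulations."""

    name: str = "control"
    loop_length_factor: float = 1.0
    bridge_count: int | None = None
    perturbed_locus: int | None = None
    probe_regions: tuple[tuple[int, int], tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.loop_length_factor <= 0:
            raise TopologyError("loop_length_factor must be positive")


def apply_knockout(config: RunConfig, scenario: str) -> RunConfig:
    """Global condensin depletion as a config transformation.

    Condensin I knockout: residual condensin II makes loops longer
    (factor 2) and bridging weaker (bridge count halved).  Condensin II
    knockout: residual condensin I makes loops shorter (factor 1/2) and
    bridging stronger (bridge count doubled).
    """
    if scenario == "control":
        return config
    if scenario == "condI_KO":
        return config.replace(
            L_loop_beads=config.L_loop_beads * 2,
            n_bridges=config.n_bridges // 2,
            scenario=scenario,
        )
    if scenario == "condII_KO":
        return config.replace(
            L_loop_beads=max(MIN_LOOP_BEADS, config.L_loop_beads // 2),
            n_bridges=config.n_bridges * 2,
            scenario=scenario,
        )
    raise TopologyError(f"unknown knockout scenario {scenario!r}")


def apply_cfs_perturbation(
    topo: ChromosomeTopology, kind: str, locus: int
) -> ChromosomeTopology:
    """Local faulty condensin loading at a common fragile site.

    ``removal``: the loop-closure springs of loops ``locus`` and
    ``locus + 1`` are deleted and their anchors retagged as plain
    chromatin (local loss of looping condensins).  ``merge``: loops
    ``locus``..``locus + 2`` are replaced by a single spring spanning all
    three (faulty condensin II recruitment creating one oversized loop).
    Bridge counts are unchanged by construction — the perturbation only
    touches the polymer.
    """
    if kind == "none":
        return topo
    n_loops = topo.loop_table.shape[0]
    need = 2 if kind == "removal" else 3
    if not (0 <= locus and locus + need <= n_loops):
        raise TopologyError(
            f"{kind} at locus {locus} needs {need} consecutive loops "
            f"inside [0, {n_loops})"
        )
    species = topo.species.copy()
    springs = topo.loop_springs
    table = topo.loop_table
    if kind == "removal":
        keep = np.ones(n_loops, dtype=bool)
        keep[locus : locus + 2] = False
        species[table[locus : locus + 2, 0]] = CHROMATIN
        new = replace(
            topo,
            species=species,
            loop_springs=springs[keep],
            loop_table=table[keep],
        )
    elif kind == "merge":
        anchors = table[locus : locus + 3, 0]
        lengths = table[locus : locus + 3, 1]
        species[anchors[1:]] = CHROMATIN
        merged_spring = np.array(
            [[anchors[0], anchors[0] + lengths.sum() - 1]], dtype=np.int64
        )
        merged_row = np.array([[anchors[0], lengths.sum()]], dtype=np.int64)
        new = replace(
            topo,
            species=species,
            loop_springs=np.concatenate(
                [springs[:locus], merged_spring, springs[locus + 3 :]]
            ),
            loop_table=np.concatenate(
                [table[:locus], merged_row, table[locus + 3 :]]
            ),
        )
    else:
        raise TopologyError(f"unknown CFS perturbation {kind!r}")
    new.validate()
    return new


def place_bridges(
    n: int,
    box: float,
    seed: int,
    near: np.ndarray | None = None,
    margin: float = 2.0,
) -> np.ndarray:
    """Random bridge coordinates, reproducible from ``seed``.

    Without ``near``, positions are uniform over the centred cubic box.
    With ``near`` (e.g. the polymer coordinates), positions are uniform
    over the bounding box of those points expanded by ``margin`` — the
    dilute-bridge limit where binding onset is not rate-limited by
    diffusion across an arbitrarily large empty box.
    """
    if n < 0:
        raise TopologyError("bridge count must be >= 0")
    rng = np.random.default_rng(seed)
    if near is None or len(near) == 0:
        return rng.uniform(-box / 2.0, box / 2.0, size=(n, 3))
    lo = np.asarray(near).min(axis=0) - margin
    hi = np.asarray(near).max(axis=0) + margin
    lo = np.maximum(lo, -box / 2.0)
    hi = np.minimum(hi, box / 2.0)
    return rng.uniform(lo, hi, size=(n, 3))


def initial_bottlebrush_coords(
    topo: ChromosomeTopology,
    bond_length: float = 1.1,
    backbone_spacing: float = 1.5,
    jitter: float = 0.05,
    seed: int = 0,
    chromatid_offset: float = 6.0,
) -> np.ndarray:
    """Near-relaxed starting geometry: loops as circles around a straight axis.

    Anchors are placed along the z axis at ``backbone_spacing``; each loop
    is laid on a circle of circumference ``L * bond_length`` in a plane
    rotated by the golden angle from its predecessor, so bristles spread
    azimuthally as in a relaxed bottlebrush.  A short equilibration run
    removes the residual construction strain.
    """
    rng = np.random.default_rng(seed)
    pos = np.empty((topo.n_beads, 3))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    per = topo.beads_per_chromatid
    n_table = topo.loop_table.shape[0] // topo.n_chromatids
    for c in range(topo.n_chromatids):
        off = c * per
        x0 = c * chromatid_offset
        table = topo.loop_table[c * n_table : (c + 1) * n_table]
        if table.size == 0:  # unlooped chain: straight line
            k = np.arange(per)
            pos[off : off + per] = np.stack(
                [np.full(per, x0), np.zeros(per), bond_length * k], axis=1
            )
            continue
        z = 0.0
        for k in range(n_table):
            a = int(table[k, 0])  # loop-table anchors are absolute indices
            L = int(table[k, 1])
            radius = L * bond_length / (2.0 * np.pi)
            phi = k * golden + c * 0.5
            u = np.array([np.cos(phi), np.sin(phi), 0.0])
            theta = 2.0 * np.pi * np.arange(L) / L
            # circle through the anchor, extending radially outward
            radial = radius * (1.0 - np.cos(theta))
            axial = radius * np.sin(theta)
            pts = (
                np.array([x0, 0.0, z])
                + radial[:, None] * u[None, :]
                + axial[:, None] * np.array([0.0, 0.0, 1.0])
            )
            pos[a : a + L] = pts
            z += backbone_spacing
    pos += jitter * rng.standard_normal(pos.shape)
    pos -= pos.mean(axis=0)
    return pos
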