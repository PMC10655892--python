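"""Analysis suite: shape, stiffness, contact scaling, clustering, elasticity.

All functions take plain coordinate arrays (unwrapped, in sigma) so they
can be applied to live simulation states or to trajectories read back
from disk.  Genomic axes are expressed in kbp through a
:class:`~condensac.units.UnitSystem`; lengths stay in sigma unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .units import UnitSystem

#: spatial cutoff defining a chromatin-chromatin contact for P(s)
CONTACT_CUTOFF = 3.5
#: bridge-bridge single-linkage cutoff for cluster analysis
CLUSTER_CUTOFF = 1.3
#: bridge-chromatin distance defining valence (22 nm at sigma = 20 nm)
VALENCE_RANGE = 1.1


class WrappedCoordinateError(ValueError):
    """A bond spans more than half the box: coordinates look wrapped."""


@dataclass
class ShapeDescriptors:
    """Gyration-tensor shape summary of a bead cloud.

    ``axes`` are the square roots of the gyration-tensor eigenvalues in
    ascending order (lambda1 <= lambda2 <= lambda3), so that
    ``Rg**2 == (axes**2).sum()``.  Acylindricity ``Ac = lambda2 - lambda1``
    vanishes for an ideal cylinder (and for a line) and grows as the
    cross-section becomes elliptical.
    """

    Rg: float
    axes: np.ndarray               # (3,) ascending
    Ac: float
    extension: float | None = None
    width: float | None = None


@dataclass
class ContactCurve:
    """Binned contact probability P(s) and its intermediate-s power law."""

    s_kbp: np.ndarray
    P: np.ndarray
    fit_exponent: float
    fit_range: tuple[float, float]   # kbp


@dataclass
class ClusterStats:
    """Single-linkage cluster statistics of bridging condensins."""

    cluster_sizes: np.ndarray
    N_c: int
    S_c: float
    valence: float | None = None


def _check_unwrapped(positions: np.ndarray, box: float,
                     bonds: np.ndarray | None) -> None:
    if box > 0 and bonds is not None and len(bonds):
        d = positions[bonds[:, 1]] - positions[bonds[:, 0]]
        if np.any(np.abs(d) > box / 2.0):
            raise WrappedCoordinateError(
                "bond longer than half the box; unwrap coordinates first"
            )


def radius_of_gyration(
    positions: np.ndarray,
    box: float = 0.0,
    bonds: np.ndarray | None = None,
) -> float:
    """Root-mean-squared distance of beads from their centre of mass."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 1:
        raise ValueError("need at least one bead")
    _check_unwrapped(positions, box, bonds)
    d = positions - positions.mean(axis=0)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def gyration_tensor_shape(positions: np.ndarray) -> ShapeDescriptors:
    """Shape descriptors from the eigen-decomposition of the gyration tensor."""
    positions = np.asarray(positions, dtype=float)
    d = positions - positions.mean(axis=0)
    tensor = d.T @ d / positions.shape[0]
    eigvals = np.linalg.eigvalsh(tensor)          # ascending
    axes = np.sqrt(np.clip(eigvals, 0.0, None))
    return ShapeDescriptors(
        Rg=float(np.sqrt(eigvals.sum())),
        axes=axes,
        Ac=float(axes[1] - axes[0]),
    )


def principal_axis(positions: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the gyration tensor's largest eigenvalue."""
    positions = np.asarray(positions, dtype=float)
    d = positions - positions.mean(axis=0)
    tensor = d.T @ d / positions.shape[0]
    _, vecs = np.linalg.eigh(tensor)
    return vecs[:, -1]


def _coarse_tangents(backbone: np.ndarray, stride: int) -> np.ndarray:
    pts = backbone[::stride]
    if pts.shape[0] < 2:
        raise ValueError(f"stride {stride} too large for backbone")
    seg = np.diff(pts, axis=0)
    norm = np.linalg.norm(seg, axis=1)
    good = norm > 1e-12
    return seg[good] / norm[good, None]


def tangent_correlation(
    backbone: np.ndarray,
    stride: int = 5,
    max_sep: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tangent-tangent correlation of the coarse-grained backbone.

    The backbone (ordered anchor beads) is decimated to every
    ``stride``-th point to smooth local crumpling; the function returns
    (separation in coarse segments, mean normalised dot product).  A
    stiff cylinder keeps the correlation near 1; a relaxed bottlebrush
    typically shows a negative dip at intermediate separations,
    reflecting its weakly helical backbone.
    """
    t = _coarse_tangents(np.asarray(backbone, dtype=float), stride)
    m = t.shape[0]
    if max_sep is None:
        max_sep = m - 1
    max_sep = min(max_sep, m - 1)
    seps = np.arange(max_sep + 1)
    corr = np.empty(seps.shape[0])
    for k in seps:
        corr[k] = float((t[: m - k] * t[k:]).sum(axis=1).mean())
    return seps, corr


def tangent_correlation_ensemble(
    frames: np.ndarray,
    backbone_idx: np.ndarray,
    stride: int = 5,
    max_sep: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-averaged tangent correlation (frames: (T, N, 3))."""
    acc = None
    for f in frames:
        seps, c = tangent_correlation(f[backbone_idx], stride, max_sep)
        acc = c if acc is None else acc + c
    return seps, acc / frames.shape[0]


def persistence_length(
    frames: np.ndarray,
    bond_length: float | None = None,
    fit_max: int = 10,
) -> float:
    """Exponential decay length of bond-tangent correlations, in sigma.

    ``frames`` holds chain snapshots (T, N, 3).  The log of the mean
    tangent correlation is fitted linearly over separations
    ``1..fit_max`` bonds; the persistence length is -b/slope with b the
    mean bond length (measured from the data unless given).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    T, n, _ = frames.shape
    seg = np.diff(frames, axis=1)                      # (T, n-1, 3)
    norm = np.linalg.norm(seg, axis=2)
    t = seg / norm[..., None]
    if bond_length is None:
        bond_length = float(norm.mean())
    fit_max = min(fit_max, n - 2)
    seps = np.arange(1, fit_max + 1)
    corr = np.empty(fit_max)
    for k in seps:
        corr[k - 1] = float((t[:, : n - 1 - k] * t[:, k:]).sum(axis=2).mean())
    good = corr > 0.05
    if good.sum() < 2:
        raise ValueError("correlation decays too fast to fit")
    slope = np.polyfit(seps[good], np.log(corr[good]), 1)[0]
    if slope >= 0:
        raise ValueError("non-decaying tangent correlation")
    return float(-bond_length / slope)


def contact_probability(
    frames: np.ndarray,
    contact_cutoff: float = CONTACT_CUTOFF,
    units: UnitSystem | None = None,
    n_bins: int = 30,
    fit_range_kbp: tuple[float, float] | None = None,
) -> ContactCurve:
    """Contact probability versus genomic separation, with power-law fit.

    ``frames`` holds chromatin coordinates of a single chromatid
    (T, N, 3).  Two beads are in contact when closer than
    ``contact_cutoff``; P(s) is the fraction of bead pairs at genomic
    separation s (binned log-uniformly) found in contact, averaged over
    frames.  The exponent is a least-squares slope of log P versus
    log s over one intermediate decade: by default 100 kbp up to a tenth
    of the polymer length, the window where mitotic chromosomes show
    P(s) ~ s^(-1/2).
    """
    units = units or UnitSystem()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    T, n, _ = frames.shape
    if T < 1 or n < 3:
        raise ValueError("need at least one frame of at least three beads")
    kbp_per_bead = units.bp_per_bead / 1e3

    counts = np.zeros(n, dtype=np.int64)               # contacts per s (beads)
    for f in frames:
        tree = cKDTree(f)
        pairs = tree.query_pairs(contact_cutoff, output_type="ndarray")
        if pairs.size:
            s = np.abs(pairs[:, 0] - pairs[:, 1])
            counts += np.bincount(s, minlength=n)
    totals = T * (n - np.arange(n))                    # pairs per separation

    edges = np.unique(
        np.round(np.logspace(0, np.log10(n - 1), n_bins + 1)).astype(int)
    )
    s_mid, P = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        c = counts[lo:hi].sum()
        t = totals[lo:hi].sum()
        if t > 0:
            s_mid.append(np.sqrt(lo * (hi - 1)) * kbp_per_bead)
            P.append(c / t)
    s_kbp = np.array(s_mid)
    P = np.array(P)

    if fit_range_kbp is None:
        fit_range_kbp = (100.0, n * kbp_per_bead / 10.0)
    lo, hi = fit_range_kbp
    sel = (s_kbp >= lo) & (s_kbp <= hi) & (P > 0)
    if sel.sum() < 2:
        raise ValueError("fit range contains fewer than two non-empty bins")
    exponent = float(np.polyfit(np.log(s_kbp[sel]), np.log(P[sel]), 1)[0])
    return ContactCurve(s_kbp=s_kbp, P=P, fit_exponent=exponent,
                        fit_range=(float(lo), float(hi)))


def cluster_bridges(
    bridge_positions: np.ndarray,
    linkage_cutoff: float = CLUSTER_CUTOFF,
) -> ClusterStats:
    """Single-linkage clusters of bridge particles under a distance cutoff."""
    pos = np.asarray(bridge_positions, dtype=float)
    n = pos.shape[0]
    if n == 0:
        return ClusterStats(cluster_sizes=np.empty(0, dtype=int), N_c=0,
                            S_c=0.0)
    pairs = cKDTree(pos).query_pairs(linkage_cutoff, output_type="ndarray")
    if pairs.size:
        graph = coo_matrix(
            (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])),
            shape=(n, n),
        )
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)
    sizes = np.bincount(labels)
    return ClusterStats(
        cluster_sizes=np.sort(sizes)[::-1],
        N_c=int(sizes.shape[0]),
        S_c=float(sizes.mean()),
    )


def bridge_valence(
    bridge_positions: np.ndarray,
    chromatin_positions: np.ndarray,
    contact_range: float = VALENCE_RANGE,
) -> float:
    """Mean number of chromatin beads within reach of a bridge (~3 in a SAC)."""
    bpos = np.asarray(bridge_positions, dtype=float)
    if bpos.shape[0] == 0:
        return 0.0
    tree = cKDTree(np.asarray(chromatin_positions, dtype=float))
    counts = tree.query_ball_point(bpos, contact_range, return_length=True)
    return float(np.mean(counts))


def extension_and_width(
    positions: np.ndarray,
    end_beads: tuple[int, int],
) -> tuple[float, float]:
    """End-to-end extension and transverse width of the chromosome.

    Width is twice the RMS radial distance of beads from the principal
    (longest) gyration axis through the centre of mass; for beads on a
    cylindrical shell of radius R it evaluates to 2R.
    """
    pos = np.asarray(positions, dtype=float)
    a, b = end_beads
    extension = float(np.linalg.norm(pos[a] - pos[b]))
    axis = principal_axis(pos)
    d = pos - pos.mean(axis=0)
    radial2 = (d * d).sum(axis=1) - (d @ axis) ** 2
    width = 2.0 * float(np.sqrt(np.clip(radial2, 0.0, None).mean()))
    return extension, width


def local_stiffness(backbone: np.ndarray, stride: int = 5) -> float:
    """Mean cosine of the turning angle between successive coarse segments.

    1 for a straight backbone, 0 for right-angle kinks and for an
    uncorrelated random walk.
    """
    t = _coarse_tangents(np.asarray(backbone, dtype=float), stride)
    if t.shape[0] < 2:
        raise ValueError("need at least three coarse-grained points")
    return float((t[:-1] * t[1:]).sum(axis=1).mean())


def probe_distance(
    frames: np.ndarray,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
) -> float:
    """Time-averaged 3D distance between two probe regions' centres of mass.

    Mimics a two-colour FISH measurement: each region is a bead-index
    interval [lo, hi); the reported value is the mean over frames of the
    distance between the two regional centres of mass.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    (a0, a1), (b0, b1) = region_a, region_b
    if a1 <= a0 or b1 <= b0:
        raise ValueError("probe regions must be non-empty")
    ca = frames[:, a0:a1].mean(axis=1)
    cb = frames[:, b0:b1].mean(axis=1)
    return float(np.linalg.norm(ca - cb, axis=1).mean())


def bristle_repulsion(T: float, spacing: float, a: float, N: float) -> float:
    """Relative repulsive force per unit axial length between two bristles.

    F ~ (T / spacing) * sqrt(N a / (pi spacing)) with unit prefactor:
    only ratios of returned values are meaningful.  Averaged over a
    Poisson loop-length distribution the concave sqrt(N) dependence
    makes the mean force smaller than the uniform-loop value at the
    same mean, which is why variable loops compact further.
    """
    if T <= 0 or spacing <= 0 or a <= 0 or N < 0:
        raise ValueError("all arguments must be positive")
    return (T / spacing) * np.sqrt(N * a / (np.pi * spacing))
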