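"""Synthetic Cα models with analytically known mechanics.

Three families cover every stage of the workflow without any structure
download: a two-bead dimer (the one-spring network whose single internal
mode is known in closed form), an ideal α-helix trace (a connected
single-body network with the classic floppy-end fluctuation profile), and a
two-lobe dumbbell (a controllable two-domain protein surrogate whose
lobe-separating mode and packing asymmetry are built in by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pullnma.geometry import PullingGeometry
from pullnma.mode_analysis import DomainMap
from pullnma.structure_io import CoarseModel, ResidueId

logger = logging.getLogger(__name__)

#: minimum bead separation used when packing lobes (≈ Cα-Cα bond distance floor)
MIN_BEAD_DISTANCE = 3.4


@dataclass(frozen=True)
class DumbbellSpec:
    """Two quasi-spherical lobes joined by a linear linker along x.

    ``lobe_packing_radius`` may be one radius for both lobes or a pair
    (radius_a, radius_b); with the same bead count, a larger radius means a
    looser, less packed lobe.
    """

    n_per_lobe: int = 36
    lobe_packing_radius: float | tuple[float, float] = 7.8
    linker_length: int = 6
    separation: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_lobe < 4:
            raise ValueError("n_per_lobe must be >= 4")
        if self.linker_length < 1:
            raise ValueError("linker_length must be >= 1")
        ra, rb = self.radii
        if self.separation <= 2 * max(ra, rb):
            raise ValueError("separation must exceed twice the largest lobe radius")

    @property
    def radii(self) -> tuple[float, float]:
        r = self.lobe_packing_radius
        if isinstance(r, (tuple, list)):
            ra, rb = float(r[0]), float(r[1])
        else:
            ra = rb = float(r)
        if min(ra, rb) <= 0:
            raise ValueError("lobe radii must be positive")
        return ra, rb


def _model(coords: np.ndarray, label: str, names=None) -> CoarseModel:
    n = len(coords)
    return CoarseModel(
        coords=np.asarray(coords, dtype=float),
        residue_names=list(names) if names is not None else ["ALA"] * n,
        residue_ids=[ResidueId("A", i + 1) for i in range(n)],
        source_label=label,
    )


def make_dimer(d0: float = 3.8) -> CoarseModel:
    """Two beads a distance d0 apart on the x-axis: the analytic one-spring network.

    With spring constant gamma its only internal mode has eigenvalue
    2*gamma along the bond, and five rigid-body modes remain.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    return _model(np.array([[0.0, 0.0, 0.0], [d0, 0.0, 0.0]]), f"dimer(d0={d0})")


def make_helix(n_residues: int) -> CoarseModel:
    """Ideal α-helix Cα trace: rise 1.5 Å, 100° per residue, radius 2.3 Å."""
    if n_residues < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    coords = np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )
    return _model(coords, f"helix(n={n_residues})")


def _pack_sphere(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n points uniform in a sphere with a minimum pair distance."""
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        attempts += 1
        if attempts > 200_000:
            raise ValueError(
                f"cannot pack {n} beads at spacing {MIN_BEAD_DISTANCE} Å "
                f"into a sphere of radius {radius} Å"
            )
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) > radius:
            continue
        if points and np.min(np.linalg.norm(np.array(points) - p, axis=1)) < MIN_BEAD_DISTANCE:
            continue
        points.append(p)
    return np.array(points)


def make_dumbbell(spec: DumbbellSpec | None = None):
    """Two-lobe bead model with linker, domain map and pulling geometry.

    Lobes are rejection-sampled uniform sphere packings centered at
    ±separation/2 on the x-axis; the linker is a straight bead chain between
    them.  Attachments are the outermost beads of each lobe, so pulling acts
    along x.  With unequal packing radii the looser lobe has measurably
    lower buried volume and stiffness — a ground truth for integrity ranking.

    Returns ``(model, domain_map, pulling_geometry)``.
    """
    if spec is None:
        spec = DumbbellSpec()
    ra, rb = spec.radii
    rng = np.random.default_rng(spec.seed)
    half = spec.separation / 2.0

    for attempt in range(10):
        lobe_a = _pack_sphere(spec.n_per_lobe, ra, rng) + np.array([-half, 0.0, 0.0])
        lobe_b = _pack_sphere(spec.n_per_lobe, rb, rng) + np.array([half, 0.0, 0.0])
        x_start, x_end = -half + ra, half - rb
        linker_x = np.linspace(x_start, x_end, spec.linker_length + 2)[1:-1]
        # helical offset: a collinear (or planar) linker would leave torsion or
        # transverse motions as spurious zero-energy mechanisms in a
        # distance-only spring network
        phase = 2.0 * np.pi / 3.0 * np.arange(spec.linker_length)
        linker = np.column_stack(
            [linker_x, 1.2 * np.cos(phase), 1.2 * np.sin(phase)]
        )
        coords = np.vstack([lobe_a, linker, lobe_b])
        d = np.linalg.norm(coords[None, :, :] - coords[:, None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() >= 1.0:
            break
        logger.info("dumbbell attempt %d produced beads closer than 1 Å; regenerating", attempt)
    else:
        raise ValueError("could not generate a dumbbell without bead overlaps")

    model = _model(
        coords,
        f"dumbbell(n={spec.n_per_lobe},r=({ra},{rb}),sep={spec.separation},seed={spec.seed})",
    )
    na = spec.n_per_lobe
    dm = DomainMap(
        {
            "lobeA": np.arange(na),
            "lobeB": np.arange(na + spec.linker_length, na + spec.linker_length + na),
        }
    )
    ia = int(np.argmin(coords[:, 0]))
    ib = int(np.argmax(coords[:, 0]))
    pull = PullingGeometry(
        attach_a=model.residue_ids[ia],
        attach_b=model.residue_ids[ib],
    )
    return model, dm, pull
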