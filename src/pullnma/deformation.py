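"""Generate conformations distorted along normal modes.

Distorted structures are linear displacements of the Cα trace along
eigenvector combinations, rescaled so that the raw RMSD to the reference
equals a chosen target exactly.  Because the unfolding-direction content of
a random combination is stochastic — one draw may pull the domains apart,
the next push them together — ensembles are evaluated statistically
downstream.  Frames are Cα-only and locally unphysical at large amplitude;
they are interpreted through buried-volume statistics, not as structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pullnma.enm import ModeSet
from pullnma.geometry import rmsd
from pullnma.structure_io import CoarseModel

#: guard against absurd amplitude requests (linear ENM extrapolation only)
DEFAULT_RMSD_CAP = 20.0


@dataclass(frozen=True)
class DeformationSpec:
    """What to distort along, how far, and how many frames.

    ``weighting`` controls the random mode coefficients: ``inverse_lambda``
    scales each draw by 1/sqrt(lambda_k) so softer modes dominate (physical
    thermal amplitudes); ``equal`` gives every selected mode the same
    variance.  The final rescale to the target RMSD removes the overall
    scale either way.
    """

    mode_indices: tuple[int, ...]
    target_rmsd: float
    n_conformations: int = 500
    seed: int = 0
    weighting: str = "inverse_lambda"  # or "equal"
    single_mode_direction: int = +1
    rmsd_cap: float = DEFAULT_RMSD_CAP

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode_indices", tuple(int(k) for k in self.mode_indices))
        if not self.mode_indices:
            raise ValueError("at least one mode index is required")
        if self.target_rmsd < 0:
            raise ValueError("target_rmsd must be >= 0")
        if self.target_rmsd > self.rmsd_cap:
            raise ValueError(
                f"target_rmsd {self.target_rmsd} exceeds the sanity cap {self.rmsd_cap} Å"
            )
        if self.n_conformations < 1:
            raise ValueError("n_conformations must be >= 1")
        if self.weighting not in ("inverse_lambda", "equal"):
            raise ValueError("weighting must be 'inverse_lambda' or 'equal'")
        if self.single_mode_direction not in (-1, +1):
            raise ValueError("single_mode_direction must be +1 or -1")


@dataclass
class DeformedEnsemble:
    """Frames produced along selected modes, with full provenance.

    ``coefficients[f, m]`` is the (post-rescale) coefficient of
    ``mode_indices[m]`` in frame f, so every frame is reconstructable as
    reference + sum_m coefficients[f, m] * a_m.
    """

    reference: CoarseModel
    frames: np.ndarray  # (M, N, 3)
    mode_indices: tuple[int, ...]
    coefficients: np.ndarray  # (M, n_modes)
    achieved_rmsd: np.ndarray  # (M,)
    spec: DeformationSpec | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def coefficient_table(self) -> pd.DataFrame:
        """Long-form log (frame, mode, coefficient, achieved_rmsd)."""
        rows = []
        for f in range(self.n_frames):
            for m, k in enumerate(self.mode_indices):
                rows.append(
                    {
                        "frame": f,
                        "mode": k,
                        "coefficient": float(self.coefficients[f, m]),
                        "achieved_rmsd": float(self.achieved_rmsd[f]),
                    }
                )
        return pd.DataFrame(rows)


def _mode_basis(modes: ModeSet, mode_indices) -> np.ndarray:
    """(n_sel, 3N) orthonormal eigenvector rows for 1-based indices."""
    return np.stack([modes.mode_vector(k) for k in mode_indices])


def deform_single_mode(
    modes: ModeSet, k: int, target_rmsd: float, direction: int = +1
) -> np.ndarray:
    """Single deterministic deformation along non-zero mode k (1-based).

    Because the eigenvector has unit norm, a flat-space step of amplitude s
    produces RMSD |s|/sqrt(N); the closed-form amplitude is therefore
    s = direction * target_rmsd * sqrt(N).  Returns the (N, 3) coordinates.
    """
    if direction not in (-1, +1):
        raise ValueError("direction must be +1 or -1")
    n = modes.n_sites
    a = modes.mode_matrix(k)
    s = direction * target_rmsd * np.sqrt(n)
    return modes.reference_coords + s * a


def pseudo_trajectory(modes: ModeSet, k: int, max_rmsd: float, n_frames: int = 11) -> DeformedEnsemble:
    """Sweep mode k from -max_rmsd through the reference to +max_rmsd.

    Frames sample the amplitude uniformly, so an odd frame count puts the
    reference structure in the middle; viewers loop the file to show the
    oscillation.  Coefficients are logged so any frame is reconstructable.
    """
    if n_frames < 3:
        raise ValueError("a pseudo-trajectory needs at least 3 frames")
    n = modes.n_sites
    s_max = max_rmsd * np.sqrt(n)
    s_values = np.linspace(-s_max, s_max, n_frames)
    a = modes.mode_matrix(k)
    frames = modes.reference_coords[None, :, :] + s_values[:, None, None] * a[None, :, :]
    reference = _reference_model(modes)
    achieved = np.abs(s_values) / np.sqrt(n)
    return DeformedEnsemble(
        reference=reference,
        frames=frames,
        mode_indices=(k,),
        coefficients=s_values[:, None].copy(),
        achieved_rmsd=achieved,
        spec=None,
    )


def _reference_model(modes: ModeSet) -> CoarseModel:
    from pullnma.structure_io import ResidueId

    if modes.reference_coords is None:
        raise ValueError("mode set lacks reference coordinates")
    n = modes.n_sites
    return CoarseModel(
        coords=modes.reference_coords.copy(),
        residue_names=["ALA"] * n,
        residue_ids=[ResidueId("A", i + 1) for i in range(n)],
        source_label="modeset-reference",
    )


def sample_ensemble(
    modes: ModeSet, spec: DeformationSpec, reference: CoarseModel | None = None
) -> DeformedEnsemble:
    """Stochastic ensemble at an exact target RMSD.

    Per frame, each selected mode receives a zero-mean unit-variance normal
    coefficient scaled by its weight; the combined displacement is rescaled
    so the frame RMSD equals the target exactly.  Deterministic given
    ``spec.seed``; all post-rescale coefficients are logged.
    """
    basis = _mode_basis(modes, spec.mode_indices)  # (m, 3N)
    lam = np.array([modes.eigenvalue(k) for k in spec.mode_indices])
    weights = 1.0 / np.sqrt(lam) if spec.weighting == "inverse_lambda" else np.ones_like(lam)
    n = modes.n_sites
    rng = np.random.default_rng(spec.seed)

    if reference is None:
        reference = _reference_model(modes)
    ref_coords = reference.coords

    frames = np.empty((spec.n_conformations, n, 3))
    coeffs = np.empty((spec.n_conformations, len(spec.mode_indices)))
    achieved = np.empty(spec.n_conformations)
    for f in range(spec.n_conformations):
        c = rng.standard_normal(len(spec.mode_indices)) * weights
        while not np.any(c):  # probability ~0; redraw rather than divide by zero
            c = rng.standard_normal(len(spec.mode_indices)) * weights
        delta = c @ basis  # (3N,)
        current = np.linalg.norm(delta) / np.sqrt(n)
        scale = spec.target_rmsd / current if current > 0 else 0.0
        c = c * scale
        delta = delta * scale
        frames[f] = ref_coords + delta.reshape(n, 3)
        coeffs[f] = c
        achieved[f] = rmsd(frames[f], ref_coords)
    return DeformedEnsemble(
        reference=reference,
        frames=frames,
        mode_indices=spec.mode_indices,
        coefficients=coeffs,
        achieved_rmsd=achieved,
        spec=spec,
    )


def derive_subseed(seed: int, step_index: int) -> int:
    """Deterministic per-step seed below 2**31 (stated splitting rule)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(step_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def rmsd_ramp(
    modes: ModeSet,
    mode_indices,
    targets,
    n_per_step: int,
    seed: int = 0,
    weighting: str = "inverse_lambda",
    reference: CoarseModel | None = None,
) -> list[DeformedEnsemble]:
    """Independent ensembles at strictly increasing RMSD targets.

    Each step uses a sub-seed derived from (seed, step index), so any step
    can be reproduced on its own.
    """
    targets = [float(t) for t in targets]
    if any(b <= a for a, b in zip(targets, targets[1:])):
        raise ValueError(f"targets must be strictly increasing, got {targets}")
    ensembles = []
    for step, target in enumerate(targets):
        spec = DeformationSpec(
            mode_indices=tuple(mode_indices),
            target_rmsd=target,
            n_conformations=n_per_step,
            seed=derive_subseed(seed, step),
            weighting=weighting,
        )
        ensembles.append(sample_ensemble(modes, spec, reference=reference))
    return ensembles
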