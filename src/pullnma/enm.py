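"""Anisotropic elastic network model: Hessian assembly and normal modes.

Every pair of Cα beads closer than a cutoff R_c in the reference structure
is joined by a harmonic spring with a uniform force constant.  The network
potential is

    V(d) = sum over contacts of (gamma / 2) * (d_ij - d_ij0)^2,

whose Hessian at the reference structure has the familiar anisotropic-
network super-element structure: -gamma * (e_ij ⊗ e_ij) off the diagonal
for contacts, with diagonal blocks closing each row to zero (translation
invariance).  Eigenvalues are reported in units of gamma; nothing here is
calibrated to absolute kcal/mol, so fluctuation and stiffness outputs are
relative quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist

from pullnma.errors import DisconnectedNetworkWarning, ZeroModeSeparationError
from pullnma.structure_io import CoarseModel

#: A dense, symmetric, positive semi-definite 3N x 3N matrix.
HessianMatrix = np.ndarray


@dataclass(frozen=True)
class ENMParameters:
    """Elastic-network parameters.

    cutoff_rc : contact cutoff in Å. Physically sensible values lie between
        8 and 20 Å for Cα networks; the default 15 Å sits mid-range.
    gamma : uniform spring constant (arbitrary units; scales all eigenvalues).
    n_modes : number of non-zero modes to retain, or "all". Mechanical
        stiffness requires the complete spectrum.
    """

    cutoff_rc: float = 15.0
    gamma: float = 1.0
    n_modes: Union[int, str] = 50

    def __post_init__(self) -> None:
        if self.cutoff_rc <= 0:
            raise ValueError("cutoff_rc must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if isinstance(self.n_modes, str):
            if self.n_modes != "all":
                raise ValueError("n_modes must be a positive integer or 'all'")
        elif self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")


@dataclass
class ModeSet:
    """Non-zero normal modes of an elastic network.

    ``eigenvalues[k]`` and ``eigenvectors[k]`` (a unit-norm 3N vector)
    describe non-zero mode k+1; the public API is 1-based over non-zero
    modes, matching how modes are quoted in the literature.
    """

    eigenvalues: np.ndarray  # (K,), ascending, > 0
    eigenvectors: np.ndarray  # (K, 3N), rows unit-norm, mutually orthonormal
    n_zero_modes: int
    n_sites: int
    params: ENMParameters | None = None
    reference_coords: np.ndarray | None = None  # (N, 3)
    n_internal_modes: int = 0  # size of the full non-zero spectrum

    @property
    def n_modes(self) -> int:
        """Number of retained non-zero modes."""
        return len(self.eigenvalues)

    @property
    def is_complete(self) -> bool:
        """True if every non-zero mode of the network is present."""
        return self.n_modes == self.n_internal_modes

    def _check_index(self, k: int) -> int:
        if not 1 <= k <= self.n_modes:
            raise IndexError(f"mode index {k} out of range 1..{self.n_modes}")
        return k - 1

    def eigenvalue(self, k: int) -> float:
        return float(self.eigenvalues[self._check_index(k)])

    def mode_vector(self, k: int) -> np.ndarray:
        """Flat 3N eigenvector of non-zero mode k (1-based)."""
        return self.eigenvectors[self._check_index(k)]

    def mode_matrix(self, k: int) -> np.ndarray:
        """Eigenvector of non-zero mode k reshaped to per-site (N, 3) displacements."""
        return self.mode_vector(k).reshape(self.n_sites, 3)

    def to_nmd(self, path, labels=None) -> None:
        """Write modes in the NMD-style text format used by mode viewers:
        one ``mode <index> <eigenvalue> <3N floats>`` line per mode."""
        with open(path, "w") as fh:
            fh.write(f"nmd generated by pullnma (n_sites={self.n_sites})\n")
            if self.reference_coords is not None:
                fh.write("coordinates " + " ".join(
                    f"{x:.3f}" for x in np.asarray(self.reference_coords).ravel()) + "\n")
            if labels is not None:
                fh.write("resids " + " ".join(str(l) for l in labels) + "\n")
            for k in range(1, self.n_modes + 1):
                vec = " ".join(f"{x:.6e}" for x in self.mode_vector(k))
                fh.write(f"mode {k} {self.eigenvalue(k):.8e} {vec}\n")


def _contact_pairs(coords: np.ndarray, cutoff: float):
    """Index pairs (i < j) with reference distance below the cutoff, plus distances."""
    dists = pdist(coords)
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = dists < cutoff
    return iu[mask], ju[mask], dists[mask]


def enm_energy(reference: CoarseModel, coords: np.ndarray, params: ENMParameters) -> float:
    """Network strain energy of ``coords`` relative to the reference structure.

    The contact topology is fixed by the reference distances; the energy is
    (gamma/2) * sum over contacts of (d_ij - d_ij0)^2 and is zero at the
    reference by construction.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != reference.coords.shape:
        raise ValueError(
            f"coords shape {coords.shape} does not match reference {reference.coords.shape}"
        )
    i, j, d0 = _contact_pairs(reference.coords, params.cutoff_rc)
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    return float(0.5 * params.gamma * np.sum((d - d0) ** 2))


def build_hessian(model: CoarseModel, params: ENMParameters) -> HessianMatrix:
    """Assemble the dense 3N x 3N elastic-network Hessian.

    Off-diagonal super-element for a contact (i, j): -gamma * (e_ij ⊗ e_ij),
    where e_ij is the unit vector along the reference bond; diagonal blocks
    are minus the sum of the off-diagonal blocks in their row, which makes
    uniform translations exact zero modes.
    """
    coords = model.coords
    n = model.n_sites
    i_idx, j_idx, d0 = _contact_pairs(coords, params.cutoff_rc)
    if len(i_idx) == 0:
        raise ValueError(f"no contact pairs under cutoff {params.cutoff_rc} Å")

    # warn (don't fail) on a fragmented network; eigendecomposition will
    # produce 6 zero modes per rigid component
    adj = np.zeros((n, n), dtype=bool)
    adj[i_idx, j_idx] = True
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"contact graph has {n_comp} connected components at cutoff "
            f"{params.cutoff_rc} Å; expect more than 6 zero modes",
            DisconnectedNetworkWarning,
            stacklevel=2,
        )

    H = np.zeros((3 * n, 3 * n))
    e = (coords[j_idx] - coords[i_idx]) / d0[:, None]
    blocks = -params.gamma * np.einsum("ka,kb->kab", e, e)  # (n_contacts, 3, 3)
    for (i, j), blk in zip(zip(i_idx, j_idx), blocks):
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += blk
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += blk
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= blk
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= blk
    return H


def compute_modes(
    H: HessianMatrix,
    n_modes: Union[int, str] = "all",
    zero_tol: float = 1e-8,
    reference_coords: np.ndarray | None = None,
    params: ENMParameters | None = None,
) -> ModeSet:
    """Diagonalize the Hessian and separate rigid-body from internal modes.

    Eigenpairs are sorted ascending; eigenvalues at or below
    ``zero_tol * lambda_max`` are counted as rigid-body (zero) modes and
    dropped.  A connected 3-D network must yield exactly six; any other count
    triggers a structural warning.  A spectral gap of at least three orders
    of magnitude between the largest discarded and smallest retained
    eigenvalue is required — without it the zero-mode split is not trustworthy.
    """
    H = np.asarray(H, dtype=float)
    dim = H.shape[0]
    if H.shape != (dim, dim) or dim % 3 != 0:
        raise ValueError("Hessian must be square with dimension divisible by 3")
    n_sites = dim // 3
    evals, evecs = scipy.linalg.eigh(H)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise ValueError("Hessian has no positive eigenvalue")
    threshold = zero_tol * lam_max
    n_zero = int(np.sum(evals <= threshold))
    if n_zero == 0 or n_zero == dim:
        raise ZeroModeSeparationError(
            f"implausible zero-mode count {n_zero} (threshold {threshold:.3e})"
        )
    largest_zero = float(np.max(np.abs(evals[:n_zero])))
    smallest_nonzero = float(evals[n_zero])
    if largest_zero > 0 and smallest_nonzero / largest_zero < 1e3:
        raise ZeroModeSeparationError(
            "rigid-body and internal eigenvalues are separated by less than 3 "
            f"orders of magnitude ({largest_zero:.3e} vs {smallest_nonzero:.3e})"
        )
    expected_zero = 5 if n_sites == 2 else 6
    if n_zero != expected_zero:
        warnings.warn(
            f"{n_zero} zero modes found where {expected_zero} were expected: "
            "the network may be disconnected or degenerate",
            DisconnectedNetworkWarning,
            stacklevel=2,
        )
    n_internal = dim - n_zero
    if n_modes == "all":
        keep = n_internal
    else:
        keep = int(n_modes)
        if keep > n_internal:
            warnings.warn(
                f"requested {keep} modes but only {n_internal} internal modes exist; using all",
                UserWarning,
                stacklevel=2,
            )
            keep = n_internal
    sel = slice(n_zero, n_zero + keep)
    return ModeSet(
        eigenvalues=evals[sel].copy(),
        eigenvectors=evecs[:, sel].T.copy(),
        n_zero_modes=n_zero,
        n_sites=n_sites,
        params=params,
        reference_coords=None if reference_coords is None else np.asarray(reference_coords, dtype=float).copy(),
        n_internal_modes=n_internal,
    )


def compute_enm_modes(model: CoarseModel, params: ENMParameters | None = None) -> ModeSet:
    """Convenience: build the Hessian for ``model`` and diagonalize it."""
    if params is None:
        params = ENMParameters()
    H = build_hessian(model, params)
    return compute_modes(
        H, n_modes=params.n_modes, reference_coords=model.coords, params=params
    )
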