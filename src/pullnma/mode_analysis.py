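"""Per-residue and per-mode observables, and selection of domain-separating modes.

The observables follow standard elastic-network practice:

* square fluctuations  f_i = sum_k (1/lambda_k) |a_k,i|^2  — per-residue
  amplitude over the softest modes (relative, gamma-normalized units);
* effective force constant between two residues (Eyal–Bahar): the inverse
  of the mode-summed compliance of their separation projected on the
  connecting vector, using the complete spectrum;
* degree of collectivity (Brüschweiler): entropy-based measure in [1/N, 1]
  of how many sites participate in a mode;
* signed axis components of each mode, and their per-domain means — the
  quantity used to spot modes that drive two domains apart along the
  pulling axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pullnma.enm import ModeSet
from pullnma.errors import InsufficientModesError, SelectionError
from pullnma.structure_io import CoarseModel, parse_ranges


class DomainMap(dict):
    """Named, disjoint sets of bead indices (``name -> sorted index array``)."""

    def __init__(self, entries: Mapping[str, Sequence[int]]):
        resolved = {}
        claimed: set[int] = set()
        for name, indices in entries.items():
            idx = np.unique(np.asarray(indices, dtype=int))
            if idx.size == 0:
                raise ValueError(f"domain {name!r} is empty")
            overlap = claimed.intersection(idx.tolist())
            if overlap:
                raise ValueError(f"domain {name!r} overlaps another domain at indices {sorted(overlap)[:5]}")
            claimed.update(idx.tolist())
            resolved[name] = idx
        super().__init__(resolved)

    @classmethod
    def from_ranges(cls, model: CoarseModel, spec: Mapping[str, str]) -> "DomainMap":
        """Resolve residue-range strings like ``{"NTD": "A:13-60"}`` against a model."""
        entries = {}
        for name, ranges in spec.items():
            sel = parse_ranges(ranges, mode="keep")
            indices = []
            for chain, first, last in sel.ranges:
                hits = [
                    i for i, r in enumerate(model.residue_ids)
                    if r.chain_id == chain and first <= r.residue_seq <= last
                ]
                if not hits:
                    raise SelectionError(
                        f"domain {name!r}: range {chain}:{first}-{last} selects nothing"
                    )
                indices.extend(hits)
            entries[name] = indices
        return cls(entries)


@dataclass(frozen=True)
class ModeSelectionCriteria:
    """Codified version of the 'examine the low modes and the most collective
    modes' rule used to shortlist candidate separating modes.

    Candidates are the union of the first ``first_k`` non-zero modes and the
    ``top_collectivity`` most collective of the first ``of_first`` modes.  A
    candidate is selected when its two domain means have opposite signs
    (if required) and their gap is at least ``min_separation`` times the
    largest gap among candidates.
    """

    first_k: int = 10
    top_collectivity: int = 10
    of_first: int = 50
    opposite_sign_required: bool = True
    min_separation: float = 0.25

    def __post_init__(self) -> None:
        if min(self.first_k, self.top_collectivity, self.of_first) < 1:
            raise ValueError("mode-count criteria must be >= 1")
        if not 0.0 <= self.min_separation <= 1.0:
            raise ValueError("min_separation must lie in [0, 1]")


def square_fluctuations(modes: ModeSet, m_modes: int = 100) -> np.ndarray:
    """Per-residue square fluctuations from the first ``m_modes`` non-zero modes.

    f_i = sum_{k<=m} (1/lambda_k) * |a_k,i|^2, in gamma-normalized units.
    """
    if modes.n_modes == 0:
        raise ValueError("empty mode set")
    m = m_modes
    if m > modes.n_modes:
        warnings.warn(
            f"requested {m_modes} modes but only {modes.n_modes} available; using all",
            UserWarning,
            stacklevel=2,
        )
        m = modes.n_modes
    vec = modes.eigenvectors[:m].reshape(m, modes.n_sites, 3)
    sq = np.sum(vec**2, axis=2)  # (m, N)
    return np.einsum("k,ki->i", 1.0 / modes.eigenvalues[:m], sq)


def _require_complete(modes: ModeSet) -> None:
    if not modes.is_complete:
        raise InsufficientModesError(
            "mechanical stiffness needs the complete non-zero spectrum; "
            f"got {modes.n_modes} of {modes.n_internal_modes} modes "
            "(recompute with n_modes='all')"
        )
    if modes.reference_coords is None:
        raise InsufficientModesError("mode set lacks reference coordinates")


def _pair_compliance(modes: ModeSet) -> np.ndarray:
    """Symmetric matrix of mode-summed distance compliances C_ij (diagonal 0)."""
    coords = modes.reference_coords
    n = modes.n_sites
    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, 1.0)
    e = diff / dist[:, :, None]  # e[i, j] is the unit vector i -> j
    compliance = np.zeros((n, n))
    inv_lam = 1.0 / modes.eigenvalues
    # chunk over modes to bound memory at ~ (chunk, N, N)
    chunk = max(1, int(2e7 // (n * n)))
    vecs = modes.eigenvectors.reshape(modes.n_modes, n, 3)
    for start in range(0, modes.n_modes, chunk):
        a = vecs[start : start + chunk]  # (c, N, 3)
        # proj[k, i, j] = (a_k,j - a_k,i) . e_ij
        proj = np.einsum("kjc,ijc->kij", a, e) - np.einsum("kic,ijc->kij", a, e)
        compliance += np.einsum("k,kij->ij", inv_lam[start : start + chunk], proj**2)
    np.fill_diagonal(compliance, 0.0)
    return compliance


def effective_force_constant(modes: ModeSet, i: int, j: int) -> float:
    """Effective spring constant between sites i and j (0-based), gamma units.

    kappa_ij = 1 / sum_k (1/lambda_k) * ((a_k,j - a_k,i) . e_ij)^2, with the
    sum over the complete non-zero spectrum and e_ij the reference-structure
    unit inter-site vector.
    """
    _require_complete(modes)
    if i == j:
        raise ValueError("sites must differ")
    coords = modes.reference_coords
    e = coords[j] - coords[i]
    e = e / np.linalg.norm(e)
    vecs = modes.eigenvectors.reshape(modes.n_modes, modes.n_sites, 3)
    proj = (vecs[:, j, :] - vecs[:, i, :]) @ e
    compliance = float(np.sum(proj**2 / modes.eigenvalues))
    return 1.0 / compliance


def residue_stiffness(modes: ModeSet) -> np.ndarray:
    """Per-residue mechanical stiffness: mean of kappa_ij over all partners j."""
    _require_complete(modes)
    compliance = _pair_compliance(modes)
    n = modes.n_sites
    kappa = np.zeros((n, n))
    off = ~np.eye(n, dtype=bool)
    kappa[off] = 1.0 / compliance[off]
    return kappa.sum(axis=1) / (n - 1)


def collectivity(modes: ModeSet, k: int) -> float:
    """Degree of collectivity of non-zero mode k (1-based), in [1/N, 1].

    With p_i the normalized squared site amplitudes, the collectivity is
    exp(entropy(p)) / N: 1 when every site moves equally, 1/N when a single
    site carries the whole mode.
    """
    a = modes.mode_matrix(k)
    p = np.sum(a**2, axis=1)
    p = p / p.sum()
    nz = p > 0
    entropy = -float(np.sum(p[nz] * np.log(p[nz])))
    return float(np.exp(entropy) / modes.n_sites)


def axis_components(modes: ModeSet, k: int, axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Signed per-residue projections of non-zero mode k onto a unit axis."""
    axis = np.asarray(axis, dtype=float)
    if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-8):
        raise ValueError("axis must be a unit vector")
    return modes.mode_matrix(k) @ axis


def domain_mean_axis_displacement(
    modes: ModeSet, k: int, dm: DomainMap, axis=(0.0, 0.0, 1.0)
) -> dict[str, float]:
    """Mean signed axis component of mode k over each named domain."""
    comps = axis_components(modes, k, axis)
    return {name: float(comps[idx].mean()) for name, idx in dm.items()}


def select_separating_modes(
    modes: ModeSet,
    dm: DomainMap,
    axis=(0.0, 0.0, 1.0),
    crit: ModeSelectionCriteria | None = None,
):
    """Rank candidate modes that drive two domains apart along the pulling axis.

    Returns ``(selected, report)``: the selected 1-based mode indices ranked
    by decreasing domain-mean gap (ties to the lower index), and a full
    per-candidate report (DataFrame: mode, eigenvalue, collectivity, domain
    means, separation, opposite sign, selected) so the ranking can always be
    overridden by inspection.  An empty selection is a valid outcome.
    """
    if crit is None:
        crit = ModeSelectionCriteria()
    if len(dm) != 2:
        raise ValueError(f"separating-mode selection needs exactly 2 domains, got {len(dm)}")
    name_a, name_b = list(dm)

    pool = set(range(1, min(crit.first_k, modes.n_modes) + 1))
    first_m = min(crit.of_first, modes.n_modes)
    coll = {k: collectivity(modes, k) for k in range(1, first_m + 1)}
    by_coll = sorted(coll, key=lambda k: (-coll[k], k))[: crit.top_collectivity]
    pool.update(by_coll)
    candidates = sorted(pool)

    rows = []
    for k in candidates:
        means = domain_mean_axis_displacement(modes, k, dm, axis)
        ma, mb = means[name_a], means[name_b]
        rows.append(
            {
                "mode": k,
                "eigenvalue": modes.eigenvalue(k),
                "collectivity": coll.get(k, collectivity(modes, k)),
                f"mean_{name_a}": ma,
                f"mean_{name_b}": mb,
                "separation": abs(ma - mb),
                "opposite_sign": bool(ma * mb < 0),
            }
        )
    report = pd.DataFrame(rows)
    max_sep = float(report["separation"].max()) if len(report) else 0.0
    selected_mask = np.ones(len(report), dtype=bool)
    if crit.opposite_sign_required:
        selected_mask &= report["opposite_sign"].to_numpy()
    if max_sep > 0:
        selected_mask &= report["separation"].to_numpy() >= crit.min_separation * max_sep
    else:
        selected_mask &= False
    report["selected"] = selected_mask
    chosen = report[selected_mask].sort_values(
        ["separation", "mode"], ascending=[False, True]
    )["mode"].tolist()
    return chosen, report
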