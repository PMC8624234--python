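"""PDB reading/writing and Cα coarse-graining.

Structures are reduced to one bead per residue (the Cα position), the
resolution at which the elastic network operates.  Parsing and serialization
are delegated to biotite; this module fixes the conventions the rest of the
package relies on: author (PDB) residue numbering, chain-then-sequence bead
order, highest-occupancy alternate locations, and protein-only beads by
default.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as biotite_pdb

from pullnma.errors import (
    EmptyStructureError,
    MissingAtomWarning,
    PDBParseError,
    SelectionError,
)

#: Canonical 3-letter amino-acid codes (used only to flag non-standard names).
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class ResidueId(NamedTuple):
    """Author-numbering residue identifier: (chain, residue number, insertion code)."""

    chain_id: str
    residue_seq: int
    insertion_code: str = ""


@dataclass(frozen=True)
class AtomRecord:
    """A single parsed ATOM/HETATM record."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    coords: np.ndarray  # (3,) Å
    occupancy: float
    b_factor: float
    element: str
    hetero: bool
    model_index: int  # 1-based

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.residue_seq, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.residue_name in STANDARD_RESIDUES


@dataclass
class Structure:
    """Parsed PDB content: atom records grouped by model."""

    models: list[list[AtomRecord]]  # models[m] holds model m+1
    source: str = ""

    @property
    def n_models(self) -> int:
        return len(self.models)

    def model(self, model_index: int = 1) -> list[AtomRecord]:
        if not 1 <= model_index <= self.n_models:
            raise EmptyStructureError(
                f"model {model_index} not present in {self.source!r} "
                f"({self.n_models} model(s))"
            )
        return self.models[model_index - 1]

    @property
    def records(self) -> list[AtomRecord]:
        """All records across models, in file order."""
        return [rec for model in self.models for rec in model]


@dataclass
class CoarseModel:
    """Cα bead model: one bead per observed residue.

    Residue identity is kept in author numbering so that selections quoted
    against the deposited structure (e.g. ``A:530-554``) resolve directly.
    """

    coords: np.ndarray  # (N, 3) Å
    residue_names: list[str]
    residue_ids: list[ResidueId]
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = self.coords.shape[0]
        if n < 2:
            raise EmptyStructureError("a coarse model needs at least 2 beads")
        if len(self.residue_names) != n or len(self.residue_ids) != n:
            raise ValueError("coords, residue_names and residue_ids must agree in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(set(self.residue_ids)) != n:
            raise ValueError("duplicate residue identifiers in coarse model")

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def index_of(self, residue: ResidueId | tuple | str) -> int:
        """Bead index of a residue, given a ResidueId, a (chain, seq[, icode])
        tuple, or a string like ``"A:159"``."""
        if isinstance(residue, str):
            chain, _, seq = residue.partition(":")
            residue = ResidueId(chain, int(seq))
        rid = ResidueId(*residue)
        try:
            return self.residue_ids.index(rid)
        except ValueError:
            if rid.insertion_code == "":
                # allow lookup ignoring insertion codes when unique
                hits = [
                    i for i, r in enumerate(self.residue_ids)
                    if r.chain_id == rid.chain_id and r.residue_seq == rid.residue_seq
                ]
                if len(hits) == 1:
                    return hits[0]
            raise SelectionError(f"residue {rid} not in model {self.source_label!r}") from None

    def subset(self, indices: Sequence[int], label: str | None = None) -> "CoarseModel":
        idx = np.asarray(indices, dtype=int)
        return CoarseModel(
            coords=self.coords[idx].copy(),
            residue_names=[self.residue_names[i] for i in idx],
            residue_ids=[self.residue_ids[i] for i in idx],
            source_label=label if label is not None else self.source_label,
        )

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "CoarseModel":
        return replace(
            self,
            coords=np.asarray(coords, dtype=float).copy(),
            source_label=label if label is not None else self.source_label,
        )


@dataclass(frozen=True)
class ResidueRangeSelection:
    """Inclusive residue ranges in author numbering, kept or removed."""

    ranges: tuple[tuple[str, int, int], ...]  # (chain_id, first_seq, last_seq)
    mode: str = "remove"  # "keep" | "remove"

    def __post_init__(self) -> None:
        if self.mode not in ("keep", "remove"):
            raise ValueError(f"selection mode must be 'keep' or 'remove', got {self.mode!r}")
        for chain, first, last in self.ranges:
            if first > last:
                raise ValueError(f"range {chain}:{first}-{last} has first > last")


def parse_ranges(text: str | Iterable[str], mode: str = "remove") -> ResidueRangeSelection:
    """Parse selections like ``"A:530-554,A:768-777"`` (or a list of such tokens).

    A bare ``A:159`` denotes a single residue.
    """
    tokens: list[str] = []
    if isinstance(text, str):
        tokens = [t for t in text.split(",") if t.strip()]
    else:
        for item in text:
            tokens.extend(t for t in str(item).split(",") if t.strip())
    ranges = []
    for tok in tokens:
        tok = tok.strip()
        chain, _, span = tok.partition(":")
        m = re.match(r"^(-?\d+)(?:-(-?\d+))?$", span.strip())
        if not chain or m is None:
            raise SelectionError(f"cannot parse residue range {tok!r}")
        first = int(m.group(1))
        last = int(m.group(2)) if m.group(2) is not None else first
        ranges.append((chain, first, last))
    if not ranges:
        raise SelectionError("empty selection string")
    return ResidueRangeSelection(tuple(ranges), mode=mode)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Read a PDB file into atom records grouped by model.

    Alternate locations are resolved by keeping the highest-occupancy
    conformer (ties: the first encountered).  MODEL/ENDMDL blocks become
    separate record groups with 1-based ``model_index``.
    """
    try:
        pdb_file = biotite_pdb.PDBFile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed content
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc

    try:
        n_models = pdb_file.get_model_count()
    except Exception as exc:
        raise PDBParseError(f"no coordinate models in {path}: {exc}") from exc
    if n_models == 0:
        raise EmptyStructureError(f"{path} contains no ATOM records")

    models: list[list[AtomRecord]] = []
    for m in range(1, n_models + 1):
        try:
            atoms = pdb_file.get_structure(
                model=m,
                altloc="occupancy",
                extra_fields=["atom_id", "occupancy", "b_factor"],
            )
        except Exception as exc:
            raise PDBParseError(f"cannot parse model {m} of {path}: {exc}") from exc
        records = []
        for i in range(atoms.array_length()):
            records.append(
                AtomRecord(
                    serial=int(atoms.atom_id[i]),
                    atom_name=str(atoms.atom_name[i]),
                    residue_name=str(atoms.res_name[i]),
                    chain_id=str(atoms.chain_id[i]),
                    residue_seq=int(atoms.res_id[i]),
                    insertion_code=str(atoms.ins_code[i]).strip(),
                    coords=np.array(atoms.coord[i], dtype=float),
                    occupancy=float(atoms.occupancy[i]),
                    b_factor=float(atoms.b_factor[i]),
                    element=str(atoms.element[i]),
                    hetero=bool(atoms.hetero[i]),
                    model_index=m,
                )
            )
        models.append(records)
    if not any(models):
        raise EmptyStructureError(f"{path} contains no ATOM records")
    return Structure(models=models, source=str(path))


def extract_ca(
    structure: Structure,
    chains: Iterable[str] | None = None,
    model_index: int = 1,
    include_hetero_centroids: bool = False,
) -> CoarseModel:
    """Reduce one model to a Cα bead per residue.

    Residues that lack a CA atom are skipped with a :class:`MissingAtomWarning`.
    HETATM residues are excluded; with ``include_hetero_centroids`` each
    non-water hetero residue contributes one extra bead at its atom centroid.
    """
    records = structure.model(model_index)
    chain_set = set(chains) if chains is not None else None

    coords: list[np.ndarray] = []
    names: list[str] = []
    rids: list[ResidueId] = []

    # group protein records by residue, preserving file order
    seen: dict[ResidueId, dict[str, AtomRecord]] = {}
    order: list[ResidueId] = []
    het_groups: dict[tuple[ResidueId, str], list[AtomRecord]] = {}
    het_order: list[tuple[ResidueId, str]] = []
    for rec in records:
        if chain_set is not None and rec.chain_id not in chain_set:
            continue
        rid = rec.residue_id
        if rec.hetero:
            key = (rid, rec.residue_name)
            if rec.residue_name != "HOH":
                if key not in het_groups:
                    het_groups[key] = []
                    het_order.append(key)
                het_groups[key].append(rec)
            continue
        if rid not in seen:
            seen[rid] = {}
            order.append(rid)
        seen[rid].setdefault(rec.atom_name, rec)

    for rid in order:
        atoms = seen[rid]
        ca = atoms.get("CA")
        if ca is None:
            warnings.warn(
                f"residue {rid} has no CA atom; skipped from coarse model",
                MissingAtomWarning,
                stacklevel=2,
            )
            continue
        coords.append(ca.coords)
        names.append(ca.residue_name)
        rids.append(rid)

    if include_hetero_centroids:
        for key in het_order:
            group = het_groups[key]
            centroid = np.mean([a.coords for a in group], axis=0)
            coords.append(centroid)
            names.append(group[0].residue_name)
            rids.append(key[0])

    if not coords:
        raise EmptyStructureError(
            f"no CA atoms after filtering (chains={sorted(chain_set) if chain_set else 'all'})"
        )
    return CoarseModel(
        coords=np.array(coords, dtype=float),
        residue_names=names,
        residue_ids=rids,
        source_label=structure.source,
    )


def apply_selection(model: CoarseModel, sel: ResidueRangeSelection) -> CoarseModel:
    """Keep or remove the beads covered by inclusive residue ranges.

    Every range must overlap the model; a range that selects nothing is an
    error rather than a silent no-op, so typos in truncation definitions
    surface immediately.
    """
    covered = np.zeros(model.n_sites, dtype=bool)
    chains_present = {r.chain_id for r in model.residue_ids}
    for chain, first, last in sel.ranges:
        if chain not in chains_present:
            raise SelectionError(f"chain {chain!r} absent from model {model.source_label!r}")
        hit = np.array(
            [
                r.chain_id == chain and first <= r.residue_seq <= last
                for r in model.residue_ids
            ]
        )
        if not hit.any():
            raise SelectionError(
                f"range {chain}:{first}-{last} selects no residue in {model.source_label!r}"
            )
        covered |= hit
    keep = covered if sel.mode == "keep" else ~covered
    if keep.sum() < 2:
        raise EmptyStructureError("selection leaves fewer than 2 beads")
    return model.subset(np.nonzero(keep)[0])


def _to_atom_array(model: CoarseModel, coords: np.ndarray) -> struc.AtomArray:
    n = model.n_sites
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([r.chain_id for r in model.residue_ids])
    arr.res_id = np.array([r.residue_seq for r in model.residue_ids])
    arr.ins_code = np.array([r.insertion_code for r in model.residue_ids])
    arr.res_name = np.array(model.residue_names)
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(["C"] * n)
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_coarse_pdb(model, path) -> None:
    """Write a coarse model — or a deformed ensemble — as a (multi-model) PDB.

    Each bead becomes one CA ATOM line; ensemble frames become MODEL/ENDMDL
    blocks, readable by any trajectory viewer and by :func:`read_pdb`.
    """
    # late import to avoid a cycle: deformation depends on structure_io types
    from pullnma.deformation import DeformedEnsemble

    if isinstance(model, DeformedEnsemble):
        base = model.reference
        arrays = [_to_atom_array(base, frame) for frame in model.frames]
        stack = struc.stack(arrays)
        payload = stack
    elif isinstance(model, CoarseModel):
        payload = _to_atom_array(model, model.coords)
    else:
        raise TypeError(f"cannot write object of type {type(model).__name__}")
    pdb_file = biotite_pdb.PDBFile()
    pdb_file.set_structure(payload)
    pdb_file.write(str(path))
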