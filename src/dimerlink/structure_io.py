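"""Read C-alpha traces of two-chain protein structures.

A dimer is represented by the ordered C-alpha coordinates of its two
chains, each traversed in N->C order.  Only ``ATOM`` records with atom
name ``CA`` contribute; heteroatoms, waters and non-polymer chains are
ignored.  Alternate locations are resolved to the highest-occupancy
conformer (first in file order on a tie).

Structures whose backbone has holes are unusable for linking estimates:
a gap cannot be bridged without inventing geometry, so chains with any
consecutive C-alpha distance above 10 Å are rejected outright
(:func:`check_gap_filter`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .errors import ChainTooShortError, NotADimerError

GAP_THRESHOLD = 10.0  # Å; strict ">" — a 10.0 Å bond passes


@dataclass(frozen=True)
class CaChain:
    """Ordered C-alpha trace of one protein chain (N->C orientation).

    Parameters
    ----------
    chain_id:
        Short chain label (PDB chain identifier for real structures).
    coords:
        Array of shape ``(n_residues, 3)`` in Å, one row per residue
        C-alpha, ordered from the N terminus to the C terminus.
    """

    chain_id: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_residues, 3)")
        if coords.shape[0] < 3:
            raise ChainTooShortError(
                f"chain {self.chain_id!r} has {coords.shape[0]} C-alpha atoms (< 3)"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if np.any(d <= 0.0):
            raise ValueError("consecutive C-alpha positions must be distinct")
        object.__setattr__(self, "coords", coords)

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def bond_lengths(self) -> np.ndarray:
        """Consecutive C-alpha distances, in Å (length ``n_residues - 1``)."""
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def reversed(self) -> "CaChain":
        """Same trace in C->N order (flips the sign of Gauss sums)."""
        return CaChain(self.chain_id, self.coords[::-1].copy())


@dataclass(frozen=True)
class DimerStructure:
    """Two C-alpha chains forming one dimer."""

    pdb_id: str
    chain_a: CaChain
    chain_b: CaChain

    def center_of_mass(self) -> np.ndarray:
        """Unweighted mean of all C-alpha positions of both chains."""
        return np.vstack([self.chain_a.coords, self.chain_b.coords]).mean(axis=0)

    def passes_gap_filter(self, threshold: float = GAP_THRESHOLD) -> bool:
        return (
            check_gap_filter(self.chain_a, threshold).passed
            and check_gap_filter(self.chain_b, threshold).passed
        )


@dataclass(frozen=True)
class GapCheck:
    """Outcome of the backbone-continuity filter."""

    passed: bool
    violations: list[int] = field(default_factory=list)  # 0-based bond indices


def check_gap_filter(chain: CaChain, threshold: float = GAP_THRESHOLD) -> GapCheck:
    """Reject chains with holes in the backbone.

    Returns ``passed=False`` iff any consecutive C-alpha distance is
    *strictly* greater than ``threshold`` (default 10 Å); the boundary
    value itself passes.  Violating bonds are reported by 0-based index
    (bond ``i`` joins residues ``i`` and ``i+1``).
    """
    d = chain.bond_lengths()
    bad = np.flatnonzero(d > threshold)
    return GapCheck(passed=bad.size == 0, violations=bad.tolist())


def _ca_coords_of_chain(chain: gemmi.Chain) -> np.ndarray | None:
    """Extract the CA trace of one gemmi chain, or None if not a polymer.

    Residues are ordered by residue sequence number (stable sort, so
    insertion-coded residues keep file order); altlocs resolve to the
    highest occupancy, first on tie.
    """
    entries: list[tuple[int, int, np.ndarray]] = []
    for file_idx, res in enumerate(chain):
        if res.het_flag != "A":  # HETATM (incl. waters) ignored
            continue
        best = None
        for atom in res:
            if atom.name == "CA" and (best is None or atom.occ > best.occ):
                best = atom
        if best is None:
            continue
        pos = np.array([best.pos.x, best.pos.y, best.pos.z])
        entries.append((res.seqid.num, file_idx, pos))
    if not entries:
        return None
    entries.sort(key=lambda e: (e[0],))  # stable: insertion codes keep file order
    return np.array([e[2] for e in entries])


def read_ca_chains(
    path: str | Path,
    chain_ids: Sequence[str] | None = None,
    pdb_id: str | None = None,
) -> DimerStructure:
    """Read a PDB (or mmCIF) file and extract a two-chain C-alpha dimer.

    Parameters
    ----------
    path:
        Structure file.  Minimal C-alpha-only PDB files (as written by
        :func:`dimerlink.fixtures.write_toy_pdb`) are sufficient.
    chain_ids:
        Optional pair of chain labels.  If omitted and the file has
        exactly two polymer chains, those are used in file order; with
        more than two, the two chains with the most C-alpha atoms are
        selected (ties broken by file order).
    pdb_id:
        Identifier stored on the result; defaults to the file stem.

    Raises
    ------
    NotADimerError
        Fewer than two usable polymer chains.
    ChainTooShortError
        A selected chain has fewer than 3 C-alpha atoms.
    """
    path = Path(path)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise NotADimerError(f"{path}: no models in file")
    model = structure[0]

    traces: dict[str, np.ndarray] = {}
    order: list[str] = []
    for chain in model:
        if chain.name in traces:
            continue
        coords = _ca_coords_of_chain(chain)
        if coords is None:
            continue
        traces[chain.name] = coords
        order.append(chain.name)

    if chain_ids is not None:
        if len(chain_ids) != 2:
            raise ValueError("chain_ids must name exactly two chains")
        missing = [c for c in chain_ids if c not in traces]
        if missing:
            raise NotADimerError(f"{path}: chain(s) {missing} not found or not polymer")
        selected = list(chain_ids)
    else:
        if len(order) < 2:
            raise NotADimerError(
                f"{path}: not a dimer — found {len(order)} polymer chain(s)"
            )
        if len(order) == 2:
            selected = order
        else:
            selected = sorted(order, key=lambda c: -traces[c].shape[0])[:2]
            selected.sort(key=order.index)  # keep file order of the winners

    chains = []
    for cid in selected:
        coords = traces[cid]
        if coords.shape[0] < 3:
            raise ChainTooShortError(
                f"{path}: chain {cid!r} has {coords.shape[0]} C-alpha atoms (< 3)"
            )
        chains.append(CaChain(cid, coords))

    return DimerStructure(pdb_id or path.stem.upper(), chains[0], chains[1])
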