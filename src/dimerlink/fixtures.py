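"""Synthetic curve pairs with known topology, and a toy PDB writer.

Every fixture is generated from a few geometric parameters (and a seed
for the random kinds), so the rest of the package is testable without
any structure download:

hopf
    Two interlocked circles in orthogonal planes, |Lk| = 1.
torus_link_k
    A core circle plus a curve winding k times around its tube, |Lk| = k.
unlinked_circles
    Two coplanar circles with disjoint interiors, Lk = 0.
open_coil_pair
    Two open random coils with protein-like 3.8 Å bonds (no defined
    linking; exercises the open-chain machinery).
cut_hopf_dimer
    A Hopf link with one arc removed from each circle at the point
    farthest from the partner, leaving an open two-chain "dimer" whose
    Gaussian entanglement sits near ±1.

Sign convention: curves are oriented the way they are generated
(counterclockwise in their construction planes), matching the N->C
convention of the protein pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import FixtureError
from .structure_io import CaChain

CA_BOND = 3.8  # Å, typical C-alpha spacing used for protein-like fixtures

KINDS = ("hopf", "torus_link_k", "unlinked_circles", "open_coil_pair", "cut_hopf_dimer")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n_vertices: int = 400
    radius: float = 20.0       # Å
    separation: float | None = None  # centre–centre distance where meaningful
    tube_radius: float = 8.0   # Å, torus minor radius
    k: int = 3                 # torus windings
    cut_fraction: float = 0.20  # cut_hopf_dimer: fraction of vertices removed
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise FixtureError(f"unknown fixture kind {self.kind!r}")
        if self.n_vertices < 3:
            raise FixtureError("n_vertices must be at least 3")
        if self.kind == "torus_link_k" and self.k == 0:
            raise FixtureError("torus_link_k requires k != 0")


@dataclass(frozen=True)
class CurvePairFixture:
    curve_a: np.ndarray
    curve_b: np.ndarray
    closed: bool
    known_linking: int | None  # None for open fixtures

    def as_dimer_chains(self) -> tuple[CaChain, CaChain]:
        return CaChain("A", self.curve_a), CaChain("B", self.curve_b)


def _circle(n: int, radius: float, center, normal: str) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n
    c, s = radius * np.cos(t), radius * np.sin(t)
    z = np.zeros(n)
    if normal == "z":
        pts = np.column_stack([c, s, z])
    elif normal == "y":
        pts = np.column_stack([c, z, s])
    else:
        pts = np.column_stack([z, c, s])
    return pts + np.asarray(center, float)


def make_fixture(spec: FixtureSpec) -> CurvePairFixture:
    """Generate the curve pair described by ``spec``.

    Closed kinds come with their exact linking number (sign fixed by
    the construction's orientations); open kinds carry
    ``known_linking=None``.
    """
    n = spec.n_vertices
    r = spec.radius

    if spec.kind == "hopf":
        sep = r if spec.separation is None else spec.separation
        a = _circle(n, r, (0.0, 0.0, 0.0), "z")
        b = _circle(n, r, (sep, 0.0, 0.0), "y")
        # with both circles traversed counterclockwise in their own
        # construction planes the Gauss integral gives -1
        return CurvePairFixture(a, b, closed=True, known_linking=-1)

    if spec.kind == "unlinked_circles":
        sep = 3.0 * r if spec.separation is None else spec.separation
        if sep <= 2.0 * r:
            raise FixtureError("unlinked_circles needs separation > 2*radius")
        a = _circle(n, r, (0.0, 0.0, 0.0), "z")
        b = _circle(n, r, (sep, 0.0, 0.0), "z")
        return CurvePairFixture(a, b, closed=True, known_linking=0)

    if spec.kind == "torus_link_k":
        rho = spec.tube_radius
        if rho >= r:
            raise FixtureError("tube_radius must be smaller than radius")
        a = _circle(n, r, (0.0, 0.0, 0.0), "z")
        t = 2.0 * np.pi * np.arange(n) / n
        w = r + rho * np.cos(spec.k * t)
        b = np.column_stack([w * np.cos(t), w * np.sin(t), rho * np.sin(spec.k * t)])
        # winds k times around the core circle; the kernel's sign
        # convention makes the linking -k for this construction
        return CurvePairFixture(a, b, closed=True, known_linking=-int(spec.k))

    if spec.kind == "open_coil_pair":
        rng = np.random.default_rng(spec.seed)
        chains = []
        for offset in ((0.0, 0.0, 0.0), (1.5 * r, 0.0, 0.0)):
            pts = [np.asarray(offset, float)]
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            for _ in range(n - 1):
                # persistent walk with a mild self-avoidance bias
                for _attempt in range(20):
                    step = d + 0.8 * rng.standard_normal(3)
                    step /= np.linalg.norm(step)
                    nxt = pts[-1] + CA_BOND * step
                    recent = np.array(pts[-12:-1]) if len(pts) > 1 else np.empty((0, 3))
                    if recent.size == 0 or np.min(
                        np.linalg.norm(recent - nxt, axis=1)
                    ) > 0.7 * CA_BOND:
                        break
                pts.append(nxt)
                d = step
            chains.append(np.array(pts))
        return CurvePairFixture(chains[0], chains[1], closed=False, known_linking=None)

    # cut_hopf_dimer
    hopf = make_fixture(FixtureSpec(kind="hopf", n_vertices=n, radius=r,
                                    separation=spec.separation))
    a, b = hopf.curve_a, hopf.curve_b
    n_cut = max(1, int(round(spec.cut_fraction * n)))
    opened = []
    # the farthest point from the partner curve is known analytically for
    # this construction: angle pi on the first ring (vertex n//2), angle 0
    # on the second (vertex 0) -- an argmax over sampled distances would
    # sit on a plateau and tie-break unstably
    for curve, far in ((a, n // 2), (b, 0)):
        # drop n_cut contiguous vertices centred on the farthest point;
        # the survivors, walked from just past the cut, form the open arc
        drop = (far - n_cut // 2 + np.arange(n_cut)) % n
        start = (drop[-1] + 1) % n
        order = (start + np.arange(n - n_cut)) % n
        opened.append(curve[order])
    return CurvePairFixture(opened[0], opened[1], closed=False, known_linking=None)


def _format_pdb_coord(x: float) -> str:
    s = f"{x:8.3f}"
    if len(s) != 8:
        raise FixtureError(f"coordinate {x} overflows the PDB fixed-width field")
    return s


def write_toy_pdb(chains: Iterable[CaChain] | CaChain, path: str | Path) -> Path:
    """Write C-alpha-only chains as a minimal valid PDB file.

    Chains keep their own ids; residues are numbered from 1 and typed
    ALA.  Coordinates must fit the fixed-width %8.3f field.
    """
    if isinstance(chains, CaChain):
        chains = [chains]
    path = Path(path)
    lines = []
    serial = 1
    for chain in chains:
        for i, (x, y, z) in enumerate(chain.coords, start=1):
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain.chain_id:1s}{i:4d}    "
                f"{_format_pdb_coord(x)}{_format_pdb_coord(y)}{_format_pdb_coord(z)}"
                f"  1.00  0.00           C"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}      ALA {chain.chain_id:1s}{len(chain.coords):4d}")
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
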