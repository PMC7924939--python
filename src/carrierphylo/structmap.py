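"""Projection of conservation results onto structure coordinates.

Takes finished homology-model coordinates (built elsewhere from carrier
templates) and writes a per-residue scalar — typically the Shannon entropy
or a category flag — into the B-factor column, so any molecular viewer can
color the model by conservation.  Also provides the small amount of
residue geometry used to discuss binding-pocket organization: minimum
inter-residue distances and radius neighborhoods.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .io_formats import Atom, StructureModel

SENTINEL_B = 99.99
BACKBONE_ATOMS = {"N", "CA", "C", "O"}


class StructMapError(ValueError):
    pass


def annotate_structure(model: StructureModel, annotation: dict[int, float],
                       chain: str, offset: int = 0,
                       sentinel: float = SENTINEL_B) -> StructureModel:
    """Write per-residue scalars into B-factors of a chain.

    ``annotation`` maps reference positions to scalars; model residue
    numbers are reference position + ``offset``.  Atoms of unannotated
    residues (and other chains) get the sentinel B-factor.
    """
    if chain not in model.chains():
        raise StructMapError(f"chain {chain!r} not in model "
                             f"(has {model.chains()})")
    shifted = {pos + offset: val for pos, val in annotation.items()}
    atoms = []
    for a in model.atoms:
        if a.chain == chain and a.res_seq in shifted:
            atoms.append(replace(a, b_factor=float(shifted[a.res_seq])))
        else:
            atoms.append(replace(a, b_factor=sentinel))
    return StructureModel(atoms)


def _scoped_atoms(model: StructureModel, chain: str, res: int,
                  atom_scope: str) -> list[Atom]:
    atoms = model.residue_atoms(chain, res)
    if not atoms:
        raise StructMapError(f"residue {res} not in chain {chain!r}")
    if atom_scope == "sidechain":
        side = [a for a in atoms if a.name not in BACKBONE_ATOMS]
        return side or atoms  # glycine: fall back to all atoms
    if atom_scope != "all":
        raise StructMapError(f"unknown atom scope {atom_scope!r}")
    return atoms


def residue_min_distance(model: StructureModel, res_a: int, res_b: int,
                         chain: str = "A", atom_scope: str = "all") -> float:
    """Minimum Euclidean distance (Å) between two residues' atoms."""
    aa = _scoped_atoms(model, chain, res_a, atom_scope)
    bb = _scoped_atoms(model, chain, res_b, atom_scope)
    pa = np.array([[a.x, a.y, a.z] for a in aa])
    pb = np.array([[a.x, a.y, a.z] for a in bb])
    diff = pa[:, None, :] - pb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def neighborhood(model: StructureModel, res: int, radius: float,
                 chain: str = "A", atom_scope: str = "all"
                 ) -> list[tuple[int, float]]:
    """Residues within ``radius`` Å of ``res``, sorted by distance.

    Excludes the query residue; returns (residue number, distance) pairs.
    """
    if radius <= 0:
        raise StructMapError("radius must be positive")
    out = []
    for other in model.residues(chain):
        if other == res:
            continue
        d = residue_min_distance(model, res, other, chain, atom_scope)
        if d <= radius:
            out.append((other, d))
    out.sort(key=lambda t: (t[1], t[0]))
    return out
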