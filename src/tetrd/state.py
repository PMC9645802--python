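"""Simulation state containers: molecule state M and delta state ΔM.

``MoleculeState`` holds integer copy numbers per owned element: a dense
(tets x volume-species) array and a (triangles x surface-species) array where
channel states count as surface species.  ``DeltaMoleculeState`` stages the
signed count changes produced by a diffusion window, keyed by the destination
element's owner rank; staged deltas are only folded into M in the synchronize
step, emulating the cross-rank exchange of a distributed run with identical
semantics in one process.
"""

from __future__ import annotations

import json

import numpy as np

from .ids import SpeciesId, TetId, TriId


class MoleculeState:
    """Integer molecule counts per element; never negative."""

    def __init__(self, num_tets: int, num_vol_species: int,
                 num_tris: int = 0, num_surf_species: int = 0):
        self.vol = np.zeros((num_tets, num_vol_species), dtype=np.int64)
        self.surf = np.zeros((num_tris, num_surf_species), dtype=np.int64)

    def count(self, elem: TetId | TriId, species: SpeciesId) -> int:
        arr = self.vol if isinstance(elem, TetId) else self.surf
        return int(arr[int(elem), int(species)])

    def set_count(self, elem: TetId | TriId, species: SpeciesId, value: int) -> None:
        if value < 0:
            raise ValueError("molecule counts must be nonnegative")
        arr = self.vol if isinstance(elem, TetId) else self.surf
        arr[int(elem), int(species)] = value

    def totals(self) -> np.ndarray:
        """Per-volume-species global totals."""
        return self.vol.sum(axis=0)

    def copy(self) -> "MoleculeState":
        out = MoleculeState(*self.vol.shape, *self.surf.shape)
        out.vol[:] = self.vol
        out.surf[:] = self.surf
        return out

    def validate(self) -> None:
        if (self.vol < 0).any() or (self.surf < 0).any():
            raise ValueError("negative molecule count in state")

    def dump(self, path, vol_species=None, surf_species=None) -> None:
        """Debug snapshot as JSON (counts only, dense)."""
        doc = {
            "vol_species": list(vol_species or range(self.vol.shape[1])),
            "surf_species": list(surf_species or range(self.surf.shape[1])),
            "vol": self.vol.tolist(),
            "surf": self.surf.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


class DeltaMoleculeState:
    """Per-destination-rank staged volume-count deltas (ΔM)."""

    def __init__(self, num_tets: int, num_vol_species: int, num_ranks: int = 1):
        self.shape = (num_tets, num_vol_species)
        self.num_ranks = num_ranks
        self._buffers: dict[int, np.ndarray] = {}

    def buffer(self, rank: int) -> np.ndarray:
        if not 0 <= rank < self.num_ranks:
            raise ValueError(f"rank {rank} outside [0, {self.num_ranks})")
        if rank not in self._buffers:
            self._buffers[rank] = np.zeros(self.shape, dtype=np.int64)
        return self._buffers[rank]

    def add(self, rank: int, tet: int, species: int, delta: int) -> None:
        self.buffer(rank)[tet, species] += delta

    def total(self) -> np.ndarray:
        """Sum of all staged buffers (what synchronization delivers)."""
        out = np.zeros(self.shape, dtype=np.int64)
        for b in self._buffers.values():
            out += b
        return out

    def species_sums(self) -> np.ndarray:
        """Global per-species delta sums; zero for a pure transport window."""
        return self.total().sum(axis=0)

    def clear(self) -> None:
        self._buffers.clear()


def apply_delta(M: MoleculeState, dM: DeltaMoleculeState) -> MoleculeState:
    """Fold staged deltas into M (the post-synchronization application).

    Mutates and returns ``M``.  A count that would go negative indicates an
    operator bug and raises with the offending element/species.
    """
    total = dM.total()
    new = M.vol + total
    if (new < 0).any():
        tet, sp = np.argwhere(new < 0)[0]
        raise ValueError(
            f"applying ΔM drives count negative at tet {tet}, species {sp} "
            f"({M.vol[tet, sp]} + {total[tet, sp]})"
        )
    M.vol[:] = new
    return M
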