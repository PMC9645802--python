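"""Windowed stochastic diffusion between face-adjacent tetrahedrons.

Voxel coupling rate for species with diffusion coefficient D across a shared
face of area A, barycenter distance h, out of a tet of volume V:
``d_k = D * A / (V * h)`` (s^-1).  Over a window of length dt the number of
molecules leaving a tet is Binomial(n, 1 - exp(-d_tot * dt)) — exact for the
single-voxel exit process when re-entry within the window is neglected — and
the leavers are split Multinomial(d_k / d_tot) over the neighbors.  Boundary
faces are reflective (no rate).  All moves are staged in ΔM per destination
owner rank and folded into M only in the synchronize step, so per-species
totals are conserved exactly and no cross-rank mutation happens mid-window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MeshMeasures, Partition
from .state import DeltaMoleculeState, MoleculeState, apply_delta


@dataclass
class SpeciesRates:
    """Per-tet neighbor exit rates of one diffusive species.

    ``d_k`` is aligned with ``measures.neighbors.ab2c`` (zero where the rule
    does not apply); ``d_tot`` is the per-tet total exit rate.
    """

    species: int
    d_k: np.ndarray
    d_tot: np.ndarray


@dataclass
class DiffusionRates:
    measures: MeshMeasures
    entries: list[SpeciesRates]

    def max_total_rate(self) -> float:
        return max((float(e.d_tot.max()) for e in self.entries if len(e.d_tot)),
                   default=0.0)


def compute_diffusion_rates(measures: MeshMeasures,
                            rules: list[tuple[int, float, np.ndarray]]) -> DiffusionRates:
    """Rates for each (species column, D, applicable tet set) rule.

    Rates are restricted to faces whose both tets are in the rule's set, so
    molecules never diffuse out of their compartment.
    """
    nbr = measures.neighbors
    entries = []
    ntets = len(measures.volumes)
    for sp, D, tets in rules:
        if D <= 0:
            continue
        in_set = np.zeros(ntets, dtype=bool)
        in_set[tets] = True
        d_k = np.zeros(len(nbr.ab2c))
        d_tot = np.zeros(ntets)
        for i in np.flatnonzero(in_set):
            lo, hi = nbr.bounds(i)
            nbrs = nbr.ab2c[lo:hi]
            ok = in_set[nbrs]
            rates = np.where(
                ok,
                D * measures.face_areas.ab2c[lo:hi]
                / (measures.volumes[i] * measures.face_dists.ab2c[lo:hi]),
                0.0,
            )
            d_k[lo:hi] = rates
            d_tot[i] = rates.sum()
        entries.append(SpeciesRates(sp, d_k, d_tot))
    return DiffusionRates(measures, entries)


def select_rd_dt(rates: DiffusionRates, dT_efield: float, alpha: float = 1.0) -> float:
    """RD window length: min(ΔT_EField, alpha / max total exit rate)."""
    if dT_efield <= 0:
        raise ValueError("ΔT_EField must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    dmax = rates.max_total_rate()
    if dmax <= 0:
        return dT_efield
    return min(dT_efield, alpha / dmax)


def diffuse_window(M: MoleculeState, rates: DiffusionRates, dt: float,
                   partition: Partition, rngs: list[np.random.Generator],
                   dM: DeltaMoleculeState | None = None):
    """One diffusion window: compute, stage, synchronize, apply.

    Each rank draws outcomes for the tets it owns with its own RNG stream.
    Returns the set of (loc, tet, species) keys whose counts changed, for
    propensity notification.
    """
    if dt < 0:
        raise ValueError("window length must be >= 0")
    meas = rates.measures
    nbr = meas.neighbors
    if dM is None:
        dM = DeltaMoleculeState(*M.vol.shape, partition.num_ranks)

    if dt > 0:
        for rank in range(partition.num_ranks):
            rng = rngs[rank]
            owned_mask = partition.owner == rank
            for e in rates.entries:
                active = np.flatnonzero(owned_mask & (e.d_tot > 0)
                                        & (M.vol[:, e.species] > 0))
                if not len(active):
                    continue
                n = M.vol[active, e.species]
                p = -np.expm1(-e.d_tot[active] * dt)
                leavers = rng.binomial(n, p)
                src_buf = dM.buffer(rank)
                for tet, out in zip(active, leavers):
                    if out == 0:
                        continue
                    lo, hi = nbr.bounds(int(tet))
                    probs = e.d_k[lo:hi] / e.d_tot[tet]
                    split = rng.multinomial(int(out), probs)
                    src_buf[tet, e.species] -= int(out)
                    for dest, cnt in zip(nbr.ab2c[lo:hi], split):
                        if cnt:
                            dM.buffer(int(partition.owner[dest]))[dest, e.species] += int(cnt)

    # synchronize: deltas become visible to every rank, then applied
    total = dM.total()
    changed = {("tet", int(t), int(s)) for t, s in zip(*np.nonzero(total))}
    apply_delta(M, dM)
    dM.clear()
    return changed
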