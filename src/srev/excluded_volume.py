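"""From SRRW overlap points to a linear excluded-volume bead chain.

A raw SRRW revisits vertices (every return lands on an earlier position),
so as a physical object it is a branched structure with coincident beads.
Here each *visit* becomes one bead of a strictly linear chain in walk
order; coincident beads are jittered apart and the chain is relaxed by a
damped overdamped descent on harmonic bonds plus a soft half-spring
repulsion until no two non-bonded beads are closer than one bead diameter.
The relaxation is purely an overlap-removal procedure — there is no
thermodynamic sampling and no attractive interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .params import BEAD_RADIUS_NM, GenerationParams, RelaxationParams
from .walk import RawWalk

__all__ = [
    "BeadChain",
    "ConvergenceError",
    "expand_overlaps",
    "count_overlaps",
    "relax",
]


class ConvergenceError(RuntimeError):
    """Relaxation hit the iteration cap with overlaps remaining."""


@dataclass
class BeadChain:
    """Linear chain of nucleosome beads.

    Attributes
    ----------
    positions
        ``(N, 3)`` bead centres in nm.  Bead ``i`` bonds only to ``i - 1``
        and ``i + 1`` (implicit linear connectivity).
    bead_radius
        Hard-core (non-overlap) radius r0 in nm.
    bond_rest_lengths
        ``(N - 1,)`` rest lengths in nm — the bond lengths of the walk the
        chain was built from, used both by the relaxation springs and by
        the genomic linker assignment.
    origin_vertex
        Per-bead index of the RawWalk vertex (visit) it came from.
    params
        Generation parameters of the source walk, if known (carries the
        confinement radius used during relaxation).
    relaxed
        Whether :func:`relax` has certified the chain overlap-free.
    """

    positions: np.ndarray
    bead_radius: float = BEAD_RADIUS_NM
    bond_rest_lengths: np.ndarray | None = None
    origin_vertex: np.ndarray | None = None
    params: GenerationParams | None = None
    relaxed: bool = False

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        n = len(self.positions)
        if self.bond_rest_lengths is None:
            self.bond_rest_lengths = bond_lengths(self)
        self.bond_rest_lengths = np.asarray(self.bond_rest_lengths, dtype=float)
        if len(self.bond_rest_lengths) != n - 1:
            raise ValueError("need N - 1 bond rest lengths")
        if self.origin_vertex is None:
            self.origin_vertex = np.arange(n)

    @property
    def n_beads(self) -> int:
        return len(self.positions)


def bond_lengths(chain: BeadChain) -> np.ndarray:
    """Current geometric bond lengths (nm) along the chain."""
    return np.linalg.norm(np.diff(chain.positions, axis=0), axis=1)


def expand_overlaps(walk: RawWalk, jitter: float = 0.1,
                    seed: int | None = None) -> BeadChain:
    """Turn every walk vertex visit into a distinct bead.

    The walk's visit sequence already is the bead order: a vertex visited
    k times yields k beads at the same point, linearly bonded through the
    intervening excursions.  Beads that coincide with an earlier bead are
    displaced by independent uniform jitter of at most ``jitter`` nm so the
    subsequent force evaluation sees no exactly degenerate pairs.  Bond
    rest lengths are the walk step lengths (in nm), recorded before
    jittering.
    """
    pos = walk.vertices.copy()
    rest = walk.step_lengths * walk.params.unit_length
    n = len(pos)

    if jitter > 0 and n > 1:
        # duplicates = beads sharing their exact position with an earlier bead
        order = np.lexsort(pos.T)
        sorted_pos = pos[order]
        same = np.all(sorted_pos[1:] == sorted_pos[:-1], axis=1)
        dup_mask = np.zeros(n, dtype=bool)
        run_dup = np.concatenate(([False], same))
        dup_mask[order] = run_dup
        ndup = int(dup_mask.sum())
        if ndup:
            rng = np.random.default_rng(walk.params.seed if seed is None else seed)
            disp = rng.uniform(-1.0, 1.0, size=(ndup, 3))
            norms = np.linalg.norm(disp, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            radii = rng.uniform(0.0, jitter, size=(ndup, 1))
            pos[dup_mask] += disp / norms * radii

    return BeadChain(positions=pos, bond_rest_lengths=rest,
                     origin_vertex=np.arange(n), params=walk.params)


def count_overlaps(chain: BeadChain, overlap_tol: float = 0.0) -> int:
    """Number of non-bonded bead pairs closer than ``2 r0 (1 - overlap_tol)``."""
    contact = 2.0 * chain.bead_radius * (1.0 - overlap_tol)
    return int(_kernels.count_overlaps_grid(chain.positions, contact))


def count_overlaps_bruteforce(chain: BeadChain, overlap_tol: float = 0.0) -> int:
    """O(N^2) reference pair scan; oracle for :func:`count_overlaps`."""
    pos = chain.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    contact = 2.0 * chain.bead_radius * (1.0 - overlap_tol)
    close = d < contact
    iu = np.triu_indices(len(pos), k=2)  # excludes self and bonded neighbours
    return int(close[iu].sum())


def relax(chain: BeadChain, params: RelaxationParams | None = None,
          rc_confine: float | None = None,
          record_energy: bool = False):
    """Remove all overlaps by damped overdamped descent.

    Beads interact through harmonic bonds at their initial rest lengths and
    a soft repulsive half-spring ``V = k (2 r0 - d)^2`` for non-bonded pairs
    with ``d < 2 r0``.  Iteration stops as soon as every non-bonded pair is
    at least ``2 r0 (1 - overlap_tol)`` apart.  A reflecting spherical
    boundary of radius ``rc_confine`` about the configuration centre of
    mass keeps the overall volume-fraction definition valid.  With
    ``temperature_scale = 0`` (the default) the procedure is deterministic.

    Returns the relaxed chain (a new object; the input is not modified),
    or ``(chain, energy_history)`` when ``record_energy`` is true.

    Raises
    ------
    ConvergenceError
        If ``max_steps`` iterations leave residual overlaps.
    """
    params = params or RelaxationParams()
    if rc_confine is None:
        if chain.params is not None:
            rc_confine = chain.params.rc_confine
        else:
            com = chain.positions.mean(axis=0)
            rc_confine = float(np.linalg.norm(chain.positions - com,
                                              axis=1).max()) + chain.bead_radius

    pos = chain.positions.copy()
    n_iters, residual, energy = _kernels.relax_chain(
        pos, chain.bond_rest_lengths, chain.bead_radius, params.overlap_tol,
        params.max_steps, params.step_scale, params.bond_stiffness,
        params.repulsion_stiffness, params.max_displacement, rc_confine,
        params.temperature_scale, params.seed, record_energy,
        params.active_refresh, params.stall_factor,
    )
    if residual != 0:
        raise ConvergenceError(
            f"{residual} overlaps remain after {n_iters} iterations "
            f"(max_steps={params.max_steps}); consider a larger max_steps or "
            f"step_scale")
    out = replace(chain, positions=pos, relaxed=True)
    # rest lengths and connectivity are preserved by construction
    if record_energy:
        return out, energy
    return out
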