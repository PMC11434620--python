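"""Genomic annotation of a bead chain.

Each bead is one nucleosome carrying 147 bp; DNA between consecutive
nucleosomes (the linker) is read off the bond length: a bond of length
``U`` nm holds ``round((U - 9.8) / 0.34)`` linker base pairs when ``U``
exceeds the 9.8 nm contact distance of two beads, and none otherwise.
Genomic positions are the cumulative sums of these per-bead contributions,
which supplies the genomic separation axis of the polymer observables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .excluded_volume import BeadChain, bond_lengths
from .params import BEAD_RADIUS_NM, BP_RISE_NM, NUCLEOSOME_BP

__all__ = ["GenomicMap", "assign_linkers", "genomic_separation"]


@dataclass(frozen=True)
class GenomicMap:
    """Base-pair bookkeeping along a bead chain.

    Attributes
    ----------
    linker_bp
        ``(N - 1,)`` integer linker lengths per bond.
    cumulative_bp
        ``(N,)`` genomic start position of each bead (bead 0 at 0);
        strictly monotone increasing by ``147 + linker``.
    nucleosome_bp
        Base pairs per nucleosome (147).
    """

    linker_bp: np.ndarray
    cumulative_bp: np.ndarray
    nucleosome_bp: int = NUCLEOSOME_BP

    @property
    def n_beads(self) -> int:
        return len(self.cumulative_bp)

    @property
    def total_bp(self) -> int:
        """Total genomic length: 147 per bead plus all linkers."""
        return int(self.n_beads * self.nucleosome_bp + self.linker_bp.sum())

    @property
    def mean_linker_bp(self) -> float:
        return float(self.linker_bp.mean())


def assign_linkers(chain: BeadChain, use_rest_lengths: bool = False) -> GenomicMap:
    """Map bond lengths to linker DNA lengths.

    By default linkers are computed from the *current* (post-relaxation)
    bond lengths of the chain, i.e. the excluded-volume configuration the
    observables see.  ``use_rest_lengths=True`` instead uses the original
    walk step lengths (pre-relaxation), for sensitivity analysis.
    """
    if use_rest_lengths:
        u = np.asarray(chain.bond_rest_lengths, dtype=float)
    else:
        u = bond_lengths(chain)
    if np.any(u < 0) or np.any(~np.isfinite(u)):
        raise ValueError("bond lengths must be finite and non-negative")
    contact = 2.0 * BEAD_RADIUS_NM
    linker = np.where(u > contact,
                      np.rint((u - contact) / BP_RISE_NM), 0.0).astype(np.int64)
    per_bead = NUCLEOSOME_BP + np.concatenate(([0], linker))
    cumulative = np.cumsum(per_bead) - NUCLEOSOME_BP
    return GenomicMap(linker_bp=linker, cumulative_bp=cumulative)


def genomic_separation(gmap: GenomicMap, i: int, j: int) -> int:
    """Genomic distance |bp(j) - bp(i)| between two beads."""
    n = gmap.n_beads
    if not (-n <= i < n and -n <= j < n):
        raise IndexError(f"bead index out of range for chain of {n} beads")
    return int(abs(gmap.cumulative_bp[j] - gmap.cumulative_bp[i]))
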