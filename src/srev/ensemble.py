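"""Convenience drivers: walk -> expand -> relax -> annotate, over ensembles.

The study conditions are parameterised by the folding parameter ``alpha``
and the overall volume fraction ``phi`` (which fixes the bead count for a
given confinement radius).  Ensemble member ``i`` uses seed
``base_seed + i`` for every stochastic stage, so ensembles are fully
reproducible from one integer.
"""

from __future__ import annotations

from typing import Iterator

from .excluded_volume import BeadChain, expand_overlaps, relax
from .genome import GenomicMap, assign_linkers
from .params import (DEFAULT_RC_NM, GenerationParams, RelaxationParams,
                     beads_for_phi)
from .walk import generate_walk

__all__ = ["generate_configuration", "generate_ensemble"]


def generate_configuration(alpha: float, phi: float,
                           rc_confine: float = DEFAULT_RC_NM,
                           seed: int = 0,
                           relax_params: RelaxationParams | None = None,
                           ) -> tuple[BeadChain, GenomicMap]:
    """One relaxed, genome-annotated SR-EV configuration."""
    n = beads_for_phi(phi, rc_confine)
    walk = generate_walk(GenerationParams(alpha=alpha, n_beads=n,
                                          rc_confine=rc_confine, seed=seed))
    chain = relax(expand_overlaps(walk),
                  relax_params or RelaxationParams(seed=seed))
    return chain, assign_linkers(chain)


def generate_ensemble(alpha: float, phi: float, n_configs: int,
                      rc_confine: float = DEFAULT_RC_NM, base_seed: int = 0,
                      relax_params: RelaxationParams | None = None,
                      ) -> Iterator[tuple[BeadChain, GenomicMap]]:
    """Lazily yield ``n_configs`` independent configurations."""
    for i in range(n_configs):
        yield generate_configuration(alpha, phi, rc_confine,
                                     seed=base_seed + i,
                                     relax_params=relax_params)
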