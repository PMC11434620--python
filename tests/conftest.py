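"""Shared fixtures: small SR-EV ensembles generated once per session.

Everything is generated programmatically at fixed seeds; there are no data
files.  The small fixtures use reduced confinement radii so the whole
suite stays desk-scale; the physics (return rules, excluded volume,
observable definitions) is identical at every scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from srev import GenerationParams, beads_for_phi, generate_walk
from srev.ensemble import generate_ensemble
from srev.excluded_volume import expand_overlaps, relax


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_chain():
    """One relaxed chain of ~850 beads (alpha=1.15, phi=0.10, Rc=100 nm)."""
    n = beads_for_phi(0.10, 100.0)
    walk = generate_walk(GenerationParams(alpha=1.15, n_beads=n,
                                          rc_confine=100.0, seed=42))
    return relax(expand_overlaps(walk))


@pytest.fixture(scope="session")
def small_ensemble():
    """Three relaxed, annotated configurations (alpha=1.15, phi=0.12, Rc=150)."""
    return list(generate_ensemble(1.15, 0.12, 3, rc_confine=150.0,
                                  base_seed=777))


@pytest.fixture(scope="session")
def small_walk():
    """A 20k-step SRRW at default full-scale confinement."""
    return generate_walk(GenerationParams(alpha=1.15, n_beads=20_000, seed=9))


# ---------------------------------------------------------------------------
# study-condition ensembles (reduced confinement, fixed seeds)
# ---------------------------------------------------------------------------

FLORY_ALPHAS = (1.10, 1.15, 1.20)


@pytest.fixture(scope="session")
def flory_ensembles():
    """20 configurations per folding parameter at phi=0.08, Rc=325 nm.

    The reduced confinement radius (half the full-scale 650 nm) keeps the
    suite desk-scale; the end-to-end scaling below the intra/inter
    crossover is a local property and carries over.
    """
    return {a: list(generate_ensemble(a, 0.08, 20, rc_confine=325.0,
                                      base_seed=1000))
            for a in FLORY_ALPHAS}


@pytest.fixture(scope="session")
def d16_ensembles():
    """10 configurations per folding parameter at phi=0.16, Rc=325 nm."""
    return {a: list(generate_ensemble(a, 0.16, 10, rc_confine=325.0,
                                      base_seed=2000))
            for a in (1.10, 1.20)}


@pytest.fixture(scope="session")
def mini_ensembles():
    """3 configurations for each of the 12 (phi, alpha) study combinations.

    Run at Rc=200 nm so the whole grid stays cheap; used for the
    packing-exponent range and trend properties.
    """
    out = {}
    seed = 5000
    for phi in (0.08, 0.12, 0.16, 0.20):
        for alpha in FLORY_ALPHAS:
            out[(phi, alpha)] = [c for c, _ in
                                 generate_ensemble(alpha, phi, 3,
                                                   rc_confine=200.0,
                                                   base_seed=seed)]
            seed += 100
    return out
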