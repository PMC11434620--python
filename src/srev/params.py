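"""Parameter containers for SR-EV generation and relaxation.

Physical conventions used throughout the package:

* lengths are in nanometres unless a field name says otherwise;
* jump/step lengths are expressed in *units* of the minimum jump length
  (``unit_length``, 10 nm by default, roughly one nucleosome diameter);
* each bead represents one nucleosome with a hard-core (non-overlap)
  radius ``BEAD_RADIUS_NM``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

#: Nucleosome non-overlap radius r0 (nm).
BEAD_RADIUS_NM: float = 4.9

#: Minimum jump length / model unit of length (nm).
UNIT_LENGTH_NM: float = 10.0

#: Default spherical global cutoff Rc (nm) for full-scale chromosomes.
DEFAULT_RC_NM: float = 650.0

#: Base pairs wrapped around one nucleosome.
NUCLEOSOME_BP: int = 147

#: DNA rise per base pair (nm), used for linker length assignment.
BP_RISE_NM: float = 0.34


def beads_for_phi(phi: float, rc_confine: float = DEFAULT_RC_NM,
                  bead_radius: float = BEAD_RADIUS_NM) -> int:
    """Number of beads N realising overall volume fraction ``phi``.

    The overall volume fraction of a configuration confined to a sphere of
    radius Rc is defined as ``phi = N * (r0 / Rc)**3``; this inverts that
    relation and rounds to the nearest integer.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if rc_confine <= bead_radius:
        raise ValueError("rc_confine must exceed the bead radius")
    return int(round(phi * (rc_confine / bead_radius) ** 3))


def phi_for_beads(n_beads: int, rc_confine: float = DEFAULT_RC_NM,
                  bead_radius: float = BEAD_RADIUS_NM) -> float:
    """Overall volume fraction realised by ``n_beads`` in a sphere of radius Rc."""
    return n_beads * (bead_radius / rc_confine) ** 3


@dataclass(frozen=True)
class GenerationParams:
    """Parameters of the self-returning random-walk (SRRW) generator.

    Parameters
    ----------
    alpha
        Folding parameter (> 1).  Controls both the probability of return
        steps and the heavy tail of the jump-length distribution; larger
        alpha means fewer, shorter-range returns.
    n_beads
        Number of walk vertices to generate (each visit later becomes one
        bead of the excluded-volume chain).
    rc_confine
        Spherical global cutoff (nm), measured from the centre of mass of
        the already-generated vertices.
    unit_length
        Minimum jump length (nm); the model unit of length.
    local_cutoff
        Maximum jump length, in units of ``unit_length``.
    seed
        Seed of the generator's random stream; generation is reproducible
        bit-for-bit for a fixed seed.
    """

    alpha: float
    n_beads: int
    rc_confine: float = DEFAULT_RC_NM
    unit_length: float = UNIT_LENGTH_NM
    local_cutoff: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError("alpha must be > 1 (the jump pdf is otherwise "
                             "non-normalizable)")
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        if not self.rc_confine > self.unit_length:
            raise ValueError("rc_confine must exceed the unit length")
        if not self.local_cutoff > 1:
            raise ValueError("local_cutoff must be > 1 unit")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenerationParams":
        return cls(**d)


@dataclass(frozen=True)
class RelaxationParams:
    """Parameters of the overlap-removal relaxation.

    The relaxation is a damped, overdamped descent on a potential made of
    harmonic bonds (rest length = initial bond length) and a soft harmonic
    half-spring repulsion between non-bonded beads closer than one bead
    diameter.  It terminates as soon as every overlap is resolved.
    """

    overlap_tol: float = 0.01         # relative tolerance on the contact distance
    max_steps: int = 40000            # iteration cap
    step_scale: float = 0.3           # mobility * dt of the overdamped update
    bond_stiffness: float = 0.5       # harmonic bond constant (model units / nm^2)
    repulsion_stiffness: float = 25.0 # half-spring constant (model units / nm^2)
    temperature_scale: float = 0.0    # amplitude of optional per-step noise (nm)
    max_displacement: float = 3.0     # per-bead per-step displacement cap (nm)
    seed: int = 0                     # used only when temperature_scale > 0
    active_refresh: int = 25          # iterations between full scans / active-set rebuilds
    stall_factor: float = 1.5         # repulsion escalation on stalled scans (1.0 disables)

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_tol <= 0.05:
            raise ValueError("overlap_tol must lie in [0, 0.05]")
        if self.bond_stiffness <= 0 or self.repulsion_stiffness <= 0:
            raise ValueError("stiffnesses must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
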