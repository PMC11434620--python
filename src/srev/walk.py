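"""Self-returning random walk (SRRW) generation.

The SRRW is a random walk in which every step is either a forward *jump*
(isotropic direction, heavy-tailed length) or a *return* that exactly
retraces the previous backbone segment.  With ``U0`` the length (in model
units) of the last backbone step, a return occurs with probability

    P_R(U0) = U0**(-alpha) / alpha,

and otherwise the walk jumps a distance ``U1`` drawn from the power-law pdf

    P_J(U1) = (alpha + 1) * U1**(-alpha - 2),   U1 >= 1,

truncated at a local cutoff.  A spherical global cutoff, measured from the
centre of mass of the already-generated vertices, contains the
configuration.  Returns stack: consecutive return steps walk back along the
backbone, so the raw walk revisits vertices and is not yet a physical
(excluded-volume) polymer — see :mod:`srev.excluded_volume`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import GenerationParams

__all__ = [
    "RawWalk",
    "return_probability",
    "sample_jump_length",
    "generate_walk",
    "return_fraction",
    "GenerationError",
    "JUMP",
    "RETURN",
]

#: step-type codes used in :attr:`RawWalk.step_types`
JUMP: int = 0
RETURN: int = 1

#: cap on rejection resamplings of a single jump against the global cutoff
MAX_PLACEMENT_ATTEMPTS: int = 10_000


class GenerationError(RuntimeError):
    """A walk vertex could not be placed inside the global cutoff."""


@dataclass(frozen=True)
class RawWalk:
    """One SRRW trajectory before excluded volume is introduced.

    Attributes
    ----------
    vertices
        ``(n_beads, 3)`` visited positions in nm, in visit order (revisits
        created by return steps appear as repeated positions).
    step_types
        Per-step code, :data:`JUMP` or :data:`RETURN`; ``len == n_beads - 1``.
    step_lengths
        Per-step length in units of ``params.unit_length``.
    params
        The :class:`~srev.params.GenerationParams` used.
    """

    vertices: np.ndarray
    step_types: np.ndarray
    step_lengths: np.ndarray
    params: GenerationParams

    def __post_init__(self) -> None:
        if len(self.vertices) != len(self.step_types) + 1:
            raise ValueError("vertex count must be step count + 1")
        if len(self.step_types) != len(self.step_lengths):
            raise ValueError("step_types and step_lengths length mismatch")

    @property
    def n_beads(self) -> int:
        return len(self.vertices)


def return_probability(u0, alpha: float):
    """Probability of a return step over a backbone segment of length ``u0``.

    ``u0`` is in model units (so ``u0 >= 1``); accepts scalars or arrays.
    The result is bounded by ``1 / alpha`` and decays as a power law, so
    returns over long backbone steps are rare.
    """
    u0 = np.asarray(u0, dtype=float)
    if np.any(u0 < 1):
        raise ValueError("u0 must be >= 1 model unit")
    if not alpha > 1:
        raise ValueError("alpha must be > 1")
    p = u0 ** (-alpha) / alpha
    return float(p) if p.ndim == 0 else p


def jump_length_from_uniform(x, alpha: float):
    """Inverse CDF of the untruncated jump-length pdf at uniform deviate ``x``."""
    x = np.asarray(x, dtype=float)
    u = (1.0 - x) ** (-1.0 / (alpha + 1.0))
    return float(u) if u.ndim == 0 else u


def sample_jump_length(alpha: float, local_cutoff: float,
                       rng: np.random.Generator, size: int | None = None):
    """Draw jump lengths from ``(alpha+1) U**(-alpha-2)`` truncated at the cutoff.

    Sampling is by inverse CDF with rejection of draws beyond
    ``local_cutoff``, which preserves the truncated pdf shape exactly.
    Returns a float for ``size=None``, else an array of ``size`` draws.
    """
    if not alpha > 1:
        raise ValueError("alpha must be > 1")
    if not local_cutoff > 1:
        raise ValueError("local_cutoff must be > 1")
    n = 1 if size is None else int(size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = jump_length_from_uniform(rng.random(n - filled), alpha)
        draw = np.atleast_1d(draw)
        keep = draw[draw <= local_cutoff]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
    return float(out[0]) if size is None else out


def generate_walk(params: GenerationParams) -> RawWalk:
    """Generate one SRRW trajectory.

    At each step a return occurs with :func:`return_probability` applied to
    the last backbone step (the first step, having no backbone, is always a
    jump); otherwise the walk jumps in an isotropic random direction with a
    length from :func:`sample_jump_length`.  Jump endpoints falling outside
    ``params.rc_confine`` of the running centre of mass are rejected and
    resampled, up to :data:`MAX_PLACEMENT_ATTEMPTS` times.

    Raises
    ------
    GenerationError
        If a vertex cannot be placed within the attempt cap.
    """
    pos, st, sl, status = _kernels.srrw_walk(
        params.n_beads, params.alpha, params.rc_confine, params.unit_length,
        params.local_cutoff, params.seed, MAX_PLACEMENT_ATTEMPTS,
    )
    if status != 0:
        raise GenerationError(
            f"failed to place a jump inside rc_confine={params.rc_confine} nm "
            f"after {MAX_PLACEMENT_ATTEMPTS} attempts (alpha={params.alpha}, "
            f"n_beads={params.n_beads}, seed={params.seed})")
    return RawWalk(vertices=pos, step_types=st, step_lengths=sl, params=params)


def return_fraction(walk: RawWalk) -> float:
    """Fraction of steps that are returns, in [0, 1]."""
    if len(walk.step_types) == 0:
        raise ValueError("walk has no steps")
    return float(np.mean(walk.step_types == RETURN))
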