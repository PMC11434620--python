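"""Ensemble polymeric observables: end-to-end scaling and contact probability.

Both observables are functions of the genomic separation ``n`` (bp).  Pairs
are enumerated by bead offset along the chain (log-spaced offsets, with
seeded subsampling at large offset counts) and accumulated into log-spaced
genomic-distance bins, pooling over every configuration of an ensemble.
Contacts are computed between bead centres — the nucleosome is the model's
resolution — using a 35 nm cutoff by default.

Both curves show a crossover near 4e4 bp between an intra-domain regime
(nearly space-filling clusters, Flory exponent ~0.35) and an inter-domain
regime, with a confinement plateau at the largest separations;
:func:`powerlaw_fit` extracts the regime exponents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .excluded_volume import BeadChain
from .genome import GenomicMap

__all__ = [
    "ScalingCurve",
    "PowerLawFit",
    "end_to_end_curve",
    "contact_probability_curve",
    "powerlaw_fit",
    "INTRA_DOMAIN_RANGE",
    "INTER_DOMAIN_RANGE",
    "DEFAULT_CONTACT_CUTOFF",
]

#: genomic-distance fit window (bp) below the intra/inter crossover at ~4e4 bp
INTRA_DOMAIN_RANGE: tuple[float, float] = (1e3, 4e4)

#: genomic-distance fit window (bp) of the inter-domain regime (full scale)
INTER_DOMAIN_RANGE: tuple[float, float] = (1e5, 1e6)

#: spatial contact cutoff (nm)
DEFAULT_CONTACT_CUTOFF: float = 35.0


@dataclass(frozen=True)
class ScalingCurve:
    """A binned observable versus genomic distance.

    ``values`` is root-mean-square end-to-end distance (nm) for kind
    ``"end_to_end"`` or mean contact probability for kind ``"contact"``;
    bins with no sampled pairs are dropped, not reported as zero.
    """

    n_bp: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    ensemble_size: int
    kind: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.n_bp) <= 0):
            raise ValueError("bins must be monotone increasing")
        if self.kind == "contact" and (np.any(self.values < 0)
                                       or np.any(self.values > 1)):
            raise ValueError("contact probabilities must lie in [0, 1]")
        if np.any(self.counts <= 0):
            raise ValueError("reported bins must have positive pair counts")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares log-log fit of a scaling curve over a genomic range."""

    exponent: float
    intercept: float      # value at n = 1 bp, in the curve's units
    r_squared: float
    n_range: tuple[float, float]
    n_bins: int


def _log_bin_edges(lo: float, hi: float, per_decade: int = 20) -> np.ndarray:
    ndec = np.log10(hi / lo)
    return np.geomspace(lo, hi, max(int(np.ceil(ndec * per_decade)), 1) + 1)


def _pair_offsets(n_beads: int, per_decade: int = 24) -> np.ndarray:
    """Log-spaced bead offsets 1..N-1 covering all separation scales."""
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    raw = np.geomspace(1, n_beads - 1, max(int(np.log10(n_beads) * per_decade), 2))
    return np.unique(np.rint(raw).astype(np.int64))


def _accumulate(ensemble, edges, cutoff, rng, max_pairs_per_offset):
    """Pool pair statistics over configurations into genomic bins.

    Returns (counts, sum of squared distances, contact counts) per bin.
    """
    nb = len(edges) - 1
    counts = np.zeros(nb, dtype=np.int64)
    sum_d2 = np.zeros(nb)
    contacts = np.zeros(nb, dtype=np.int64)
    c2 = cutoff * cutoff if cutoff is not None else None
    n_configs = 0
    for item in ensemble:
        chain, gmap = item
        pos = chain.positions
        cum = np.asarray(gmap.cumulative_bp, dtype=np.int64)
        n = len(pos)
        for s in _pair_offsets(n):
            i0 = np.arange(n - s)
            if max_pairs_per_offset and len(i0) > max_pairs_per_offset:
                i0 = rng.choice(len(i0), size=max_pairs_per_offset, replace=False)
            d = pos[i0 + s] - pos[i0]
            d2 = np.einsum("ij,ij->i", d, d)
            sep = (cum[i0 + s] - cum[i0]).astype(float)
            which = np.searchsorted(edges, sep, side="right") - 1
            ok = (which >= 0) & (which < nb)
            which = which[ok]
            np.add.at(counts, which, 1)
            np.add.at(sum_d2, which, d2[ok])
            if c2 is not None:
                np.add.at(contacts, which, (d2[ok] < c2).astype(np.int64))
        n_configs += 1
    if n_configs == 0:
        raise ValueError("ensemble is empty")
    return counts, sum_d2, contacts, n_configs


def _as_pairs(ensemble) -> list[tuple[BeadChain, GenomicMap]]:
    out = []
    for item in ensemble:
        if isinstance(item, BeadChain):
            raise TypeError("pass (BeadChain, GenomicMap) pairs; annotate "
                            "chains with srev.genome.assign_linkers first")
        out.append(item)
    return out


def end_to_end_curve(ensemble: Iterable[tuple[BeadChain, GenomicMap]],
                     bins: np.ndarray | None = None,
                     per_decade: int = 20,
                     max_pairs_per_offset: int = 20000,
                     seed: int = 0) -> ScalingCurve:
    """Root-mean-square end-to-end distance vs genomic separation.

    For every genomic bin the squared spatial distances of all sampled bead
    pairs in the bin are averaged over the whole ensemble and the square
    root is reported (nm).
    """
    ensemble = _as_pairs(ensemble)
    if bins is None:
        top = max(g.total_bp for _, g in ensemble)
        bins = _log_bin_edges(100.0, float(top), per_decade)
    rng = np.random.default_rng(seed)
    counts, sum_d2, _, n_cfg = _accumulate(ensemble, bins, None, rng,
                                           max_pairs_per_offset)
    centers = np.sqrt(bins[:-1] * bins[1:])
    keep = counts > 0
    return ScalingCurve(n_bp=centers[keep],
                        values=np.sqrt(sum_d2[keep] / counts[keep]),
                        counts=counts[keep], ensemble_size=n_cfg,
                        kind="end_to_end")


def contact_probability_curve(ensemble: Iterable[tuple[BeadChain, GenomicMap]],
                              cutoff: float = DEFAULT_CONTACT_CUTOFF,
                              bins: np.ndarray | None = None,
                              per_decade: int = 20,
                              max_pairs_per_offset: int = 20000,
                              seed: int = 0) -> ScalingCurve:
    """Probability that two beads at genomic separation n are in contact.

    A pair is in contact when the centre distance is below ``cutoff`` nm;
    the reported value per bin is the ensemble-pooled contact fraction.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ensemble = _as_pairs(ensemble)
    if bins is None:
        top = max(g.total_bp for _, g in ensemble)
        bins = _log_bin_edges(100.0, float(top), per_decade)
    rng = np.random.default_rng(seed)
    counts, _, contacts, n_cfg = _accumulate(ensemble, bins, cutoff, rng,
                                             max_pairs_per_offset)
    centers = np.sqrt(bins[:-1] * bins[1:])
    keep = counts > 0
    return ScalingCurve(n_bp=centers[keep],
                        values=contacts[keep] / counts[keep],
                        counts=counts[keep], ensemble_size=n_cfg,
                        kind="contact")


def powerlaw_fit(curve: ScalingCurve,
                 n_range: Sequence[float]) -> PowerLawFit:
    """Slope of log(value) vs log(n) restricted to ``n_range`` (bp).

    Unweighted least squares on the binned curve; requires at least three
    populated bins (with nonzero values) inside the range.
    """
    lo, hi = n_range
    sel = (curve.n_bp >= lo) & (curve.n_bp <= hi) & (curve.values > 0)
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 bins with data inside n_range {n_range}")
    x = np.log10(curve.n_bp[sel])
    y = np.log10(curve.values[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(exponent=float(slope), intercept=float(10 ** intercept),
                       r_squared=float(r2), n_range=(float(lo), float(hi)),
                       n_bins=int(sel.sum()))
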