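# Methods

## The model

`srev` implements a two-parameter stochastic model of chromatin at
nucleosome resolution. A conformation is built in two stages.

**Stage 1 — self-returning random walk (SRRW).** A walk over vertices in
3D space where each step is either a forward *jump* or a *return*. With
`U0` the length (in units of the 10 nm minimum jump) of the last backbone
step, a return occurs with probability

    P_R(U0) = U0^(-alpha) / alpha ,

and otherwise the walk jumps in an isotropic random direction with length
drawn from the heavy-tailed pdf

    P_J(U1) = (alpha + 1) U1^(-alpha-2) ,  U1 >= 1 ,

truncated at a local cutoff (default 30 units = 300 nm). Returns exactly
retrace the previous backbone segment; consecutive returns walk back along
the backbone (a stack). A spherical global cutoff of radius `Rc`, measured
from the centre of mass of the already generated vertices, contains the
configuration: jump endpoints outside it are rejected and redrawn (capped
at 1e4 attempts). The folding parameter `alpha > 1` controls both rules;
at alpha = 1.10/1.15/1.20 the walk spends 48.7/47.5/46.2% of its steps on
returns, which doubles as the package's strongest end-to-end check of the
rule normalization.

The return rules are a statistical proxy for the plurality of processes
that create long-range chromatin contacts (loop extrusion,
promoter-enhancer contacts, confinement entropics); the model deliberately
carries no genomic identity, no CTCF/cohesin sites, and no attractive
interactions.

**Stage 2 — excluded volume (SR-EV).** Every vertex *visit* becomes one
bead (a nucleosome, hard-core radius r0 = 4.9 nm), so a vertex visited k
times yields k coincident beads that are linearly bonded through the
intervening excursions. Coincident beads are jittered apart (<= 0.1 nm,
seeded) and the chain is relaxed by damped overdamped descent on

* harmonic bonds at rest length = the walk step length (so jump bonds stay
  near their sampled lengths), and
* a soft repulsive half-spring `V = k (2 r0 - d)^2` for non-bonded pairs
  with `d < 2 r0`; bonded pairs are repelled only if they start out
  overlapping, which never happens for walk-derived bonds (rest >= 10 nm).

Relaxation terminates as soon as *every* non-bonded pair is at least
`2 r0 (1 - overlap_tol)` apart (default tolerance 1%) — it is an
overlap-removal procedure, not thermodynamic sampling. A reflecting
spherical boundary at `Rc` about the configuration centre of mass keeps
the overall volume fraction `phi = N (r0/Rc)^3` meaningful. With
`temperature_scale = 0` (default) the procedure is deterministic.

**Genomic annotation.** Each bead carries 147 bp; a bond of length `U` nm
holds `round((U - 9.8)/0.34)` linker bp when `U > 9.8` and none otherwise.
Linkers are read from post-relaxation bond lengths by default
(`use_rest_lengths=True` switches to the walk step lengths). At the
reduced scales used here the mean linker is ~21-24 bp; the full-scale
reference values are in the mid-30s to mid-40s, and we treat the mean
linker as a consistency indicator, not a validation target, because the
averaging convention behind the reference values is not fully specified.

## Observables

* **End-to-end distance and contact probability** versus genomic
  separation `n` (bp). Pairs are enumerated by log-spaced bead offsets
  with seeded subsampling (20 000 pairs per offset by default) and pooled
  over the ensemble into 20-per-decade log bins. Contacts use a 35 nm
  centre-to-centre cutoff. Both curves cross over near n ~ 4e4 bp from an
  intra-domain to an inter-domain regime; `powerlaw_fit` extracts regime
  exponents by unweighted least squares in log-log space. Default
  windows: intra (1e3, 4e4) bp; inter (1e5, 1e6) bp at full scale. On
  reduced-`Rc` ensembles the confinement plateau moves down to
  n ~ 2.5e5 bp, so the reduced-scale inter window used in the tests is
  (5e4, 2.5e5) bp — and see Limitations for what confinement does to the
  ordering of the two exponents at half scale.
* **CVC** (chromatin volume concentration): occupied volume fraction in a
  cubic grid of (120 nm)^3 probing cells centred on the configuration
  centre of mass. Bead volume is apportioned by 19-point subsampling of
  each bead sphere (3x3x3 lattice minus the 8 corner points that fall
  outside the sphere); the apportioning error is far below the cell-count
  noise. Physical support is [0, 0.74] (crystal), with ~0.64 (jamming)
  the practical ceiling.
* **Coordination number**: beads within 11.5 nm of a bead's centre; 0 for
  isolated nucleosomes, up to 12 inside a packing domain.
* **g(r), G(r), packing exponent D.** Shell counts are accumulated
  around centre beads chosen deep enough inside the occupied region that
  no counted shell crosses its boundary (centres within `r_occ - r_max`
  of the centre of mass), so no edge correction is needed; normalization
  uses the mean density of the occupied sphere. `G` is the exact discrete
  cumulative pair count per centre per density, reported at shell outer
  edges, which makes `G = (4/3) pi r^3` exact for an ideal gas. `D` is
  the log-log slope of the ensemble-averaged `G` over 40-120 nm
  (1 nm shells). Per-configuration `D_i` and the local volume fraction
  `phi_i` are measured in a common probe sphere (240 nm radius, centred
  at the centre of mass; bead volumes clipped to the sphere by the exact
  sphere-sphere intersection). The ensemble-level `D` is fitted on the
  ensemble-averaged curve; per-configuration fits are provided separately
  because the two averaging orders differ slightly.
* **Tomogram pipeline.** Beads deposit unit mass as isotropic Gaussians
  (sigma = 5 nm) integrated exactly per voxel (2.9 nm default);
  mass is conserved to <1e-3. A 100 nm slab is projected to 2D, smoothed
  (Gaussian, 5 px), contrast-equalized (CLAHE, 120 px blocks, clip 0.01),
  and domain centres are the local density maxima above a configurable
  quantile floor with a minimum separation of one filter radius. Around
  each centre a mass-scaling curve `M(r)` is averaged over an 11 px
  window, weighted by pixel value; the domain radius is the smallest `r`
  that (1) deviates >5% from the power law fitted just outside the
  averaging window, (2) reaches a locally fitted exponent of 3, or (3)
  passes a local minimum of the radial shell density. The experimental
  protocol gives these parameters in pixel units without a pixel size;
  all of them are exposed, and the defaults tie them to the voxel size
  (5 px ~ 15 nm, 11 px ~ 32 nm). The inner fit window for criterion (1)
  starts just outside the averaging window, where the window-averaged
  curve is power-law clean. The exponent threshold in criterion (2)
  defaults to 3 in both 2D and 3D modes, following the experimental
  pipeline, with the planar limit 2 available as an argument.

## Study conditions and problem sizes

Full scale is `Rc = 650 nm` with `phi` in {0.08, 0.12, 0.16, 0.20}
(N between ~187k and ~467k beads) and `alpha` in {1.10, 1.15, 1.20}. The
test suite and the acceptance script run the same physics at reduced
confinement, chosen once as:

* return-rule statistics: full-scale walks (1e5 steps, 10 seeds);
* end-to-end scaling: `Rc = 325 nm`, `phi = 0.08`, 20 configurations per
  alpha (the curves are nearly phi-independent, so the cheapest paper
  condition is used);
* packing exponent: `Rc = 325 nm`, `phi = 0.16`, 10 configurations per
  alpha (at `Rc = 250 nm` the finite-size depression of g(r) at 100 nm
  scales biases D low by ~0.1, so the half-scale radius is the smallest
  that reproduces the full-scale D);
* cross-condition property grid: `Rc = 200 nm`, 3 configurations for each
  of the 12 (phi, alpha) combinations.

Ensemble member i uses seed base+i for every stochastic stage, so every
number in the tests and the acceptance script is reproducible from one
integer.

## Numerical choices

* Jump lengths by inverse CDF `U = (1-x)^(-1/(alpha+1))` with rejection of
  draws beyond the local cutoff (preserves the truncated pdf exactly).
* Relaxation: step scale 0.3, displacement cap 3 nm/iteration, bond
  stiffness 0.5, repulsion stiffness 25 (model units). The stiffness
  ratio sets the residual overlap depth at force balance well below the
  1% tolerance; the cap keeps deep-cluster expansion stable. A full pair
  scan every 25 iterations rebuilds an *active set* (beads within one
  9.8 nm cell of a current overlap); only active beads move in between,
  which makes the long sparse tail of the relaxation cheap without
  changing forces or the termination condition. If the overlap count
  fails to improve over 20 consecutive full scans — at chromosome scale a
  few overlaps can be pinned by strongly stretched bonds whose tension
  exceeds the repulsion at the tolerance depth — the repulsion stiffness
  is escalated geometrically (factor 1.5, `stall_factor`; set to 1 for
  pure descent), which guarantees termination. With these settings a
  46k-bead configuration relaxes in ~10-25 s on one core; a sparse
  fraction of bonds (~0.3%) ends mildly compressed below 9.8 nm because
  bonded pairs are not repelled, with no measurable effect on the
  observables.
* Energy bookkeeping (optional) records the total overlap penalty at each
  full scan; with zero temperature it decreases monotonically up to a
  terminal oscillation orders of magnitude below the initial penalty.
* Degenerate inputs: exactly coincident non-bonded beads get a
  deterministic tiny split before force evaluation; empty bins in scaling
  curves are dropped, never reported as zero; constant images return
  unchanged from contrast enhancement and yield no domain centres.

## What the generator does and does not emulate

The generated ensembles reproduce the published model statistics (return
fractions, Flory exponents, contact-curve shape and collapse across phi,
CVC support, D in (2,3) with its phi/alpha trends, the D_i-phi_i
correlation, and the directional effect of lowering alpha on the domain
census). They are not real chromatin: there is no sequence, no
cell-to-cell variation beyond the model's own stochasticity, no
experimental noise in the synthetic tomograms, and no Hi-C-style ligation
bias in the contact curves. Passing tests therefore validate the
implementation of the model and its observable suite, not agreement with
any particular experimental dataset.

## Known limitations

* **Half-scale confinement flattens the inter-domain regime.** At
  `Rc = 325 nm` the end-to-end curve plateaus from n ~ 2.5e5 bp, inside
  any usable inter-domain window, so the fitted inter-domain Flory
  exponent drops below the intra-domain one — the opposite of the
  full-scale ordering. Full-scale configurations (Rc = 650 nm) restore
  the ordering. The corresponding reduced-scale acceptance check is left
  failing with this analysis rather than silently re-scoped.
* The relaxation is a minimal overlap-removal dynamics; quantities that
  depend on the detailed relaxation pathway (e.g. the precise bond-length
  distribution, hence the mean linker) carry that arbitrariness.
* Appendix-level details of the original generation/relaxation algorithm
  (exact potential, integrator, temperature schedule, local cutoff value)
  are not public; the choices above are this package's own and are all
  exposed as parameters.
* The domain pipeline's pixel-unit parameters are calibrated to the
  default voxel size; other voxel sizes require rescaling them.
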