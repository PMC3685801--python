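# Methods

## Model and assumptions

The package treats every conduit in the unloading pathway — sieve pores
and, above all, plasmodesmal microchannels — as a no-slip cylindrical
pipe.  Volume flow obeys the Hagen–Poiseuille law
R<sub>v</sub> = π r⁴ ΔP / (8 η L); diffusion obeys Fick's first law
R<sub>i</sub> = D A ΔC / Δx with A = π r² and Δx = L; solute advected by
a bulk flow moves at R<sub>v</sub>·C.  These laws are linear in their
driving terms, and negative driving terms produce signed (reversed)
flows, which the network solver relies on.

Assumptions inherited from that idealization:

- Continuum, laminar, fully developed flow in channels a few water
  molecules wide.  This is the conventional basis for these estimates,
  but nanoconfined water can deviate strongly; slip-enhanced flow is
  exposed only as an optional multiplicative `enhancement` factor on
  the Poiseuille law (default 1), not modelled.
- Fixed temperature: viscosity (2×10⁻⁹ MPa s for phloem sap) and the
  sucrose diffusivity (0.52×10⁹ nm² s⁻¹, water at 25 °C) are constants,
  with no temperature or concentration dependence.
- Osmotic machinery is collapsed into boundary values.  Source pressure
  and sink-cell turgors are fixed Dirichlet boundaries; loading,
  retrieval and aquaporin water exchange that generate them are out of
  scope, as is any coupling of concentration to viscosity along the
  path (no Münch-style feedback).  Turgor-regulated plasmodesmal gating
  enters only as whatever conductance value the user assigns an edge.

## Internal units

All formulas are evaluated in nm–MPa–s–mol (lengths nm, pressures MPa,
viscosity MPa s, volume flow nm³ s⁻¹, concentration mol nm⁻³), the
system in which the published constants are quoted, so no hidden
factors appear in any law.  Lab-facing interfaces accept μL day⁻¹,
millimolar and Pa s and convert at the boundary with exact decimal
factors (1 μL = 10¹⁸ nm³; 86 400 s day⁻¹; 1 Pa s = 10⁻⁶ MPa s); all
conversions round-trip to 10⁻¹² relative.

## The packing rule for microchannels per plasmodesma

Microchannel centres are taken to lie on a circle of radius 10.5 nm
(half the 21 nm internal radius of the plasmodesma) with their
diameters occupying 50 % of its circumference.  The occupied arc is
first quantized into 1 nm slots — the diameter of the smallest channel
considered — giving 33 slots at the default geometry; a channel of
radius r then occupies 2r slots and the quotient is rounded half-up
(floor is available as an option), with a floor of one channel.  The
quantized rule is what the published tabulation actually used: it
yields 33, 17, 11, 8, 4, 2 channels for r = 0.5…8 nm, whereas dividing
the un-quantized arc (32.99 nm) directly would give 16, not 17, at
r = 1 nm.  At r = 10 nm the rule gives 2 against a printed 1; that row
of the source is internally inconsistent on its own terms (3×10⁴
channels at 1 per plasmodesma cannot give 10×10³ plasmodesmata) and is
flagged in all reports rather than reproduced.

## Feasibility procedure and thresholds

For a sink organ importing V (default 10 μL day⁻¹ ≡ 1.157×10¹⁴ nm³ s⁻¹)
across plasmodesmata of length 500 nm at differential ΔP (default
1.0 MPa): microchannels required = V / per-channel flow; plasmodesmata
required = that / channels-per-plasmodesma; feasible iff required ≤
observed (4.4×10⁷ for the wheat grain), with margin = observed/required
and equality counting as feasible.  The minimum feasible differential
is found on a fixed grid (default 0.1 MPa resolution, capped at 5 MPa —
above any measured sieve-tube pressure); an infinite sentinel marks an
unreachable target.  The plasmodesma requirement is strictly decreasing
in radius except for hair-width inversions at integer packing steps,
where the r⁴ gain across the boundary can be smaller than the packing
loss; the property suite asserts monotonicity on the unrounded
requirement and within equal-packing strata.

## Agreement with printed values

Golden comparisons use a printed-precision-aware tolerance: a computed
value agrees with a printed one if it is within max(1 % of the printed
value, one unit in its last printed digit), and derived columns
additionally inherit the propagated rounding of the parent column they
were printed from (the published plasmodesma counts were formed from
already-rounded microchannel counts).  The 1 % floor reflects rounding
slack the source itself carries (its r = 10 per-channel flow prints
392 900 ×10⁴ where the law gives 392 699).  Two printed values are
annotated, never matched: the (r = 0.5, C = 450 mM) bulk-flow cell
(prints 0.22 ×10⁻¹⁰ nmol s⁻¹ where R<sub>v</sub>·C gives 0.11) and the
r = 10 nm feasibility row.  Likewise the excision residuals (computed
17.1/15.2 vs published 17.8/14.2) and the radius increase for a 10 %
flow gain (r⁴ law gives 2.41 %, published 1.3 %) are reported side by
side with their published counterparts.

## Manifold network

The source–path–sink system is a comb graph: a chain of axial segments
from the source with one sink-interface edge per junction.  Each edge
carries a lumped hydraulic conductance (for N parallel plasmodesmata of
a given microchannel radius, N × channels-per-plasmodesma × the
single-channel Poiseuille conductance).  Interior pressures solve the
Kirchhoff conservation equations, assembled as the interior block of
the weighted Laplacian with boundary terms on the right-hand side and
solved by a direct dense solve with a fixed node ordering — fully
deterministic, no iteration.  Solutions are accepted only when the
interior flow imbalance is below 10⁻⁹ of gross node flow.  The regime
metrics are the axial pressure drop normalized by the overall
source-to-sink differential, and the worst deviation of a sink's
partition fraction from its normalized interface conductance; both
vanish as axial/sink conductance → ∞ (verified over a 1→10³ sweep).
The 2 % "manifold regime" threshold used in reports and the demo is a
package convention — no quantitative threshold for a "minimal" axial
gradient exists in the literature the parameters come from.  Note the
comb is not permutation-symmetric: at finite axial conductance the sink
nearest the source always receives slightly more than an identical sink
further along.

## Synthetic data

`sample_bundle` draws one measurement bundle per seed, uniformly within
the measured ranges: SE pressures 0.5–2.4 MPa, sink-cell turgors
0.08–0.33 MPa, SE sucrose 450–600 mM, parenchyma sucrose 200–260 mM,
microchannel radii 0.5–10 nm.  Two quantities have no published range
and were fixed once at field-plausible values: organ import rates
uniform on 5–15 μL day⁻¹ (bracketing the wheat-grain 10), and
plasmodesma counts log-uniform on 10⁷–10⁸ (bracketing the observed
4.4×10⁷; log-uniform because counts vary over orders of magnitude
between interfaces).  Invariants (SE pressure above sink turgor, SE
sucrose above parenchyma sucrose) hold by construction for the default
ranges and by rejection for overrides.  Sampling is a pure function of
the seed via a dedicated generator — no global random state.

What the generator does *not* emulate: temporal pressure oscillations,
axial gradients within an organ, correlated errors between quantities
measured on the same plant, or plasmodesmal gating dynamics.  Passing
the end-to-end fuzz contract therefore shows the pipeline is total and
numerically sound over the physiological envelope, not that it has been
validated against raw experimental traces.

## Numerical choices

- Crossover radius: bracketing root find (Brent) on the log of the
  bulk/diffusion ratio, tolerance 10⁻³ nm, default bracket 0.1–20 nm;
  the closed form √(8 η D ΔC / (ΔP C)) is kept as an independent
  cross-check in the tests.  "Comparable" means a ratio within a
  configurable factor-2 band — an operational convention, since no
  numeric criterion accompanies the qualitative statement it encodes.
- Dominance classification defaults to the ΔC = 400, C = 450 mM
  pairing, the mid-grid pairing under which r = 2 nm falls in the
  comparable band; all four grid pairings are always reported.
- Half-up rounding is implemented as floor(x + 0.5) to avoid banker's
  rounding surprises.
- Report serialization uses 6 significant digits; all comparisons are
  made at full precision before serialization, and identical inputs
  give byte-identical CSV/JSON artifacts.

## Problem sizes

Every computation here is desk scale: closed-form arithmetic on single
channels, grids of ≤ 7 radii, pressure scans of ≤ 50 grid points, and
dense solves of networks with a handful of nodes (property tests sweep
networks up to a few dozen nodes; the acceptance script's networks have
≤ 7).  The full test suite and the acceptance script each run in
seconds on one CPU.

## Known limitations

- No hindered-diffusion or steric corrections: a 1 nm channel barely
  exceeds a sucrose molecule's Stokes radius, where both laws used here
  are optimistic.
- No electro-osmotic or surface-charge effects.
- The network edge law is strictly linear; no concentration–viscosity
  coupling, no time dependence, no pressure–concentration waves.
- Plasmodesmal substructure (desmotubule, protein filaments, callose
  gating) appears only through the packing rule and whatever
  conductances the user assigns.
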