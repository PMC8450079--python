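# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic generators do and do not emulate.

## Base-pair-step parameters

A base-pair step is the rigid transformation between the reference frames of
two successive base pairs, ``(R_a, o_a) -> (R_b, o_b)``. We use the exact
mid-step rotation-vector decomposition:

* step rotation ``Q = R_a^T R_b`` with rotation vector ``v`` (axis × angle,
  in frame-a coordinates); **tilt, roll, twist** are the x, y, z components
  of ``v`` in degrees;
* mid-step frame ``R_m = R_a·exp(v/2)``; **shift, slide, rise** are
  ``R_m^T (o_b − o_a)`` in Å.

Because the rotation axis of ``Q`` is unchanged by its own half rotation,
the decomposition inverts in closed form (`rebuild_step`), and
extract∘rebuild is exact to machine precision — the round-trip tolerance of
1e-6 demanded by the tests is met with ~1e-13 to spare. This symmetric
mid-frame convention is in the family of standard base-pair-step definitions
(El Hassan–Calladine / 3DNA / Curves+); we chose the rotation-vector form
over the hinge-axis construction because exact invertibility is what the
synthetic DNA builder and the round-trip contracts require. For pure-twist
and pure-rise steps all conventions in this family coincide.

Sign convention: the frame x axis points into the major groove, y along the
short base-pair axis toward the Watson backbone, z advances 5'→3'. Positive
shift therefore displaces a base pair *out of* the major groove, and
right-handed helical twist is positive (canonical B-DNA ≈ 34.3°, rise
≈ 3.38 Å, packaged as `BDNA_STEP`).

Frames are taken as given when data come from the synthetic builder, or
fitted from coordinates: the idealized planar ring template of each base
(standard-reference-frame coordinates in `_basegeom.py`) is superposed onto
the observed ring atoms by least squares; the Crick-strand frame is flipped
into pair orientation (y, z negated) and the two base frames averaged with
SVD re-orthonormalisation. Builder and fitter share one template, so
build → re-extract round-trips do not depend on the template's absolute
accuracy.

## Distributions, state calls, alteration reach

Per-step histograms are normalised to unit area with bin edges aligned to
multiples of the bin width (defaults 0.1 Å for translations, 2° for
rotations). The most-populated-state call partitions values at a neutral
band of ±0.3 Å (suited to shift/slide, whose bimodal lobes sit near ±1 Å);
ties are called neutral. Both choices are exposed as arguments.

Bound-vs-unbound alteration is scored per step by the two-sample
Kolmogorov–Smirnov statistic — distribution-free, in [0, 1], equal to 1 for
disjoint supports — with a default alteration threshold of 0.2. At 2000
frames the KS statistic between identical distributions fluctuates around
~0.03, while a 1 Å mean displacement against an 0.35 Å-wide distribution
scores ~0.85, so the threshold separates the two regimes by a wide margin.
A scale-sensitive variance ratio is reported alongside, since "broad" vs
"narrow" is not captured by KS alone. The flank reach counts contiguously
altered steps outward from the response-element edge on each side,
stopping at the first unaltered step; the step straddling the element edge
is the first flank step (offset −1 or +1).

Equilibration handling: series expose `drop_equilibration` (by count or
fraction) so a leading transient can be discarded before any statistics;
analysis of a sliced series is identical to slicing after analysis (no
hidden state).

## Contact detection and strength

Detection criteria (CPPTRAJ-style, all inclusive at the boundary,
configurable):

| contact | criterion | default |
|---|---|---|
| hydrogen bond | donor–acceptor heavy-atom distance; plus D–H…A angle when the donor hydrogen is present | ≤ 3.5 Å, ≥ 120° |
| salt bridge | cationic ↔ anionic heavy atoms | ≤ 4.0 Å |
| apolar | apolar (C/S not in a charged or carbonyl group) ↔ apolar | ≤ 4.5 Å |

Without hydrogens the hydrogen-bond detector falls back to distance only and
logs it. Donor/acceptor/charge/apolar roles ship as a packaged TSV covering
the 20 amino acids, the four deoxynucleotides and the synthetic probe
group, and merge with user TSVs. Unknown heavy atoms are reported, never
silently dropped. A pair that satisfies both the hydrogen-bond and the
salt-bridge criterion (e.g. a lysine ammonium against a phosphate oxygen at
3.4 Å) is counted under both types, as the independent all-pairs filter in
the tests also does.

Contact strength of a residue pair in a frame is the unit-weighted count of
its contacts; no attempt is made to weight by interaction energy. The
dynamic contact map reports the full frames × pairs strength matrix, its
per-pair mean and the occupancy (fraction of frames with strength > 0),
in total and specific-only variants — averages and per-frame values are
both available since either view may be wanted.

Substate clustering reduces per-frame binary fingerprints (one bit per
partner-atom/contact-type) to the bits set in ≥ 10% of frames, then merges
identical reduced patterns via average-linkage hierarchical clustering on
Jaccard distances cut at distance zero. Two substates therefore always
differ in at least one non-rare contact, rare flicker does not split
states, and the procedure is fully deterministic (occupancy-ordered labels,
lexicographic tie-break).

## Promoter-library analysis

Coordinates are 0-based and half-open; minus-strand motif hits are reported
by forward-strand start, with flanks read in motif orientation from the
reverse complement. Palindromic motifs (YRE2) are deduplicated to one site
per location by default. Overlapping occurrences count separately toward
the single-instance filter, and minus-strand instances count toward
multiplicity (both configurable). The dispersion comparison uses the
classical equal-variance two-sample Student t-test on the collections of
within-group standard deviations (groups of size 1 are listed but excluded
— their SD is undefined); Welch's variant is available. Identical degenerate
SD collections give t = 0, p = 1; degenerate collections with different
means give t = ±∞, p = 0. Differential expression profiles are element-wise
log2(WT/mutant), requiring strictly positive values or an explicit
pseudocount.

## Ensemble utilities

Kabsch superposition (SVD-based, proper rotation enforced) requires ≥ 3
non-collinear atoms. Windowed average structures superpose every frame onto
the first window's mean — itself seeded from frame 0, i.e. the
mean/superpose cycle is iterated once — with the default selection being
DNA heavy atoms; the convergence table holds superposed RMSDs between all
window means. The RMSD reference is always an explicit argument. Torsions
follow the standard signed convention on (−180°, 180°]; backbone substates
are BI when the wrapped ε − ζ difference is negative, BII otherwise.

## Synthetic generators: what they emulate, and what not

The generators reproduce the *structure* of the study's inputs so that each
analysis has a recoverable planted truth; they do not attempt physical
realism.

* **Promoter libraries** — i.i.d. uniform A/C/G/T background with rejection
  sampling until the planted element is the only motif instance (and no
  exclusion motif occurs); defaults: 80-bp promoters, 18 expression bins
  (0 = weakest), one element per promoter. The expression model plants a
  group mean on the *width-4* flank key — bin centre 8.5 plus an effect of
  3 bins times a per-key standard-normal offset — and adds Gaussian noise
  (sd 1 bin) before rounding and clamping into the bin range; clamping
  inflates the edge bins slightly, which is accepted and tested. Real
  promoter libraries have composition bias, multiple weak sites and
  position effects; none of these are modelled, so passing tests show the
  *pipeline* recovers planted structure, not that real libraries behave
  this way.
* **Helical series** — per-step Gaussian mixtures (default a single
  component, sd 0.35 Å, matching the width of observed shift
  distributions); binding is a pure mean displacement (default 1 Å) applied
  within the element and over a configurable per-side flank reach. The
  non-focal parameters fluctuate independently around B-DNA means. Real
  series have frame autocorrelation and step-step coupling (e.g.
  shift–twist via BI/BII); both are absent, so significance calibrations
  on synthetic data are optimistic in the autocorrelated real case.
* **Structure ensembles** — duplexes built by chaining steps over the
  idealized pair templates with pseudo-backbone (P, OP1, OP2) atoms at
  plausible local positions, and a probe group (donor ND+HD, cation NZ at
  3.8 Å — inside the salt-bridge cutoff, outside the hydrogen-bond one —
  apolar CP) placed radially outside the helix at its contact distance in
  scheduled 'on' frames and ~25 Å away otherwise. No sugars, no hydrogens
  on DNA, no sequence-dependent stiffness.

Default problem sizes used by the tests and the acceptance script — 2000
frames for reach recovery, 3000-promoter sampled libraries, 10⁴ round-trip
draws, 20-seed repetition — were chosen so each planted effect is recovered
with a comfortable statistical margin while the whole suite completes in
seconds.

## Known limitations

* Helical-parameter values follow this package's fixed convention; they
  agree with Curves+/3DNA for small rotations but are not bit-compatible
  with either tool.
* Contact criteria are geometric only; water-mediated bridges, π-stacking
  and energetic weighting are out of scope.
* The `.ser` reader assumes the generic frame-index + one-column-per-step
  layout; exotic Canal output variants are not auto-detected.
* The dihedral/BI-BII utilities classify single torsion pairs; they do not
  extract torsions from structures.
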