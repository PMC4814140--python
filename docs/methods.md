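# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `aqpscope`, and what the desk-scale tests do and do not
establish about real channels.

## Pore-radius profiling

The profile follows the classical sphere-fitting definition: at each axial
position z the pore radius is the radius of the largest probe sphere, centered
in the slice plane, that touches but does not overlap any atom,

    r(z) = max_{c ∈ plane, |c| ≤ lateral_bound} min_i ( |c − x_i| − vdw_i ).

The inner maximisation is non-concave in general, so it is solved by
multi-start Nelder–Mead: one start on the axis plus `n_restarts − 1` seeded
random lateral offsets, followed by a tight polishing pass (xatol 1e-9) so
the result is reproducible to ~1e-6 Å under rigid motions of the whole
system. Defaults: `z_step` 0.25 Å, `lateral_bound` 5 Å, `n_restarts` 8,
fixed seed. On wall structures of a few hundred atoms the profiler agrees
with an exhaustive 0.05 Å lateral grid search to within 0.05 Å at every
slice (this oracle equivalence is asserted in the tests, which keep the
oracle as an independent implementation).

Slices with no atoms within `atom_cutoff` (12 Å) of the axis point are bulk
sentinels, and slices whose optimal center drifts to the lateral bound mark
the vestibule; both are truncated from the profile ends. Radii are clipped at
zero for fully occluded slices. The z origin convention places z = 0 at the
midpoint of the two NPA asparagine side-chain amide carbons, with z
increasing toward the non-cytosolic mouth; profiles from different structures
are compared by linear interpolation onto the intersection of their z ranges.

vdW radii come from a single documented element table (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.09 Å, …); unknown elements fall back to 1.70 Å with a
warning. Coordinates are treated as orthogonal Å; no symmetry expansion.
Alternate locations keep the highest-occupancy conformer.

## Selectivity-filter annotation

The two NPA motifs are located by a strict `NPA` scan (one motif required per
sequence half); if fewer than two strict motifs exist the relaxed pattern
`NP[AST]` is admitted with a warning. Filter positions are then fixed
offsets from the NPA asparagines — H2ᴾ = npa1 − 20, H5ᴾ = npa2 − 12,
LEᴾ = npa2 − 3, HEᴾ = npa2 + 3 — calibrated on AtTIP2;1 (NPA asparagines
83/197; filter His63, His131, Ile185, Gly194, Arg200) and exposed as a
configurable anchor table, since the positions are defined structurally and
universal offsets cannot be guaranteed across the superfamily. LCᴾ has no
stable offset: by default it is the His/Phe/Asn/Trp/Tyr residue in loop C
(between H2ᴾ and H5ᴾ) nearest to npa1 + 48, overridable by an explicit
alignment position.

Structure-based annotation takes residues with side-chain atoms within
4.5 Å of the channel axis in the selectivity-filter window (z between 2 and
15 Å above the NPA origin, mirrored automatically if the axis points the
other way). With a sequence prior the geometric candidates arbitrate
conflicts (geometry wins; the conflict is recorded). Without a prior a
heuristic assigns the arginine to HEᴾ, the most pore-facing His/Phe/Asn to
LCᴾ, remaining aromatics to H2ᴾ and hydrophobics to H5ᴾ; LEᴾ is the residue
whose backbone carbonyl oxygen lies nearest the axis, since it contributes
its carbonyl rather than a side chain.

Specificity rules, applied in order to the five-letter code:

1. H5ᴾ = H and LCᴾ = N → `water_specific`;
2. H2ᴾ = H, LCᴾ ∈ {H, F, W, Y}, H5ᴾ ∈ {I, V, L, A, G} → `aquaammoniaporin`;
3. H2ᴾ ∈ {W, F}, H5ᴾ ∈ {G, A, S}, bulky LEᴾ → `glycerol_like`;
4. otherwise `unknown`, with the failed clauses in the rationale.

The LCᴾ aromatic set includes W and Y as a conservative extension of the
observed H/F. Channels lacking the HEᴾ arginine, or with unusual
combinations, deliberately fall through to `unknown` rather than being
guessed. A separate flag, `requires_dual_permeability`, marks codes with a
hydrophobic H5ᴾ but no small (G/A) LEᴾ: such filters can be ammonia-biased
in vitro yet fail in growth assays that demand simultaneous water transport,
so in-vivo complementation outcomes are treated as data, not classification
rules. The packaged 14-construct panel carries exactly three such flagged
exceptions; for every unflagged construct the classifier's call maps onto
the observed growth outcome (`aquaammoniaporin` → growth, otherwise → no
growth). The panel is a curated reconstruction of the published mutational
series for these channels; one documented complementing single mutant
(H5ᴾ Ile→His on the TIP2;1 background) is not representable under rule 2
and is excluded from the panel — a known limitation of the rule scheme
rather than of the fixture format.

The LEᴾ-carbonyl spatial group is a single geometric rule: group II iff the
LCᴾ residue is an asparagine whose side-chain amide nitrogen (ND2) lies
within 3.5 Å of the LEᴾ backbone carbonyl oxygen; all other filters are
group I (carbonyl free to engage substrates).

## Trajectory observables

Trajectories are plain arrays (times, per-frame coordinates, optional
orthorhombic box, atom metadata) with a text frame-matrix dialect for
interchange, so all analyses run without an MD engine. Axial coordinates are
unwrapped by per-frame minimum-image increments when a box is present;
wrapped data without a box is rejected.

**Permeation events.** A molecule scores an event only on a full traversal:
it must enter the region [z_lo, z_hi] from one side and exit the other,
staying within `lateral_radius` of the axis while inside. Molecules already
inside at the first frame never receive an entry side. Re-crossings that
exit the entry side are discarded. The test suite checks the state machine
against an independently written brute-force scan on seeded random-walk
ensembles.

**Collective-diffusion permeability.** Per frame pair, the collective water
coordinate advances by dn = Σᵢ Δzᵢ / L over molecules inside the pore at both
endpoints; n(t) performs a random walk whose diffusion constant D_n gives
p_f = v_w·D_n with v_w = 2.99 × 10⁻²³ cm³ (bulk water molecular volume).
D_n is the MSD slope of n(t) over lags of 10–50 % of the analysis window,
fit through the origin; windows are averaged and their SD reported. The
synthetic test bed uses N = 16 independent axial Brownian walkers
(D = 1 Å²/τ) re-injected periodically over a 20 Å pore for 10⁵ frames split
into 200 windows, for which D_n has the closed form N·D/L²; the estimator
recovers it within 15 % (the MSD estimator's sampling error at these sizes
is ~5–10 %). This model reproduces the single-file bookkeeping but none of
protein flexibility, hydrogen-bond ordering or osmotic driving, so passing
it validates the estimator, not any particular channel's p_f; published
p_f values for real channels require the original MD trajectories.

**Hydrogen bonds.** Geometric criterion, donor–acceptor ≤ 3.5 Å and
D–H···A angle ≥ 150° (configurable). Counts are averaged per z-bin of the
solute and stratified by partner label (e.g. filter position), which
reproduces scripted duty cycles exactly on synthetic trajectories.

**Density grids** are per-voxel counts normalised by frame count and voxel
volume, so the grid integral equals the mean particle count in bounds
(conserved to 1e-6 relative, asserted).

**χ₁ dihedrals** use the standard signed dihedral (N–CA–CB–CG, IUPAC sign
convention, validated against an independent implementation during
development); rotamer basins are the nearest of −60°/180°/+60° (g⁻/t/g⁺) and
transitions are basin changes between consecutive frames.

**WHAM.** Umbrella windows (center, spring constant, samples) are combined
by the standard self-consistent iteration on binned histograms; convergence
when every window free-energy shift changes by < 1e-7 kJ/mol (default),
with an iteration error carrying the residual otherwise. Adjacent windows
must overlap (sample ranges), the default grid spans the 0.1–99.9 %
percentiles of all samples in 120 bins, and G is zeroed at the minimum over
a bulk region (default: the whole covered grid). Barrier height is
max G inside a region minus min G over the flanking bulk. The synthetic
umbrella generator draws exact (rejection-sampled) points from
exp(−(G(z) + ½k(z−c)²)/RT); 21 windows (k = 8 kJ mol⁻¹ Å⁻²) recover a flat
profile to < 0.5 kJ/mol at 4 × 10⁴ samples/window and a harmonic curvature
to well within 10 % at 4 × 10³. Published permeation barriers for real
channels (tens of kJ/mol from hundreds of ns of sampling) are outside desk
scale; the package instead asserts the analytic consequence that a
15 vs 20 kJ/mol barrier pair at 298 K implies a ≈7.5-fold (order-of-
magnitude) permeability difference, exp(ΔΔG/RT).

## Stopped-flow and yeast-assay kinetics

Traces are fit as single exponentials (`A(1 − e^{−kt}) + c` rising,
`A e^{−kt} + c` falling, direction auto-detected from the trend) by
Levenberg–Marquardt with k ≥ 0, initial k from the 63 %-span time;
dead-time points are excluded by configuration. Degenerate (flat) traces
return k ≈ 0 with infinite standard error and a flag instead of failing.
Rate-versus-gradient analysis is ordinary least squares on per-gradient mean
rates, with per-point SDs carried for presentation. Free NH₃ from total
ammonium follows Henderson–Hasselbalch, NH₃ = total/(1 + 10^(pKa − pH)),
default pKa 9.25; the assay pH is always an explicit argument because
published gradients do not fix it.

The specificity table works in the assay's printed units (ammonia rates in
10⁻² s⁻¹, water rates in s⁻¹). Background correction subtracts the
empty-vector strain's rate and clips negatives to zero; corrected standard
errors combine fit and background errors in quadrature, and the ratio error
uses first-order relative-error propagation. A corrected rate is treated as
insignificant below max(3 × SE, 0.1 table units). The ratio is NA when both
corrected rates are insignificant; a zero water rate with significant
ammonia sets an infinite-ratio flag (classified as ammonia-specific with no
numeric ratio). Classification compares each ratio with the reference
channel's: within ±25 % → reference-like, above → Ammonia, below (including
zero) → Water. The ±25 % band is a package choice — no published threshold
exists — selected so that ratios of ~0.9× the reference classify as
reference-like while 5×–15× classify as Ammonia; it is configurable.
The published corrected water columns for this panel reflect unrounded
inputs (e.g. 1.91 where the printed raw values give 1.95), so ratios
recomputed from printed raw rates can differ from printed ratios by a few
per cent; propagated ratio errors likewise reproduce the printed magnitudes
only approximately. Table output rounds corrected rates to 3 significant
figures and ratios to 2, matching the assay's presentation convention.

## Synthetic data

Every generator is deterministic given (parameters, seed) and returns its
ground truth alongside the data. Toy channels are built from wall-atom rings
whose ring radius is inner radius + vdW, so the true sphere-fit radius is
known by construction (24 atoms/ring, 0.5 Å ring spacing keep the
discretisation error below 0.01 Å); the default wall vdW equals the carbon
table radius so constructions survive a PDB round trip. Brownian walkers use
Euler–Maruyama steps (variance 2·D·dt) with periodic axial re-injection (for
collective-diffusion work, keeping the pore population constant), reflecting
boundaries, or strong drift (every walker crosses once); traversals of the
pore interval are logged by the generator's own scan of the continuous
paths. The AtTIP2;1 sequence scaffold is synthetic (the real sequence is not
bundled): a 250-residue filler carrying the NPA motifs and the five filter
residues at their native numbers, with a filler alphabet chosen so motif and
loop-C searches resolve uniquely. The construct-panel fixtures (14 filter
codes with growth outcomes; 9 raw rate rows) are data tables, not generated.

## Known limitations

- Sequence offsets are calibrated to TIP-like architecture; divergent AQPs
  need an explicit anchor table or alignment-provided LCᴾ.
- The structure-annotation heuristic without a sequence prior relies on
  residue-type patterns and will not resolve filters with duplicated types
  beyond His at H2ᴾ/LCᴾ.
- The collective-diffusion and WHAM test beds validate estimators on ideal
  models; they say nothing about force-field accuracy or sampling of real
  trajectories.
- Classification covers the water/ammonia/glycerol axes observed in the
  panel; filters outside those patterns return `unknown` by design.
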