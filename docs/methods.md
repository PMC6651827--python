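# Methods

## The hydrogen-bond energy criterion

`hydrobridge` scores a candidate donor–hydrogen⋯acceptor contact with an
empirical energy function of three geometric observables: the
hydrogen–acceptor distance *d* (Å), the donor–hydrogen–acceptor angle, and
the hydrogen–acceptor–X angle, where X is an atom covalently bound to the
acceptor:

```
E = E_opt · (d₀ − max(d, d_c)) / (d₀ − d_c) · S_DHA · S_HAX     [kJ/mol]
```

with defaults `E_opt = 25` kJ/mol, clamp `d_c = 2.1` Å and zero-crossing
`d₀ = 2.6` Å. The distance term is 1 for any contact at or under 2.1 Å and
falls linearly to 0 at 2.6 Å; beyond 2.6 Å it is negative, so such contacts
can never pass the positive threshold and the detector prunes them with a
KD-tree before scoring (the pruning is a pure optimisation and is
oracle-checked in the test suite).

Both angular factors are piecewise-linear ramps clipped to [0, 1]:

* `S_DHA` rises from 0 at 100° to 1 at 165° — a bent donor geometry
  destroys the bond, a near-linear one is optimal;
* `S_HAX` rises from 0 at 85° to 1 at 95° when X is a heavy atom, and from
  0 at 75° to 1 at 85° when X is itself a hydrogen (slightly smaller
  approach angles are tolerated at, e.g., a water oxygen).

A bond is *detected* when `E > 6.25` kJ/mol strictly — 25 % of the optimum.
The comparison is deliberately strict: a contact engineered to score the
threshold exactly is not reported, and a unit test pins this down.

**Choice of X.** When the acceptor has several covalent partners, the
partner giving the *smallest* `S_HAX` is used and recorded on the bond
record. This is the conservative reading of the acceptor rule: the least
favourable substituent geometry governs. The alternative reading — keeping
only one bond per acceptor — would contradict the many-bonds-per-acceptor
structure of the contact maps this package produces; it remains available
as the `strongest_per_acceptor` toggle of `detect_hbonds`. An acceptor
with no covalent partner at all (a bare ion) gets `S_HAX = 1`, though ions
are excluded from the polar-element set by default anyway.

Donors are polar heavy atoms (N, O, S by default; configurable) with a
covalently bound hydrogen; acceptors are all polar heavy atoms. Sulfur is
included because sulfate-bearing solutes (e.g. chondroitin sulphate) carry
acceptor-capable SO₄ groups. Intramolecular bonds are computed; the
group-pair filter (`between=`) restricts the headline statistics to
intergroup contacts.

## Water bridges

A *water bridge* is a single water residue that, in one frame, carries at
least one above-threshold hydrogen bond to each of the two solute groups.
The water's role is not restricted: it may donate to one side and accept
from the other, or donate to both. Bridge qualification uses the same
energy criterion as direct bonds — there is a single source of truth for
what counts as a bond. Chains of two or more waters are out of scope.

For mapping, a bridge is identified by the (A-atom, B-atom) heavy-atom
pairs it joins; two distinct waters spanning the same pair in one frame are
two bridges but one mapped pair.

## Contact maps and durations

Contact maps count *unique* heavy-atom pairs (donor heavy, acceptor) per
frame — a pair recurring within one frame, e.g. through two hydrogens of
the same donor, counts once. Percentages normalise each pair's
frame-presence count by the total number of pair-frame incidences, so a
map's legend sums to 100 %.

Durations use the occurrence-counting estimator: occupancy time equals
presence-frame count × snapshot interval. This deliberately ignores
contiguity; the longest contiguous run is reported as a separate labelled
column and never substituted. Frames must be equally spaced — durations on
a non-uniform clock raise an error instructing resampling rather than
guessing. The snapshot interval is a required configuration value with no
default: the analysed trajectory's cadence is not something the package
can infer.

## Solvent-accessible surface

The solvent-accessible surface is the locus of the centre of a spherical
probe (default 1.4 Å, the water-oxygen probe) rolling over the van der
Waals surface of the selection. It is estimated by Shrake–Rupley point
sampling: each atom's expanded sphere (r_vdW + probe) is sampled at
`n_sphere_points` (default 960) quasi-uniform directions; a point covered
by any other selected atom's expanded sphere is inaccessible; the atom's
area is its accessible fraction × 4π(r + probe)².

The direction set is a deterministic golden-angle (Fibonacci) spiral rather
than a random sample, so results are reproducible without seeds and
re-runs diff clean. Convergence and orientation sensitivity are bounded in
the tests: doubling the point count moves a single-atom area by < 0.5 %,
and a rigid rotation moves a cluster area by < 0.5 %. Radii default to the
Bondi set, shipped as a plain-text table (`data/vdw_radii.txt`) and fully
overridable. Only atoms inside the selection occlude each other — waters
and counterions are invisible to a solute-group SAS unless explicitly
selected, matching the rolling-over-the-solute definition.

No analytic (LCPO / power-diagram) surface is attempted; the sampling
estimator has a closed-form oracle (an isolated sphere) and exact
additivity for disjoint atoms, which the acceptance suite exploits.

## Trajectory model and file dialect

The canonical trajectory dialect is multi-model PDB: one `MODEL` block per
snapshot over a fixed atom table. The dialect was chosen because fixtures
remain text-diffable and openable in any structure viewer. Parsing is
delegated to biotite; this package adds the trajectory-level contracts: a
model with a deviating atom count is reported by its 1-based index, an
atom whose element cannot be determined is reported by serial and name,
and CONECT records — written for the full adjacency, including waters —
override distance-based bond inference on read. Inference, used when no
CONECT is present, bonds pairs within 1.15 × the sum of single-bond
covalent radii and prunes each hydrogen to its nearest heavy partner; a
stranded hydrogen triggers a warning and is excluded from donor roles.

Waters are recognised by residue name (HOH/WAT/SOL/TIP3 aliases,
configurable) and must be composed of one O and two H; a matching residue
with any other composition is warned about and left ungrouped. Waters are
treated as rigid 3-atom residues throughout. Monatomic ions (NA, CL, …)
go to the `other` group and take no part in bond statistics.

Coordinates are carried at PDB precision (three decimals). The reader
re-rounds to three decimals after the float32 parse so the in-memory
values equal the printed ones exactly — this is what lets planted fixture
energies round-trip to 1e-6 kJ/mol.

## The synthetic fixture generator

`synthetic.generate_fixture` builds desk-scale systems (40–60 atoms, 3–5
frames) that emulate the *analysis-relevant* features of a
glycosaminoglycan–phospholipid system in explicit water: hydroxyl and
carboxylate groups on solute A, phosphate and amine headgroups on solute
B, waters planted to bridge specific atom pairs, plus decoys — methane, a
sodium ion, a polar pair beyond the 2.6 Å horizon and a pair at a
destructive 90° donor angle — so empty-result paths are always exercised.

Every interaction is planted at an exactly known geometry. Motifs are
rigid; each gets a seeded random rotation (which cannot change internal
geometry) and a position on a line with radius-aware spacing that
guarantees ≥ 8 Å between atoms of different motifs, far beyond the bonding
horizon. An interaction is switched off in a frame by displacing its
mobile fragment 6.5 Å perpendicular to the placement axis. The manifest
records, per planted bond, the realised geometry and energy recomputed
from the emitted file-precision coordinates with inline arithmetic —
independent of the scoring module — so end-to-end tests compare two
separate routes to the same number.

What the generator does **not** emulate: force-field energetics, realistic
conformational sampling, periodic boundaries, crowding, or the
competitive solvation of a 150,000-atom box. Passing the fixture suite
therefore demonstrates that the *measurement machinery* is correct, not
that any particular biological system behaves a certain way. One
qualitative observation does carry over by construction: under identical
placement statistics, a headgroup with N–H donors
(`ethanolamine_B` scenario) forms strictly more distinct bonded sites than
a donor-free choline-like headgroup (`choline_B`), because the donor-free
variant simply has no polar hydrogens to offer.

## Numerical and design choices

* Strict `>` threshold comparison; ties are excluded by definition.
* KD-tree candidate generation at `d₀`; equivalence with an exhaustive
  scorer is asserted over hundreds of randomised systems.
* Angles from `arccos` with the cosine clipped to [−1, 1]; degenerate
  zero-length vectors cannot arise because candidate distance is checked
  first and covalent geometry keeps D ≠ H ≠ A.
* Rigid-motion invariance of every scored energy holds to 1e-9 relative.
* CSV outputs use a fixed dialect (comma, `.` decimal, LF, `%.6f`) and are
  written atomically (temp file + rename); identical inputs give
  byte-identical outputs, which the tests assert.
* The selection grammar is deliberately minimal (`chain`, `resname`,
  `resid`, combinable with `or`); a full MD-suite selection language is a
  non-goal.
* Analysis problem sizes in the tests — ≤ 60-atom fixtures, ≤ 10 frames,
  200 randomised oracle systems — were chosen as the smallest systems that
  exercise every code path with planted ground truth.

## Known limitations

* Only single-water bridges are identified.
* No periodic-boundary handling: frames are assumed whole-molecule.
* The occupancy estimator cannot distinguish one long contact from many
  short ones; the longest-run column is informative but no kinetic
  (autocorrelation) lifetime model is provided.
* Absolute SAS values depend on the van der Waals radii set; comparisons
  across radii tables are not meaningful.
* PDB is the only trajectory dialect; binary MD formats must be converted
  upstream.
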