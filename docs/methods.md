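# Methods

This note documents the models and numerical conventions behind each
analysis stage, the choices made where the design was genuinely open, and
what the synthetic fixtures do and do not demonstrate.

## Structure model and parsing policies

Coordinates are read through gemmi (PDB and mmCIF) into a light
chain → residue → heavy-atom hierarchy with ligand groups kept separate.
Policies, chosen for single-conformer geometry on mid-resolution cryo-EM
models:

* **Altlocs** — one conformer per atom name is kept: highest occupancy,
  ties broken by alphabetical altloc id. This makes parsing deterministic
  under record-order permutations.
* **Hydrogens** — dropped everywhere; a ~3.4 Å map carries no reliable
  hydrogen positions, and all geometry is defined over heavy atoms.
* **Waters** — stripped by default; all other hetero groups are retained
  as ligands.
* **Multi-model files** — first model only, with a logged notice.
* **Numbering** — author numbering as deposited, insertion codes honored,
  because variant catalogues cite author numbering. Polymer residues
  lacking a Cα are flagged on the model, never silently dropped.

### Segment annotation

Segments (TM1–TM6, EH, CH, NBD) are inclusive author-numbering ranges per
chain, validated for start ≤ end and for non-overlap between distinct TM
helices within a chain. The bundled default for human ALDP
(`data/aldp_segments.yaml`) pins EH to 364–374 and CH to 683–745 from the
published deletion constructs; the TM and NBD bounds are **curated
approximations** from ABC-transporter domain organisation, not deposited
annotations, and should be recalibrated against deposited coordinates
before quantitative use on real structures.

## Superposition and distances

Kabsch superposition is the closed-form SVD solution for the proper
rotation R and translation t minimising Σ|R·mᵢ + t − rᵢ|²; the
determinant correction excludes reflections, and near-collinear point
sets (second singular value < 1e-8 of the first) raise a conditioning
error rather than returning an arbitrary rotation. Reported RMSD is the
post-transform value.

Per-residue displacement maps pair residues across states by chain id
(with an explicit mapping override) and author number, superpose on an
alignment window (intended use: the NBD core of one protomer), and report
|Δ| per shared Cα.

**TM4–TM6 juxta-membrane convention.** State-series distances are
intra-model, so no cross-state superposition is involved. The default
gate metric is the minimum Cα–Cα distance between the five
highest-numbered (cytosolic-end) residues of TM4 and TM6 of one protomer.
Published figures of this transporter family rarely state which atoms
were measured; this convention is therefore the package's own
operationalisation and its absolute values should be treated as
calibration-dependent (± a few Å against any particular published
number) until checked against the deposited entries. The
`pair_ca_ca` metric supports pinning the measurement to one residue pair
once a convention has been calibrated.

## Cavity detection

A Cartesian grid (default spacing 0.6 Å) covers the bounding box of the
heavy atoms plus a probe margin. A node is *blocked* if it lies within
`probe + vdW(element)` of any heavy atom (probe default 1.4 Å, the water
convention; fixed internal vdW table C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80, 1.70 otherwise). Open nodes are clustered by 6-connectivity;
every cluster touching a boundary face is bulk solvent; the remaining
clusters are cavities. Volume is `|nodes| · spacing³`, an estimator that
converges from a lattice approximation as spacing shrinks (the test
surface requires < 10 % change upon halving the spacing and 15 %
agreement with the analytic volume of a planted spherical void).
Lining residues are those with a heavy atom within 4.5 Å (a standard
contact cutoff) of any cavity node.

Two operational choices deserve emphasis. "Cavities formed by the
transmembrane domains" is operationalised as restricting the grid to the
TM-segment bounding box when a segment annotation is supplied — no
membrane is modelled. And published pocket volumes computed by external
web services embed unknown settings; the package's contract is
qualitative (cavity count, symmetry agreement, size ordering between
pockets) plus grid convergence, not exact agreement with any
service-computed number.

`ligand_seeded` mode excludes a named ligand's atoms from the occupancy
set and keeps only cavities overlapping that ligand's probe envelope —
the natural way to measure the substrate cavity of a holo structure.
Ligand extent is the maximal heavy-atom pairwise distance, the "length"
relevant to comparing a linear acyl-CoA (~55 Å extended) with a compact
phospholipid (~40 Å).

## Variant hotspots and spatial classification

"Mutated to two or more types of amino acids" is read literally: per
residue position, the set of distinct alternate amino acids is counted
(not distinct nucleotide changes), and `is_hotspot ⇔ n_distinct ≥ 2` by
default. Only missense variants enter hotspot calling — a spatial
interpretation needs a substituted residue — while nonsense/other rows
are retained in the rejects report. Catalogue-scale counts (e.g., 970
records / 232 affected residues / 88 hotspots) are snapshot- and
curation-dependent: the pipeline reports them, asserts them only on the
planted demo where they are true by construction, and supports a
configurable numbering offset for catalogue/structure reconciliation.

Classification uses a fixed precedence so each hotspot gets exactly one
label: in a TM range and in the lining set → `cavity_lining`; in a TM
range only → `tmd_other`; in the NBD range → `nbd`; in the CH range →
`ch_other`; otherwise `unassigned` (reported, with a loud warning when
≥ 50 % of hotspots are unassigned — the usual symptom of a numbering
mismatch). The C-terminal helix keeps its own label because it is a
distinct structural element carrying a known single-residue hotspot; the
conventional three-way summary reports `nbd + ch_other` as group 3.
Reproducing any particular published 10/35/43-style split on real data
depends on the curated segment ranges and the lining cutoff; on the
bundled demo the split is planted and exact.

## Kinetics and melts

Michaelis–Menten fitting is nonlinear least squares (scipy `curve_fit`,
positivity bounds) initialised from the Hanes–Woolf linearisation
s/v = s/V<sub>max</sub> + K<sub>m</sub>/V<sub>max</sub>, which is robust
on sparse concentration grids; standard errors are Jacobian-based
covariances at the optimum, matching the usual "±" reporting style
without bootstrap cost. Degenerate inputs (all-zero rates, < 3 distinct
concentrations) raise explicit errors.

Melt curves are nanoDSF-style: T<sub>m</sub> is located at the extremum
of the first derivative of the F350/F330 ratio. Numerically, the ratio is
smoothed by a centred moving average (default window 7 points), the
finite-difference derivative is smoothed again with the same window, the
first/last window of points is excluded from the peak search (both
smoothing passes and the gradient stencil bias the edges), a transition
is required to stand out from the derivative's own background (max
excursion ≥ 3× the median absolute excursion — flat or linear curves
raise a no-transition error), and the peak is refined to sub-grid
precision by the vertex of a quadratic fitted over the contiguous
half-maximum region of the derivative peak. On the synthetic generator's
conditions (0.5 °C grid, two-state sigmoid of width 2 °C, 1 % per-channel
multiplicative noise) this recovers the planted midpoint with a
Monte-Carlo sd of about 0.2 °C; single draws can err by ~0.6 °C, which is
the intrinsic precision of the derivative-extremum method at that noise,
not a smoothing artefact. The estimate is exactly equivariant under
common rescaling of both fluorescence channels, since only the ratio
enters.

WT normalisation divides each construct's measurement by the wild-type
value (WT maps to 1.0); a missing or zero WT raises.

## Synthetic fixtures: what they show and what they don't

The generators emulate the geometric and statistical *shape* of the real
inputs with exactly known truth: Cα-only ideal helix bundles (rise 1.5
Å/residue, twist 100°, Cα radius 2.3 Å) with a recorded C2 operator for
dimers; straight-line (radius-0) helices where a planted inter-segment
distance must be exact; spherical pseudo-atom shells (golden-spiral
lattice, default vdW radius) whose interior void has analytic volume;
linear pseudo-ligands with closed-form extent; variant tables with a
planted hotspot/singleton split; Michaelis–Menten and two-state-melt data
at known parameters. All randomness flows through one seeded generator —
same seed, bit-identical fixture.

They deliberately lack: side chains and realistic packing, membranes,
experimental noise structure (correlated detector noise, baseline drift),
cryo-EM model error, and any sequence realism in the variant tables.
Passing the planted-recovery suite therefore demonstrates algorithmic
correctness and numerical convergence, not that the curated segment
ranges, the juxta-membrane convention, or the cavity parameters reproduce
any particular measurement on real deposited coordinates — those checks
require the deposited entries (fetchable with `aldpkit fetch` where
network is available) and are kept separate in the test suite.

## Pipeline determinism and problem sizes

Every stage writes plain TSV/JSON; the run report records a sha256
checksum per output, and identical config + seed reproduces identical
checksums. Default problem sizes (demo bundle ~370 residues/chain, shell
fixtures of 6–8 Å void radius at 0.5–1.0 Å spacing, 100-draw Monte-Carlo
recovery checks) were chosen so the full suite runs in seconds on a
single CPU while keeping grid-convergence and Monte-Carlo assertions
meaningful.
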