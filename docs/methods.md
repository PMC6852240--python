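# Methods

This note documents the models and procedures implemented in `surfpatch`,
the defaults chosen where the design was genuinely open, and what the
synthetic test system does and does not demonstrate.

## Surface and interface definitions

Accessible surface area is computed by Shrake–Rupley sphere sampling with a
1.4 Å probe and a fixed golden-spiral lattice of 960 points per atom, so
results are deterministic bit-for-bit. Van der Waals radii are per element
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å; 1.80 Å otherwise). Relative
accessibility (rasa) divides the residue ASA by the Tien et al. (2013)
theoretical maxima, which are tripeptide-context values; a fully solvent-free
residue therefore scores rasa > 1, and the surface rule is rasa ≥ 5 %.
Sampling accuracy is ~0.5 Å² per atom at 960 points (validated against an
independent Monte-Carlo occlusion oracle in the tests).

A residue is interfacial when any of its atoms lies strictly closer than
5 Å to any atom of a partner chain; interfaces contain surface residues
only, with the surface evaluated on the unbound side (monomer context).
Interface layers use the 25 % rasa burial threshold computed with and
without the partner: support stays buried, core becomes buried on binding,
rim stays exposed. These three sets partition the interface exactly.

## Residue scores

**T_JET (conservation).** Homologs aligned to the query are binned by
percent identity ([20,40), [40,60), [60,80), [80,98]); subsets are drawn
without replacement targeting one quarter per bin, redistributing deficits
to the bins with spare sequences. Defaults: ⌈√pool⌉ subsets of ⌈√pool⌉
sequences each, capped at 50 (the sampling literature this follows does not
fix the count; both are configurable). Distances are p-distances over
mutually gap-free columns; trees are neighbor-joining with deterministic
lowest-index tie-breaking and negative branch lengths clamped to zero.
NJ produces an unrooted tree, and trace levels need a root: midpoint
rooting is used, deterministically. Levels count edges from the root
(root = 0); the trace level of a query position is the depth of the
shallowest ancestor of the query leaf whose entire leaf set carries the
query's amino acid. Positions with no such ancestor are flagged "no trace"
and excluded from the average, so

    T_JET(j) = (1/M_j) Σ_t (L_t − l_j^t)/L_t ∈ [0, 1],

with M_j the number of trees contributing a trace. A column conserved at
the root of every tree scores exactly 1.

**PC (interface propensity of amino-acid types).** Scaled by the published
maximum 2.21 (global scaling, not per-protein min–max). The bundled table
is a synthetic stand-in with a standard enrichment ordering (aromatics and
large hydrophobics high, charged/small polar low) because the original
numbers are not reproduced here; any table can be supplied as a TSV and the
tests do not depend on the bundled values.

**CV (circular variance).** Per atom, one minus the normalised resultant of
unit vectors to all atoms within r_c (strict); residue CV averages over
heavy atoms. Default r_c = 100 Å, effectively a global density descriptor:
with a smaller radius CV degenerates to a local packing measure and loses
the smooth surface-to-core gradient. An atom with no neighbour within r_c
is maximally protruding (CV 0, with a warning). Residue values are min–max
rescaled over the surface so 0 marks the most protruding and 1 the least
protruding residue.

**NIP (docking propensity).** Per partner, poses within 2.7 kcal/mol
(strict) of that partner's best pose are retained; IP(i) is the fraction of
retained poses (pooled over partners) placing residue i at the docked
interface, and NIP normalises IP by its per-protein mean and maximum. NIP
is computed over surface residues only: buried residues can never dock, and
including them only deflates the mean. A constant IP distribution maps to
all-zero NIP with a warning. NIP keeps its native scale (max exactly 1,
mean 0); a min–max copy in [0,1] is stored alongside for any use that
requires the common scale.

## Patch prediction

Each strategy names the score used by each admission layer; where two
scores are named the combined score is their arithmetic mean on the [0,1]
scale (symmetric, monotone; min or product would sharpen or soften the
conjunction and are trivial local edits).

| strategy | seed | extension | outer |
|---|---|---|---|
| SC_cons | T_JET | (T_JET+PC)/2 | (PC+CV)/2 |
| SC_notLig | (T_JET+CV)/2 | (T_JET+CV)/2 | (PC+CV)/2 |
| SC_geom | (PC+CV)/2 | (PC+CV)/2 | (PC+CV)/2 |
| SC_dock | NIP | NIP | NIP |

Admission quantiles default to 0.9 (seed), 0.6 (extension), 0.5 (outer) and
must strictly decrease — the signal is strongest in the seed and fades
outward; the ordering is enforced at configuration load. Admission takes
residues at or above the layer quantile and strictly above the layer's
global minimum: a saturated top score (e.g. a block of fully conserved
residues, T_JET = 1) still seeds, while a flat score distribution never
does. Seeds are 5 Å-connected components of at least three admitted
residues; anything closer than 5 Å belongs to one component, which realises
the seed-merge rule. Extension admits surface residues in contact (< 5 Å)
with the growing patch in descending score order up to a target size;
growing patches in mutual contact merge (layer-wise union, seed taking
precedence). The outer layer is added once at the end from contacting
residues above the outer quantile.

Target patch sizes are a fraction of the surface residue count: 0.33 for
the conservation strategies and 0.25 for SC_geom/SC_dock, matching the
relative sizes these patch families should reach (region-sized versus
site-sized predictions).

The iterative consensus runs 10 iterations and keeps residues detected at
least twice. For T_JET-based strategies each iteration re-samples the
homolog subsets (fresh trees, hence score diversity); SC_geom and SC_dock
scores are deterministic, so their iterations are identical and the ≥2/10
rule is satisfied trivially — no artificial jitter is injected. All
tie-breaks are lexicographic on (score desc, chain, residue number,
insertion code), making every prediction reproducible byte-for-byte for a
fixed seed.

## Sites and regions

Partners of a query chain are grouped by transitive 5 Å contact among
themselves; each group yields one interacting site (multi-partner when the
group has several chains). Sites from homolog structures are mapped onto
the query through a global pairwise alignment (BLOSUM62, gap open −10,
extend −0.5); site residues aligned to gaps are dropped, and a mapped pair
below 90 % identity warns (outside the close-homolog criterion) but still
maps.

Region merging iterates to a fixpoint: two sites (or a site and an
accumulated region — the closure semantics; "iterate over all sites"
implies accumulated unions) merge when max(|A∩B|/|A|, |A∩B|/|B|) > 60 %
strictly, relaxed to one shared residue when either side has at most five
residues. After the fixpoint, regions of five residues or fewer are
dropped. Processing order is canonical (size descending, then smallest
residue), so the output is invariant under input permutation; the engine is
pinned to an exhaustive closure oracle in the tests.

## Seed analysis

Seeds from SC_notLig, SC_geom and SC_dock are clustered by agglomerative
average linkage on all inter-atomic distances between seed atom sets
(atom-count-weighted Lance–Williams updates, i.e. the linkage distance is
the exact mean over all atom pairs), cutting at 23 Å; SC_cons seeds are
discarded — they are systematically larger and overlap several other
strategies' seeds, which makes them poor locators of distinct regions.
Partner multiplicity of a region counts the distinct strategies having a
seed with precision ≥ 80 % relative to the region (range 0–3). Partner
counts are single-linkage clusters of partner sequences at ≥ 90 %
global-alignment identity (identity over the longer sequence).

## Evaluation

Precision, recall and F1 are residue-level; the empty prediction scores 0
by convention. Per region, the best-matching union over patch subsets is
searched exhaustively up to 12 candidate patches (ties prefer the smaller
union), greedily beyond with a warning. Coverage is the surface fraction
used by a set union. Regional conformational deviation superposes each
homolog on the region's backbone atoms (N, CA, C, O; CA-only fallback) by
the Kabsch algorithm and averages the per-homolog RMSD; homologs with fewer
than three mappable residues are skipped.

## Synthetic test system

The fixture generator plants known ground truth:

* **Complexes.** The default geometry stacks two slab-like chains of
  pseudo-residues on a 4 Å grid with perpendicular side-chain arms; the
  partner slab covers about half the query surface, so the planted
  interface is a contiguous block at the coverage scale experimentally
  derived interacting regions reach. Ground truth is defined as exactly
  what interface detection reports on the noise-free coordinates (a
  consistency gate), and noisy conformers add isotropic Gaussian
  displacement. An ideal α-helix geometry is also available; its contact
  face is a sparse stripe, useful for testing detection but not patch
  recovery. Defaults (40-residue query, 20-residue partner, 500 poses,
  24 homologs) keep the full suite in well under five minutes on one CPU.
* **Homolog pools.** Random substitutions reach target identities within
  ±2 %, never touching a designated conserved column set (the planted
  conservation signal). Default occupancies put six homologs in each
  sampling bin.
* **Docking poses.** Each pose picks a contact centre with weight `bias`
  inside the planted hot region and 1 outside; its interface is the
  contiguous neighbourhood (ten nearest surface residues) of the centre,
  since docked interfaces are patches rather than random residue sets.
  For bias > 1 energies decrease with the pose's hot-region fraction, so
  the energy filter enriches the signal; at bias = 1 energy and region are
  independent and the empirical IP matches the exact neighbourhood-coverage
  expectation.

What passing these tests shows: the formulas are implemented exactly, the
combinatorial engines (merging, clustering, NJ, superposition) match
brute-force oracles, and the pipeline recovers planted signals of realistic
contrast. What it does not show: performance on real protein shapes, real
conservation patterns, or real docking energetics — the fixtures have
idealised geometry, uniform backbone chemistry and a single planted region.

## Numerical choices and degenerate inputs

Strict inequalities follow the rules' wording: contacts < 5 Å, surface
rasa ≥ 5 %, energy window < 2.7 kcal/mol, overlap > 60 %, sites > 5
residues retained. Quantiles use linear interpolation (numpy default).
Empty pose sets, empty surfaces and empty merge inputs raise; no-seed
score landscapes return empty predictions (valid). All stochastic steps
take an explicit seed and the pipeline derives every stream from the
single run seed.

## Known limitations

* The PC table is a labelled synthetic stand-in, not the published scale;
  supply the original values by file for production use.
* Homolog search, multiple alignment and docking are inputs, not computed:
  the package consumes aligned pools and pose records.
* mmCIF, nucleic-acid chains and symmetry-mate generation are out of
  scope; biological assemblies must be pre-expanded in the input file.
* The exact subset count/size of the conservation sampling and the
  original seed/extension admission internals are not published at this
  granularity; the defaults here are explicit, documented stand-ins pinned
  by the planted-recovery tests.
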