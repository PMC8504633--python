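# Methods

## The chimera-construction model

chimeraforge builds chimeric proteins with exactly one crossover. Given a
fragment-homology hit between a query and a subject domain, the pipeline is:

1. **Alignment mapping.** Each gap-free column of the hit's gapped alignment
   is mapped to one residue in each parent, walking the alignment from the
   fragment start positions (`q_start`, `s_start`; 0-based, half-open, on
   the internal sequential residue index, i.e. ATOM-record file order —
   author numbering is never used by algorithms). Columns with a gap on
   either side map to nothing. The alignment letters are checked against
   the structure sequences; agreement below a configurable fraction
   (default 0.9) aborts with per-column diagnostics, catching
   bounds/numbering mistakes early.

2. **Superposition.** The aligned Cα pairs are superposed with the Kabsch
   algorithm (SVD of the cross-covariance, reflection-corrected, so the
   rotation is always proper with det +1). Two modes exist:
   *global* fits all aligned pairs at once; *partial* fits each
   gap-delimited alignment segment independently, which accommodates long
   fragments whose sub-motifs (e.g. βα units) are mutually hinged.
   Correspondence always comes from the sequence alignment; no structural
   re-alignment is attempted. In partial mode each column's Cα distance is
   measured under its own segment's transform, and segments with fewer
   than `min_seg_len` (default 3) aligned columns are excluded entirely:
   1–2-point rigid fits are ill-conditioned and would manufacture spurious
   sub-cutoff distances.

3. **Fusion points.** An aligned column is a fusion point when its
   post-superposition Cα–Cα distance is strictly below the cutoff
   (default 1.0 Å, user-adjustable). Low distances occur inside shared
   secondary-structure elements and mark positions where crossing over
   perturbs the backbone least.

4. **Assembly.** Each fusion point yields two candidates. Combination 1
   keeps the query N-terminus: query residues `[0 .. q_idx]` followed by
   subject residues `[s_idx+1 .. end]`, with the subject brought into the
   query frame by the governing superposition. Combination 2 is the mirror
   construct. The residue *at* the fusion column therefore comes from the
   N-terminal parent — a convention, documented here and fixed by tests,
   since the crossover residue could equally be assigned to the other side.
   Chimeras are renumbered 1..L on a single chain; per-residue parent
   provenance is kept and written into the B-factor column (query 1.0,
   subject 2.0). A fusion at a terminal residue that would leave one side
   empty is rejected as degenerate.

5. **Clash filter.** A candidate is discarded when any backbone heavy-atom
   pair (N, CA, C, O) between a query-derived and a subject-derived residue
   lies closer than `d_clash` (default 2.5 Å, just below the shortest
   non-bonded backbone contacts seen in folded proteins). Atom pairs
   between residues *adjacent in the chimera* are exempt: the only
   cross-parent adjacent pair is the junction itself, where the implied
   peptide linkage necessarily places C(j)–N(j+1) ≈ 1.33 Å,
   O(j)–N(j+1) ≈ 2.25 Å and C(j)–CA(j+1) ≈ 2.44 Å — covalent geometry, not
   steric failure. Exempting only the C–N pair would mislabel every
   junction (including the identity chimera of two identical parents) as
   clashing. Side-chain clashes are deliberately ignored — repacking is a
   minimisation problem, out of scope here — and intra-parent geometry is
   trusted as given.

No junction idealisation or energy minimisation is performed; the output
PDB is provenance-complete input for any external forcefield tool.

### Counting

For `n` mapped alignment positions the candidate space is bounded by `2n`
(two combinations per position); `k` accepted fusion points send `2k`
candidates (minus degenerate terminals) into the clash filter. These counts
are exposed in `BuildReport` and recomputed by `scripts/acceptance.py`.

## Hit tables and networks

Hits carry fragment bounds per domain, gapped alignment strings (ungapped
length must equal the bounds span — validated on load with row-numbered
diagnostics), HHsearch probability (percent), fragment RMSD (Å), TM-score,
identity and SCOPe lineages. Filter semantics follow the conventional
thresholds: probability **>** 70, RMSD **<** 3 Å, fragment length (query
side) **between 10 and 200 inclusive**, TM-score **<** 0.3 — strict on
scores, inclusive on length, each independently disablable. The single
`tm_score` column is whatever the producing database reports; if a table
distinguishes fragment-alignment from full-domain TM-scores, the filter
applies to the stored column and can be disabled.

Network nodes are `domain_cluster` identifiers: the same domain carrying
two different fragment clusters becomes two nodes, which is what makes
node counts exceed domain counts in fragment databases. A
`collapse_clusters` mode merges them when a per-domain view is wanted.
Reciprocal and duplicate hits collapse to one unweighted edge with recorded
multiplicity; components and hubs treat edges as unweighted. Export is
GraphML/DOT rather than interactive rendering.

## Structural analyses

* **SASA** — Shrake–Rupley with a deterministic golden-spiral quadrature
  (default 960 points/atom, probe 1.4 Å; vdW radii C 1.7, N 1.55, O 1.52,
  S 1.8 Å, unknown elements 1.7 Å with a warning). 960 points keep the
  single-sphere analytic error and the 960-vs-10000-point self-convergence
  gap both under 1–2%.
* **Contact maps** — full Cα–Cα distance matrices.
* **Relative contact order** — `100/(L·N) · Σ|i−j|` over the N residue
  pairs with any heavy-atom pair within 6 Å and sequence separation ≥ 1,
  the standard relative-CO definition; both parameters are exposed.
* **Salt bridges** — closest Asp OD1/OD2 or Glu OE1/OE2 oxygen to
  Lys NZ / Arg NE,NH1,NH2 / His ND1,NE2 nitrogen below 4.0 Å, one record
  per residue pair (minimum distance kept). His counts as basic by
  default; configurable.
* **Hydrogen bonds** — heavy-atom criterion (donor N to acceptor O < 3.5 Å;
  backbone–backbone pairs require sequence separation ≥ 2) because the
  structures handled here carry no hydrogens; an angle term is accepted in
  the API but inert without hydrogens.
* **Hydrophobic clusters** — apolar atoms are side-chain C and S of
  hydrophobic-class residues (ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, CYS);
  two atoms are in contact when centre distance ≤ r_vdw(a) + r_vdw(b) +
  2·1.4 Å (a solvent-pad relaxation standing in for a full
  contact-surface-legitimacy test — an approximation of CSU-style contact
  classification: connectivity semantics are preserved, exact per-contact
  areas are not). Clusters are connected components over residues linked
  by ≥ 1 atomic contact, size-filtered (default ≥ 4 residues; analyses on
  small fixtures use 2). The reported area sums, per atomic contact, the
  spherical cap of the smaller atom's padded sphere lying inside the
  partner's padded sphere, estimated with the same quadrature as SASA.
  Areas should be compared within one parameter set only.

All detectors are rigid-motion invariant and are tested against brute-force
all-pairs scans.

## Synthetic data

`build_ideal_ss` grows a backbone+Cβ poly-Ala chain by NeRF
(internal-coordinate) placement with Engh–Huber-like bonds/angles and
canonical dihedrals: helix φ/ψ = −57°/−47°, strand −139°/+135°, loop
−60°/+150°. The loop dihedrals are PPII-like, chosen so that direct
helix↔strand block transitions keep all non-adjacent backbone atoms above
the clash threshold (an abrupt helix→strand junction without a loop places
one O···O pair at 2.49 Å — use a loop block between elements when a
clash-free fixture is needed).

`make_toy_pair(n_shared, n_fusable, seed)` emulates the study condition the
builder is designed for: two parents sharing an `n_shared`-residue fragment
(extended-strand geometry, flanks of 4/4 query and 3/5 subject residues so
no fusion point is terminal) in which exactly `n_fusable` randomly chosen
aligned pairs superpose below the 1 Å cutoff. Non-fusable residues are
displaced perpendicular to the chain plane, alternating sides; a fixed-point
loop then re-fits the Kabsch transform, snaps fusable Cα pairs onto their
targets and pushes non-fusable ones further until every fusable distance is
< 0.8 Å and every non-fusable one > 1.3 Å, so the 1.0 Å decision boundary
is never near a constructed distance. Finally the subject is moved by a
random rigid transform so nothing depends on the construction frame. The
generator is seeded and byte-reproducible.

What the fixtures do **not** emulate: real side chains (only Cβ), loops and
turns of natural topologies, alignment errors, missing density, alternate
conformers. Passing tests on them demonstrates the correctness of the
geometry, bookkeeping and filtering logic — not predictive validity on
natural domains, where fusion-point counts depend on the actual structural
divergence of the parents.

## Numerical choices and degenerate inputs

* Kabsch requires ≥ 3 pairs; near-collinear point sets warn (rotation about
  the common axis is under-determined) but still return the optimal fit.
* TM-score uses the standard `d0 = 1.24·(L−15)^{1/3} − 1.8`, floored at
  0.5 Å, with a warning, for targets of length ≤ 15.
* Fusion cutoff comparisons are strict (`<`); filter thresholds strict on
  scores, inclusive on lengths (see above).
* PDB dialect: fixed-column ATOM records only; HETATM, waters and
  hydrogens dropped; altloc blank/'A' kept; models after the first
  ignored; unparseable lines raise with the line number; writing renumbers
  serials from 1 and refuses empty structures. Coordinates round-trip at
  the format's 3-decimal precision.
* Empty analysis results (no contacts, no apolar atoms) raise or return
  empty lists per operation; the aggregate `report` records per-analysis
  errors without aborting the rest.

## Problem sizes

Tests and the acceptance script run on synthetic chains of 12–110 residues
and hit tables of 12–80 rows; all detectors are cross-checked against
O(n²) oracles at these sizes, where exhaustive enumeration is exact and
fast. The full suite completes in well under a minute.

## Known limitations

* Single crossover only; no multi-fragment recombination, loop rebuilding
  or junction minimisation.
* Sequence-alignment-guided superposition only; no structure-based
  re-alignment of the fragment.
* The hydrophobic-cluster contact test is a distance-threshold
  approximation (see above); absolute cluster areas are not comparable to
  surface-decomposition implementations.
* H-bond detection without hydrogens over-counts relative to
  angle-resolved criteria.
* Analyses run on coordinates as given; minimised and unminimised models
  of the same protein will differ numerically.
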