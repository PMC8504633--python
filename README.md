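# chimeraforge

Automated design of **single-crossover protein chimeras** from
fragment-homology hits, with a structural-analysis battery for the results.

Many natural protein folds share evolutionarily conserved sub-domain
fragments. When two domains — say, a P-loop NTPase and a Rossmann-fold
enzyme — share such a fragment, the fragment defines a region where the two
backbones superpose closely, and every aligned residue pair whose Cα atoms
lie within a small distance of each other after superposition is a
geometrically seamless *fusion point*: a position where the N-terminal part
of one parent can be joined to the C-terminal part of the other with minimal
structural perturbation. chimeraforge automates that construction for
protein engineers exploring fragment recombination:

1. **hits** — load fragment-homology hit tables (TSV or SQLite) carrying
   profile-HMM (HHsearch) alignments, fragment bounds and scores; filter by
   probability, RMSD, fragment length and TM-score; fetch SCOPe lineage
   groups (e.g. all `c.37` hits).
2. **network** — represent hits as a similarity network whose nodes are
   domain-fragment clusters and whose edges join domains sharing a fragment;
   connected components group domains around one fragment type.
3. **superpose** — Kabsch least-squares superposition of the aligned
   fragment Cα atoms, either globally or per gap-delimited alignment
   segment, plus RMSD and TM-score
   (`d0 = 1.24·(L−15)^{1/3} − 1.8`).
4. **builder** — detect fusion points (default cutoff 1 Å), assemble both
   chimeras per point (combination 1 = query N-terminus, combination 2 =
   subject N-terminus), and reject models whose parent halves clash
   backbone-on-backbone (default 2.5 Å).
5. **analysis** — SASA (Shrake–Rupley), Cα contact maps, relative contact
   order, salt bridges, hydrogen bonds and hydrophobic clusters
   (connected components of the apolar side-chain contact graph).
6. **structures** — PDB reading/writing and a deterministic ideal-geometry
   generator that builds synthetic α/β parent pairs with engineered
   fusion points for testing and benchmarking.

For a hit whose alignment maps *n* residue pairs onto both structures, at
most `2n` offspring chimeras exist before filtering; with *k* accepted
fusion points, `2k` candidates enter the clash filter.

## Worked example

Generate a synthetic parent pair sharing a 20-residue fragment in which
exactly 5 aligned Cα pairs superpose below 1 Å, then build all chimeras:

```sh
$ chimeraforge fixtures --toy-pair 20 5 1 -o fix
wrote query.pdb, subject.pdb, hit.tsv to fix
$ chimeraforge build --hits fix/hit.tsv --qpdb fix/query.pdb \
      --spdb fix/subject.pdb -o out
20 mapped positions (max 40 candidates), 5 fusion points, 10 candidates, 0 clashed, 10 chimeras written to out
$ head -4 out/manifest.tsv
name    fusion_column   q_res   s_res   ca_distance     n_residues
comb1_0 0       4       3       0.425   29
comb2_0 0       4       3       0.425   27
comb1_7 7       11      10      0.649   29
```

The 20 aligned positions bound the offspring at 40; the 5 fusion points
yield 10 candidates (both N-terminal combinations each), and none clash, so
all 10 are written. `comb1_0` fuses query residues 0–4 to subject residues
4–27 at alignment column 0, where the superposed Cα pair sits 0.425 Å
apart. Each PDB records parent provenance in the B-factor column
(query = 1.0, subject = 2.0).

Analyse any model:

```sh
$ chimeraforge analyze out/comb1_0.pdb
{
  "id": "comb1_0",
  "n_residues": 29,
  "sasa_total": 3793.0,
  "relative_contact_order": 5.11,
  ...
}
```

A low relative contact order (~5%) is expected for a short extended chain;
globular domains typically fall between 5% and 25%.

The library API mirrors the CLI:

```python
from chimeraforge import make_toy_pair, build_report

q, s, hit = make_toy_pair(n_shared=20, n_fusable=5, seed=1)
rep = build_report(hit, q, s, mode="global", cutoff=1.0)
print(rep.n_fusion_points, len(rep.chimeras))  # 5 10
```

A 12-row toy hit table ships with the package
(`chimeraforge.load_toy_hits()`) for experimenting with the filtering and
network layers.

## Scope

Forcefield scoring/minimisation of the assembled chimeras, regeneration of
fragment databases (all-vs-all profile-HMM searches) and interactive 3-D
visualisation are out of scope; the builder emits standard PDB files with
full provenance so any external minimiser can take over, and networks
export to GraphML/DOT. See `docs/methods.md` for the model, parameter
defaults and limitations.
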