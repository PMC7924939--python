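# carrierphylo

Comparative genomics of the PIC2/MIR1/SLC25A3 subfamily of mitochondrial
carriers (SLC25 family), as a tested, reusable pipeline.

In *Saccharomyces cerevisiae*, mitochondrial copper and phosphate import
are split between two paralogous carriers, PIC2 and MIR1, while mammals
use a single ortholog, SLC25A3, for both substrates. Reconstructing how
that division of labour arose — and which residues set substrate
preference — requires the same analysis in any eukaryotic lineage:

1. **harvest** carrier-domain proteins from each proteome (a PSSM scan
   standing in for the Pfam PF00153 profile),
2. **deduplicate** transcript variants (CD-HIT-style greedy clustering at
   0.9 identity),
3. **screen** each taxon's carriers against labeled references with a
   fast neighbor-joining tree (Poisson distances, pairwise gap deletion),
4. **classify** the pooled candidates as PIC2-like, MIR1-like or other on
   a final tree (NJ, optionally refined by LG+F+FreeRate likelihood with
   NNI search; bootstrap supports),
5. **reconcile** per-taxon copy numbers against the eukaryotic species
   tree by Sankoff parsimony to date duplications and losses,
6. **score conservation** per residue by Shannon entropy, clade-resolved,
   to nominate specificity-determining positions, and
7. **project** those scores onto structure coordinates via PDB B-factors.

## The statistics at the core

* Poisson-corrected distance: `d = −ln(1 − p)`, `p` the fraction of
  differing sites over columns where both sequences have residues.
* Felsenstein-pruning log-likelihood under Poisson or LG
  exchangeabilities, `+F` empirical frequencies, FreeRate categories
  (k pairs `(r_i, w_i)`, `Σ w_i r_i = 1`).
* Sankoff parsimony over copy numbers `{0..c_max}` with asymmetric costs
  `w_gain·max(0, c−p) + w_loss·max(0, p−c)`; the focal classes are pinned
  to one ancestral copy because the founding duplication predates the
  species-tree root.
* Column entropy `H = −Σ p_i log2 p_i` (bits); a position is conserved
  when `H < 0.5`, clade-specific when conserved in one clade while the
  other clade is variable or fixed for a different residue (the
  Cys44-vs-Thr pattern that separates the copper- and phosphate-carrier
  clades), shared when conserved in both with the same consensus.

A synthetic-data module generates the full study design with known truth
— gene families born by duplication/loss on a species tree, planted
invariant/clade-specific/neutral sites, decoy proteins — and every stage
is tested against that truth.

## Worked example

Generate a self-contained synthetic bundle (12 taxa, two paralog
classes, three deeper carrier families, 20 decoys per proteome) and run
every stage:

```
carrierphylo demo --seed 42 --outdir demo
carrierphylo run-all --config demo/config.yaml
```

The log reports each threshold as it is used; the headline lines of the
seed-42 run are:

```
INFO carrierphylo: classification at support >= 75: 12 A-like, 8 B-like, 0 other-family, 9 outside
INFO carrierphylo: reconciliation: cost 1.0 (w_gain=2, w_loss=1, c_max=4), 1 event branches
INFO carrierphylo: conservation: entropy threshold 0.50 bits, coverage >= 0.50; 300 positions, 38 shared, 20 A-specific, 26 B-specific
```

Reading this: all 12 surviving A-class genes and all 8 surviving B-class
genes were recovered and correctly labeled (the 9 "outside" sequences
are deep other-family carriers correctly rejected from the subfamily);
one gene-loss event was inferred, on the same species-tree branch (`N3`)
where the generator actually placed it:

```
$ cat demo/results/events.tsv
branch  class   duplications    losses
N3      B_like  0       1
```

`demo/results/` also holds the per-taxon copy-number table, per-supergroup
means, the final tree with bootstrap supports, the per-residue
conservation table with categories, and a manifest of checksums; run the
same command twice and the artifacts are byte-identical.

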