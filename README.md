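# phosbe

Base-editor gRNA library design and pooled-screen analysis for
**functional phosphoproteomics**: turning annotated phosphorylation
sites into testable loss-of-phosphorylation alleles at scale.

## The problem

Phosphorylation of Ser/Thr/Tyr residues controls much of cell
signalling, but databases annotate orders of magnitude more sites than
have known functions. CRISPR base editors make it possible to test
sites directly in pooled screens: a cytosine base editor (CBE, C→T) or
adenine base editor (ABE, A→G) guided to a phosphosite codon can
convert the residue into one that cannot be phosphorylated, and drug
selection then reads out which sites matter for a phenotype such as
5-FU resistance.

`phosbe` implements the computational side of this approach:

- **editing model** — enumeration of all codon-level outcomes of a base
  editor (same-strand combinations of window edits, both strands of the
  duplex). Exhaustive enumeration shows S/T/Y can reach exactly **10**
  other amino acids across CBE+ABE ({F,L,N,I,M} via C→T-class edits,
  {G,P,A,C,H} via A→G-class edits), and that Tyr is CBE-untargetable.
- **library design** — scan coding sequences on both strands for 20-nt
  protospacers with an NGG PAM placing an editable target-codon base in
  the position 4–8 window; keep guides whose complete-edit outcome is a
  missense change that is not silent, not a stop, and not
  charge-altering (acidic {D,E} / basic {K,R,H} products are excluded
  because they mimic or flip the site's charge rather than cleanly
  removing the phospho-acceptor); append non-targeting controls.
- **screen simulation** — pooled selection with per-guide survival
  `p = min(1, p0·2^s)` per round (defaults: 500 cells/guide, 3 rounds,
  p0 = 0.20), log-normal initial representation and negative-binomial
  sequencing noise, so planted effects have closed-form expectations
  (s = 2 over 3 rounds ⇒ log2FC = 6).
- **screen analysis** — control-median normalization, per-guide log2
  fold change centred on the non-targeting-control median, empirical
  control-null p-values `p_g = (1+#{ctrl ≥ lfc_g})/(1+n_ctrl)`, twofold
  enrichment calls, and site-level α-RRA aggregation
  `ρ = min_j P(Beta(j, k−j+1) ≤ u_(j))` over guide percentiles
  `u_(j) ≤ α`, with permutation p-values and Benjamini–Hochberg FDR.

## Worked example

```bash
python examples/simulate_and_analyze.py
```

builds a 2000-guide library (200 sites × 10 guides + 100 non-targeting
controls), plants resistance effects (s = 2) at 8 sites, simulates a
three-round screen at 500× coverage and analyzes it. It prints:

```
planted guides: 80 across 8 sites
mean log2FC of planted guides: 5.99 (expected ~6)
twofold-enriched calls: 88, recall of planted guides: 1.00
sites at BH q < 0.1: 8, recall of planted sites: 1.00
```

The planted guides land at the survival model's analytic expectation
(log2FC ≈ 6), the control-centred twofold call recovers all of them,
and α-RRA recovers all 8 planted sites with no false positives at
q < 0.1. `examples/conversion_space.py` and
`examples/design_library.py` demonstrate the editing model and the
library designer the same way.

The same workflow is available from the shell:

```bash
phosbe fixtures --out fx --seed 7
phosbe design --editor CBE --fasta fx/proteome.fasta --sites fx/sites.tsv \
              --out design --n-controls 400 --seed 1
phosbe simulate --library design/library.tsv --out sim --seed 3 --frac-enriched 0.02
phosbe analyze --counts sim/counts.tsv --library design/library.tsv \
               --roles sim/sample_roles.tsv --out results
```

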