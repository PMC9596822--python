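# Methods

## Editing model

A base editor is specified by its chemistry (source → product base on
the protospacer strand: C→T for CBE, A→G for ABE), an activity window
on the protospacer (default positions 4–8, counting position 1 at the
PAM-distal end), a PAM pattern (default NGG) and a protospacer length
(20 nt). Codon-level outcome enumeration applies every nonempty subset
of editable bases *on one strand at a time*: a single deaminase acts on
the displaced strand of one R-loop, so sense- and antisense-strand
conversions never combine within one predicted outcome. A guide on the
antisense strand appears on the coding sequence as the complement
conversion (CBE: G→A; ABE: T→C).

The **complete-edit model** — every editable window base converts —
defines each guide's *primary* outcome. A3A-class and TadA deaminases
edit processively within the window, and committing to the complete
edit makes every designed guide's predicted substitution a single
well-defined allele; partial (subset) outcomes and bystander-codon
changes are enumerated and reported but never filtered on. No
editing-efficiency or sequence-context activity model (e.g. TC
preference) is attempted; a guide is treated as either editing its
window completely or not at all. This is the model's strongest
simplification: real screens produce outcome mixtures.

Exhaustive enumeration over the genetic code gives the substitution
space of the phospho-residues: C→T-class edits reach {F,L,N} from Ser,
{I,M} from Thr and nothing from Tyr (both Tyr codons admit only silent
C-edits); A→G-class edits reach {G,P} from Ser, {A} from Thr and {C,H}
from Tyr. The two-editor union is exactly 10 amino acids. With the
charge filter applied the union loses His and drops to 9.

## Library design

For each annotated site, the site position is mapped to its codon
(validated against the annotated residue; mismatches are reported and
skipped in batch mode) and both strands of the record are scanned for
every protospacer+PAM placement putting at least one editable
target-codon base in the window. Both strands must be scanned: roughly
half of all reachable placements lie on the antisense strand, and
realistic per-site guide yields are unreachable without them.

Kept guides are those whose primary target-codon substitution is
**allowed missense**: not silent, not a stop (a nonsense allele ablates
the protein rather than the phosphosite; retention is available behind
a flag), and not in the charge set. The charge set defaults to acidic
{D,E} (phosphomimetic) and basic {K,R,H}; His is treated as basic by
default and the set is configurable, since His is only partially
protonated at physiological pH.

Conventions: protein residues and CDS bases are 1-based inclusive;
protospacer position 1 is PAM-distal. Placements requiring sequence
beyond the record are skipped unless flanking context is supplied.
Identical protospacers hitting different sites are retained as separate
rows with a duplicate flag. Non-targeting controls are random 20-mers
rejected on any exact match (either orientation) in the supplied
records; published control sets could be substituted. Off-target
screening against a genome is out of scope — guides are designed
against the provided coding records only.

## Synthetic data

`generate_toy_proteome` builds random coding sequences (stop-free
filler codons, ATG start) with planted sites whose designability is
guaranteed *by construction* rather than by re-running the designer:

- designable sites sit in a hand-verified 27-nt cassette containing one
  valid guide (CBE: Ser TCA with its only window C at protospacer
  position 6, TGG PAM, complete edit TCA→TTA Ser→Leu; ABE: Ser AGT with
  its only window A at position 5, complete edit AGT→GGT Ser→Gly);
- undesignable sites are an AGT codon inside 21-nt A/T-only flanks.
  A window-compatible PAM must lie within 19 nt of an editable
  target-codon base, so every reachable PAM position falls inside the
  flanks, which contain no GG (sense PAM) and no CC (antisense PAM) —
  no guide can exist, for either editor.

`simulate_screen` models the pooled selection. Initial cell counts are
a multinomial draw of `coverage × n_guides` cells (default coverage
500) over a log-normal representation (σ = 0.5, emulating the roughly
uniform but not flat guide distribution of a well-made library). Each
of `rounds` (default 3: one treatment plus two repeat rounds) applies
binomial survival with `p_g = min(1, base_survival · 2^{s_g})`
(default base survival 0.20), then multinomial regrowth to constant
population. A guide's per-round abundance advantage over neutral guides
is exactly `2^s`, so planted truths are analytic: s = 2 for 3 rounds ⇒
expected log2FC = 6; the model saturates at survival 1, i.e. for
`s > log2(1/p0)` (≈2.32 at p0 = 0.2). Baseline samples are sequenced
from the pre-selection population and treated samples from the final
one (default 3 replicates each); reads are gamma-Poisson
(negative-binomial) with variance `μ + φμ²` (default φ = 0.05, a
typical count-level overdispersion for pooled screens), falling back to
exact-sum multinomial at φ = 0. All randomness derives from one seed
through named substreams (proteome / effects / screen).

What the simulator does not model: multi-integration cells (MOI is
assumed low), editing-efficiency heterogeneity between guides,
outcome mixtures (a guide's cells are all "edited" in the sense that
their selection coefficient is fixed), resistance mutations, and
PCR-jackpot artifacts beyond NB dispersion. Passing recovery tests
therefore demonstrates the statistics, not robustness to those real
phenomena.

## Screen analysis

Normalization is control-median by default: per-sample size factors are
the median, over non-targeting controls, of each control's count
divided by its geometric mean across samples — robust when a large
fraction of targeting guides shifts under selection. Counts-per-million
is available and is the automatic fallback below 10 controls.

Per-guide log2 fold change uses replicate means on the normalized scale
with pseudocount 1 (configurable), and is centred by subtracting the
control median, making the twofold enrichment call invariant to global
drift. Guide-level significance is an empirical control-null p-value,
`p = (1 + #{controls ≥ lfc})/(1 + n_controls)` (≤ for depletion) — a
deliberate substitution for a parametric negative-binomial test that
keeps the null assumption-free and the toolkit self-contained.

Site-level aggregation is modified robust rank aggregation (α-RRA):
guide p-values are converted to percentiles `u` among all targeting
guides; for a site with `k` guides, `ρ = min_j P(Beta(j, k−j+1) ≤
u_(j))` over the sorted percentiles with `u_(j) ≤ α` (default α = 0.05;
ρ = 1 if none qualify). Significance is by permutation: `n_perm`
(default 1000) random k-draws from the percentile pool, with +1
smoothing so p ∈ (0,1], followed by Benjamini–Hochberg FDR. Both
directions (enrichment and depletion) are always scored.

Two numerical points deserve note:

- **Percentile ties.** The empirical null is discrete (atoms of
  `1/(1+n_controls)`), so with strong selection many guides tie at the
  minimal p. Percentiles therefore break p-ties by the guide's centred
  fold change (stronger first). Tied guides are exchangeable under the
  null, so the tiebreak leaves null percentiles uniform, while under
  the alternative it preserves the rank resolution the aggregation
  needs. Without it, average-rank ties can push every strongly enriched
  guide just past α and erase real signal.
- **Calibration testing.** Within one screen all guides share a single
  realized control set, so their empirical p-values are dependent; they
  are uniform marginally (over control realizations), not conditionally.
  Uniformity is therefore checked by Kolmogorov–Smirnov on a pooled
  sample drawn a few hundred guides per simulated screen across
  independent seeds, where the between-screen independence the KS test
  assumes actually holds. Site-level calibration (fraction of null
  sites at permutation p < 0.05) is checked at full size.
- **α censoring.** The percentile cutoff admits at most a fraction α of
  all targeting guides; if a screen's true-hit fraction exceeds α, the
  surplus cannot contribute to any site score. Recovery tests plant
  effects at ~4% of guides, comparable to the few-percent twofold-hit
  fraction of real resistance screens.

## Testing strategy

Every scanner/enumerator is checked against an independent brute-force
oracle (naive subset mutation over the genetic code; naive scan of all
20-mers on both orientations), BH against a from-the-definition step-up
on 1000 random vectors, and the simulator against its closed-form
expectations. Toy-proteome fixtures are generated programmatically; no
data files ship with the package.

## Known limitations

- The complete-edit model over-calls editing; predicted alleles are
  upper bounds on what a real screen produces.
- Library-scale numbers from real proteomes (library sizes, fraction of
  sites targetable) depend on the annotation and transcript versions
  used and are not reproduced here.
- The empirical control null requires a few hundred controls for useful
  p-value resolution (its floor is `1/(1+n_controls)`).
- Depletion power is bounded by the baseline representation: a guide
  cannot deplete below zero reads, and at default depth the dynamic
  range downward is far smaller than upward.
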