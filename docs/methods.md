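# Methods

## Scope and model

`seedtox` implements the transcriptomic arm of a safety-assessment workflow
for GalNAc-conjugated, chemically modified siRNAs.  The biological premise:
an siRNA's RISC-loaded antisense (guide) strand can repress unintended
transcripts in a miRNA-like fashion, through perfect Watson–Crick pairing of
its seed (antisense nucleotides 2–8, numbered 1-based from the 5′ end) with
sites in 3′UTRs.  If such seed-mediated off-targeting is active in a
dataset, transcripts downregulated after treatment should be enriched for
3′UTR occurrences of the seed-match site — the reverse complement of the
seed — while two negative controls should stay null: the same analysis run
with the *sense*-strand seed, and the same analysis run on *up*regulated
transcripts.

The statistical core is a 2×2 contingency table per (seed, direction)
crossing seed-match presence (≥1 perfect site in the gene's 3′UTR) against
membership in the regulation class, evaluated by the one-sided Fisher's
exact test

  p = P(X ≥ a),  X ~ Hypergeometric(N, K, n)

with N analysed genes, K seed-matched genes, n genes in the class, and a
matched genes in the class.  The one-sided (enrichment) p is the primary
statistic because the claim under test is directional; the
minimum-likelihood two-sided p is reported alongside.  Tail probabilities
are computed through log-space hypergeometric machinery (scipy) and are
stable at transcriptome scale (N ~ 1e5).  Sample odds ratios use the
Haldane 0.5 correction only when a zero cell exists, and are flagged when
they do.  No multiple-testing correction is applied across the four
(seed × direction) cells: each is reported as its own panel.

Two-sided caveat: the minimum-likelihood two-sided p is *not* bounded by
twice the one-sided p (e.g. table (2,25,0,13): one-sided 0.45, two-sided
1.0); it does satisfy pmf(a) ≤ p₂ ≤ P(X ≤ a) + P(X ≥ a).

## Sequence and chemistry model

Duplexes are modelled residue-by-residue: base, sugar chemistry
(ribo / 2′OMe / 2′F / GNA / LNA / 2′deoxy), and 3′-linkage (PO/PS), plus
strand-level 5′-caps (inverted abasic, morpholino, 5′-deoxy) and a 3′-GalNAc
conjugate.  Design decisions:

- **Pairing alignment.** Antisense position *i* pairs sense position
  P − i + 1 over the paired region P = length − overhang; 3′ overhangs
  (default 2 nt) are excluded from the complementarity check.  This is the
  canonical 21-mer/2-nt-overhang siRNA architecture.
- **U/T equivalence.** U and T are interchangeable for complementarity;
  serialization preserves the spelling it was given.
- **Abasic residues** (X) are permitted only at strand termini, never pair,
  and may not fall inside a seed window.
- **RISC-loading competence** is a derived flag: false iff the *antisense*
  5′ end carries a cap (phosphorylation blocked).  A sense-strand cap alone
  leaves competence — and thus predicted off-target activity — intact.
- **Seed swap** moves base identities only (donor antisense window into the
  recipient, sense bases re-complemented); every sugar/linkage/cap/conjugate
  annotation of the recipient is untouched, so swapped variants isolate
  sequence effects from chemistry.
- **GNA placement** rewrites the sugar of one antisense residue (canonically
  position 7, mid-seed).  Thermodynamic consequences (ΔTm) are out of scope;
  the model tracks placement only.
- **Strand notation** is a compact token dialect (`m`/`f`/`d`/`l`/`(gna)`
  sugar prefixes, `*` for PS, bracketed cap/conjugate tokens); round-tripping
  through the parser is the identity on canonical strings.

Positions are 1-based from the 5′ end; caps are annotations, not residues,
and do not shift numbering (if a dataset's convention counts a cap residue,
renumber before import).

## Site scanning

Seed-match sites are searched as exact, possibly overlapping substrings of
the annotated 3′UTR (not CDS or 5′UTR), case-folded, U→T; windows containing
N never match.  Coordinates are 1-based closed intervals on the UTR itself.
Per-gene isoform resolution defaults to the longest UTR (site-sensitivity
maximizing); `first` and `concatenate` rules are available.  Wobble pairing,
mismatch tolerance, context scores, and conservation weighting are
deliberately out of scope — the operation is a perfect-complement scan.

## DE classification

Genes are classified from an upstream differential-expression table
(gene_id, log2FC, pvalue, padj): *down* iff padj ≤ α (default 0.05) and
log2FC < −c, *up* symmetric (default fold-change cutoff c = 0), *excluded*
iff padj is missing (genes dropped by upstream independent filtering were
never tested, and are removed from contingency tables rather than pooled
into "unchanged").  The artifact consumes DE tables; it does not reprocess
reads or re-implement shrinkage estimators.

## Synthetic data generator

The simulator produces a transcriptome with the structure the analysis
assumes, so every stage and the end-to-end claim are testable without
external data.  Reference condition (all values are `SyntheticConfig`
defaults, chosen once):

| parameter | default | rationale |
|---|---|---|
| n_genes | 2000 | enough genes for stable contingency margins, small enough for Monte-Carlo repetition |
| utr_length_range | 200–2000 nt (uniform) | spans short to typical mammalian 3′UTRs |
| base_composition | uniform ACGT | neutral background; chance 7-mer hit rate ~1100/4⁷ ≈ 6% per gene |
| frac_seed_match | 0.15 | planted antisense-site fraction; with chance hits ~20% of genes carry a site |
| n_on_target | 1 | one full-complement transcript |
| ontarget_lfc | −2.5 | strong knockdown (~5.7-fold) |
| offtarget_lfc | truncated Normal(−0.6, 0.2) on [−1, 0] | mild repression; the cap encodes the observation that seed-mediated changes stay within twofold |
| reps_per_group | 3 | treated vs control triplicates |
| mean_log_expression | 6 (natural log) | lognormal baseline, ~400 counts median |
| dispersion (NB size) | 1000 | overdispersion 0.001: technical-replicate, near-Poisson counts |
| background_frac / background_lfc_sd | 0 / 0.8 | seed-independent regulation, off by default |

Truth is recomputed by scanning the generated UTRs, never assumed: chance
sites count as real matches, and a "planted" site overwritten by a later
plant would be caught.  Sense-strand sites are planted into a disjoint,
equal-size gene fraction and carry zero expression effect, making the
sense control null by construction.  All randomness derives from one
`rng_seed` through `SeedSequence` substreams (duplex, UTRs, effects,
counts), so identical configs give byte-identical outputs stage by stage.

The **null calibration condition** (`null_config`) sets the off-target
effect to zero and instead regulates a random 10% of genes (Normal(0, 0.8)
log2FC, both directions) independently of seed matches.  This is a design
requirement, not a convenience: under a *global* null the BH-adjusted
downregulated class is empty in almost every run and the Fisher p is
trivially 1, so the test's operating characteristics would never be
exercised.  With background regulation the independence null holds while
the margins are non-degenerate.  Even so, exact tests are conservative
under discreteness: with a median of ~36 down genes the realized type-I
error sits at or slightly below the nominal 5% (typically 0.02–0.04 across
master seeds).

The **DE caller stand-in** is a Welch t-test on log2(normalized count +
0.5) with Benjamini–Hochberg adjustment, with median-of-ratios size factors
(geometric-mean-normalized; under equal library composition they reduce to
total-count scaling).  Median-of-ratios matters here: with ~20% of genes
repressed, total-count normalization deflates every fold change by the
library-size shift (~+0.1 log2 bias), which the ratio-median absorbs.  This
caller is documented as NOT a negative-binomial Wald framework: no
dispersion shrinkage, no independent filtering, no cooks-distance
filtering.  Degenerate rules: zero variance in both groups ⇒ p = 1;
all-zero genes ⇒ padj missing (excluded downstream).

### What the simulator does and does not emulate

It reproduces: seed-match-linked mild downregulation with a hard twofold
ceiling, a strong on-target knockdown, strand- and direction-specific
asymmetry of the enrichment signal, and NB counting noise.  It does not
emulate: 3′-supplementary pairing contributions, CDS/5′UTR sites, GC- or
length-biased UTR composition, expression-dependent dispersion trends,
library-size variation, or correlated replicates.  Passing tests therefore
demonstrate internal correctness and statistical calibration of the
pipeline under its stated assumptions — not performance on any particular
real dataset.

## REVERSIR screen

A REVERSIR-like antidote oligo (6–30 nt) is screened for *full*
complementarity against a caller-supplied miRNA list: a hit is a contiguous
miRNA window equal to the reverse complement of the entire oligo.  "Full"
is taken strictly — G·U wobble pairs do not count — with a wobble-tolerant
mode available (`wobble=True`) for sensitivity analyses.  Tissue filtering
(e.g. "liver-expressed") is the caller's responsibility.

## Numerical choices

- Log-space hypergeometric tails; p-values clamped to (0, 1].
- Two-sided tie handling: tables whose point probability is within relative
  1e-11 of the observed one count as ties (well above pmf rounding error,
  well below genuine probability gaps at the scales tested; verified
  exactly against integer enumeration for all tables with total ≤ 60).
- Pseudocount 0.5 on normalized counts in fold changes and log transforms.
- padj = 0 is clamped to the smallest positive double before −log10 in
  volcano exports.
- Monte-Carlo problem sizes: 1000 null runs and 200 effect runs at 2000
  genes for calibration/power summaries; 5 runs for effect-size recovery;
  10⁴ random duplexes for chemistry invariants.

## Known limitations

- Only the perfect 7-mer (positions 2–8) site class is scored; 7mer-A1 and
  8mer classes, site context, and dose–response in site counts are not.
- The DE stand-in's t-test loses power below ~3 replicates and does not
  model count-level variance at low expression; conclusions about real
  datasets should rest on a dedicated DE tool's output consumed through
  `read_de_table`.
- Concrete duplex sequences shipped in examples/tests are synthetic; no
  proprietary siRNA sequences are included.
- The enrichment background is "all analysed genes with a UTR record";
  restricting to expression thresholds is left to the caller (filter the DE
  table before classification).
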