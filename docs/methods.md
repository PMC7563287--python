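# Methods

## Problem and model

`lncsift` separates long non-coding RNAs (lncRNAs, transcripts > 200 nt
with low protein-coding potential) from mRNAs using only the transcript
sequence — no genome, annotation, or alignment. The classifier combines
three ingredients:

1. **Sequence-intrinsic scalar features.** Length; GC content; the
   population standard deviation (divisor 3) of non-overlapping
   stop-codon counts across the three forward frames; longest-ORF
   structure (integrity, CDS length / percentage and a bespoke CDS
   score); predicted-peptide length and theoretical isoelectric point;
   the Fickett TESTCODE statistic; and an in-frame hexamer
   log-likelihood score.
2. **A tri-nucleotide screen.** Per-transcript overlapping 3-mer
   proportions are compared between classes with the two-sample Z
   statistic Z = (X̄₁−X̄₂)/√(S₁²/n₁+S₂²/n₂) (sample SDs, divisor n−1),
   two-sided normal p-values, and Benjamini–Hochberg FDR adjustment;
   3-mers significant at 1% FDR in every species set are ranked by
   summed |Z|. Published animal (15) and plant (24) subsets ship as
   presets.
3. **Feature selection + balanced random forest.** Features are ranked
   by |Pearson r| against the class label; of any pair with |r| > 0.8
   the weaker-vs-label member is dropped (the stop-codon SD is pinned:
   it measures frame deviation that exists whether or not an ORF is
   translated). Incremental feature selection (IFS) cross-validates each
   classifier on the top-k prefix, k = 1..p, with min-max scaling fit
   inside each training fold (the leakage-free reading). The final model
   is a balanced random forest: each tree trains on a bootstrap that
   draws min(n_pos, n_neg) samples with replacement from each class
   (per-tree down-sampling of the majority class), with √p feature
   subsampling at the splits. The prediction score is the fraction of
   trees voting lncRNA, thresholded at 0.5 by default.

## Numerical and procedural choices

* **Alphabet.** U is folded to T at parse time; everything downstream is
  DNA. N is tolerated: excluded from GC and Fickett counts, 3-mer/6-mer
  windows containing N are skipped, and N-containing codons never match
  ATG or a stop.
* **ORF finder.** Three forward frames only (inputs are sense-strand
  transcripts). Priority: longest complete ATG..stop ORF (stop codon
  included in the length); else the longest ATG-initiated stop-free
  stretch; else the longest stop-free codon run. Ties break to the
  smaller start, then the smaller frame. Coordinates are 0-based
  half-open. Verified against brute-force enumeration on short random
  sequences.
* **CDS score.** The external CDS-scoring program used by comparable
  tools is opaque; we define cds_score = CDS length + 100·integrity +
  25·Kozak bonus (A/G at −3 and G at +4 around the ATG). It is monotone
  in ORF length and rewards completeness — the two properties that give
  the score its discriminative role.
* **Hexamer model.** Coding training sequences contribute step-3 6-mers
  along the longest predicted ORF *excluding the stop codon* (a hexamer
  is a pair of sense codons; the stop encodes nothing); non-coding
  sequences contribute frame-0 6-mers of the whole sequence, which is
  also the scoring fallback for ORF-less queries. Add-one pseudocount
  before normalization keeps all 4096 log ratios finite; logs are
  natural.
* **Fickett score.** Position parameters MAX(Nᵢ)/(MIN(Nᵢ)+1) and content
  proportions are converted to probabilities via the original Fickett
  (1982) lookup tables (constants in `_fickett.py` with citation) and
  combined with the published weights.
* **Isoelectric point.** Henderson–Hasselbalch charge sum over a fixed
  Bjellqvist-style pKa set (N-term 7.5, C-term 3.55; D 4.05, E 4.45,
  C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0), solved by bisection on pH
  ∈ [0, 14] to |charge| < 1e-4 or bracket < 1e-3. The empty peptide
  returns 7.0 by convention.
* **FDR.** The raw p·m/rank adjustment alone is non-monotone; the
  standard step-up cumulative minimum (from the largest rank) plus a cap
  at 1 is applied, with stable ordinal ranks for ties. Cross-checked
  against statsmodels.
* **Degenerate statistics.** Zero-variance 3-mers with equal means give
  Z = 0, p = 1; with unequal means they are flagged degenerate with
  p = 0 rather than producing NaN.
* **Scaling.** Min-max to [0,1] with clipping at application time;
  constant features map to 0.5 with a warning.
* **Determinism.** Every stochastic stage (generators, bootstraps, CV
  folds, tree seeds) derives from a single user seed; (data, seed) fixes
  predictions bit-for-bit, and a saved bundle reloads to identical
  predictions. Bundles embed a format version and refuse newer formats.

## Synthetic data: what it emulates, what it does not

The generator produces the two contrasts the classifier exploits.
mRNA-like transcripts are a 5′UTR + ATG + codons drawn from a biased
codon-usage table (human usage frequencies by default) + stop + 3′UTR,
with the ORF occupying at least 60% of the length (utr_fraction 0.4).
lncRNA-like transcripts are length/GC-matched chains of 3-mers sampled
from a product-of-base-frequencies distribution, optionally multiplied
by per-3-mer bias factors (so selection tests can control exactly which
3-mers differ); any complete ORF longer than 300 nt has its start codon
knocked out — sub-100-codon ORFs are left alone, since real lncRNAs
carry small ORFs. Defaults: 1000 transcripts per class for training
(500 per class held out), lengths uniform on 200–3000 nt, GC 0.5.

Not emulated: splice structure, expression levels, conservation,
sequencing error, and the long-tailed length distributions of real
catalogues. Passing tests therefore demonstrate that the machinery is
correct and that the method recovers planted signal — not that the
shipped presets are optimal for any particular genome; for real use the
screen and IFS should be retrained per species, which is what the CLI
does.

## Study sizes and open design choices

The end-to-end study uses 1000+1000 training and 500+500 held-out
transcripts; the screen characterisation uses 20 replicates of 500
transcripts per group; the imbalance experiment fixes 500 negatives,
scales positives by the ratio, and averages 10 seeds. These sizes give
stable statistics while keeping a full run in tens of seconds on one
core.

Choices made where the design was genuinely open:

* **Cross-species consensus.** Intersection of 1%-FDR significance
  across species, ranked by summed |Z|. Other merge rules are defensible;
  the shipped presets bypass the question for default use.
* **IFS inside the convenience pipeline** sweeps logistic regression
  only and caps the screened 3-mers at the top 15 by summed |Z|; the
  full five-classifier sweep (LR, SVM, DT, RF, KNN, library-default
  hyperparameters) is available through `featsel.run_ifs` and the `ifs`
  subcommand. The pipeline takes argmax-F with ties to smaller k and
  the priority RF > LR > SVM > KNN > DT; a fixed k can be forced by
  selecting columns before training.
* **Imbalance experiment features.** Defaults to the 64 tri-nucleotide
  frequencies alone. With the ORF/CDS features the synthetic classes are
  perfectly separable and every ratio reaches F = 1, so the balanced-vs-
  unbalanced comparison would be vacuous; the 3-mer-only problem has
  irreducible overlap, the regime where balancing matters.
* **3-mer counting** is overlapping (step 1). Frame-wise (step 3)
  counting is equally plausible from first principles; overlapping was
  chosen and is the convention throughout.

## Known limitations

* The CDS score is a package-defined statistic; its absolute values are
  not comparable to external CDS scorers, only its ordering is meant to
  be informative.
* The isoelectric-point solver uses one fixed pKa set; tools using
  residue-specific terminal pKa refinements will differ by a few
  hundredths of a pH unit.
* The hexamer table is trained on the same transcripts used for feature
  extraction in the pipeline, a mild optimism that mirrors common
  practice; use a held-out table for unbiased hexamer effect sizes.
* Sequences shorter than 200 nt are accepted (with a warning) but are
  outside the lncRNA definition and the generator's support.
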