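# Methods

This note documents the models and procedures implemented in `xenoscan`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Degenerate-pattern scanning and two-pass refinement

A pattern is a string over the IUPAC ambiguity alphabet with a mismatch
budget that applies to its *fixed* (non-`N`) positions only. Matching is
conservative about ambiguity in the subject sequence: `N` in the pattern
matches any base at zero cost, while `N` in the genome fails every fixed
position (a draft-genome gap is never evidence for a binding site). Both
strands are scanned by default — H-NS binding is not strand-specific — and
minus-strand hits are reported with pattern-oriented matched sequences at
genome-forward coordinates. Overlapping hits are all reported; downstream
operon attribution is interval-based and insensitive to overlap.

The two-pass procedure mirrors how genome-specific H-NS site models are
built from a heterologous seed:

1. scan with the seed site (default `TCGATAAATT`, the high-affinity
   *E. coli*-type site; a required, user-visible parameter rather than a
   hard-wired constant) at ≤ 2 mismatches;
2. stack the hits into a position frequency matrix (hits containing `N` are
   excluded from the counts and tallied separately);
3. collapse each column to its majority base if that base reaches the
   consensus threshold (default 0.65), else `N` — only plain bases and `N`
   are emitted, reproducing the fixed-flanks-plus-degenerate-core shape of
   refined H-NS patterns without inventing two-fold ambiguity codes;
4. rescan at 0 mismatches with the refined pattern. The degeneracy is
   already encoded in the `N` positions; allowing a further budget on top
   would double-count it.

The scanner is vectorised (per-position lookup tables over the encoded
sequence) but its contract is defined by the exhaustive window-by-window
oracle the tests implement independently; the two are checked set-equal on
random sequences at budgets 0–2.

**Consensus refinement and background hits.** First-pass hits include
chance near-miss windows whose expected number grows linearly with genome
length (about 2·L·4.2×10⁻⁴ windows at ≤ 2 mismatches over a 10-fixed-base
pattern on 60% GC background). The refinement demonstration therefore
plants its 10+10 two-variant occurrences in a 10 kb background, where the
planted sites dominate the PFM and the split columns sit well below the
0.65 threshold; at 40 kb the background contribution is comparable to the
planted signal and the constructed case no longer isolates the refinement
step. On real genomes the first pass yields hundreds to thousands of sites
and the consensus is driven by genuine binding-site abundance, not by a
planted minority.

## GC tiling and low-GC intervals

Windows are consecutive, non-overlapping tiles (default 1 kb) phased at
position 0; a `step` parameter enables sliding windows for sensitivity
analysis. Flagging uses strict inequality (GC < 55.0%). The trailing
partial tile is kept iff it is at least half the width, with GC computed
over its actual length — contig ends are not discarded, but sub-500 bp
remainders are too noisy to call. `N` bases are excluded from GC numerator
and denominator everywhere (all-`N` windows are skipped); on `N`-free
sequences the width-weighted mean of per-window GC recombines exactly to
the whole-sequence value. Runs of flagged windows merge into half-open
intervals.

## Operon inference and the regulon union rule

No transcription-unit evidence is assumed: operons are runs of
co-directional genes with intergenic gaps ≤ 100 bp (overlapping same-strand
genes merge regardless), a standard prokaryotic heuristic. Both the gap and
the 250 bp upstream promoter window are exposed parameters echoed into
every output header, because the affected-gene fraction is sensitive to
them.

An operon is *affected* if (a) any site start lies within its span or
within the upstream window 5′ of its first gene — left of the span for a
plus-strand operon, right of it for a minus-strand one — or (b) its span
overlaps a low-GC interval by ≥ 1 bp (the weakest reading of
"associated with"; strict containment is available via the interval
inputs). The affected-gene fraction counts member genes of affected
operons, not operons, matching how genome-wide repression percentages are
quoted.

## Tetranucleotide binning

Each 2 kb window of each contig (contigs < 2 kb are skipped with a warning)
is summarised as frequencies of its 1,997 overlapping 4-mers; 4-mers
containing `N` are dropped from numerator and denominator. All 256
tetramers are kept as separate features by default — strand-collapsed
canonical counting (136 features) is available but changes cluster
geometry. Clustering is Lloyd's k-means with k-means++ seeding, Euclidean
distance on raw frequencies (no standardisation by default), a 20-iteration
cap, and full determinism under the seed; `k` defaults to 3 but is a user
decision — no automatic model selection is attempted. Contigs take the
majority cluster of their windows, ties breaking to the lowest cluster
index, with vote fractions reported. The implementation delegates to
scikit-learn's `KMeans` restricted to exactly this configuration.

## SNP windows and Nei–Gojobori dN/dS

SNP frequency is computed per non-overlapping 250-column window in
alignment coordinates: percent mismatching bases among *comparable*
columns, where a column is comparable iff both sequences carry an
unambiguous base and it lies outside every mask interval (masks exist for
non-homologous replacement regions that would otherwise dominate the
track). Indels are not SNPs: gap columns count toward neither numerator
nor denominator. Windows with < 50 comparable columns are reported missing
rather than as unstable percentages. A `step` smaller than the window
width turns the tiled track into a true sliding one.

dN/dS uses the Nei–Gojobori (1986) counting method — chosen because it is
fully specifiable from first principles and is the default counting method
of the MEGA family of tools — with Jukes–Cantor correction:

* per-codon synonymous site fraction: at each codon position, the fraction
  of the three possible point changes that preserve the amino acid;
  nonsense (stop-creating) changes are excluded from the fraction's
  denominator, so each position still contributes exactly one site and
  S + N = 3 × codons compared;
* sites are averaged between the two sequences;
* differences at multi-hit codons are averaged over all minimal mutational
  pathways that avoid stop codons; if every pathway is blocked the average
  falls back to all pathways. Codon pairs containing `N` or a gap are
  skipped; a premature (non-terminal) stop codon is an error naming the
  codon index, a shared terminal stop is silently skipped;
* p = d on request (`correction="none"`), else d = −(3/4)·ln(1 − 4p/3),
  undefined (`nan`) at p ≥ 3/4 with the raw proportion retained; the ratio
  is `nan` when dS = 0.

**Calibration note.** Under neutral simulation (substitutions placed
uniformly at 2% divergence on 500-codon ORFs) the *per-replicate* ratio
dN/dS has a heavy right tail: with only ~7 synonymous differences expected
per replicate, E[1/dS] exceeds 1/E[dS] by roughly 15%, so the mean of
per-replicate ratios centres near 1.15 even though the median is ~1.0 and
the estimator is well behaved. The calibration statistic reported by the
tests and the acceptance script is therefore the pooled ratio
mean(dN)/mean(dS), which concentrates tightly on 1. Users comparing many
short ORFs should prefer pooled or median summaries over means of ratios
for the same reason.

## Synthetic data

The generator draws background bases i.i.d. at the target GC (60% default,
matching a high-GC betaproteobacterial host), redraws island segments at
their own GC, sanitises gene regions into clean ORFs (in-frame stops
resampled), and finally overwrites planted site sequences verbatim
(minus-strand sites as their reverse complement); planted sites may not
overlap one another. Genes are laid out as operons with short intra-operon
and long inter-operon gaps so the operon-inference truth is exact.
Genotype pairs carry *exact* per-class substitution counts: each
synonymous/nonsynonymous substitution is placed at a codon position
verified against the genetic code (never creating a stop, at most one
substitution per codon so labels stay exact), and intergenic substitutions
fall outside all ORFs. Contig sets draw k groups at distinct GC values
(35/55/70% default — the spread needed for unambiguous compositional
separation at 6 kb contigs).

Because the base model is i.i.d., tetranucleotide separation between
groups comes from GC content alone, and no fixture reproduces dinucleotide
bias, codon usage, repeats or mobile elements. Passing tests therefore
demonstrate the *bookkeeping* of every stage (coordinates, counts,
thresholds, determinism, oracle equivalence) and recovery under honest
noise at realistic sizes — not performance on real genomes, where motif
abundance, compositional heterogeneity and operon structure are all less
clean. Truth tables are verifiable by independent checkers: planted sites
by direct string comparison, substitution labels by re-translation.

## Problem sizes and determinism

Test and acceptance fixtures use 10–50 kb genomes, 15 × 6 kb contigs,
300–500-codon ORFs and 50–200 Monte-Carlo replicates — sizes at which every
quantity is measurable in seconds while leaving the statistical margins
(binomial GC bounds, cluster separation, calibration bands) comfortably
wide. All randomness flows from explicit seeds: generators are documented
to be byte-identical under the same seed and to change under any other.

## Known limitations

* No PWM/log-odds scoring or background-model correction in the scanner;
  the pattern-plus-mismatch model is the method being provided, not an
  approximation to an energy model.
* Operon inference is purely positional; it will merge convergent gene
  pairs that a transcription-aware method would split, and the affected
  fraction inherits that.
* Nei–Gojobori weights all pathways equally (no transition/transversion
  bias) and the Jukes–Cantor correction assumes equal base frequencies;
  ORFs at high divergence or extreme composition warrant a codon-model
  method instead.
* k-means requires the user's k and assumes roughly isotropic clusters in
  tetramer space; it is a validation aid, not a general-purpose binner.
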