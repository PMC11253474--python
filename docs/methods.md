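# Methods

This note documents the models, conventions and numerical choices behind
`bulkmap`, and what the synthetic-data generator does and does not
emulate.

## Experimental designs and allele orientation

The toolkit analyzes pooled-sequencing designs in which each VCF sample
column plays a declared role. MBS designs use R (required: the bulk of
phenotypically recessive segregants), D (an optional dominant-phenotype
bulk), Pr/Pd (resequenced recessive/dominant parents) and Wr/Wd
(non-mutagenized wild-type lines). QTL-seq designs use the two extreme
bulks H and L (both required) and optionally one resequenced parent P.
Samples are matched to roles positionally: the i-th `-d` label applies to
the i-th sample column; the toolkit has no access to how the VCF was
generated, so the caller is responsible for that correspondence.

Every statistic is computed on biallelic counts whose alleles are, where
possible, assigned to parental haplotypes:

1. **Resequenced parents.** A parent is called homozygous for an allele
   when that allele holds at least 90% of the parent's reads and the
   parent has at least 4 reads (both thresholds are exposed as
   `--parent-homo-frac` / `--min-parent-depth`; the defaults are a
   pragmatic compromise between tolerating sequencing error and not
   mis-calling heterozygous parents at low depth). With both parents
   present, only sites where the parents are homozygous for *different*
   alleles survive — inter-parent polymorphisms are the informative
   markers of an outcross design.
2. **Reference-genome identity** (`-r D|R`, or `-r P` for QTL-seq): when
   the reference genome is one parent, the REF allele is assigned to that
   parent.
3. **Neither**: the site is emitted unoriented. The SNP-index then reports
   the most abundant allele (≥ 0.5 by construction) and Δ(SNP-index) its
   absolute value; both remain useful for peak-finding even though the
   sign of the deviation is lost.

W samples never participate in orientation; with `--parental-filter` any
site whose ALT allele has ≥ 1 read in a W sample is discarded (one read is
the most conservative discard rule; `--w-min-depth` relaxes it for noisy
W libraries).

The EMS filter (`--EMS`) keeps substitutions with (REF, ALT) ∈
{G→A, C→T}. An EMS lesion alkylates guanine, so the same event reads out
as G→A on one strand and C→T on the other; accepting both pairs covers
both strand orientations of the reference.

Multiallelic records are parsed but rejected before statistics
(`non-biallelic`): every downstream quantity is defined on a 2×2 table.
Sites with zero depth in a required bulk are skipped and counted rather
than emitted as missing values, keeping downstream consumers free of NA
handling in count columns.

## Marker statistics

With oriented counts (a, b) per bulk, d = a + b:

- SNP-index = a/d; Δ = idx(D) − idx(R) (or H − L).
- Fisher's exact test, two-tailed: p sums the hypergeometric probabilities
  of all tables sharing the observed margins whose point probability is ≤
  that of the observed table; ties are included with a relative slack of
  1e-12 to make the comparison robust to floating-point rounding. The
  implementation evaluates the whole hypergeometric support in log space
  (gammaln) and normalizes the support to sum exactly to one, which keeps
  the result within ~1e-14 of exact rational arithmetic. A zero margin
  returns p = 1.
- G statistic: 2 Σ n ln(n/ê) with 0·ln 0 := 0 and ê from margin products.
  Expected counts are computed as (row·col)/total in that order, so
  proportional integer tables yield G = 0.0 *exactly*, not merely to
  rounding.
- ED_m: Euclidean distance between the two bulks' allele-frequency
  vectors; for a biallelic site this is algebraically √2·|Δ|. The adopted
  formula is the standard BSA-seq Euclidean distance; windowed ED100⁴
  (fourth power of the sum over 100 consecutive markers, sliding one
  marker at a time) is computed only for chromosomes with at least 100
  markers and is deliberately deferred to plot time, as are all
  quantities that need the complete marker set.
- Confidence bands for Δ: per-marker normal-approximation bounds for a
  difference of two proportions, Δ ± z_{1−α/(2n)}·√(p₁q₁/d₁ + p₂q₂/d₂)
  with Bonferroni-adjusted level (n = number of markers plotted); the
  plotted band is the depth-weighted moving average of the per-marker
  limits. Significance thresholds on p-value panels are −log10(α/n).

Moving averages are depth-weighted by default (weight = total reads of
the marker across its count columns), since deep markers estimate allele
frequency with less variance; uniform weighting is available. Windows are
centered, truncated at chromosome ends, and never span chromosomes.
Physical-length windows are non-overlapping, anchored at position 1, and
emit nothing for empty intervals.

The boost transform is a reciprocal-distance-to-fixation curve,
min(1/(1−af), cap) with cap 100: monotone in af, equal to 1 at af = 0 and
finite at fixation. Only its monotonicity and boundedness are relied
upon; it is a visualization aid, not a test statistic.

## Binning

`merge -w n` forms overlapping bins of n consecutive markers (stride 1);
`merge --window-bp L` forms non-overlapping L-bp bins containing at least
one marker. Windows with fewer than n markers at chromosome ends are
dropped rather than truncated, so every count-mode bin aggregates exactly
n markers and bin-level statistics are comparable along the genome. The
representative position of a bin is the midpoint of its first and last
member positions. Member counts are summed per bulk and every statistic
is recomputed on the summed table; a single-marker bin therefore
reproduces the marker's statistics exactly. Binning refuses unoriented
input: summing counts across markers is only meaningful when "allele A"
denotes the same haplotype at every member marker.

## Annotation

Gene models (gene → mRNA → exon/CDS/UTR) are read from GFF3 via gffutils;
missing UTR features are tolerated (the corresponding regions simply
classify as exonic/noncoding). Genes per chromosome are sorted by start
with a prefix-maximum-end array, so point queries are a binary search plus
a bounded leftward scan, and all overlapping genes are reported. A
transcript whose CDS length (after phase adjustment) is not a multiple of
3 is flagged non-canonical and reported, never silently dropped.

Substitutions in a CDS are translated on the coding strand with the
standard genetic code: synonymous, missense, nonsense (stop gained) or
nonstop (stop lost). Intronic variants report the distance to the nearest
exon boundary per isoform and are labelled `splice-site` within 10 nt of
a donor/acceptor (`--splice-window`; the canonical 2-nt sites always fall
inside any sensible window). 5'-UTR substitutions are scanned for
upstream-ATG creation in the three transcript-strand trinucleotides
covering the substituted base, with the distance to the translation
start. Indels overlapping a CDS are frameshifts unless the length change
is a multiple of 3; deletions extending beyond a gene boundary are
partial gene disruptions, and deletions covering a whole gene complete
disruptions, reported once per affected gene. Coordinates are 1-based
inclusive throughout; indels use VCF anchoring (first base shared). The
REF allele is checked against the genome FASTA and a mismatch is a hard
error — it means the VCF and FASTA are from different builds, and every
downstream codon would be wrong.

The classifier does not attempt large structural variants, re-annotation
of gene models, or effect calls inside non-coding genes (these report the
gene and biotype with a `noncoding` label).

## Synthetic data

The MBS simulator draws each gamete as a haplotype mosaic along the
chromosome: crossovers between adjacent loci occur independently with the
Haldane step probability at 4 cM/Mb (configurable), which makes the
haplotype a Markov chain and lets the recessive bulk be simulated exactly
by conditioning every gamete on the causal allele. Expected
recessive-allele frequencies are 1 − r in the recessive bulk and
(1 + r)/3 in the dominant bulk, with r the Haldane recombination fraction
to the causal locus. Read counts are binomial in the pooled genotype
frequency at Poisson-distributed depth; an optional symmetric per-read
error rate can blur fixation. Defaults (5 × 20-Mb chromosomes, 1000
markers each, 30 individuals per bulk, mean depth 50) represent a
well-powered but ordinary F2 experiment.

What the simulator does *not* emulate: mapping bias toward the reference
allele, depth heterogeneity along the genome, crossover interference,
duplicate reads, or variant-caller artifacts. Pipeline tests on this
generator therefore demonstrate statistical correctness of the method
under its own model, not robustness to alignment pathologies — those are
the province of the upstream caller and of the explicit filters.

The toy-genome generator builds compact two-exon genes (5'-UTR, split
CDS with intron and correct phases, 3'-UTR) from fixed sequence templates
whose codons make every planted effect unambiguous, plants at least one
variant of every effect label, and mirrors the whole chromosome as its
reverse complement with minus-strand gene models. The mirror provides a
metamorphic check: a correct classifier must label a mirrored variant
identically, with the same amino-acid change.

## Verification problem sizes

The acceptance checks use: exhaustive Fisher comparison over all 46,376
tables with total ≤ 30 against an exact Fraction-arithmetic oracle; exact
G = 0 on the 1,175 proportional tables with margins ≤ 20; the √2 identity
on 10,000 random sites; CI coverage on 2,000 binomial replicates at depth
500; binning conservation on 100 random fixtures and power on 200
low-depth replicates; annotation truth on 66 planted variants plus 1,000
locate queries against a linear scan; and causal-locus recovery (peak
within 2 Mb) over 100 simulated experiments at the default design. These
sizes give stable pass/fail behaviour at interactive runtimes.

## Known limitations

- Orientation treats parents as homozygous lines; heterozygous parents
  (e.g. F1-derived pools) reduce to the unoriented path.
- The confidence band uses the Wald interval, which undercovers slightly
  at extreme allele frequencies or very low depth; bands are a visual
  guide, the Fisher test is the inferential tool.
- BCF and compressed VCF are not parsed; convert upstream
  (e.g. `bcftools view`).
- The qtl command exposes no EMS/indel filters; those criteria are
  specific to mutagenesis screens and live in mbs.
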