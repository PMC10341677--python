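# Methods

## The mapping model

The pipeline assumes an F2 intercross between two fully homozygous inbred
lines segregating a single, fully penetrant recessive locus: phenotype
classes segregate 3:1 (dominant:recessive) and genotypes 1:2:1. One
parent (P1) is sequenced; the other (P2, the line in which the trait
arose) is not, and its alleles are inferred by contrast. All genotype
codes are therefore *relative to P1*: 0 = P1-homozygous, 1 =
heterozygous, 2 = P2-homozygous, −1 = missing.

### Meiosis and the genetic map

Gametes are simulated and modelled under the Haldane map function:
crossover counts are Poisson with mean equal to the chromosome's genetic
length in Morgans, breakpoints are uniform on the genetic map, and there
is no interference, so the recombination fraction at map distance *d* cM
is r = (1 − e^(−2d/100))/2. Physical positions are converted to map
positions at a constant rate (`cm_per_mb`, default 4.0 cM/Mb, the
genome-wide average for rice). With marker spacing well below the scale
of one crossover per chromosome, the scan is insensitive both to
interference and to local deviations from a constant rate, which is why
a more elaborate map is not constructed.

### Genotype probabilities

A three-state HMM per individual per chromosome converts observed codes
into posteriors over {AA, AB, BB}: initial distribution (¼, ½, ¼); F2
transition matrix between adjacent markers at recombination fraction r

    AA → ((1−r)², 2r(1−r), r²)
    AB → (r(1−r), (1−r)²+r², r(1−r))
    BB → symmetric to AA;

emission P(observed = hidden) = 1 − ε and ε/2 for each wrong code, with
ε the genotyping-error probability (default 1e-4, configurable); missing
observations are uninformative. Forward–backward passes rescale at every
step, so posteriors are exact to float precision (each triple sums to 1
within 1e-9; verified against exhaustive path enumeration on small
instances).

### Haley–Knott scan, thresholds, interval

At each marker the phenotype is regressed on an intercept plus P(AB) and
P(BB) (2-df QTL model) and LOD = (n/2)·log₁₀(RSS₀/RSS₁) with RSS₀ from
the intercept-only fit. The regression is computed through per-marker
orthonormal bases of the design (batched SVD with rank truncation), which
makes a whole permutation matrix a single tensor contraction and keeps
rank-deficient designs (e.g. a monomorphic marker) exact rather than
overfit. A zero-variance phenotype yields an all-zero profile and a
warning. LOD is clipped at 0; the model nests the null so negative values
can only arise from rounding.

Genome-wide thresholds are empirical (1−α) quantiles (linear
interpolation, as in R's default quantile) of the max-LOD distribution
over phenotype permutations; permuting labels only is the standard
single-phenotype scheme. Ties at the maximum break leftmost (chromosome,
then bp). The support interval walks outward from the peak while LOD
stays within `drop` (default 1.8, the F2 convention) of the maximum,
stops at the first marker below the cutoff, and then extends one flanking
marker per side — the usual interval-mapping convention, so the interval
brackets rather than clips the supported region. The scan evaluates
marker positions only, no pseudomarker grid: at the marker densities this
design produces, resolution is marker-limited anyway.

## Variant filtering and phasing

Four rules run in a fixed order and are reported separately: (1) keep
bi-allelic sites with QUAL ≥ 50 (inclusive); (2) mask single genotypes
with depth outside [10, 90] (both ends inclusive) rather than dropping
the site, so the missingness rule can then judge the site as a whole —
the two rules are only jointly coherent under this reading; (3) remove
every site within 150 bp (symmetric, inclusive) of a site where the
inbred parent is called heterozygous, including the seed site itself —
heterozygosity in a fully inbred line is diagnostic of mis-mapping;
(4) remove sites with strictly more than half of the sample columns
missing. Rules 1 and 4 commute on clean data (asserted in tests); the
fixed order exists so the per-rule counts are well defined.

Phasing drops sites where the parent call is missing or heterozygous
(they cannot be recoded), then excludes sites with minor allele frequency
below 5% computed over non-missing F2 allele calls (two per homozygote,
one each per het). The MAF screen's purpose is structural: differences
between both parents and the reference segregate at MAF ≈ 0 in the cross
and carry no linkage information. The threshold is read as a frequency
(0.05), the conventional meaning of MAF, matching the screen's purpose.

## Effect classification

A deliberately small consequence predictor covering loss-of-function
screening: splice windows are the two intronic bases at each intron end
(the SnpEff/Ensembl convention), strand-aware; coding SNVs are classified
by ref/alt codon translation (synonymous, missense, stop gained/lost,
start lost); indels are frameshift when the number of *coding* bases
added or removed is not a multiple of 3 (for deletions straddling a
UTR/CDS boundary only the CDS bases count), in-frame otherwise. Splice
consequences outrank coding ones (rarer, more specific); frameshift
outranks stop-gain for indels since downstream disruption is already
implied; per gene, the worst-impact transcript consequence is reported.
Impact tiers are a pure function of consequence (HIGH = frameshift, stop
gained/lost, start lost, splice donor/acceptor; MODERATE = missense,
in-frame indels; LOW = synonymous; MODIFIER = the rest). Insertions are
attributed to a feature only when the insertion point falls strictly
inside it; an insertion exactly at a feature junction is classified by
the enclosing gene region. Content of in-frame insertions is not
inspected for introduced stops, and cryptic splice-site usage is not
predicted — establishing the transcript-level consequence of a splice
variant is wet-lab territory. A REF/genome mismatch is a hard error by
design: it signals a coordinate-convention bug, not data to tolerate.

## Co-segregation and parental ruling-out

For a fully penetrant recessive trait, a causal variant must satisfy:
every recessive-class individual is P2-homozygous and no dominant-class
individual is. Missing genotypes neither satisfy nor violate the rule,
but a variant is eligible only when ≥ 80% of each phenotype class is
called there (configurable; strictness on missing data is a judgment
call, so it is a parameter with the default stated here). Among
co-segregating HIGH-impact variants, the disrupting (ALT) allele is
assigned to P1 if the sequenced parent is ALT-homozygous, else to P2.
Which parent the phenotype arose in is prior knowledge, passed as
`direction_of_change`: genes damaged only from the other parent are
ruled out (they would imply the wrong direction of effect), genes damaged
from both parents are ruled out (the phenotype is present in only one),
and the remainder are candidates. The manual step of screening candidate
gene descriptions for plausibility is intentionally *not* automated; it
is a human judgment, not an algorithm.

## The synthetic cross

`simcross` emulates the study design the analysis assumes: 49 F2
individuals by default, two 25 Mb chromosomes, a recessive causal locus
with a 1.0 mm grain-length effect against 0.2 mm residual SD (clearly
separable classes — the real phenotype distributions are not published
numerically, so these are configuration defaults, not estimates), grain
width given a small opposite shift, Poisson read depths around 40× and a
constant QUAL so the filters are exercisable but pass by default. The
sequenced parent is homozygous everywhere; at the causal site it carries
the reference allele, since the causal allele is derived in the mutant
parent. Genotyping error replaces a code with one of the other two
uniformly — the simplest perturbation the HMM's error parameter can
absorb — and missingness is applied afterwards; both act on a copy taken
after the hidden truth (crossover points, causal genotypes, classes) is
recorded. Identical seeds give bit-identical output.

`simulate_annotation` builds the matching toy annotation: the causal
marker becomes the last intronic base of a two-exon gene (any
substitution there is a splice-acceptor HIGH), and decoy genes are placed
the same way at nearby markers whose ALT allele is carried by the
sequenced parent, so the ruling-out logic has something to rule out.

What the simulator does **not** model: read-level data (depth is a single
integer), linked selection or segregation distortion, polygenic
background, incomplete penetrance, multi-allelic sites, and structural
variants. Passing tests therefore demonstrate correctness of the
*inference machinery* under the stated model, not robustness to every
pathology of real resequencing data.

## Problem sizes and numerical choices

Tests exercise the scan at up to 2000 markers × 49 individuals and 200
replicates for the stochastic claims (support-interval coverage ≥ 90%,
unique-candidate recovery ≥ 95%, permutation type-I error in [0.02,
0.09] at α = 0.05 with 200 permutations per replicate), sizes chosen so
Monte-Carlo error is small relative to the margins being asserted.
Permutation thresholds use all-marker max-LOD maxima; quantiles use
linear interpolation. The pipeline expands one global seed into per-stage
substreams keyed by stage name (CRC32 of the name into a SeedSequence),
so adding a stage never perturbs the randomness of earlier ones, and the
provenance manifest hashes every input and output so a rerun with the
same config is verifiably bit-identical.

## Known limitations

* Only the recessive co-segregation rule is implemented; dominant or
  additive variants of the rule are an extension point.
* Only the Haley–Knott scan is provided (EM and imputation variants are
  not), no covariates, no sex chromosomes, no multiple-QTL models.
* The effect classifier is not a SnpEff/VEP replacement: no regulatory
  features, no NMD annotation, no canonical-transcript machinery.
* Absolute LOD values on real data depend on the (unknowable) true
  genetic map; with dense markers the *location* of the peak and the
  candidate logic downstream are robust to the constant-rate assumption,
  but LOD magnitudes should not be compared across map choices.
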