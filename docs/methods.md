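# Methods

This note documents the models implemented in `deepenz`, the defaults and
why, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Substrate model and simulation

A single-CpG substrate is a 67-bp duplex: a 6-nt class barcode, fixed
filler arms, 10 randomized nucleotides on each side of a central CpG. The
barcode and arms are drawn from {A,G,T} only, so bisulfite conversion
cannot corrupt demultiplexing and the arms can never contribute the C of a
spurious CpG. Substrate classes differ only in the lower-strand CpG state:
C (UM), 5mC (HM), 5hmC (OH).

**Extra CpGs in the flanks.** Conditioning a random 20-mer on containing no
second CpG is not neutral: it shifts flank C/G marginals by ~4%, and
forbidding CpGs *anywhere* in the window would make the 31 contexts that
contain a second CpG (CGCGNN, NNCGCG, …) unrealizable, shrinking the
context space below 256. `generate_pool` therefore supports three
policies: `"context"` (default — reject CpGs outside the central NNCGNN
6-mer; all 256 contexts realizable, context abundances mildly non-uniform),
`"strict"` (no extra CpG at all; 225 realizable contexts), and `"off"` (no
rejection; exactly i.i.d. uniform flanks, as in an N-base synthesis).
Profile analyses normalize against the class's own pool composition, so
the abundance bias of the default policy cancels there; rate fitting is
per-context and unaffected.

**Kinetics.** The methylated fraction follows first-order progress,
`y(d) = plateau·(1 − exp(−k·d))`, with dose `d` = relative enzyme
concentration × time (pseudo-first-order; absolute units arbitrary). On UM
substrates both CpG cytosines are targets: the simulator methylates the
lower strand independently with the rate of the reverse-complement
context, which matches the double-strand counting rule used downstream.
On HM/OH substrates the lower strand is pre-modified and only the upper
strand reacts.

**Read-out.** Hairpin ligation is modeled by emitting read1 = converted
upper strand and read2 = converted lower strand (5'→3'), joinable through
a fixed C-free 8-nt linker into one amplicon. Unmethylated cytosines
convert with probability `conversion` (default 1.0 for tests; a realistic
setting is ~0.995), 5mC and 5hmC are fully protected (no oxidative
chemistry, so 5hmC reads as C), and uniform substitution errors are applied
at `error_rate` (default 0). PCR duplicates, quality modeling and indels
are out of scope. Reads are emitted 1:1 with molecules, with constant
Phred+33 qualities.

## Read processing

Reconstruction uses the two-strand rule table: upper C ⇒ original C with a
protected (methylated) upper strand; upper T over lower G ⇒ converted
(unmethylated) C; G over C / G over T distinguish protected/converted
lower-strand cytosines; contradictory pairs are flagged ambiguous.
Flank positions are numbered −10..−1 and +1..+10 (no position 0; the CpG
occupies two unnumbered core slots); the stored window is the 22-nt
−10..+10 stretch including the CpG.

Counting policy: HM and OH contribute upper-strand events only; UM
contributes one event per unambiguous strand, lower-strand events booked
under the reverse-complement context (`"per-strand"`, default) or one
event per molecule (`"per-molecule"`). Whether the original analysis
pooled per strand or per molecule is not determinable from public
information; both are implemented. Ambiguous calls are excluded from both
numerator and denominator; reads failing the expected-size filter (±2 bp)
or carrying an unknown barcode are counted in the QC report, never dropped
silently. A zero-dose control yields a pooled background fraction per
class (reported, not subtracted by default).

## Rate fitting and merging

Per (class, context), `k ≥ 0` is fitted by bounded nonlinear least squares
with weights equal to read counts and multi-start initialisation
(k₀ ∈ {0.01, 0.1, 1}; ties broken by lowest residual, then smallest k).
The plateau is fixed at 1.0 by default; `plateau="fit"` estimates one
global plateau per experiment first (pooled per class and dose, a shared
plateau absorbing non-convertible or inactive substrate) and then fits
per-context rates against it. Points with fewer than `min_reads` total
reads (library default 50; the demo pipeline uses 20 to match its ~40
reads per context and dose) are excluded; contexts left with fewer than
two distinct doses are flagged `insufficient-data`. All-zero fractions
short-circuit to k = 0 with status `boundary`.

Experiments are merged by scaling each to a reference via the geometric
mean over shared substrate classes of the ratio of class-average rates
(computed over contexts fitted `ok` in both), then averaging scaled rates
per context; SEM = SD/√n (0 for n = 1). The merge is exactly invariant to
rescaling any single experiment by a positive constant.

## Profiles and specificity

o/e profiles divide per-position base frequencies of the methylated
(or unmethylated) subset by the frequencies of the class's full pool
(absorbing synthesis/rejection bias; a `uniform` expectation exists for
synthetic data), with a pseudo-count of 1 per (base, position, subset)
cell — negligible at real depths, and removable for exactness checks.
Replicate profiles aggregate cell-wise with SEM = SD/√N. Context ranking
sorts descending by rate with a lexicographic tie-break.

Pairwise specificity reports both the mean of per-context ratios and the
ratio of class means, side by side: the two conventions genuinely differ
on skewed rate distributions (a noisy small denominator right-skews
per-context ratios), and published average specificities plausibly mix
them. Undefined ratios (zero denominator) are flagged and counted, never
silently dropped. Enzyme-variant comparison runs a two-sided paired t-test
on natural-log specificity ratios (ratio data, multiplicative noise) and
reports the geometric-mean fold change; identical inputs report p = 1 by
convention, a constant non-zero shift p = 0. Energetics use
ΔΔG‡ = R·T·ln(ratio) with R = 8.314 J/(mol·K) and a default temperature of
298 K (configurable; no temperature is canonical for this conversion), and
hydrophobic burial as area × coefficient with a default coefficient of
60.8 J/(mol·Å²).

## Long substrates

The generated long substrate is 349 bp with 44 CpGs, 18 of which sit in
CCGG/GCGC 4-mers and carry lower-strand 5mC (the patterned,
post-replication-like configuration); site positions, contexts and pattern
are fully specified and an exclusion list supports sites introduced by
sequence tags. Site series are simulated as binomial draws of per-site
progress-curve fractions — the quantity the group fits consume — rather
than as full hairpin reads; read-level round-tripping is exercised by the
single-site pipeline. Group rates pool read-weighted fractions per dose
and refit the progress curve. Expected group specificity uses unweighted
arithmetic means of per-context single-site rates over the site contexts
(the simplest expectation consistent with pooled initial-rate behavior;
read-weighted means were the alternative), making the expectation
invariant to rescaling the whole rate table.

## Genomic correlation

Coverage tables are Bismark-coverage-like (1-based, one row per cytosine).
Sites with coverage ≤ 4 are excluded by default (keep > 4); the default
strand policy uses upper-strand CpG cytosines only, with an optional
`both` policy booking lower-strand cytosines under the reverse-complement
context. Per-context means are coverage-weighted; an o/e representation
(context mean ÷ global mean) is computed alongside, since either raw or
o/e means can reasonably be correlated with enzyme preferences. The
randomization test permutes the 256 context means, recomputes the Pearson
correlation per shuffle, and converts the observed r to
Z = (r_obs − mean(r_null))/SD(r_null) with a one-sided upper-tail normal
p (two-sided optional). The default of 20 shuffles supports only a
Z-extrapolated p — the CLI warns accordingly and ≥10⁴ shuffles give
empirical resolution; results with < 10 shuffles are flagged
low-confidence. A degenerate null (observation equal to every shuffle)
reports p = 0.5; a zero-SD null otherwise reports p as undefined. The
difference test applies the same machinery to Δr between two preference
profiles; swapping the profiles negates the statistic and maps p to 1 − p.

## Synthetic genome

The genome generator emulates only what the context analysis needs: random
chromosomes at a set GC fraction, per-CpG Poisson coverage, and binomial
methylation counts whose mean depends solely on the NNCGNN context. It
does not emulate CpG islands, domain-scale methylation structure,
strand-asymmetric coverage, mapping artifacts or batch effects — a green
genomic-recovery test therefore establishes that the profile/correlation
machinery is correct, not that real methylomes behave this simply.

## What a green test does and does not establish

The simulators implement exactly the forward model the fitters invert, so
recovery tests validate the pipeline's correctness and its noise behavior
at given read depths — not the adequacy of the monoexponential model for
the real enzyme (competition between substrates, processivity and
enzyme-preparation effects are deliberately out of scope). Replicate SEM
checks use four simulated replicates; published rate tables average far
more data sets, so SEM magnitudes are compared as orders of magnitude
only.

## Defaults that matter

| parameter | default | why |
| --- | --- | --- |
| flank_len / total_len | 10 nt / 67 bp | the deep-enzymology substrate layout |
| conversion / error_rate | 1.0 / 0.0 | exactness for tests; ~0.995/0.001 realistic |
| plateau | 1.0 fixed | no background subtraction by default; `"fit"` for a global per-experiment plateau |
| min_reads | 50 (library), 20 (demo pipeline) | ≈3× the binomial SE crossover at the respective depths |
| min_coverage | 4 (keep > 4) | standard WGBS context filtering |
| n_shuffles | 20 | the field's customary randomization depth; Z-extrapolated p |
| temperature | 298 K | room temperature; configurable |
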