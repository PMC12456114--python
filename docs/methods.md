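# Methods

This note records the model implemented by `ancbreed`, the defaults and why
they were chosen, the numerical and design decisions, and what the
synthetic scenarios do and do not show about real breeding programs.

## Genome and meiosis model

Individuals are diploid over a single chromosome described purely by its
genetic map: `L` SNPs (default 500) at evenly spaced positions
`R_l = l·D/L` on a map of length `D` Morgans (default 5). Three binary or
integer tracks are carried per haplotype and propagated jointly: genotype
(0/1 alleles), local ancestry (1 = target population, 0 = introgressed) and
a founder label identifying which founder haplotype each locus descends
from. Because all three tracks travel through the same meioses, identity by
descent, ancestry tracts and genotypes stay mutually consistent without any
inference step.

Meiosis is a crossover process without interference: a gamete starts on a
uniformly chosen parental copy and inherits alternating segments with
i.i.d. Exponential(1)-Morgan lengths, so the crossover count per gamete is
Poisson(D) — one expected crossover per Morgan. There is no de-novo
mutation: all variation is standing variation from the source populations,
which is the relevant regime for a program a few tens of generations long.
There are no sexes and generations are discrete and non-overlapping; the
mating schedule (below) treats every individual as capable of pairing with
any other. Real programs have sexed, age-structured, overlapping
generations; those details change the bookkeeping of who can mate, not the
genetics of what selection on these measures does.

## Source populations and wild history

Two source populations — the conservation *target* and the *introgressing*
population — diverge from a common ancestor under the Balding–Nichols
model: each locus draws an ancestral frequency `f ~ U(0.05, 0.95)` and
population frequencies `Beta(f(1−F)/F, (1−f)(1−F)/F)` with drift parameter
`F = 0.2` per population, giving a between-source divergence of
`F_ST = 0.4` by construction (the scale observed between domestic cat and
wildcat). Source panels are drawn as independent Bernoulli haplotypes
(`N_A = N_I = 500` diploids by default — large enough that source-panel
sampling noise is secondary; the value is exposed in the config).

The wild history runs `T_init` Wright–Fisher generations (default 10) at
constant size; each parent of each offspring comes from the *static*
introgressing source with probability `alpha_t` and from the evolving wild
population otherwise. The default schedule is a two-generation pulse
`alpha = (0.2, 0.2, 0, …)`, which compounds to an expected introgressed
fraction of `1 − 0.8² = 0.36` before any selection.

Captivity is then founded in two steps: a uniform *bottleneck* keeping a
fraction 0.25 of the wild population (these individuals are the program
founders and receive fresh unique founder labels `2i − I(a=1)`), one round
of uniform random breeding at constant size, then *selection* of the
least-introgressed 0.25 of that brood, bred by Wright–Fisher mating up to
the program capacity `N = 150`. The pulse therefore sits `T_init + 2`
generations before generation 0 of the program.

When an experiment requires a controlled starting introgression level `q`
(the sensitivity analyses use 25%), the pulse strength is set to
`alpha = 1 − sqrt(1 − q_raw)` per pulse generation and `q_raw` is adjusted
multiplicatively — at most 8 fresh simulations — until the post-selection
captive mean is within ±0.02 of `q`. This is a design choice of this
package: controlling the *post-selection* level is what makes runs at
different delays comparable, since formation-time selection removes much
more introgression when the pulse is recent (large tracts) than when it is
old.

## Selection measures

Seven pairwise expected measures are defined per locus and averaged along
the genome (table in the README): empirical kinship K (founder-label
sharing; IBD conditioned on the realized genomes rather than the pedigree),
expected offspring heterozygosity H, target-ancestry dose Q, the
ancestry-masked forms PH and PK (loci not target-on-both-copies count as
heterozygosity 0 and kinship 1), and the weighted forms
`WPH = (1−δ)Q + δ·PH`, `WPK = (1−δ)(1−Q) + δ·PK` with `δ = 0.5` by default.
The matrix builder computes the weighted kernels from their printed
definitions (the interpolation identities then hold to machine precision and
are asserted in the tests, alongside a brute-force enumeration oracle).
Useful exact facts: self-kinship is at least 0.5; PH ≤ H and PK ≥ K
pointwise; WPH at δ = 0.5 values a realized locus 0 / 0.25 / 0.5 / 1 for
zero / one / two-identical / heterozygous target alleles.

Realized population scores (`S_Q, S_H, S_K, S_PH, S_PK`) are unweighted
means over individuals and loci of the corresponding single-individual
quantities. Matrix entries for the cheap measures (H, Q, PH, WPH) are
assembled from matrix products of the binary tracks; founder-label equality
(K, PK, WPK) is evaluated by broadcasting in row chunks bounded to ~3·10⁷
elements so memory stays flat for large L.

## Breeding program

*Ranked* rule (default): compute the pairwise matrix, then iteratively move
the least promising individual onto a stack, where an individual's breeding
score is the mean of its pairwise entries over the individuals still in the
pool. The self term is excluded from that mean — self-kinship is bounded
below by 0.5 and would push all scores toward uniformity; self-pairs are
never bred in any case. Ties break toward the lower index, and the
per-iteration pool sums are recomputed fresh (not updated incrementally) so
exact ties stay exact and the tie-break is deterministic given the seed.

Pairing consumes the stack best-downwards, two at a time; each pair draws
`Poisson(4.2)` offspring until capacity `N` is reached. The last brood is
truncated to hit `N` exactly, and if the stack is exhausted while short of
capacity, pairing restarts from the best pair with fresh Poisson draws —
the capacity is a hard program constraint, so `N` is exact every
generation. With an odd stack the single worst individual sits out. Under a
compliance rate `c < 1`, each recommendation is followed with probability
`c`; otherwise the recommended partner is replaced by an unpaired
lower-ranked individual chosen uniformly at random (excluding the
recommendation, which returns to the pool and may still mate later that
generation).

The offspring mean 4.2 is itself derived from a studbook schedule
implemented in `ancbreed.demography`: brood sizes 1–5 with probabilities
(0.23, 0.36, 0.30, 0.10, 0.01) (mean 2.3) and an age-a breeding probability
`0.5·(1−0.3)·(1−0.1)^(a−1)` for ages 1–7 (sum ≈ 1.83). The schedule is
implemented literally as printed — the first-year factor `(1 − 0.3)`
multiplies every age term — rather than being re-derived as a life table,
so the product reproduces 2.3 × 1.83 ≈ 4.2 from the studbook. Note the
literal formula makes expected offspring *decrease* in the
`first_year_survival` field (the factor is `1 −` that value); the tests
assert the literal behaviour.

A simpler *threshold* rule (retain the better half by realized score, then
random mating) and a RANDOM baseline (uniform Wright–Fisher mating) are
provided for sensitivity comparisons.

## Synthetic wildcat-like scenario

`make_wildcat_like_fixture` emulates the shape of a real founder dataset:
36 diploids on a single 1.26-Morgan chromosome (17,720 SNPs by default;
tests use 2,000 for speed), generated by a short pulse history whose
strength is calibrated so per-haplotype target-ancestry fractions average
≈0.6 with a wide spread; all 36 are annotated as founders, the top 24 by
genome-wide target fraction are kept, and one uniform breeding step expands
them to N = 150. It reproduces the *statistics* a diversity panel presents
to the method (few founders, high and heterogeneous introgression, short
genome), not any real genotypes — linkage-disequilibrium structure, allele
frequency spectra and ancestry-call errors of real data are not emulated,
so passing tests on it show the algorithms behave correctly under this
scenario's geometry, not that inference on real sequence data would be this
clean.

## Numerical and design notes

- All randomness flows from a single seeded `numpy` generator per run;
  experiment drivers derive independent child streams from
  `SeedSequence([seed, …])` so replicates and strategies are reproducible
  and paired. Outputs carry the seed and a config hash in their headers.
- Strategy comparisons share founder panels within a replicate (paired
  design) to remove founder-sampling noise from between-strategy contrasts.
- Degenerate inputs: a zero-drift Balding–Nichols parameter collapses to
  the ancestral frequency; an empty genome map yields empty gametes;
  self-mating and sub-2 selections raise errors rather than silently
  proceeding.
- Scale choices for the shipped experiments: orderings are checked as
  replicate means over 10 (comparisons) or 8 (sweeps) runs at the default
  L = 500, N = 150; the sweep grids use their endpoints. These sizes give
  stable orderings for the large effects involved while keeping a full
  suite run inexpensive.
- On the short fixture chromosome every compliance level removes
  essentially all introgression within 20 generations; compliance is
  therefore compared on the trajectory-mean residual (recovery speed)
  rather than the converged endpoint, which is noise at the 10⁻⁴ level.

## Known limitations

- No inbreeding or outbreeding depression: kinship is reported, not fed
  back into fitness or survival.
- Kinship uses the tracked founder labels, which a simulation knows
  exactly; a real program would estimate IBD segments from genotypes, with
  error this package does not model.
- Single chromosome; a multi-chromosome genome is approximated by a longer
  map (unlinked chromosomes behave like distant map positions, but not
  identically).
- Uniform recombination map by default (positions are configurable but all
  shipped experiments use even spacing); no sex chromosomes, no
  sex-specific maps, no crossover interference.
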