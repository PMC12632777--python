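# Methods

This note documents the models behind `funnelmap`, the choices made where
the design was genuinely open, and what the synthetic-data validation
does and does not establish.

## The cross model

Eight founders (labelled 1–8) are combined in three levels: fixed pairs
(1,2), (3,4), (5,6), (7,8) at level 1; random matings between the
(1,2)×(3,4) and (5,6)×(7,8) gamete pools at level 2; and random matings
between the two four-founder pools at level 3. Pools default to 576
strains (the design's per-mating-type pool size) and matings draw
parents uniformly with replacement — the offspring-number distribution
of pool members is not specified by the design, so uniform random mating
is assumed, and the `Bottleneck` option exists precisely to perturb it.
Mating types are tracked only as pool membership.

Crossovers follow a Poisson process along the physical sequence with no
interference and no obligate chromosome-level crossover: each meiosis
places Poisson(c·L/10⁶) breakpoints uniformly on a chromosome of length
L bp, with c = 3 crossovers/Mb per meiosis by default. The process acts
on the transmitted gamete, so Haldane's function with m = c·d/10⁶
Morgans is exact for the simulator — the convention required for the
identity-decay law I = (1−R)³ to hold with the same c that parameterizes
the HMM transitions.

## Haplotype inference

The HMM has eight states (founders). Emissions treat reads as
independent Bernoulli trials reporting the founder's allele with
probability 1−ε (ε = 0.01); a site with zero coverage contributes 0 to
every state and is carried by the transitions rather than imputed away.
Transitions for one marker interval at recombinant fraction R:

| target                        | probability |
|-------------------------------|-------------|
| same haplotype                | (1−R)³      |
| level-1 partner               | R(1−R)²     |
| other pair, same quartet (×2) | ½·R(1−R)    |
| other quartet (×4)            | ¼·R         |

Rows sum to 1 algebraically; R = 0 gives the identity, R = ½ the uniform
matrix, and the stationary distribution is uniform for every R. This law
is the unique one consistent with the funnel topology, the two
closed-form entries above, and row normalization. The initial
distribution is uniform (1/8), matching the design's expected
frequencies. Decoding is Viterbi in log space with ties broken toward
the smallest haplotype index, so output is deterministic. Chromosome-IX
frequency distortions (below) do not alter transitions — they depend
only on R and topology — and enter only as scan expectations.

Disomic chromosomes are decoded over the 36 unordered haplotype pairs:
the two homologs follow independent funnel chains (ordered-pair
transition products collapsed to unordered states) and each read picks a
homolog uniformly before reporting its allele, giving mixture emissions.
The initial pair distribution is the collapse of independent uniforms
(1/64 for {i,i}, 2/64 for {i,j}).

Strains with ≤12,000 total reads (configurable) are excluded before
inference, mirroring the coverage filter such populations require.

Validation: Viterbi output equals exhaustive path enumeration on random
instances (L ≤ 6 monosome over 8^L paths, L ≤ 4 disome over 36^L), and
marker-level accuracy on simulated 3.8× data exceeds 99%, rising with
depth.

## Ploidy and scaffold

Copy number is called from mean read count per marker site per
chromosome, normalized by the strain's median chromosome depth; a
chromosome is disomic when its normalized depth is ≥1.5 (midpoint of the
1 and 2 expectations). Using marker-site counts rather than all aligned
reads is a dialect choice forced by the package's input (count
matrices); it recovers simulated copy numbers exactly at 3.8× depth.

The scaffold is selected greedily: the first marker of each chromosome,
then repeatedly the first marker ≥2000 bp downstream (inclusive
difference). Genome coverage of the scaffold is reported over the
per-chromosome span between outermost markers, excluding the telomeric
regions beyond them.

## Genetic map

For markers on the same chromosome, identity I(d) = (1 − R(c·d/10⁶))³
decays from 1 to 1/8 (the unlinked identity of a balanced 8-haplotype
population). The conversion coefficient is fitted by grid search
(0.5–6.0 per meiosis, step 0.01): for each candidate, observed identity
is regressed (OLS with intercept) on predicted identity and the
candidate minimizing residual variance wins; the post-funnel rate is 3ĉ.
Same-chromosome scaffold pairs are subsampled (default cap 20,000,
seeded) — the fit is insensitive to the pair-selection policy, which is
otherwise unspecified.

## Trisomy IX and expected frequencies

The simulator can give one level-1 diploid an extra chromosome copy
(default: a duplicated haplotype-6 copy of chromosome IX in the (5,6)
diploid), with loss-of-heterozygosity intervals in which all three
copies carry one haplotype. Transmission uses unbiased multivalent
segregation: a trisomic meiosis emits a 2-copy gamete with probability
0.5 (pairs uniform) or a 1-copy gamete (uniform), so each copy has
marginal transmission probability ½, and disomy propagates through
later levels by the same rule. Consequently each of the nine
founder-level copies is (approximately) equally represented among
euploid final strains, reproducing the expected chromosome-IX
frequencies w_i/Σw: 1/9 for uninvolved haplotypes, 1/9 + 2/9 for the
carrier pair outside LOH, and 0 + 3/9 inside. The three chromosome-IX
copies do not recombine within trisomic meioses — a simplification that
leaves the frequency expectations untouched but ignores rare
recombinant trisomes. The default LOH interval coordinates are a package
choice; real events would be supplied as a region table.

## Population structure

A marker with haplotype h was inherited through identifiable pools
(h ∈ {1,2} via G1_12; h ∈ {1..4} via G2_14, …). Pairwise discordance is
the proportion of non-matching haplotypes over markers masked in *both*
strains for the same pool: 0 when the two strains descend from the same
pool member, ≈0.5 (G1) or ≈0.75 (G2) otherwise. Aneuploid strains
contribute only monosomic chromosomes. Complete-linkage clustering of
the discordance matrix, cut at 0.25, screens for shared-ancestor groups;
pairs with fewer than 50 jointly masked markers are treated as missing.

An important caveat established on full-genome simulations: the jointly
inherited G1 region of an unrelated pair spans only on the order of ten
independent G1-meiosis segments, so chance agreement is heavy-tailed —
several percent of unrelated pairs fall below the 0.25 cutoff and a few
per thousand agree exactly. The default cutoff is therefore a screening
threshold, not a proof of shared ancestry; confident calls require exact
agreement over a large joint region (hundreds of markers), and the
cluster report should be read accordingly.

## QTL power

LOD at a marker is (n/2)·log₁₀(RSS₀/RSS₁) with maximum-likelihood
(divide-by-n) variance estimates — exactly the difference of the two
normal log-likelihoods (single mean vs one mean per observed haplotype
class; classes with no strains contribute no parameter). REML/OLS
variants would shift LOD slightly; the ML form is used because it makes
the likelihood identity exact. Missing haplotype calls are dropped
marker-wise.

The family-wise threshold is empirical: the 95th percentile of the
per-replicate maximum LOD over the scaffold under standard-normal
phenotypes (1,000 replicates by default; 200 in the desk-scale
acceptance run). On simulated scaffolds the null per-marker LOD is
exactly χ²₇/(2·ln10) and the threshold lands near 7.4 LOD for ~6k
markers × 11,392 strains.

Simulated phenotypes place the effect on the biallelic SNV allele (0/1
derived from the haplotype via the founder table), not on an 8-level
haplotype effect — causative markers are SNVs while the scan fits the
haplotype factor, and this asymmetry is intentional. The realized
variance decomposition is exact: residuals are orthogonalized against
the causative genotype and rescaled so each phenotype has mean 0,
variance 1 and variance explained exactly h² in the sample. This is the
literal reading of "a phenotype with mean 0, variance 1 and heritability
h²", and it is the construction under which the power, threshold and
resolution figures are mutually consistent (with distributional
residuals, replicate-to-replicate drift in realized h² caps power near
85% at h² = 0.0036 for any threshold consistent with the null scan).

Power runs use true simulated haplotypes rather than re-inferred ones;
inference error (<1% of markers) is quantified separately and would
slightly blur mapping resolution. Desk-scale problem sizes: 11,392
strains, ~6k scaffold markers, 200 null replicates, 150 phenotype
replicates per heritability.

## Selection scans

Single-marker: haplotype counts at each scaffold marker are tested
against expected frequencies (1/8; region-specific weights on a trisomic
chromosome) by χ² goodness-of-fit. Because the final population is far
larger than the intermediate pools, null counts are overdispersed; the
scan estimates an integer divisor D (grid 1–100) such that the central
95% of ordered counts, divided by D, Q-Q regress on same-mean simulated
Poisson quantiles with slope closest to 1, then tests counts/D against
expected/D (categories with zero expectation are dropped with df
reduction). The divisor recovery is validated on gamma-Poisson mixtures
with variance k× mean for k ∈ {1, 8, 31}.

Pairwise: Pearson χ² on the 8×8 joint table (df 49), strains missing at
either marker excluded. The bottom 95% of inter-chromosomal statistics
(presumed null) are Q-Q regressed log-log against simulated χ²₄₉
quantiles; the inverse map transforms all statistics to the theoretical
null scale, and the Holm cutoff is computed from the transformed
inter-chromosomal p-values. Intra-chromosomal pairs are scored but
flagged — linkage itself violates independence. Measured family-wise
error across seeded no-selection runs is ≈5–7% at the design pool size
of 576; smaller pools add genuine structure (strains sharing
intermediate ancestors) that the bulk log-linear correction does not
remove, inflating the tail — a real property of bottlenecked
populations, not a calibration defect.

Holm correction is step-down: with p(1) ≤ … ≤ p(m), the largest k with
p(i) ≤ α/(m−i+1) for all i ≤ k determines the nominal-p cutoff
α/(m−k) (α when everything is rejected, 0 when nothing is).

## What the synthetic validation shows — and does not

The generator reproduces the statistical structure the analyses assume:
marker density and minor-allele sharing spectrum, balanced 1/8 haplotype
representation, Haldane-consistent linkage decay, the 0/0.5/0.75
discordance geometry, trisomy-IX frequency distortions, Poisson depth
with 1% read error. It does not simulate sequence-level artifacts
(alignment bias, mapping errors, indels, structural variants), founder
genotyping errors, non-uniform coverage along the genome, or selection
during pool growth other than the explicit viability rules — so passing
tests certify the inference machinery under the model's assumptions, not
robustness to every failure mode of real sequencing data.

## Numerical choices

All HMM computation is in log space; transition matrices are rebuilt per
interval from closed forms (no caching error). Viterbi ties break to the
smallest state index. Identity fits guard against degenerate (constant)
predictors. Scan statistics zero out cells with zero expectation. All
randomized stages take explicit seeds (numpy Generators); identical
seed + configuration reproduces byte-identical outputs.
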