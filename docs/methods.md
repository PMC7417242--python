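# Methods

## The demographic null population

The quantity everything rests on is the theoretical total recruiting
cohort (TRC): the complete pool of larvae arriving at the focal reef on
the sampling night, of which the light trap catches a subsample. Its
size is a chain of multiplications,

    TRC_r = R_Cd × C_A × F_R × d × A_r

| symbol | meaning | default | unit |
| --- | --- | --- | --- |
| `E` | eggs per colony clutch | 803 | eggs |
| `H` | hatch rate | 0.5 | fraction |
| `Hd` | eggs hatching per day | 0.5 | fraction |
| `S` | survival through the pelagic phase | 0.03 | fraction |
| `R_Cd` | daily surviving recruits per colony (≈ `E·H·Hd·S`) | 6 | recruits/day |
| `Da/At` | colony density `C_A` | 10.23 / 0.1 = 102.3 | colonies/km² |
| `F_R` | simultaneously reproducing female fraction | 0.33 | fraction |
| `L, W` | habitat strip length × width | 160 or 387 × 1.2 | km |
| `d` | daily factor | 0.5 | fraction |

Two conventions deserve comment because the published arithmetic is not
internally uniform, and the package reproduces it *explicitly* rather
than silently:

* **The daily factor.** The plain product `R_Cd × C_A × F_R × A_r`
  yields ≈38,776 for the 25 km strip, not the published 19,445. An extra
  factor of 0.5 — numerically equal to the daily hatch fraction —
  reconciles the chain exactly for both radii (19,445 and 47,033). It is
  exposed as `daily_factor` (default 0.5) on `HabitatModel` rather than
  folded into any other parameter, since the published record does not
  say which interpretation was intended.
* **Colony-density precision and rounding.** Forward TRC calculations
  need the unrounded density 102.3/km² and integer *truncation* to
  reproduce all printed cohort sizes (19,445 / 47,033 / 5,911); the
  printed inverse calculations (area and radius back from a cohort size)
  use the rounded 102/km² and no daily factor. Both chains are kept,
  as `c_a_forward`/`c_a_inverse` and the absence of `daily_factor` in
  `radius_from_colonies`, and the pipeline report labels every number
  with the convention that produced it.

The cohort is partitioned into `K = floor(TRC / s)` families of exactly
`s = 6` recruits (the mean daily colony output); the ≤5 remainder
recruits are dropped, a deterministic and negligible truncation at the
10³–10⁴ cohort sizes in play.

## Monte-Carlo sampling and the exact oracle

A catch is `n = 168` recruits drawn uniformly without replacement. The
sufficient statistic is the sibship composition `c_k` (families with
exactly `k` sampled members); "sibling pair" means a family contributing
exactly two members, not a count of dyads — the only reading under which
the published means are recovered. Conservation `Σ k·c_k = n` holds for
every draw and is property-tested.

Because families are exchangeable and equal-sized, `E[c_k]` has the
closed form `K · HypergeomPMF(k; N, s, n)`. The Monte-Carlo sampler is
checked against this oracle at three standard errors throughout. The
sampler itself is a partial Fisher–Yates shuffle (a numba kernel fed by
uniforms from a seeded numpy `Generator`): per draw it performs `n`
swaps and resets only the touched family counters, so cost per draw is
O(n) independent of cohort size, and 10⁵ draws from a 47,000-recruit
cohort take well under a second. Default iteration counts are 10⁵
(pipeline and acceptance) and 2×10⁴ inside the bisection search; at 10⁵
iterations the standard error of the pair-count mean is ≈0.006, an
order of magnitude below the precision of the published values.

## Radius inference

The halving rate `Rp = SP_r25 / SP_r50` (≈2.37) measures how fast pairs
accumulate as the source radius shrinks. The number of halvings needed
to make the empirical 48 pairs typical is `n = 48 / (Rp · SP_r25)` ≈
5.81, and the compatible radius is the *linear* division `25 km / n` ≈
4.31 km, mirroring the published arithmetic; a geometric option
(`r25 / 2^n`) exists behind a flag but is off by default. Printed
intermediates are recomputed at full precision; the published area
58.37 km² (vs. π·4.31² = 58.36) is accepted as an override when the
cohort 5,911 is to be reproduced exactly.

## Scoring and the confidence-TRC search

The published record describes the scoring system only as "indirectly
proportional" to null event frequencies and does not print the weight
formula, so the literal score value and tail percentage are treated as
non-reproducible descriptors. The package's documented scheme is

    w_k = round(1 / max(mean c_k, 1/iterations)),  capped at 1000,

forced nondecreasing in `k` by a running maximum (a rarer, larger event
never scores less; Monte-Carlo noise on near-zero means could otherwise
invert the order). The empirical rarity claim survives in percentile
form: the observed composition scores beyond the 99.9th percentile of
the null even for the reduced ~5,900-recruit cohort. Tail probabilities
use the upper tail (≥) with add-one smoothing, so an estimate is never
exactly zero.

The confidence search formalizes "small enough to make the data
unsurprising": the largest cohort size `T*` (multiple of the family
size, found by bisection) with `P(null score ≥ empirical score) ≥ α`
(α = 0.05), weights rebuilt from each candidate's own null and a
deterministic per-candidate random stream derived from the run seed.
Acceptance is monotone in the sparse regime (cohort ≫ sample); very
near `T = n` a clumped composition becomes infeasible under the null and
the search reports a boundary flag instead of a bracket.

## Sibship assignments and the empirical fixture

Pairwise assignments are accepted when the posterior strictly exceeds
0.75. Families are connected components of the accepted-pair graph
(networkx), singletons allowed. The headline arithmetic defines
`Cmax = n − accepted_pairs` (= 120 for 168 recruits and 48 pairs) even
though collapsing the 32 families implies 47 non-redundant merges and
hence 121; both numbers appear in the report rather than silently
reconciling the discrepancy.

The packaged fixture `kinrecruit/data/rcs_sibship.csv` is a *synthetic*
reconstruction of the published assignment summary — 3 full-sib pairs at
posterior 1.0, 126 half-sib candidates of which 45 exceed the threshold
(18 at ≥0.95), arranged into 20 pairs, 10 triplets, one quadruplet
(carrying the one redundant within-family assignment) and one
quintuplet. Individual identities and the sub-threshold posteriors are
arbitrary; only the thresholded summary statistics are meaningful.

## Relatedness classification

For each pair the genotype log-likelihood is computed under the three
non-inbred IBD classes U = (1,0,0), HS = (½,½,0), FS = (¼,½,¼)
(probabilities of sharing 0/1/2 alleles identical by descent), with loci
independent, allele frequencies estimated from the sample, and a
symmetric per-allele error rate ε (default 0.01) mixed into a 3×3
emission matrix. Calls are maximum likelihood with ties to U;
monomorphic loci are excluded with a warning and missing calls skipped
per pair.

At 300 common-variant loci the half-sib vs. unrelated likelihood ratio
separates only moderately, and in a cohort the unrelated pairs outnumber
sibling pairs by two orders of magnitude, so raw calls have an
unacceptable false-pair load. `corroborated_sib_pairs` exploits the
transitivity of sibship: members of a sampled family form a near-clique
of kin edges, while a spurious edge lands between individuals with no
shared kin. Edges with kin-vs-U log-likelihood ratio above 8 are
accepted outright; edges in (2, 8] need ≥2 common neighbours in the
LLR > 2 candidate graph; edges in (−2, 2] need ≥3. Under the
generator's default single-sire haremic pedigree this recovers ≥96% of
true sibling pairs with ≤4% false pairs across seeds (the acceptance
property requires ≥90% / ≤5%).

Known limitation: isolated half-sib pairs (no other family member
sampled) below the strong-evidence threshold cannot be corroborated and
are missed, and two-sire colonies — whose members do not all share a
parent — corroborate less and lose recovery (roughly 0.75–0.93 depending
on strictness). Full-pedigree likelihood reconstruction, which clusters
jointly instead of pairwise, is explicitly out of scope.

## Population-genetic summaries

Per locus with allele frequencies (p, q): `He = 1 − p² − q²`,
`Ne = 1/(p² + q²)`, `Ho` the observed heterozygote fraction, averaged
over loci; `F_IS = (He − Ho)/He` from the locus means. Between two
samples, `F_ST = (Ht − Hs)/Ht` with `Hs` the mean within-sample `He` and
`Ht` the expected heterozygosity of averaged frequencies;
`F'_ST = F_ST / F_ST_max` with `F_ST_max = (1 − Hs)/Ht`. The multilocus
probability of identity is `Π_l [p⁴ + q⁴ + (2pq)²]`, computed in log
space. Loci uncalled in a sample are dropped pairwise with a logged
warning. These formulas are verified on their closed-form cases
(He = 0.5, Ne = 2, PI = 0.375 per locus at p = 0.5); validating the
empirical table would require the archived study genotypes, which the
package deliberately does not depend on.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
allele frequencies uniform on the admissible band [0.33, 0.67] (only the
band is documented for the real panel; a spike at 0.5 is available for
worst-case identity tests), parents drawn in Hardy–Weinberg proportions,
Mendelian transmission of one allele per parent per locus, optional
symmetric allele-flip genotyping error (default 0 — the real panel is
heavily quality-filtered), and uniform-at-random missing calls at 5% per
genotype (the per-individual cap is 15%). Colonies default to one sire
and three dams with six offspring — the haremic structure typical of the
species — with a two-sire variant for the secondary-male pattern the
empirical quadruplet/quintuplet sibships suggest.

What it does **not** emulate: linkage between loci, an empirical allele
frequency spectrum, clutch timing, age structure within colonies,
spatial structure among colonies, or sequencing-level artifacts beyond a
flat error rate. Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
every property of real ddRAD data.

## Problem sizes and determinism

Tests run the Monte-Carlo blocks at 2×10³–10⁵ iterations and the
classifier validation on 30-colony (180-recruit), 300-locus cohorts —
sizes at which the whole suite completes in well under a minute while
keeping Monte-Carlo standard errors far below the tolerances being
asserted. Every random stage takes a numpy `Generator` or an integer
seed; the seed is recorded in summaries and reports, and a fixed seed
reproduces a pipeline report byte-for-byte.
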