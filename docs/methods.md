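# Methods

## Haplogroup assignment

Four West-Eurasian mtDNA haplogroups are distinguished by an extended
haplotype over five diagnostic positions (rCRS coordinates, haploid):

| label | 1719 | 7028 | 9055 | 10398 | 12308 |
|-------|------|------|------|-------|-------|
| H     | G    | C    | G    | A     | A     |
| J     | G    | T    | G    | G     | A     |
| K     | G    | T    | A    | G     | G     |
| U     | G    | T    | G    | A     | G     |

The decision table is total: any other complete five-tuple is classed
OTHER, and any missing marker yields UNKNOWN (5-SNP typing cannot place a
partially genotyped subject). OTHER is reportable — real cohorts contain
non-H/J/K/U lineages — but is not an association feature by default.
UNKNOWN subjects are excluded from the denominators of frequency and
association tables (complete-case per feature). How non-H/J/K/U haplotypes
should be handled is not fixed by 5-SNP typing itself; the OTHER class is
this package's convention.

## Carriership association

Features are scored as binary carriership: a haplogroup label (carrier iff
the call equals the label), a nuclear allele under dominant coding
(carrier iff ≥ 1 copy), or an exact unordered genotype. Subjects missing
the relevant genotype(s) are uninformative for that feature and excluded
from its table only.

* **Fisher exact test**, two-sided by probability ordering: the P value
  sums hypergeometric point probabilities of all tables with the observed
  margins whose probability is at most the observed one, with a relative
  tie tolerance of 1e-12. Sidedness conventions differ between software
  packages; probability ordering is the most common and is cross-checked
  against an independent implementation in the tests.
* **Odds ratio** ad/bc with the **Woolf CI**
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96. If any cell is zero, 0.5 is
  added to all four cells (Haldane–Anscombe) and flagged.
* Report rounding follows the field's tables: 2 decimals for OR/CI, 1 for
  percentages; stored values keep full precision.

Sex stratification partitions subjects with known sex; missing-sex
subjects belong to neither stratum.

## Combination mining

All subsets of 1..max_order features on distinct loci are scored as joint
carriership (carrier iff carrying every component; uninformative iff any
component is missing). Enumeration is exhaustive — with a handful of
haplogroups and tens of nuclear features at order ≤ 2 this is a few
thousand tables, so an exact sweep replaces any stochastic search over the
same space. Two features at one locus are never combined (carriage of two
alleles at one site is a different hypothesis). Output order is
deterministic: descending |ln OR|, then lexicographic name. A combination
is flagged significant when P < α and the OR CI excludes 1; nominal P
values are reported by default, with Benjamini–Hochberg adjustment
available but off (the flagging rule always uses nominal P). Permutation
validation shuffles case/control labels among informative subjects and
reports (hits+1)/(n_perm+1).

## Synergy factor

On the disease × A × B table with double-non-carriers as reference,

    OR11 = (case11/case00)/(ctrl11/ctrl00),  OR10, OR01 analogous
    SF   = OR11 / (OR10 · OR01)

SF = 1 is the multiplicative null; SF > 1 positive epistasis. The CI is
log-normal with Var(ln SF) = Σ 1/cell over the eight working cells.

**Small-cell rule:** if the minimum cell is below 5 (parameter), 0.5 is
added to all eight cells before estimation, and the same corrected cells
feed both the point estimate and the variance — a single internally
consistent rule. The threshold-5 choice reproduces the published point
estimates for both reference pairs (the {J, CCL5*A} table, smallest cell
4, corrected → 4.32; the {J, PVT1*G} table, smallest cell 10, uncorrected
→ 3.05). The published CI for the corrected pair does not match either
variance convention exactly and likely reflects unreported cell handling;
the package reports its own internally consistent interval.

## Exact test of no three-way interaction

Conditioning on all three two-way margins (status×A, status×B, A×B)
leaves a one-parameter family of 2×2×2 tables indexed by the pivot cell
(joint-carrier cases). Under the null of no three-way interaction each
feasible table has probability proportional to 1/∏(cell!) (the
conditional exact construction; the two-sided P sums tables no more
probable than the observed, relative tie tolerance 1e-12). A one-sided
tail P over pivot ≥ observed is also reported, since synergy is the
directional hypothesis of interest. Enumeration uses log-factorial
(gammaln) arithmetic with log-sum-exp normalization — naive factorials
overflow at realistic counts. Degenerate families (single feasible pivot)
give P = 1 by construction. Exact interaction tests of this name are not
uniquely standardized; published interaction P values computed by other
software are therefore comparable only qualitatively, and the tests
validate this implementation against a brute-force rational-arithmetic
enumeration instead.

**Classification:** a pair is *epistatic* iff the exact test rejects at α
AND the SF CI excludes 1 (strictly); *suggestive* iff exactly one
criterion holds; otherwise *not supported*.

## Synthetic cohorts

The generator emulates a retrospective case-control design over two binary
exposures. Population stratum frequencies come from independent carriage
(p_a, p_b); disease odds in stratum (i, j) are
baseline_odds·or10^i·or01^j·sf^(i·j); case and control stratum
distributions follow by Bayes' rule and subjects are drawn multinomially.
This is exact and fast, and matches the estimand: odds ratios, not risks,
are identifiable under retrospective sampling. Factor A is realized as the
J-defining haplotype (non-carriers draw from a background haplogroup mix,
H most common, as in European-ancestry controls); factor B as a nuclear
genotype, heterozygous with probability het_fraction.

Defaults mirror the reference pair's study conditions: n = 283/290,
p_a = 0.10, p_b = 0.37, or10 = 1.25, or01 = 0.97, sf = 4.3,
baseline_odds = 0.01 (rare disease), het_fraction = 0.88 (the
Hardy–Weinberg heterozygote share among carriers at carrier frequency
0.37), female fractions 198/283 and 197/290.

What the generator does **not** emulate: linkage disequilibrium among
nuclear loci (only one nuclear locus per cohort), mtDNA phylogenetic
structure beyond the four patterns, population stratification, genotyping
error, and any sex×genotype dependence. Passing tests therefore
demonstrate correctness of the statistics under the stated sampling model,
not robustness to those real-data features.

The `study_fixture` cohorts are deterministic individual-level
reconstructions of the published aggregate tables via inclusion–exclusion
(n11 = nAB, n10 = nA−nAB, n01 = nB−nAB, n00 = N−nA−nB+nAB per status).
Only pairwise-with-J counts were published, so fixtures are per-pair; sex
is assigned deterministically and independently of genotype, so
sex-stratified fixture results are conventions, not reconstructions.

## Numerical and design choices

* Exact tests use scipy's hypergeometric pmf (2×2) and gammaln/logsumexp
  (2×2×2); property tests compare both against exact rational-arithmetic
  enumeration oracles on small tables.
* Tie handling in probability ordering uses a relative tolerance of 1e-12,
  applied on the log scale as log1p(1e-12) for the 2×2×2 test.
* All randomness flows from a single integer seed through
  numpy.random.default_rng; identical configuration gives byte-identical
  cohorts and result tables.
* Problem sizes in the test suite: oracle agreement on tables up to
  N ≈ 60 (hundreds of hypothesis-generated examples), type-I-error
  calibration on 2,000 simulated null cohorts of 500+500, parameter
  recovery at 20,000+20,000 — sizes at which the Monte-Carlo and
  delta-method error bands quoted in the tests are meaningful.
* Exit codes (CLI): 0 success, 2 config error, 3 data error, 4 degenerate
  statistics.

## Known limitations

* The exact interaction test and the synergy-factor CI are asymptotically
  compatible but can disagree near the boundary (e.g. an SF CI touching 1
  with interaction P just above α); classification deliberately requires
  both.
* 5-SNP haplogroup typing cannot resolve sub-haplogroups and misclassifies
  lineages that share the five-marker haplotype by homoplasy.
* The Woolf CI and log-normal SF CI are normal approximations; with very
  sparse tables (post-correction cells near 0.5) coverage degrades.
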