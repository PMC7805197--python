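# Methods

## Model and procedure

`dpgsea` treats a drug screen as a directional gene set enrichment problem.
The disease contrast supplies, per gene, a signed effect (log2 fold-change
or signed moderated statistic) and a significance value in (0, 1]. Genes
are merged with the drug signatures by identifier (case-folded,
whitespace-stripped) and ranked by the absolute value of the ranking
statistic `T(j)`, most significant first, so rank 1 is the top of the list
and the minimal `|T|` sits at the bottom. The default `T = −log10 p`
(signed by the effect) ranks on statistical evidence rather than effect
size; a `signed_stat` option ranks on the effect column itself for users
who prefer a moderated-t ordering.

Each drug's signature carries a per-gene regulation direction. A hit is
*directional*: in antagonist mode (the signature-reversion screen, the
default) the drug direction must oppose the disease direction; in agonist
mode it must match. Signature genes absent from the DE table are ignored;
present-but-discordant genes count as misses — excluding them would
silently change the list length `p` and hence every score. Genes with a
zero effect have no disease direction and never match. The hit count `γ`
counts directional hits only; this is the only count under which the
running sum closes exactly at zero, `v(p) = 0`.

The running sum walks the list accumulating the hit-weight fraction
(weights `|T|^ω`) minus the miss fraction `1/(p−γ)` per miss. `ES` is the
maximum of `|v|`; `TCS` is the rank distance from the ES maximiser to the
minimal-`|T|` position, scaled by `1/(p−1)` so maximal top-of-list
separation maps to exactly 1. Leading-edge genes are the hits at ranks up
to the maximiser.

Per drug, a permutation null redraws the `γ` hit labels uniformly over the
`p` fixed rank positions and rescores. The same ensemble serves three
purposes: normalisation (`NES = ES / mean null ES`, likewise `NTCS`),
empirical significance (proportion of null scores strictly greater than
the observed score), and — after per-drug normalisation and pooling across
drugs — a GSEA-style FDR, the ratio of the null tail fraction to the
observed tail fraction at each drug's normalised score, clipped to [0, 1].

## Parameters

| parameter | default | meaning |
|---|---|---|
| `omega` (ω) | 1 | running-sum weight exponent on `|T|`; 0 gives the unweighted KS-style statistic, larger values emphasise the significant tail |
| `n_perm` | 1000 | permutations per drug; sets the p-value floor at 1/n_perm (0 is rendered `<0.001` at the default) |
| `mode` | antagonist | directional matching rule; agonist is the positively-correlated validation setting |
| `fdr_alpha` | 0.05 | threshold for the report's pass/fail flag columns |
| `sort_key` | `es_p` | report order (ties broken by NES descending, then drug id) |
| `top_n` (builder) | 20 | signature size when deriving proto-matrices; labels follow the `"Sig Rank 10"` / `"FC Rank 20"` convention |

ω is deliberately user-settable: the statistic family is defined for any
ω ≥ 0 and the literature it follows uses 1 as the standard weighting; 0 is
useful as an analytically tractable reference (several tests exploit it,
since unweighted scores have exactly enumerable nulls).

## Numerical and design choices

- **Ranking direction.** Rank 1 is the most significant gene and the
  minimal-`|T|` index is therefore `p`. This is the orientation under which
  a top-of-list enrichment yields TCS near 1, matching how the score is
  meant to behave (compact top-ranked driver sets score high).
- **TCS scale.** The raw rank distance is divided by `p−1`, mapping the
  maximal separation (peak at rank 1, minimum at rank `p`) to exactly 1.
- **Ties.** Ranking ties in `|T|` are broken lexicographically by gene id;
  argmax/argmin ties take the smallest rank. Both rules exist purely for
  deterministic, regression-testable output.
- **Duplicate genes** in a DE table collapse to the most significant row
  (strongest evidence) with a logged count. **Zero significance** values
  (upstream underflow) are clamped to 1e−300 so `−log10` stays finite.
- **Leading edge at a depletion peak.** When the maximal `|v|` is a
  negative deviation (hits depleted from the top), there are no hits at or
  before the maximiser; the driver set is then the hits *after* it, which
  is provably non-empty (the walk can only return to `v(p)=0` through
  hits). Screens of interest peak positively; this case matters only for
  null-ish drugs.
- **Empirical p-values** use the strict `>` count divided by `n_perm`, with
  no +1 smoothing, so a score above every null is representable as 0 and
  rendered `<1/n_perm`. This matches the permutation-floor reporting
  convention the FDR machinery expects.
- **FDR.** The pooled two-fraction ratio is computed on normalised scores
  (normalisation before pooling is what makes drugs with different `γ`
  comparable); a numerator-only variant is available as a config option. A
  BH-style monotonicity pass makes q non-increasing in the score. P-values
  use each drug's own raw null (the ratio is scale-invariant per drug).
  Benjamini–Hochberg adjustment of the empirical p-values is *not* the
  primary error rate; it is available as optional extra columns (`--bh`).
- **Permutation-null evaluation.** Between consecutive hits the running sum
  falls linearly, so `|v|` can only peak at a hit rank or the rank just
  before one. The null scorer evaluates exactly those `2γ` candidate points
  with the same float operations and the same smallest-rank tie-break as
  the full scan, making the two paths bitwise identical (property-tested)
  at O(γ) instead of O(p) per permutation.
- **RNG.** One master seed plus a CRC-32 hash of each drug id seeds an
  independent per-drug stream, so per-drug statistics are invariant to
  screening order and reports are byte-reproducible under a fixed seed.

## The synthetic-data generator

`simulate_screen_inputs` emulates the statistical structure the method
consumes, starting at the DE-table level: background genes draw
significance ~ Uniform(0, 1] and effect ~ N(0, 1); a spiked drug's
signature genes are, with probability `concordance`, given disease effects
opposing their drug direction and significance `10^(−Exp(mean =
spike_strength) − 1)` — an exponential tail on the −log10 scale that places
them near the top of the ranked list at stochastic positions, the way
genuine perturbation targets appear in a DE list. Null drugs draw
signatures uniformly. Defaults (2000 genes, 10 drugs, one spiked,
signature size 20, concordance 1, spike strength 3) describe a clearly
detectable reversal in a screen-sized gene universe.

What the generator does **not** emulate: gene–gene correlation, shared
pathway structure between drugs, effect-size/significance coupling, or the
count-level noise the upstream DE model handles. Passing tests therefore
demonstrate calibration and power under independent-gene conditions; on
real data, correlated gene sets can inflate permutation significance, as
with any gene-label-permutation method. Signatures may overlap between
drugs (as in real proto-matrices); `disjoint=True` gives clean power
studies. When several spiked drugs share a gene, the later drug's spike
wins — with the default single spiked drug this never triggers.

## Validation study sizes

The statistical checks use simulation sizes chosen to give tight binomial
or KS error bars while staying desk-scale: 1000 random instances for the
brute-force oracle comparison; 20 000 permutations against the exact
45-placement null average (p=10, γ=2, ω=0); 500 independent null screens
(1000 genes, 1000 permutations) for type-I error and p-value uniformity;
100 screens (2000 genes, 10 drugs) for spiked-drug recovery; 150 null
drugs for the NES-centring check. The leading-edge/TCS-significance
relationship is assessed on null-dominated screens (40 drugs, 4 weakly
spiked at concordance 0.3), because the tendency of TCS significance to
accompany compact driver sets is a statement about where the running sum
peaks across a heterogeneous screen, not about strongly spiked drugs — in
an all-spiked design every drug peaks at the top and the contrast
vanishes.

## Known limitations

- Gene-label permutation assumes exchangeable genes; correlated expression
  modules violate this and make p-values optimistic (a phenotype
  permutation is not possible at the DE-table level this tool operates on).
- The p-value resolution is 1/n_perm; FDR estimates for scores deep in the
  pooled tail inherit the pooled ensemble's granularity.
- Drugs whose signature has no directional hit (`γ = 0`) are reported with
  NA statistics rather than a score of zero: the statistic is undefined,
  and 0 would be misleadingly comparable.
- Proto-matrix construction consumes finished per-drug DE tables; fitting
  the perturbation DE model (and any batch correction) is upstream of this
  package.
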