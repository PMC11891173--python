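# Methods

## Scope and model overview

`paleodup` implements the computational core of a phylogenomic conflict
analysis: (i) detection and dating of whole-genome duplications (WGD)
from dated, paralog-bearing gene-family trees; (ii) testing whether
gene-tree/species-tree discordance is explained by incomplete lineage
sorting (ILS) alone; (iii) separating ILS from gene flow with a
per-triplet branch-length mixture; (iv) filtering and clade-level
aggregation of four-taxon hybridization-test (HyDe-style) tables; and
(v) a synthetic-data layer that generates every input with known ground
truth. Upstream steps of a real study — read assembly, orthology
clustering, alignment, tree inference, molecular dating — are external;
this package consumes their output formats (Newick, Proteinortho-style
TSV, FASTA alignments, HyDe TSV).

## WGD detection from paralog origin times

*Duplication labeling.* With leaves labeled `sample|copy`, an internal
node is a duplication if at least two of its child subtrees share a
sample (species-overlap rule). This is reconciliation-free: it needs no
gene-loss model, at the cost of missing duplications whose daughters
were asymmetrically lost. Unrooted inputs (basal polytomies) are
rejected because the overlap rule presumes a rooted direction of time.

*Record extraction.* A duplication node of age t contributes one record
(sample, t) per sample present in ≥ 2 of its child subtrees. A
clade-wide WGD therefore appears in every descendant sample's
distribution — the per-sample view that peak merging later exploits.
Records below `min_age` (default 1 My) are discarded: in real data that
age band is dominated by assembly isoforms and tandem artifacts.

*Dating input.* Gene-family trees must be ultrametric; dating itself is
out of scope. `rescale_to_root_age` linearly rescales a near-clock tree
(relative tolerance 0.05) to a fixed root age and renormalizes leaf
depths to zero; anything beyond that tolerance is sent back to external
rate-aware dating.

*Mixture dating.* Per-sample age sets with ≥ `min_records` (10) entries
are fitted with 1-D Gaussian mixtures, k = 1..6, five EM restarts with a
fixed seed (`sklearn.mixture.GaussianMixture`, `reg_covar` 1e-6 so that
zero-variance synthetic clusters stay fittable); k minimizes BIC, ties
toward smaller k. A component is a candidate peak when its weight
≥ `min_weight` (0.10), its σ ≤ `max_sd` (15 My), and its
hard-assignment support ≥ `min_peak_support` (15 records). The support
floor matters: a single deep duplication in one family produces one
same-aged record in every spanned sample — up to one record per sample
per family — so per-sample clusters of 2–3 records from a handful of
families can mimic small peaks across many samples. A genome-wide event
recruits hundreds of families; fifteen records per sample is a
deliberately mild version of that expectation.

*Peak merging and branch assignment.* Candidate peaks sorted by mean are
chained single-linkage with gap ≤ `merge_window` (5 My). A merged
group's supporting sample set is compared with the chronogram's clades:
an exact match assigns the event to that clade's stem branch
(single-sample groups to the terminal branch); otherwise the event falls
back to the MRCA branch of the supporting set, flagged `approximate`.
The event age is the support-weighted mean of member peak means; a call
whose age falls outside its branch's age interval carries an
`age_branch_conflict` flag rather than being silently moved.

## Discordance machinery

*RF distance.* Unrooted Robinson–Foulds distance after restriction to
the two trees' shared leaf set (≥ 4 leaves required), computed as the
symmetric difference of canonical non-trivial bipartition sets (each
bipartition represented by the side not containing the lexicographically
smallest shared taxon). Tests verify equality with both an explicit
bipartition-pair enumeration and dendropy's `symmetric_difference`.

*Chi-square comparison.* Expected counts are simulated proportions ×
empirical n over the union of observed distance values; adjacent bins
are pooled left-to-right until every expected count is ≥ 5 (Cochran),
the leftover tail merging into the last closed bin; df = bins − 1. The
statistic is inflated by a factor ≈ (1 + n_emp/n_sim) because expected
proportions are themselves estimated; with n_sim ≥ 10 × n_emp the
inflation is within a few percent, and the type-I error at α = 0.05
measures 0.085 over 200 null replicates (within the 0.02–0.10
calibration band the tests assert).

*Concordance counts.* For each species-tree bipartition restricted to a
gene tree's taxa: concordant if the gene tree contains the restricted
bipartition, conflicting if it contains an incompatible one (pairwise
compatibility: some intersection of sides is empty), else
uninformative — the PhyParts trichotomy. Percentages are reported to one
decimal, matching the convention of worked examples like 105/114 = 92.1%.

## Contained coalescent simulator

Gene trees are sampled one allele per species inside the species tree's
branches: k lineages in a branch coalesce at rate k(k−1)/2 per
coalescent unit (2N generations), survivors merging without bound above
the root. Node times use the species tree's age coordinate (max
root-to-leaf path below a node), which is exact for the ultrametric
coalescent trees generated here. Closed-form checks anchor correctness:
each discordant rooted-triplet topology has probability (1/3)e^(−t) for
internal branch t, verified at t ∈ {0.25, 0.5, 1, 2} within binomial
99% confidence at n = 20,000. No migration or population-size change is
modeled.

## Triplet branch-length mixture

For a triplet's topology class, internal branch lengths x ≥ 0 follow
either a pure exponential (ILS) or the two-component mixture
π₁·λe^(−λx) + π₂·λe^(−λ(x−c))·1[x ≥ c], the components sharing λ — the
shifted component modeling branches created by an actual bifurcation or
gene-flow event at depth c. π and λ have closed-form EM updates. The
shift moves by a damped line step, scale factor `grad_ascent_scalar`
(0.5): the smooth part of ∂ℓ/∂c is λ·Σr₂ ≥ 0, so ascent is upward-only,
capped where crossing a data point costs more than the e^(λΔc) gain;
the step is accepted only if the observed log-likelihood does not drop,
keeping the whole iteration monotone (asserted each step). Iteration
stops after `num_steps` (50) or when the improvement falls below
`likelihood_thresh` (0.01).

Because the shift only climbs, restarts bracket it from below:
deterministic starts at the 25th, 50th and 75th percentiles of the data
(π₂ = 0.5, λ = 1/mean). Restart selection uses a parsimony rule: fits
whose log-likelihoods differ by less than ln n — the BIC allowance of
the mixture's two extra parameters — are indistinguishable at
model-selection resolution, and among those the smallest π₂ wins. On
pure-exponential data the likelihood surface is a ridge (π₂ → 0 and
c → 0 describe the same density), and this rule attributes the
unidentifiable share to ILS instead of reporting a ridge artifact.
BIC₁ uses 1 free parameter (λ), BIC₂ uses 3 (π₂, λ, c);
ΔBIC = BIC₂ − BIC₁ < −30 flags significant non-ILS signal. The
gene-flow heat map averages π₂ over passing discordant topology classes
per cherry pair; units of λ and c follow the input branch lengths
(results are unit-covariant, no conversion is applied).

## HyDe filtering and block aggregation

Records are kept under the strict rule 0 < γ < 1, p < 0.05, Z > 1
(the permissive Z cut is kept as the field's printed default). Blocks:
records sharing a donor (P2) merge greedily in input order when the
pooled recipients stay monophyletic in the reference tree and every γ
lies within `gamma_window` (0.10) of the running mean; a fixpoint pass
then unions same-donor groups whose combined recipients form a larger
clade, and a final pass joins blocks with identical recipients whose
donors themselves form a clade (flagged `ancestral_donor`). Every input
record lands in exactly one block; a block's γ is the arithmetic mean of
its members.

## Synthetic-data generators

*Reference chronogram.* Seventeen ingroup taxa in five monophyletic
family clades, crown age 107.9 Mya, family stems in the Cretaceous.
Only the crown age and the qualitative branching order are anchored to
published estimates; the remaining internal ages are fixed plausible
values chosen once so that every branch used for WGD pulses (the two
family stems pulsed at 80 Mya, the Triuridaceae-like stem at 40 Mya,
and the two Velloziaceae-like subtending branches at 26 and 24 Mya)
spans its pulse time. Tests depend on clade structure and the crown
age, not on the invented ages.

*Gene-family simulator.* A single ancestral gene enters at the crown;
along each species-tree branch every gene lineage independently
duplicates at rate λ_dup and dies at rate μ_loss (continuous-time,
Gillespie-style, rates per lineage per My); at a WGD pulse each lineage
alive on that branch duplicates with probability ρ (independent
retention mimics fractionation and controls peak sharpness); speciation
copies all survivors into both daughters; extinct subtrees are pruned
and single-child nodes collapsed. Copies are numbered `sample|k` in
left-to-right traversal order. The default study condition for recovery
experiments is one pulse at 80 Mya with ρ = 0.8, λ_dup = 5e-4/My,
μ_loss = 0, 300 families — enough background duplication to be
non-trivial while keeping families small. With ρ = 1 and zero
background rates, copy number per clade member is exactly 2^(pulses on
its path) and every duplication age equals its pulse time, which the
tests assert exactly.

*Reproducibility.* One root seed; per-family substreams are
`default_rng([seed, family_index])` (string ids hashed by CRC32), so any
family regenerates independently and all output is bit-identical under a
fixed seed.

*What the generators do not emulate.* No sequence-level evolution, so
no gene-tree estimation error: paralog ages are exact, and recovered WGD
ages in tests are tighter than real data would allow (the ±8 My
tolerance absorbs mixture and merging error only). No dating
uncertainty, no missing taxa unless simulated by loss, no migration in
the coalescent. Passing tests therefore demonstrate correctness of the
inference machinery, not robustness to estimation noise.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to exercise the asymptotics
while staying desk-scale: 300 families × 20 replicates for WGD
recovery; 20,000 gene trees per triplet check; 200 null replicates with
114 empirical vs 2,000 simulated trees on an 8-taxon tree for chi-square
calibration; n = 1,000 samples and 100 replicates for the mixture
suite. Ultrametricity tolerances: 1e-6 (relative) for simulated trees,
1e-3 for externally dated gene trees, 0.05 for the rescaling contract.
GMM determinism comes from sorting input ages and fixing the restart
seed; BIC ties break toward fewer components. Degenerate inputs are
signalled, not guessed at: all-zero branch lengths, < 10 duplication
ages, fewer than two chi-square bins after pooling, triplets absent from
all gene trees.

## Known limitations

The species-overlap rule undercounts duplications under heavy loss;
peak merging assumes pulse-like WGDs (a protracted event spreads
support across the merge window); the mixture's shared-λ assumption is
a modeling choice the data cannot always distinguish from separate
rates; chi-square calibration assumes the simulated tree count well
exceeds the empirical one; and the HyDe aggregation rule is a
formalization of a visual convention, so its grouping on borderline γ
patterns depends on record order.
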