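# Methods

## Substitution model and likelihood

All sequence computation uses a reversible amino-acid model (S, π, α, K):
symmetric exchangeabilities S, equilibrium frequencies π, gamma shape α and
K equal-probability discrete rate categories. The generator matrix is
q_ij = S_ij π_j (i ≠ j), diagonal closing rows, rescaled so that
−Σ_i π_i q_ii = 1, i.e. branch lengths are expected replacements per site.
The default empirical model is LG (bundled as a PAML dat-style file, state
order A R N D C Q E G H I L K M F P S T W Y V); a Poisson model (uniform
everything) and models over reduced alphabets exist for controlled tests.
Transition matrices come from the symmetric eigendecomposition of
D^{1/2} Q D^{-1/2}; tiny negative entries from round-off are clipped and
rows renormalized, and t = 0 returns the exact identity so that impossible
configurations at zero branch length produce the −∞ log-likelihood sentinel
rather than a rounding artifact.

Discrete-gamma category rates are the **mean of each quantile bin** of
Gamma(α, mean 1) (not the median), computed via the incomplete-gamma
identity and renormalized to mean exactly 1. α defaults to 1.0 with K = 4
categories, the standard "+G4" configuration.

Gaps and unknown residues are missing data: their partial vectors are all
ones. Per-node scaling protects long alignments from underflow. Site rates
are posterior means over categories (equal priors, weights ∝ per-category
column likelihood); an all-gap column carries no signal, its posterior
equals the prior, and it is flagged.

## Column filters

Two filters mirror common practice for deep phylogenies: columns with
strictly more than 20% gaps are dropped after family alignment, and
fast-evolving columns are removed in steps of 10% of sites ranked by the
posterior mean rate. Rates are estimated **once** on the full alignment and
removal is cumulative across steps (no re-estimation between steps); ties
are broken by removing the lower column index first. A flag re-estimates
rates between steps for users who prefer that convention — the two differ
only when removal changes the rate ranking.

## Distance trees

Gene trees are inferred at desk scale by pairwise maximum-likelihood
distances (two-sequence likelihood under the full gamma mixture, maximized
over t ∈ [10⁻⁶, 10] by bounded scalar optimization; gap-containing columns
skipped) followed by neighbor joining (scikit-bio; negative branch estimates
clamped to zero) and midpoint rooting. Branch lengths are used as NJ
estimates them; no joint branch-length re-optimization is performed — a
documented limitation, adequate for topology-level checks against the truth.

## DTL reconciliation

The dated species tree is cut into time slices bounded by consecutive
internal-node ages; a branch belongs to every slice it spans. Reconciliation
is a minimum-cost dynamic program over (gene node × species branch × slice)
with event costs δ (duplication), τ (transfer), λ (loss) and free
speciations; defaults δ = 2, τ = 3, λ = 1. Transfers connect distinct
branches within one slice only (no transfers from unsampled extinct
lineages). Compound moves are speciation-loss (λ) and transfer-loss (τ + λ);
one transfer-loss relaxation per slice suffices because chains of
transfer-losses are never cheaper than a single one. Origination is fixed at
the species root — the entering lineage immediately meets the root
speciation (or loses one side) — matching the simulator's semantics, so a
congruent gene tree reconciles at cost 0 with n − 1 speciations. One optimal
scenario is backtracked with a deterministic tie-break (event order
S < D < T, then species-branch index, then child orientation). In the event
count vector a speciation-loss contributes one loss (and no speciation), a
transfer-loss one transfer plus one loss, preserving the identity
cost = δ·D + τ·T + λ·L. Note the consequence of the default costs: a
duplication-plus-loss (cost 3) ties a transfer (cost 3) and the tie-break
then prefers the duplication; analyses that want sparse true transfers
identified as transfers should set τ < δ + λ.

Conditional clade probabilities are computed from any gene-tree sample
(clade frequency = fraction of trees containing the clade; split
conditionals normalized within each clade). They serve as a support
diagnostic only — no amalgamated tree search is performed.

## Marginal ancestral reconstruction and gaps

Ancestral states are reconstructed marginally (empirical Bayes, model
parameters fixed): an inside–outside computation yields, per internal node
and column, the posterior distribution over the 20 states given all tip
data, **marginalized over the gamma categories** with their per-column
posterior weights (the per-site category is not fixed). The MAP state is
reported with its PP; ties resolve to the fixed state order and are logged.

Ancestral gaps are inferred on the binary presence/absence character of each
column by two-pass Fitch parsimony. Where the minimum-change reconstruction
leaves freedom, "present" is preferred at the root and descendants inherit
the parental state; the per-column parsimony score is returned and checked
against brute-force enumeration in the tests. An optional Dollo mode places
a single origin at the MRCA of the present leaves with losses below it.
Composition substitutes the gap symbol wherever presence is 0, regardless of
the amino-acid posterior — the final gapped ancestral sequences.

The confidence statistic is the fraction of non-gap ancestral columns with
MAP PP **strictly** greater than 0.9 (strictness chosen and fixed here;
a site at exactly 0.9 does not count).

Replacement counts between gapped sequences count columns where both
sequences are non-gap and differ; columns with a gap on either side are
excluded. (Counting gap-crossing columns would conflate indels with
replacements.)

## Synthetic data generator

The generator emulates a halobacterial unicopy-family study at desk scale;
every generator is a pure function of (parameters, seed).

- **Species trees**: forward Gillespie birth–death simulation conditioned on
  reaching n extant lineages (extinct runs restart). The present is set one
  censored waiting time after the n-th lineage appears, so the youngest
  speciation is strictly older than the leaves; extinct side branches are
  pruned. Defaults birth 1.0, death 0.5 give moderately unbalanced, realistic
  dated trees.
- **Gene histories**: one lineage enters at the species root; along each
  species branch D/T/L fire as independent Poisson processes; speciations
  bifurcate survivors. Transfers copy into a uniformly chosen contemporaneous
  other branch; an optional replacement flag kills the recipient's resident
  copies, emulating replacement by horizontal transfer. The event list
  carries lineage identifiers and replays exactly to the returned gene tree.
  DTL rates for Halobacteria are not quantified anywhere usable, so the
  defaults used in the analyses (0.05/0.1–0.15/0.1 per unit time) are
  illustrative, chosen to yield one-to-a-few events per family.
- **Sequences**: the root is drawn from π (or the halophilic bias); each
  site carries a gamma category drawn at the root and inherited; child
  states are sampled directly from rows of exp(Q r t) (exact, no
  uniformization). Indel events per branch are Poisson with rate
  indel_rate × t × current length; each event is an insertion or deletion
  with probability ½ (keeping expected length drift zero) and geometric
  length (default mean 3). Substitutions are applied before indels within a
  branch, so residues inserted on a branch do not also mutate on it. Global
  column bookkeeping keeps the true alignment exact — inserted columns never
  re-merge — so no aligner runs downstream and reconstruction error is
  isolated from alignment error. The **halophilic bias** pins the stationary
  mass of D+E to 0.22 and K+R to 0.06 (splits within each pair and the
  remaining mass proportional to the base model), giving an expected DE/KR
  around 3.7, comfortably in the >2 regime that marks halophilic MalDHs; the
  bias re-parameterizes Q so it is genuinely stationary.
- **Stability curves**: folded fraction f(c) = 1/(1 + exp(−(c − m)/w)) —
  increasing in concentration, since halophilic enzymes unfold when salt
  drops — plus truncated Gaussian noise; the generating midpoint is recorded
  as truth.

What the generator does **not** emulate: alignment uncertainty (truth
alignments are exact), site-heterogeneous (CAT-like) replacement processes,
compositional drift between lineages, structural constraints, and real
measurement error structure in stability assays. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
generating model, not robustness to these real-data complications.

## Pipeline, seeds, determinism

One master seed drives a run; stage seeds derive by a fixed counter scheme
(master × 100 + stage offset, mod 2³¹) and are recorded, so any stage can be
replayed in isolation. ASR runs on the true gene tree by default
(`asr_tree: inferred` switches to the NJ tree), separating reconstruction
error from tree error. Recovery scoring matches internal nodes by identical
descendant leaf sets; unmatched nodes are reported, never silently dropped.
Event precision/recall compares (kind, donor, recipient) multisets; losses
on fully extinct lineages are invisible to reconciliation, so recall < 1 is
expected on loss-rich histories. Two runs of the same configuration are
byte-identical; wall-clock timings stay in memory and are never written.

## Problem sizes

The bundled analyses and tests run on deliberately small instances — species
trees of 4–32 taxa, alignments of 80–357 columns, 5–10 replicates,
enumeration oracles on ≤5 leaves and ≤4-letter alphabets — sizes at which
exhaustive brute-force checks are feasible and the full suite runs in well
under a minute. The confidence analog (32 taxa × 300 columns × 5 replicates,
mean root-to-tip divergence 0.4 replacements/site) was sized to match a
single enzyme family of a 51-proteome study rather than the genome-scale
concatenation.

## Known limitations

- NJ branch lengths are not re-optimized; deep-branch length estimates are
  rough.
- Parsimony reconciliation reports one optimal scenario; co-optimal scenario
  enumeration is only practical on small trees, and no attempt is made to
  estimate DTL rates.
- The bell-shaped MgCl₂-type stability curves are handled by restricting the
  fit window to the low-concentration limb, not by a two-transition model.
- DE/KR is computed on whole sequences; solvent-accessible-surface ratios
  would need structures.
- No plotting layer: the tables are written as CSV/TSV for external tools.
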