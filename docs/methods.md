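# Methods

This note documents the probabilistic model, the estimation and search
procedures, the synthetic-data generator, and the numerical and design
choices, in enough detail to reproduce or audit any behaviour of the
package.

## Model

### Event trees and genotypes

A tumour history is a rooted tree whose nodes carry ordered event sets:
SNVs and allele-specific copy-number events (gain, loss, CNLOH) on
*regions* — gene-level units grouping the amplicons that target one gene.
Each SNV occurs exactly once; a region carries at most one CNA per
root-to-leaf lineage; a CNA may only affect an allele present in the node's
pre-event genotype; region copy numbers are capped at 3 (beyond one gain,
exact copy numbers are not identifiable from noisy targeted counts, and a
loss-then-gain on one region is invisible to depth data). SNV loss arises
implicitly — a loss or CNLOH can remove the mutated allele — giving
Dollo-style semantics without a dedicated "SNV loss" event.

Within one node, events apply SNVs-first (ties by target id), so "SNV +
CNLOH in the same node" means the mutation is acquired before the copy
event; CNLOH transfers *all* copies of the affected allele to the other
allele. Germline SNPs are ordinary SNV events placed at the root, where
they start as (1, 1).

Doublet genotypes add allele copy numbers and average region copy numbers
(a doublet has twice the genome but the same read budget, so depth
fractions mix while absolute allele counts add).

### Read-count likelihood

Per cell `j` and region `k`, conditioned on the cell's total depth `D_j`:

    D_kj ~ NB(mean = D_j · c_k ρ_k / Σ_l c_l ρ_l,  inverse dispersion θ)

with variance `m + m²/θ`. `ρ` lives on the simplex and captures amplicon
efficiency; the copy-number scaling renormalises because targeted
sequencing fixes the per-cell read budget. A region at zero copies gets a
point mass at zero depth.

Per variant `i` with genotype `(c_r, c_a)` and per-variant dropout rate
`μ_i`, the ALT count is a mixture over amplification outcomes `(k, l)`,
`0 ≤ k ≤ c_r`, `0 ≤ l ≤ c_a`, `(k, l) ≠ (0, 0)`:

    P(A | D) = Σ C(c_r,k) C(c_a,l) μ^(c−k−l) (1−μ)^(k+l) · BB(A; D, f_kl, ω_kl)
    f_kl = l/(k+l) · (1−ε) + k/(k+l) · ε
    ω_kl = ω_hom if k = 0 or l = 0, else ω_het

By default the mixture is renormalised by `1 − μ^(c_r+c_a)` so the retained
terms form a proper conditional distribution given at least one amplified
copy; `dropout_renormalize=false` reproduces the literal unnormalised sum
(which penalises high-copy genotypes slightly). Zero observed depth at a
locus contributes nothing (the model conditions on `D_ij`). A locus on a
fully deleted region — unreachable under the one-CNA-per-lineage rule, but
possible for doublet genotypes or hand-built trees — is scored as pure
sequencing error, `BB(A; D, ε, ω_hom)`: residual reads mapping there must
be explained as error rather than given probability zero.

### Marginalised tree likelihood

Cell attachments are marginalised over nodes with learned weights `π`:

    P(D, A | T) = Π_j [ (1−δ) Σ_n π_n L_j(n) + δ Σ_n Σ_n' π_n π_n' L_j(n,n') ]

Doublet attachments `(n, n')` are evaluated over unordered pairs including
self-pairs, with weights `π_n²` and `2 π_n π_n'`, which equals the ordered
double sum at half the cost. All sums use log-sum-exp.

### Tree prior

    log P(T) = − p1 · n_SNVs · n_nodes
               − (1500 + n_cells) · p2 · (n_CNA_LOH + n_CNA_no_LOH / 2)
               − Σ_{variant i off-root} (p3 + p4 · pop_freq(i))   (+ const)

CNA events of the same kind on regions adjacent in genomic order within one
node merge into one counted event (large CNAs often span whole
chromosomes); merges never cross chromosomes or kinds. A merged event is
LOH if any constituent removes the last copy of a previously present allele
or is a CNLOH. Defaults `p1=0.1, p2=0.01, p3=3, p4=20`; `p2` is the main
knob — raise it if too many CNAs are called. The additive constant is
dropped (all uses are comparative).

## Estimation

### Per-tree EM

Latent variables: the attachment of each cell and, per cell × locus, the
amplified copy counts. E-step: attachment responsibilities by Bayes rule;
dropout-outcome posteriors per admissible `(k, l)`. M-step: `π_n` is the
expected cell fraction (flat Dirichlet prior; each member of a doublet pair
is credited half a cell, a self-pair the whole cell); `μ_i` maximises the
expected complete-data log posterior under a Beta(α=2, β=38) prior (mean
0.05, strength 40). With the renormalised likelihood this objective gains a
`− Σ_c M_c log(1 − μ^c)` term and has no closed form; it is maximised by
bounded scalar optimisation on [1e-4, 0.5], guarded to never return a value
worse than the incumbent, so the procedure is a generalised EM and the
observed-data log posterior is non-decreasing — asserted at every fit, with
1e-6 internal slack for float accumulation. In the literal mode the
familiar closed form `(α−1+E[dropped])/(α+β−2+E[total])` is exact.

Cells with zero reads at a locus are excluded from that locus's dropout
update (they carry no information). A variant absent from every attached
genotype keeps its previous rate.

EM budgets: 2 iterations at tolerance 0.1 log-units inside each annealing
step (warm-started from the incumbent's parameters: μ always, π whenever
the node count is unchanged), and a final refit at 200 iterations,
tolerance 1e-4, on the best tree. The short inner budget biases each
proposal's score slightly low, identically for proposer and incumbent, and
is what makes thousands of annealing steps affordable.

### Simulated annealing

Phase 1 searches CNA-free trees. The initial tree has 3–10 nodes (uniform,
capped at n_variants+1), a topology decoded from a random Prüfer sequence,
and SNVs assigned uniformly at random. Moves (with default weights):
prune-and-reattach a subtree (0.25), swap two nodes' event sets (0.1), move
one SNV (0.25), split/merge a node (0.2), add/remove a CNA (0.15), toggle a
CNA's allele for one variant (0.05). Invalid draws are resampled (20
tries), then the move type is redrawn (10 tries). Acceptance is the
annealed Metropolis rule `min{1, exp((Δ log posterior)/T + log Hastings
ratio)}` with a geometric temperature decay from 8 to 1. The
prune-reattach, swap, move-SNV and toggle moves are symmetric (ratio 0);
add/remove-CNA ratios are computed exactly so a paired add and remove sum
to zero; the split/merge ratio is approximated as 0 — acceptable because
the chain is an annealed optimiser, not an exact posterior sampler. The
best posterior ever visited is returned (ties broken toward fewer nodes,
then fewer CNAs, then lexicographic events).

Between phases, `ρ` is estimated from root-attached cells (weighted by
their responsibilities); if the root holds under 1% of cells, all cells are
used — unbiased in a CNA-free tree where every genotype is diploid in
region space. Candidate gain/loss regions are those whose
responsibility-weighted mean of `D_kj/(D_j ρ_k)` at some node holding ≥ 1%
of cells departs from the root's mean by more than ±20% (if the root is
empty, the all-cell mean is the baseline — the ratio is invariant to the
`ρ` scale either way). Regions with `ρ_k` below 0.1 of the uniform share
`1/n_regions`, or flagged unusable, are never candidates: their depth is
too unreliable. Phase 2 restarts annealing from the phase-1 optimum with
copy-number moves enabled; gains and losses are restricted to the
candidates, while CNLOH — which leaves read depth untouched and is
identified purely through allelic imbalance — may be proposed on any
usable variant-bearing region. `ρ` stays frozen after phase 1.

Defaults: 1 chain, 2000 iterations per phase. Targeted panels give small
tree spaces (≤ ~10 SNVs), where a diversified budget (2 shorter chains,
best-of) recovers rare small subclones more reliably than one long chain;
the recovery study below uses 2 × (600 + 900).

## Synthetic data

The generator mirrors the likelihood's generative process plus the
characteristic artefacts of amplicon panels. Defaults are the reference
study conditions: 3000 cells, 30 regions, 6-node trees, 7 somatic SNVs
(+30% germline SNPs placed at the root, population frequency U(0.05, 0.5)),
3 CNAs, clone sizes Dirichlet(0.3) (the concentration estimated from real
data), non-uniform coverage. Per-cell total depth is NB with mean 40 reads
× n_regions and inverse dispersion 20; region depths are NB(θ = 6) around
the copy-scaled expectation; amplicon efficiencies are log-normal(0, σ = 1)
(an order-of-magnitude spread, as in real panels — uniform mode instead
gives every region an equal weight, making depth fractions exchangeable);
per-variant depths split region reads multinomially over amplicons;
dropout is per-copy Bernoulli(μ_i), truncated to at least one amplified
copy, with μ_i ~ N(0.05, 0.02) clipped to [0.01, 0.5]; ALT fractions are
beta-binomial with ε = 0.01, ω_hom = 50, ω_het = 15. Doublets (off by
default — the reference design treats them as a separate stressor) draw two
attachments and merge genotypes. Optional coverage correlations multiply a
random half of the regions by 1.3 in a random half of the cells before
renormalisation — a minimal mechanism for the clone-independent block
correlations seen in real panels.

Trees are sampled so that every non-root node carries at least one event,
CNAs respect all validity rules, a configurable fraction lack SNV/LOH
support (default: all supported), and — an identifiability guard — no two
nodes share a genotype (e.g. a CNLOH replacing the ALT allele of a
same-node SNV would cancel it and collapse the node onto its parent,
making the weight split between them arbitrary).

What the generator does not emulate: read-level artefacts (mapping,
strand), per-amplicon GC effects, copy numbers above 3, whole-genome
duplication, cell-cycle or ambient-DNA contamination. Passing tests
therefore demonstrate correctness of the inference under the stated noise
model and scale, not performance on any particular real dataset.

## Evaluation

Inferred nodes map to the true node with the smallest genotype Hamming
distance (per-variant allele pairs + region copy vector), ties toward the
smaller true id. Cell-assignment accuracy is the fraction of singlet cells
whose MAP node maps to their true node (doublets excluded). CNA calls are
labelled (region, kind); FNR = missed / true, FPR = spurious /
(n_regions × 3 kinds − n_true), with FNR stratified by whether the true CNA
has an SNV or LOH at or below its node. The exact 2×2 association test
reports the one-sided Fisher p, the conditional-MLE odds ratio under the
noncentral hypergeometric model and the one-sided 95% CI lower bound by
test inversion (via `scipy.stats.contingency.odds_ratio` / `fisher_exact`;
the test suite cross-checks the p-value against direct hypergeometric
enumeration).

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the simulation study at a
reduced scale chosen as the smallest at which the signal structure of the
reference design survives: 1000 cells (depth signal for a 30%-subclone
one-copy loss is ~hundreds of log-likelihood units, far above the CNA
penalty of 25), 20 replicates in the suite and 8 in the script, with 2 × 
(600 + 900) annealing iterations. EM recovery uses 1000 cells and uniform
coverage: under log-normal(σ=1) weights some variants land on near-dead
amplicons (~1 read/cell) where dropout is unidentifiable for reasons
unrelated to the estimator; non-uniform coverage is exercised end-to-end
by the recovery study instead. The null check uses 400 cells × 12 regions
× 20 runs.

## Known limitations

* **Dropout rates of weakly covered variants are information-limited.** A
  variant heterozygous in N cells contributes ~2N Bernoulli(μ) dropout
  draws; at μ = 0.08 the MAP estimate under the default prior has shrinkage
  bias −2.04/(38+2N) and sampling SD ≈ √(0.074·2N)/(38+2N) — at N ≈ 15,
  bias −0.03 and SD 0.02. Clone-size draws from Dirichlet(0.3) routinely
  produce such variants, so a blanket "±0.03 for ≥90% of variants" recovery
  claim does not hold at those study conditions (the oracle ML with known
  attachments fails it too); the corresponding acceptance test documents
  this and is expected to fail there.
* Subclones defined only by a gain or loss (no SNV or LOH at or below) are
  usually invisible to phase 1 and hence missed — the candidate-region
  design trades this sensitivity for a near-zero false-positive rate.
* The split/merge Hastings ratio is approximate (see above), so the chain
  is not a calibrated posterior sampler; only the optimum is reported.
* Phase 2 does not re-estimate `ρ` after CNAs enter the tree; a clonal CNA
  on a region therefore biases that region's weight estimate when the root
  population is below the 1% floor.
* Region order must be supplied (`order_index`); contiguity for the prior's
  event merging is not inferred from coordinates.
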