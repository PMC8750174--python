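# Methods

## Scope and model

The package implements the computational arm of an RNAi oxidative-stress
protection screen as five composable stages plus a synthetic-data generator.
Each stage consumes and produces plain text files (CSV/TSV/GMT/JSON), so any
stage can be re-run independently from prior outputs.

## Effect-size statistics

Per-siRNA protection is quantified as Cohen's d between the test siRNA's
replicate readings and the negative-control siRNA's replicates at the same
timepoint:

    d = (x̄_test − x̄_ctrl) / s_pooled,
    s_pooled² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2)

using the Bessel-corrected two-sample pooled SD. The 95% CI is the normal
approximation d ± 1.96·SE with SE = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))) — the
standard large-sample variance of d. Exact noncentral-t intervals would be
tighter at small n but the normal form is conventional for screen-scale
summaries and is monotone in d, which is all the binning consumes.

Bin boundaries are: large (0.8, ∞); medium [0.5, 0.8]; small [0.2, 0.5);
very_small [0.01, 0.2); none (−∞, 0.01). The convention keeps the customary
">0.8" and "<0.01" edges literal and makes the classification a total,
monotone step function; the ambiguous interior boundaries are closed downward
except medium's upper edge, which is closed so that d = 0.8 is "medium", not
"large". Negative d (siRNAs that reduce survival) classifies by signed value
and therefore lands in "none": the screen selects protection, and a harmful
siRNA is "no protective effect" for downstream cataloging.

Effects are computed per timepoint with no cross-timepoint pooling; repeated
measures modelling across times is out of scope here and is better served by a
mixed-effects package on the raw table.

Degenerate inputs: fewer than 2 replicates per arm raises
`InsufficientDataError`; zero pooled SD with unequal means raises
`InfiniteEffectError` (a diverging standardized difference is a signal, not a
number); zero pooled SD with equal means returns d = 0.

qPCR fold changes use 2^(−ΔΔCt) with
ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control, so
−log₂(fold change) recovers ΔΔCt to machine precision.

## Target-catalog reduction

The reduction chain is: accession-prefix whitelist (NM, NR, NP, XM, XR, XP —
the RefSeq mRNA/ncRNA/protein classes, applied to the text before the first
underscore) → per-query minimum-E-value hits with **ties retained** → Entrez
annotation join (version suffixes like ".6" stripped; rows without an Entrez
id pruned) → case-insensitive symbol deduplication keeping the minimum-E
occurrence. Ties are retained because a short query genuinely can match
several transcripts equally well, and the catalog's per-query lists are meant
to carry all of them; the unique-gene set and biotype tally count each Entrez
id once regardless of how many queries hit it.

Prefix filtering and best-hit selection commute only when no
disallowed-prefix hit holds a query's strict minimum E-value; the synthetic
generator guarantees this (decoy E-values exceed the planted best by ≥1 order
of magnitude), and the property is asserted on generator output rather than
on adversarial tables.

## PPI shell networks

Networks grow from the target set over a scored interactome (integer combined
scores in [41, 998], probability × 1000). Shell 1 holds direct interactors of
targets at score ≥ t1; shell 2 holds interactors of shell 1 at ≥ t2 (fixed at
900 by default — only very-high-confidence edges are admitted at depth 2 to
contain network size). Defaults t1 = 900 ("very high confidence") with a
relaxed variant at 700 ("high confidence"). Thresholds are inclusive.

After node selection the edge set is the **induced subgraph**: all qualifying
edges among selected nodes, including shell1–shell1 and shell2–shell2 edges
(edges touching a shell-2 node qualify at t2, edges among targets/shell-1
nodes at t1). This matches the STRING-viewer convention and makes summaries
depend only on (nodes, thresholds), not on discovery order.

Summaries count only nodes with at least one interaction; targets, flagged
genes (e.g. a supplied oxidative-stress annotation set) and the LCC are
reported as counts plus percents of that total, rounded to one decimal. The
targets-only column of a summary table is produced with shells = 0 at
t1 = 900. Duplicate unordered edge pairs collapse to their maximum score on
load. LCC ties break on the lexicographically largest sorted node list purely
for determinism.

Evidence-channel filtering of interaction sources is out of scope: the input
table is assumed pre-filtered to the evidence the analyst trusts.

## Enrichment and term clustering

Over-representation uses the hypergeometric upper tail P(X ≥ k) for an
overlap of k between the n-gene query and a K-gene set in an N-gene universe.
The universe defaults to the union of all collection genes ("all available
annotations"), and the query is intersected with the universe before testing.
BH-FDR adjustment spans all sets tested within one collection; a term is
significant below adjusted p 0.05. No gene-set size filters apply by default
(exposed as options). An "integrated" multi-knowledgebase analysis is run by
concatenating collections into one and adjusting jointly.

Note that BH-adjusted values are not a fixed point of the BH map (re-adjusting
adjusted values can inflate them); the invariant that holds, and is tested, is
that {i : adj_pᵢ ≤ α} equals the classic step-up rejection set at α.

Significant terms are grouped ClueGO-style. The membership universe for kappa
is the union of genes of all significant terms; for terms A, B the 2×2 joint
membership table gives κ = (p_o − p_e)/(1 − p_e). Identical memberships are
assigned κ = 1 directly, since the 2×2 table degenerates (p_e = 1) when both
sets span the whole reference; `kappa_score` itself signals that case as
undefined. Each term seeds a candidate group of itself plus all terms with
κ ≥ 0.5; groups sharing more than 50% of the smaller group's terms merge
iteratively to a fixed point (the ">50% shared terms" rule follows ClueGO's
documented default; the comparison base — the smaller group — makes merging
insensitive to seed-group size asymmetry). The leading term is the member
with minimum adjusted p, ties broken by lexicographically smaller set id.
All intermediate orderings are sorted, so grouping is independent of input
order. "GO terms fusion" is not implemented.

## Drug mining

Both dialects normalize to (drug_id, name, status, gene, source) with status
in {approved, patented, other}; known development-stage tokens
(investigational, experimental, withdrawn, …) map to "other" silently,
genuinely unknown tokens map to "other" with a warning. Within one database,
intersections use drug ids (name variants for salts/formulations would
collide); across databases, where code systems differ, identity is by
normalized name (lowercased, trimmed, internal whitespace collapsed), one
pairing per name. The packaged demo fixture uses real approved-drug names and
codes with synthetic gene assignments; its within-database intersection is
taken over approved drugs, matching the convention of reporting "common
approved drugs".

## Synthetic data: what it emulates and what it does not

The generator plants, per input kind: standardized viability differences
(cycling through bin-center values (1.2, 0.65, 0.35, 0.1, 0.0)); one best-hit
gene per query with rule-violating decoys; internally connected interactome
modules at the top score tier with sparse low-score background pairs; one
gene set with a controlled query overlap; and exact drug-overlap counts.
Identical seeds give byte-identical files.

Viability noise is Gaussian and homoscedastic across conditions and
timepoints — the simplest model under which Cohen's d is the planted
parameter. Real resazurin readings are heteroscedastic, temporally
autocorrelated, and plate-position biased; passing recovery tests on this
generator therefore validates the statistical machinery, not robustness to
assay artifacts. Test siRNA means are 100 + d·σ with noise SD σ, so the
planted d is scale-free. σ = 0 selects a deterministic limit: replicate
deviates with exactly zero sample mean and unit sample SD around means 100
and 100 + d, making the estimated d equal the planted d exactly (a literal
zero-variance limit would leave the standardized difference undefined, and
for σ > 0 the sampling distribution of d̂ is invariant to σ, so no continuous
limit exists).

A practical consequence of sharing one negative-control arm across all
siRNAs: the control's standardized mean error (SD 1/√n) shifts every estimate
coherently, and the d = 0 bin is separated from "very small" by only 0.01, so
exact bin recovery for null siRNAs remains noisy even at thousands of
replicates per arm. The four non-null bins recover essentially perfectly at
n = 2000, which is the problem size the acceptance script uses (chosen from a
normal-theory power analysis of the 0.01 boundary); at the screen's own
geometry of 4 replicates per arm, bin assignments are coarse summaries, not
reliable per-siRNA calls.

E-values are drawn log-uniformly in [1e-30, 1e-2]; decoys exceed the planted
best by 1–6 orders of magnitude, so no ties arise and catalog recovery is
exact for any seed, decoy count, or biotype mix. Accessions follow the
`PREFIX_######.#` shape; parsers ignore the version suffix. Interactome
modules are connected by a random spanning tree plus density-p_within extras
(p_within = 0 suppresses module edges entirely, so no component exceeds a
background pair); no sequence-level or evidence-channel structure is
simulated. Drug tables plant the two intersection counts disjointly
(cross-database drugs target list-A genes only) so the planted counts are
exact by construction.

## Pipeline

`run_pipeline` validates the configuration (reporting every violation, not
just the first), fills the default thresholds 900/900/700/0.05/0.5, requires
an explicit seed in simulation blocks (no wall-clock seeding), runs the five
stages, and writes a manifest with a SHA-256 of the normalized configuration
and of every output file. Stage failures abort with the failing stage named;
partial outputs are retained. The CLI (`oxscreen`) is a thin wrapper: all
logic lives in the library modules.

## Problem sizes

The default test and acceptance runs use deliberately small instances —
tens of genes per module, hundreds of universe genes, 20 seeds for closure
checks — because every closure property asserted (exact catalog, exact LCC,
exact drug counts, planted-set significance) is size-independent by
construction; the effect-bin recovery run uses 181 siRNAs at 2000 replicates
per arm as discussed above.

## Known limitations

- No mixed-effects repeated-measures modelling across timepoints.
- No BLAST execution, live annotation retrieval, or STRING/DrugBank/TTD
  parsing of native formats; generic tabular dialects stand in.
- No GO DAG propagation before enrichment; collections are taken as given.
- Kappa grouping reproduces the documented ClueGO defaults only; fusion of
  related GO terms is not implemented.
- Absolute published network/drug counts depend on specific database releases
  and are not reproducible from synthetic inputs; only release-independent
  arithmetic and recovery properties are asserted.
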