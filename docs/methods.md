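# Methods

This note documents the models and procedures implemented in `bcrcsf`,
the assumptions behind them, the defaults and why they were chosen, and
what the bundled simulator does and does not emulate.

## The scientific setting

In autoantibody-mediated encephalitis (LGI1- and CASPR2-antibody disease),
antibody-secreting cells (ASCs) in the cerebrospinal fluid secrete
autoantibodies close to their target organ. Two questions drive the
analyses here: whether clonally expanded CSF B-lineage cells are enriched
for autoantigen reactivity, and whether their affinity maturation happened
peripherally (before CNS entry, presumably in germinal centers) or
intrathecally. Both are answered from sequence alone: the first by
clone-size-stratified reactivity rates, the second by comparing each
clone's inferred naive ancestor (UCA) with its least-mutated observed
member (the founder) and with its most diverged member.

## Clonal inference

**Germline assignment.** Each chain is aligned, ungapped, against every
V and J segment of its locus at all sliding offsets; the call maximizing
identity (matches / segment length) wins, with ties broken by
lexicographically smallest segment id so results are deterministic.
Chains where either call falls below 50% identity are flagged and
excluded rather than gap-aligned: under a substitution-only mutation
model the ungapped alignment is exact, and sequences violating it are
more likely assembly artefacts than real chains. Alignment ends are
clipped back to the nearest run of 4 consecutive matches, so
exonuclease-trimmed segment ends and N-region overhangs are not reported
as templated positions. D segments are not aligned: the junction interior
between the V end and the J start is short, highly trimmed and flanked by
random insertions, and mis-assigned D templates would corrupt the UCA
(reverting positions toward the wrong template). All junction-interior
positions are therefore treated as untemplated, which also matches how
the reversion handles N regions.

**Clone definition.** Cells are partitioned by heavy-chain V gene, J gene
(allele suffixes `*01` stripped — the gene, not the allele, defines the
clone) and junction nucleotide length; within a partition, single-linkage
clustering joins two cells when their junction Hamming distance is
strictly below 6 nucleotides. The threshold is strict: distance exactly 6
does not link. The distance is computed on nucleotides by default (the
Immcantation convention); `junction_on="aa"` switches to amino acids.
Single linkage over a fixed threshold equals connected components of the
thresholded distance graph, which the test suite verifies against an
independent graph-based oracle. Clone ids are content-addressed (hash of
the sorted member ids), making the output invariant to input order.

**Founder.** The member with the fewest mutations; by default mutations
are counted on heavy plus light chain (both counted against their
germline templates over the templated position map). Ties break to the
lexicographically smallest cell id.

**TCR clones.** T-cell receptors do not hypermutate, so TCR clones are
defined by identical junction nucleotide sequences across all recovered
chains. The clonality fraction is the share of cells lying in clones of
size ≥ 2.

## UCA reconstruction

The unmutated common ancestor of a chain is rebuilt by germline
reversion. For every templated position where the observed base differs
from its germline template:

- `revert_all` restores the germline base (the conventional UCA
  definition; under substitution-only mutation it exactly recovers the
  naive sequence on templated positions, which the simulator verifies).
- `revert_nonsilent` (default) restores it only when the substitution
  changes the encoded amino acid in the observed reading frame. This
  leaves silent mutations in the "UCA"; it is kept as the default because
  it is the more conservative reversion when the reverted construct is to
  be re-expressed, and both modes are tested.

N-region positions are never modified. When a position's codon carries
several mutations, reverting one base can change whether its neighbours
are silent, so `revert_nonsilent` iterates passes until a fixed point;
the iteration is monotone toward germline and therefore terminates, and
it makes the reversion idempotent. The N-region mask comes from
annotation/simulation truth when present; otherwise positions outside the
V/J position map are simply never touched, which has the same effect.

UCA accuracy is defined and measured over germline-templated positions
(the assignment's position map): N insertions carry no template at all,
and D-proximal junction positions are deliberately not templated (above),
so no reconstruction claim is made there.

## Compartment contrast

Per clone with founder f and UCA u:

    d_peripheral  = d(u, f)
    d_intrathecal = max over members m of d(f, m)

where d is the normalized Hamming distance (mismatches / length) on the
heavy chain. This proxies phylogenetic sequence distances: orderings and
contrasts are meaningful, absolute values are on a different scale than
codon-model distances, so conclusions are drawn from the paired contrast,
never from magnitudes. The paired two-sided Wilcoxon signed-rank test is
run across clones (overall, and stratified into < 4 versus ≥ 4 members);
when every pair of distances is equal the test is undefined and reported
as NaN. Singleton clones have d_intrathecal = 0 by construction.

## Specificity enrichment

Reactivity is a clone-level property (clone members empirically share
reactivities), so one tested member labels its whole clone; conflicting
tested labels within a clone raise an error rather than being averaged.
Post-propagation rates are reported per clone-size category — singletons,
small (2–3 members), large (≥ 4) — over tested cells only; an empty
category reports an absent rate, not zero.

The **adjusted rate** extrapolates the observed singleton rate r to the
n_u untested singletons:

    adjusted = (n_reactive + r · n_u) / (n_tested + n_u)

This formula is this package's explicit reconstruction of the "adjusted"
presentation of such data (the adjustment is stated here precisely
because conventions vary); it is monotone in r and bounded between the
unadjusted rate and r. Adjusted rates are reported pooled and per donor
(each donor's own singleton rate applied to that donor's untested
singletons).

The overall size–reactivity association is tested by Fisher exact on the
singleton-versus-clonal collapse of the category table: the exact test
implemented here is 2×2, and collapsing to "expanded vs not" is the
hypothesis of interest.

**Fisher exact test.** Two-sided p by full hypergeometric enumeration:
the sum of point probabilities of all tables with the observed margins
whose probability is ≤ that of the observed table (the
"minimum-likelihood" rule, the most common two-sided convention), with
relative tolerance 1e-7 on the ≤ comparison to absorb floating-point
noise. When every table qualifies the p-value is exactly 1. The test
suite checks agreement with an independent integer-arithmetic enumeration
oracle to 1e-9 on all tables with margins ≤ 12, and with scipy's
implementation on random larger tables.

**Other statistics.** The antibody index AI = (autoantibody CSF/serum) /
(total IgG CSF/serum) flags intrathecal synthesis strictly above 4; it is
invariant to rescaling both autoantibody measurements by a common factor.
CDR3 charge counts K/R as +1, D/E as −1 and H as 0 (configurable to 0.1),
matching the integer medians conventionally reported. The
mutations-vs-affinity analysis takes one cell per clone (the founder),
computes Spearman rank correlation between total heavy+light mutations
and log10 endpoint concentration, and reports not-applicable on constant
inputs. Closest-identity search compares concatenated heavy-CDR amino
acid strings against a reference set over equal-length pairs only and
flags "private" receptors strictly below 80% identity; the reference set
is pluggable (a synthetic generator ships for tests — no external
database is bundled).

**Subclass switching.** Class-switch recombination deletes DNA, so
switching only moves downstream on IGHG3 < IGHG1 < IGHG2 < IGHG4. Clones
are summarized by the number of distinct subclasses expressed, and a
violation is flagged when a member's subclass lies upstream of its
founder's — an impossible event that indicates clonal mis-assignment or
annotation error.

## Cell states and expression

Cell states (MBC, prePB, PB, PC) are assigned by Spearman correlation of
each cell to bulk reference profiles over the 500 most variable reference
genes (at least 50 shared genes required); the label is the argmax, ties
breaking along the differentiation order MBC < prePB < PB < PC, and cells
with undefined correlations are "unknown". This is the nearest-reference
core of correlation-based classifiers without iterative fine-tuning — an
approximation that is rank-based and hence invariant to monotone per-cell
transformations. XBP1 positivity is expression strictly above 0 on the
log-normalized scale.

The differential-expression screen is deliberately minimal and fully
reproducible: per donor, group means with pseudocount 1, fold change
reactive/unreactive, and an "up-regulated" set of genes exceeding the
fold threshold (default 100) in every donor and never below 1 in any.
Donors missing a group are dropped with a warning; at least two usable
donors are required. No covariate model is fitted; the screen is labelled
as such in reports.

## The simulator

`simulate_repertoire` emulates the statistical structure the analyses
assume, with full ground truth per cell:

| parameter | default | meaning |
|---|---|---|
| `n_clones` | 200 | clones drawn; with the size weights below this yields ≈ 380 cells, the scale of a deeply sampled CSF repertoire |
| `clone_size_weights` | 1: 0.60, 2: 0.16, 3: 0.10, 4: 0.05, 5: 0.04, 6: 0.02, 7: 0.02, 8: 0.01 | singleton-dominated size distribution, max 8 |
| `mu_peripheral` | 0.05 /site | germline → founder substitution rate (peripheral load) |
| `mu_intrathecal` | 0.002 /site | per-branch substitution rate inside the clone tree |
| `n_insertion_mean` | 4 nt | Poisson mean of N-insertion length per junction side |
| `trim_max` | 3 nt | max exonuclease trimming per segment end |
| `p_reactive_by_size` | 0.6 / 0.8 / 1.0 | clone-level reactivity probability per size category |
| `state_weights` | MBC 0.10, prePB 0.04, PB 0.60, PC 0.26 | ASC-dominated cell-state mix |
| `subclass_start_weights` | G3 0.05, G1 0.30, G2 0.05, G4 0.60 | IgG4-skewed starting subclass |
| `p_switch` | 0.10 | per-cell probability of one further downstream switch |
| `p_test_singleton` | 0.5 | fraction of singletons carrying a tested label |

Mechanics: one naive ancestor per clone is recombined as trimmed V + N1 +
trimmed D + N2 + trimmed J (light chains: V + N + J), with N1 padded so
the junction stays in frame; the founder is the naive mutated at
`mu_peripheral`; members grow along a random branching tree with
`mu_intrathecal` per branch, the founder itself being member 0. Subclass
switches are drawn per cell and inherited by descendants, so switching is
downstream-only along every lineage. Reactive tested cells get endpoint
concentrations log10 c = 1.5 − 0.06 · (total mutations) + N(0, 0.25)
µg/mL, so binding strength rises with mutation load and the Spearman
analysis has signal to recover. Identical seeds give byte-identical AIRR
output.

Two deliberate simplifications: (1) **substitution-only SHM** — no
indels, no hotspot (WRCY) targeting, no selection; this matches the
assumption of the reversion algorithm and means tests establish
correctness under that model, not robustness to indels. (2) **clone
separation** — a new clone whose founder junction lies within Hamming 10
of an existing same-V/J/length clone is redrawn, so distinct simulated
clones are identifiable by the < 6 rule; real repertoires can contain
coincidentally similar junctions, where clonal inference is inherently
ambiguous. The toy germline library is synthetic (random coding DNA with
correctly placed conserved anchor codons), not real IMGT segments; tests
never require a germline download.

Consequently, passing tests demonstrate that the inference chain is
correct under its own model assumptions and recovers known parameters;
they do not certify behaviour on indel-containing, hotspot-biased or
selection-shaped real data.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; FASTA headers for
  germline segments use the pipe dialect `id|locus|type|anchor`.
- Marker positivity gates use per-marker thresholds (default 0.5 on a
  normalized 0–1 scale); the gate definitions are rules over positivity,
  thresholds are data-dependent and therefore configurable.
- Cells with more than one heavy chain are excluded on read (logged);
  cells without a light chain are kept for heavy-only analyses and
  dropped by the `paired_only` flag where complete pairs are required.
- All tie-breaks (segment calls, founder selection, classification
  labels) are deterministic and documented at the point of use.
- The statsmodels-style `RepertoireAnalysis.fit() -> RepertoireResults`
  surface wraps the function modules; every operation is also usable
  directly.

## Limitations

- No gapped alignment: indel-containing chains fail the identity floor
  and are excluded rather than rescued.
- The UCA leaves junction-interior (N/D) positions as observed; claims
  about naive-state binding based on reverted constructs inherit this
  uncertainty, as any reversion approach does.
- Normalized Hamming distances are not calibrated to codon-model
  phylogenetic distances; only contrasts are interpreted.
- The cell-state classifier omits fine-tuning iterations and will blur
  states whose reference profiles differ only in a few genes.
- The pseudobulk screen has no dispersion model; it is a screen, not a
  test, and is reported as such.
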