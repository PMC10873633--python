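# bcrcsf

Analysis of B-cell-receptor (BCR) repertoires from cerebrospinal fluid
(CSF), built around the questions raised by autoantibody-mediated
encephalitis (LGI1- and CASPR2-antibody disease): *where do the
autoantigen-reactive B cells mature — in the periphery or inside the CNS —
and how strongly does clonal expansion in the CSF predict autoantigen
specificity?*

The package is aimed at computational immunologists working with paired
heavy/light single-cell BCR data (AIRR Rearrangement TSVs). It provides:

- **Clonal inference** — cells share a clone when their heavy chains use
  the same V and J gene (allele-stripped), have identical junction length,
  and their junction nucleotide sequences fall within Hamming distance
  < 6 under single-linkage clustering. The clone **founder** is the member
  with the fewest somatic mutations.
- **UCA reconstruction** — the unmutated common ancestor of a chain is
  obtained by germline reversion: templated positions that differ from the
  best-matching germline V/J segment are backmutated (by default only when
  the substitution is nonsilent); non-templated N-region positions are
  never modified.
- **Compartment contrast** — per clone, the normalized Hamming distance
  d_peripheral = d(UCA, founder) is compared against
  d_intrathecal = max over members of d(founder, member) with a paired
  two-sided Wilcoxon signed-rank test. Peripheral maturation appears as
  d_peripheral ≫ d_intrathecal.
- **Specificity enrichment** — clone-level reactivity propagation,
  reactive rates stratified by clone size (singletons / 2–3 / ≥4 members),
  an adjusted rate extrapolating the singleton rate to untested
  singletons, and a two-sided Fisher exact test computed by full
  hypergeometric enumeration (point-probability rule).
- **Supporting statistics** — intrathecal antibody index
  AI = (auto CSF/serum)/(IgG CSF/serum) with the AI > 4 flag, IgG4:IgG
  ratios, IgG subclass-switch accounting on the genomic order
  IGHG3 < IGHG1 < IGHG2 < IGHG4, CDR3 length/charge features, a
  mutations-vs-endpoint-concentration Spearman correlation, closest-identity
  ("privacy") search against a CDR reference set, FACS-style phenotype
  gating, reference-correlation cell-state classification (MBC / prePB /
  PB / PC) and a per-donor pseudobulk fold-change screen.
- **A ground-truthed simulator** — a V(D)J recombination and somatic
  hypermutation generator (substitution-only) whose defaults emulate a
  clonally expanded IgG CSF repertoire: heavy germline→founder (peripheral)
  mutation loads versus light intraclonal (intrathecal) ones, reactivity
  probabilities rising with clone size (0.6 → 0.8 → 1.0), downstream-only
  subclass switching, ASC-dominated cell states, and binding strength
  increasing with mutation count. Every cell carries full truth (naive
  sequence, N-region mask, clone id, mutation counts) so all inference
  steps are testable against ground truth.

## Worked example

```python
import bcrcsf as b

library = b.toy_library()                      # bundled synthetic germline segments
cells, truth = b.simulate_repertoire(library, b.SimConfig(seed=42))

model = b.RepertoireAnalysis(cells, library)   # statsmodels-style: model -> fit -> results
results = model.fit()
print(results.summary())
```

prints

```
              Repertoire Analysis Results
==========================================================
Cells analysed:            372
Clones:                    200  (clonality fraction 0.669)

Specificity by clone size (post-propagation)
----------------------------------------------------------
  singletons   reactive   36/59    61.0%
  2-3 members  reactive  121/135   89.6%
  >=4 members  reactive  114/114  100.0%
  adjusted (pooled):       83.3%
  singleton-vs-clonal Fisher p = 4.84e-10

Compartment contrast (normalized heavy-chain distance)
----------------------------------------------------------
  median UCA->founder (peripheral):    0.0323
  median founder->furthest (CNS):      0.0000
  paired Wilcoxon p:                   1.43e-34

Subclass switching
----------------------------------------------------------
  clones with one subclass:  197
  clones with two:           3
  clones with more than two: 0
  order violations:          0

Mutations vs endpoint concentration (founders)
----------------------------------------------------------
  Spearman rho = -0.676  (p = 1.21e-09, n = 63)
==========================================================
```

Reading the output: the simulated repertoire was generated with a
reactivity gradient of 60/80/100% across size categories, a large
peripheral mutation rate and a small intrathecal one, and affinity tied to
mutation count — and the fitted results recover exactly that structure:
reactive rates rising to 100% in expanded clones, a peripheral median
distance far above the intrathecal one (p ≈ 1e-34), no upstream subclass
switches, and a clearly negative mutations-vs-endpoint-concentration
correlation (stronger binding with more mutations).

The same pipeline runs from the shell:

```bash
bcrcsf simulate --seed 42 --out rep.tsv --truth truth.tsv \
    --germline lib.fasta --metadata meta.csv
bcrcsf clone    --airr rep.tsv --germline lib.fasta --out clones.tsv
bcrcsf contrast --airr rep.tsv --germline lib.fasta --out contrast.tsv
bcrcsf enrich   --airr rep.tsv --germline lib.fasta --metadata meta.csv
```

`docs/methods.md` documents the model, its assumptions, all defaults, and
known limitations.

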