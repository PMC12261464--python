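# Methods

## The model

A cell's functional profile is the row of `F = C · B`, where `C` is the
cell×gene count matrix and `B` the binary gene×GO-BP indicator built from
the species' annotations. The entry `F[c, t]` sums the counts of all
genes annotated to term `t`, so it scales with both the activity of the
process and the cell's sequencing depth; the depth dependence is removed
by per-cell total normalization. The modelling assumption is that cell
types performing the same biological program distribute their expression
over terms similarly even when the contributing genes differ between
species — which is what makes the term space, unlike the gene space, a
valid common coordinate system for arbitrarily distant species.

Only direct annotations are used when building `B` (no true-path
propagation up the DAG, available behind `propagate_ancestors=True`).
Propagation concentrates signal in broad high-level terms; using the
annotations as provided, combined with per-term z-scaling, keeps broad
terms from dominating: a term active in every cell has low variance and
therefore small scaled values. Records whose term is absent from the
supplied ontology are dropped with a logged count at matrix build
(annotation exports routinely lag or lead the ontology release);
unresolvable ids passed to the traversal operations themselves raise.

## Hierarchy handling

Three mechanisms address the GO's hierarchical redundancy:

1. **Scaling.** Correlations are computed on z-scaled profiles, damping
   uniformly high broad terms (above).
2. **Minimal set.** A result list keeps only its most specific members:
   a term is dropped iff another listed term is its descendant. The
   output is an antichain of the ancestor partial order.
3. **Harmonization.** Two species' term lists are represented by their
   intersection plus, for every cross-list ancestor/descendant pair, the
   ancestor — so one species' finer-grained annotation does not hide
   shared biology. Only direct ancestor/descendant pairs between the two
   lists are merged; promoting two *unrelated* terms to a deeper common
   ancestor would introduce terms neither species reported, and is
   deliberately not done.

Ancestry follows `is_a` edges by default; `part_of` can be added
explicitly, since it changes ancestor sets and should be a conscious
choice. No depth-based truncation is applied anywhere: term depth is not
comparable across branches of the ontology, so a depth cutoff would
remove information unevenly.

## Evidence codes

Twenty GAF evidence codes are recognized, in six families: experimental
(EXP, IDA, IPI, IMP, IGI, HDA, HMP, HGI), phylogenetic (IBA),
computational (ISS, ISO, ISA, ISM, RCA), author/curator (TAS, NAS, IC),
expression-pattern (IEP, HEP) and electronic (IEA). The `standard` set
drops only IEA (not manually reviewed); the `stringent` set keeps exactly
{EXP, IDA, IPI, IMP, IGI, HDA, HMP, HGI, RCA, TAS, IC} — reviewed
computational analysis (RCA) survives, other computational and
phylogenetic codes do not, NAS is dropped for lacking traceable
citations, and IEP/HEP are dropped because expression change alone cannot
distinguish a process member from a downstream event. A (gene, term)
pair survives filtering if *any* of its records does, since one pair may
carry several codes. Sources without codes (eggNOG-mapper) carry an
`IEA-like` sentinel admitted only by `all`. Unknown codes are kept under
`all` with a warning and treated as non-curated otherwise.

## Single-cell treatment

- **Normalization**: per-cell total scaled to `normalize_total`
  (default 10,000) then `ln(1+x)` — the standard library default for
  count data, making profiles depth-invariant (verified by a test that
  rescales each cell's counts by a random scalar).
- **Scaling**: per-term z-score with the sample (n−1) standard
  deviation, clipped to ±`clip` (default 10); zero-variance terms are
  set to 0 rather than NaN.
- **Variable terms**: dispersion (variance/mean of the de-logged
  normalized values) z-standardized within 20 equal-frequency
  mean-abundance bins; top `n_variable_terms` (default 2000, i.e. usually
  all terms for GO BP-sized feature spaces) with lexical tie-breaking for
  determinism. Bins with under two members fall back to unit spread so
  tiny inputs stay finite.
- **Embedding/clustering**: PCA (arpack) on variable terms, kNN graph
  (`k_neighbors=20`), UMAP, Leiden at `resolution=1.0`, all consuming the
  run seed; identical seeds give identical labels and coordinates. The
  PC embedding is computed on variable terms (standard practice); the
  choice is recorded in the config echo.

## Differential testing

One-vs-rest two-sided Wilcoxon rank-sum (Mann–Whitney) tests per group
and term, on the **normalized** layer (the per-term z-scale is monotone
per column and cannot change ranks; normalized is the layer the
field's tooling documents testing on). The historical label for this
procedure is a "Wilcoxon test"; the signed-rank variant applies to
paired data and is not meaningful for one-vs-rest groups, so the
rank-sum form is what is computed. P-values use exact enumeration when
the smaller group has ≤ 8 observations and the pooled values are
tie-free, otherwise the normal approximation with tie and continuity
corrections. With groups of ≥ 5 the approximation tracks exact
enumeration within 0.02; below that only the exact path is ever taken.
Bonferroni correction multiplies by the number of tests actually
performed in the call (groups × tested terms) — the most conservative
family. Fold change is
`log2((mean(expm1(x))_in + ε)/(mean(expm1(x))_rest + ε))` with
`ε = 1e−9`. Groups under 3 cells are skipped with a warning. A minimum
expressed-fraction filter (`min_pct`) exists but defaults to 0.

## Cross-species comparison

Profiles are restricted to the term intersection, re-z-scaled on that
subset, averaged per cell type, and correlated (Pearson) across all
cell-type pairs, using **all** shared terms (a variable-terms-only
restriction is available but not the default: the correlation is meant
to reflect the full shared functional space). Zero-variance mean vectors
produce NaN, not 0 — 0 would masquerade as "measured, no similarity".
Shared signatures attach to each harmonized representative the source
term's log2FC from each species (no re-aggregation over descendants,
which would invent values); when several sources contribute, the one
with the largest |log2FC| represents its species, and duplicate
representatives keep the row with the largest |average log2FC|. Ranking
is by |average log2FC| descending, top 10 by default.

## Synthetic data

`make_ontology` grows a rooted DAG term by term, each new term taking
1–2 parents among earlier terms (shallow parents preferred), acyclic by
construction. `make_species_pair` plants, per cell type, a set of active
leaf terms shared verbatim by the corresponding cell type of the other
species; each species then annotates its own genes (1–3 terms per gene)
over a term universe that is partly common and partly species-private
(`shared_term_fraction=0.7`), and draws counts from a negative binomial
(gamma–Poisson, dispersion `noise=2`, log-normal baseline means around
`base_mean=2`) with means multiplied by `signal_fold` (default 8) for
genes touching a cell's active terms. Gene ids are disjoint between
species by construction, so any recovered correspondence must flow
through the ontology. Default verification scale: 5 cell types × 50
cells × 300 genes per species over a 60-term ontology — small enough to
run the whole 10-seed recovery study in seconds, large enough that the
rank tests and correlations operate far from their degenerate regimes.

What the generator does *not* emulate: realistic GO topology (tens of
thousands of terms, 10+ levels), batch effects, doublets, ambient RNA,
annotation bias toward well-studied genes, or inter-species differences
in annotation depth beyond term privacy. Passing tests therefore show
the machinery is correct and the signal flows through the ontology as
designed — not that any particular pair of real atlases will map
cleanly.

## Numerical and degenerate-input choices

- Zero-variance columns scale to 0; zero-total cells are dropped (with
  logged counts), not imputed.
- All randomized steps consume one integer seed; reruns with the same
  config are byte-identical (output headers carry the tool version,
  ontology checksum and seed, not timestamps).
- Ties in variable-term ranking break lexically by term id.
- `minimal_set`/`harmonize_lists` resolve alternate ids at entry and
  raise on unknown terms rather than dropping them silently.
- Comparing profiles built against different ontology files (checksum
  mismatch) is an integrity error.

## Known limitations

- Correlation values carry no significance estimate; the method ranks
  pairs, it does not test them.
- Uneven granularity across GO BP branches is inherited from the
  ontology; nothing corrects for it beyond scaling and minimal-set
  reduction.
- The eggNOG-mapper route provides no evidence codes, so evidence
  filtering degenerates to all-or-nothing for such species.
- Bonferroni over all groups×terms is deliberately conservative;
  borderline terms may be lost relative to FDR-style corrections.
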