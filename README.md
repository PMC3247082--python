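# etbiclust

Error-tolerant constant-row biclustering of real-valued gene-expression
matrices, for transcriptomics analysts who want association-mining-style
biclusters — small, overlapping, bottom-up — that survive the random noise
that fragments exact patterns.

## The problem and the model

A bicluster is a set of genes coherently expressed across a subset of
experimental conditions. Through the association-mining lens, genes are
items and conditions are transactions. A transaction *t* supports a gene
set *G* when the values are coherent: restricted to a strictly same-sign
retained set, the relative range `(max|v| − min|v|) / min|v|` must be ≤ α.
Pattern strength is the **RangeSupport**

```
RS(B) = Σ_{t ∈ T} min_{g ∈ retained(t)} |v_{g,t}|  ≥  RS_threshold
```

the real-valued analogue of binary support, with each supporting
transaction contributing its minimum absolute retained value.

Exact miners require every value to cohere, so a single noisy cell
fragments a true bicluster. Here each transaction carries an **error
budget**: up to `⌊k·ε⌋` of its *k* values (ε ∈ [0, 1)) may be discarded —
always from the extremes of the sorted value list — before the range test
is applied. The miner works level-wise bottom-up with Apriori pruning;
with ε = 0 it is exhaustive (exact mode), with ε > 0 it is a heuristic
that subsumes the exact output and recovers fragmented patterns. Mined
collections are post-processed by greedy top-*k* selection (gene-count
ordered, mean-squared-residue tie-break, bounded pairwise gene overlap)
and evaluated by hypergeometric gene-set enrichment, case/control
biomarker filtering (odds ratio + Fisher exact test), and two
randomization significance tests. See `docs/methods.md` for the full
model, parameter guidance and limitations.

## Worked example

A 5-gene × 8-condition matrix (`worked_example_fixture`) contains a
quintuple `abcde` fragmented by one noisy cell in each of several
conditions:

```python
import etbiclust as eb

m = eb.ETBiclusterMiner(alpha=0.5, epsilon=0.25, rs_threshold=5.0)
m.fit(eb.worked_example_fixture())
print("n biclusters:", m.n_biclusters_)
ab = m.get_bicluster("ab"); q = m.get_bicluster("abcde")
print("RS(ab) =", ab.range_support, "support:", ab.transactions)
print("RS(abcde) =", q.range_support, "support:", q.transactions)
print("errors:", {t: q.errors_of(t) for t in q.transactions if q.errors_of(t)})
exact = eb.ETBiclusterMiner(alpha=0.5, epsilon=0.0, rs_threshold=5.0) \
    .fit(eb.worked_example_fixture())
print("exact finds abcde:", exact.get_bicluster("abcde") is not None)
```

prints

```
n biclusters: 31
RS(ab) = 19.6 support: ('t1', 't2', 't3', 't4', 't7', 't8')
RS(abcde) = 33.6 support: ('t1', 't2', 't3', 't4', 't5', 't6', 't8')
errors: {'t1': ('c',), 't2': ('d',), 't3': ('c',), 't4': ('e',), 't5': ('b',), 't6': ('a',)}
exact finds abcde: False
```

Reading this: the pair *ab* is supported by six conditions whose
contributions (2 + 2.1 + 4 + 6.5 + 3 + 2) sum to RangeSupport 19.6. With a
25% error tolerance the full quintuple *abcde* is supported by seven
conditions (RS 33.6) because one aberrant value per condition — gene c's 8
in t1, c's 9 in t3, b's 20 in t5, and so on — is discarded as an error;
t7 stays unsupported because no single discard makes it coherent. The
exact run (ε = 0) cannot stitch the fragmented quintuple back together.

The same pipeline is scriptable from the shell via the `etbiclust`
console command (`mine`, `select`, `enrich`, `biomarker`, `randomize`,
`simulate`); every output echoes its configuration and seed.

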