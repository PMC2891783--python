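# treecarto

Tools for treating unrooted binary phylogenetic tree topologies as points
in *split space* — one 0/1 coordinate per possible nontrivial bipartition,
dimension `2^(n-1) - n - 1` — and projecting that space to 2-D/3-D with a
fast, linear, hash-table-backed "cartographic" projection.

Because every fully resolved tree on `n` taxa carries exactly `n - 3`
nontrivial splits, all trees lie on a hypersphere of squared radius
`n - 3`, and the squared Euclidean distance between two tree vectors equals
their Robinson–Foulds distance. The projection computes, in `O(n)` time and
fixed memory, the inner products of a tree's split vector with `k`
(default 3) reference vectors that are never stored explicitly: each
reference vector is realized by a short *representative* vector (default
length 65,535) indexed through a hash of the serialized split
(Jenkins one-at-a-time by default). The map is linear and deterministic,
so it can run inline during a search and can be inverted (beam search,
exhaustive for `n <= 7`).

The package also contains the evaluation apparatus around the projection:

* `tree_core` — Newick I/O (via dendropy), split extraction,
  reconstruction from compatible splits, exhaustive enumeration
  (`(2n-5)!!` topologies), majority-rule consensus and resolution.
* `split_space` — explicit split vectors, split indexing, RF distance.
  **Note:** RF here is the raw symmetric-difference count (twice the
  "shared-splits" convention some tools use), because that is the quantity
  equal to the squared embedded Euclidean distance.
* `cartographic` — hash schemes, reference-vector construction
  (uniform[-1,1] representatives, Gram–Schmidt, equal-magnitude rescale),
  projection, expansion-based diagnostics (rank / angles / magnitude
  ratios / hash evenness), and inverse point-to-tree lookup.
* `evaluation` — m-nearest-neighbour consensus-resolution locality
  statistic, with 2-D/3-D stress-majorization (SMACOF) MDS baselines.
* `search` — Fitch parsimony, TBR/NNI neighbourhoods, score spectra,
  steepest-descent hill climbing with sampled traces.
* `cli_fixtures` — run configuration and a seeded synthetic generator
  (random topology + symmetric-model DNA alignment).

## Command line

```sh
treecarto enumerate --n 9 --count-only                 # 135135
treecarto project --trees trees.nwk --seed 1 --out cloud.tsv
treecarto project --trees trees.nwk --hash modulo_sum  # printed toy scheme
treecarto invert --point 2.0,1.8 --labels 1,2,3,4,5 --hash modulo_sum
treecarto locality --n 6 --m-max 25 --replicates 10 --seed 1 --out loc.tsv
treecarto simulate --n 9 --sites 500 --p-change 0.05 --seed 1 --out-prefix ds
treecarto search --alignment ds.fasta --seed 1 --out trace.tsv
treecarto spectrum --tree ds.nwk --alignment ds.fasta --out spec.tsv
treecarto plot --points cloud.tsv --out cloud.png
```

Outputs are plain text (TSV / Newick / FASTA); every file-writing command
echoes its full configuration to a `*.config.json` sidecar.

## Conventions

* Taxa are indexed 0-based in lexicographic label order unless an explicit
  taxon map is given; all cross-tree operations require identical maps.
* A split is stored by the side **not** containing taxon 0.
* Branch lengths are parsed and discarded; rooted binary inputs are
  unrooted by suppressing the root.
* Consensus resolution of the 3-taxon star is defined as 1.0.
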