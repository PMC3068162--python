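# Methods

## Problem setting

A eukaryotic protein may reside at one site ("singleplex") or at several
sites simultaneously ("multiplex"). The package treats localization as
multi-label classification over `C` sites (default 22, the standard
eukaryotic repertoire from acrosome to vacuole), with the label set of a
query inferred from annotated proteins near it in a feature space.

## Representations

### GO hit-frequency vectors

A fixed GO term universe is compressed onto `1..G` by sorting the term
identifiers numerically and numbering them consecutively; the index is a
bijection, so vectors built against the same universe are comparable. The
encoder averages indicator hits over the homology set: each representative
contributes at most once per term, and the value at term `i` is the
fraction of representatives annotated with `i`. Using frequencies rather
than 0/1 incidence preserves how consistently a term recurs among
homologs, which is the signal that separates sites with overlapping
annotation vocabularies.

Deliberate scope choices:

* the denominator is the full homology-set size, including unannotated
  representatives — an unannotated homolog is evidence of absence, not
  missing data, under this reading;
* terms outside the index are skipped silently (the universe defines the
  feature space); no GO-hierarchy propagation is performed;
* the encoder never filters the homology table (no expect-value or
  identity cutoffs); an optional `--min-identity` filter is applied while
  *reading* the table, keeping the encoder a pure function of its inputs;
* a protein appearing among its own representatives is kept at encode
  time; removing it is the evaluator's job (see Jackknife below), so
  encoding stays honest for production use, where self-hits are
  legitimate evidence.

### SeqEvo vectors

The `L x 20` PSSM is standardized per column (per amino-acid type, mean and
*population* standard deviation over the `L` positions; zero-variance
columns become zero columns rather than raising, so low-complexity profiles
pass through). The choice of column-wise statistics makes the subsequent
`20 x 20` transpose-product compare residue-type score profiles on a common
scale; the product is divided by `L` by default (`length_normalize`) so
proteins of different lengths live on the same scale under Euclidean
distance. The 210 serialized entries (diagonal + lower triangle, row-major)
are invariant to any permutation of sequence positions: the descriptor
captures which residue-type columns co-vary along the sequence, not where.

Population (divisor `L`) standard deviation keeps the degenerate `L = 2`
case well-defined and the transform deterministic; the flag and the
divisor are documented constants, not tunables.

## Classifier

Distances are Euclidean; the neighbor list is the stable ascending sort of
distances, ties broken by training order, and a tie means bitwise-equal
distance — no tolerance window — so runs are exactly reproducible.

The label cardinality `m` of the query is inherited from the single
nearest neighbor. Site scores accumulate over nested neighbor layers:
layer `k` counts site carriers among the `k` nearest, and the layers
`1..K` are summed, which is equivalent to giving the rank-`j` neighbor
weight `K - j + 1`. The scheme reduces to plain nearest-neighbor label
copying at `K = 1` and degrades toward a majority vote as ranks flatten.
The weight rule lives in one function (`neighbor_weights`) so alternative
layer weightings can be swapped without touching the scoring loop.

Site selection takes the `m` highest scores; ties break first by the
distance of the nearest neighbor carrying the site, then by the smaller
site code. Only positive-score sites are eligible — when `m` comes from
the nearest neighbor this can never run short, since that neighbor's own
sites all score positively (asserted as an invariant).

`K` defaults to 10 and is exposed on every command (`--k`, `--k-sweep`);
no value of `K` is claimed optimal, and the jackknife command supports
sweeping it.

## Evaluation

* **Locative rate** (virtual-protein accounting): per site `u`, the
  denominator is the number of evaluated proteins truly carrying `u` and
  the numerator those whose predicted set contains `u`; the overall rate
  is the ratio of the summed numerators and denominators. Over-predicted
  sites never enter a numerator. This transparent recall-style rule is the
  package's own accounting; the strict metric below is the harsher
  complement.
* **Absolute-true rate**: exact set equality per protein, no partial
  credit for under- or over-prediction; abstentions count as wrong in both
  metrics and are tallied separately.
* Percentages are rounded half-up to two decimals at presentation only;
  all internal arithmetic is full precision.

**Jackknife.** Each protein is predicted with (a) itself excluded from the
neighbor pool and (b) itself removed from its own homology set before its
GO vector is re-encoded. Only exact-accession self-matches are removed;
pruning of near-duplicate sequences is a dataset-construction concern, not
the evaluator's. Feature vectors of the *other* proteins are not
re-encoded per fold (they do not depend on the held-out protein), which
makes the evaluation O(N) encodings instead of O(N^2) while remaining
exactly equal to the naive retrain-per-fold loop — an equality the test
suite checks against a brute-force oracle on a 40-protein world.

## Synthetic worlds

The generator emulates the data regime the classifier assumes, with one
seed driving a single stream in a fixed draw order (signature permutation,
site directions, then per protein: multiplicity, sites, orphan flag,
homology size, representative annotations, PSSM, residues), so bundles are
byte-reproducible.

* **Labels**: set sizes follow the benchmark multiplicity proportions
  6687 : 1029 : 48 : 2 for 1–4 sites; sites are uniform without
  replacement.
* **GO signal**: each site owns a disjoint block of signature terms
  (default 10 of `G = 500`); representatives carry each signature term of
  the protein's sites with `p_sig = 0.8` and any term with background
  probability `p_bg = 0.02`; homology-set sizes are `1 + Poisson(mean-1)`
  with mean 8, so sets are never empty unless a protein is drawn as an
  orphan (`orphan_fraction`, default 0 — used to exercise the SeqEvo
  fallback and abstention paths). Disjoint signatures make the
  Bayes-optimal labels recoverable, which is what makes parameter-recovery
  tests meaningful.
* **PSSM signal**: each site owns a fixed unit direction in the
  20-dimensional residue-type space (scaled by `pssm_effect = 3`); a
  protein's rows are the summed directions of its sites multiplied by an
  independent per-position amplitude `a_i ~ N(0,1)`, plus `N(0, 1)` noise.
  The amplitude modulation is essential: a constant per-site row offset
  would be erased by column standardization, whereas modulated directions
  put the signal into the between-column correlation structure — precisely
  what the transpose-product descriptor measures.

What the generator does **not** emulate: the GO hierarchy (terms are
exchangeable symbols, no DAG), realistic BLAST score or identity
distributions, skewed site abundances (real benchmarks concentrate mass in
nucleus/cytoplasm; here sites are uniform), and correlated site
co-occurrence. Passing tests therefore demonstrate that the pipeline
recovers planted structure of the assumed form, not that it attains any
particular accuracy on real proteomes.

## Problem sizes

The test suite uses worlds of 40–60 proteins for oracle-equivalence checks
(small enough for brute-force re-loops), 10,000 proteins for label-
distribution statistics (with minimal PSSMs), and the default 500-protein,
22-site world for end-to-end parameter recovery; `scripts/acceptance.py`
evaluates the same 500-protein world plus the published benchmark's
worked-example arithmetic.

## Known limitations

* **Unique multi-label patterns are unrecoverable by design.** The
  predicted cardinality is inherited from the single nearest neighbor, so
  a protein whose exact label set occurs only once in the training pool
  can never be exactly recovered, however strong the feature signal. In
  the default world (500 proteins, sites uniform over 22), most two- and
  three-site patterns are singletons, and the jackknife's exact-match
  errors are concentrated entirely in those proteins; the absolute-true
  and locative rates the acceptance script reports for the synthetic world
  reflect this structural ceiling, not encoder noise. Larger samples, or
  worlds whose multiplex patterns repeat, remove the ceiling (a noise-free
  duplicated-pattern world evaluates to 100% in the test suite).
* Hit-frequency encoding treats the homology table as given; poor homolog
  retrieval upstream degrades the GO space silently (the naught-vector
  fallback only catches the empty case).
* The accumulation-layer weights are fixed and unnormalized; scores are
  rank statistics, not probabilities, and should not be compared across
  different `K`.
* With all-equal distances (e.g. many identical training vectors), ranking
  falls back to training order; this is deterministic but arbitrary.
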