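# lexiviable

Viable-cluster analysis of multiplex lexical networks: explosive
vocabulary growth, randomisation null models, psycholinguistic group
statistics, and robustness of lexical navigability to word failure.

## The problem

The mental lexicon stores words together with several kinds of similarity
relations at once — free associations, synonymy, taxonomic relations,
phonological similarity.  Modelling it as a *multiplex network* (one
shared word set, one layer per relation type) exposes structure invisible
to any single-layer view.  The central object is the **viable cluster**:
a set of words whose induced subgraph is connected on *every layer
considered in isolation*, so that any member can reach any other member
using only associations, or only synonyms, or only phonological links.
On a single-layer network the largest viable cluster (LVC) reduces to the
largest connected component; with several layers it is a far stronger
notion, and its emergence under growth is discontinuous ("explosive").

This package is for cognitive network scientists and psycholinguists who
want to:

- detect maximal viable clusters on node-aligned multiplex networks
  (with a certified brute-force oracle for small instances);
- simulate vocabulary growth under acquisition orderings — smeared
  age-of-acquisition (each word's age resampled from
  N(a_i, σ_a(i))), frequency, polysemy, multidegree, word length, or
  random — and detect explosive transitions: the first step where the
  LVC grows by more than a threshold (default 10 words) with the arrival
  of a single *critical word*;
- compare growth against null models: degree-preserving configuration
  rewiring, per-layer label reshuffling (full / targeted / small-fraction
  perturbation), and attribute reshuffling with fixed topology;
- characterise LVC-in vs LVC-out words with sample-size-corrected and
  degree-corrected group statistics, exact sign tests, Kendall τ-b,
  cumulative attribute curves, and In/In–In/Out–Out/Out link densities;
- run progressive-anomia experiments: remove words at random from a
  target pool and track median closeness centrality
  c_i = (N−1)/Σ_j d(i,j) on the layer-union graph.

Because the empirical lexical datasets are licence-bound, the package
ships a first-class synthetic generator: a planted-core multiplex with
heavy-tailed degrees, cross-layer overlap carried by high-polysemy
"connector" words, and a latent Gaussian copula producing attributes
whose Kendall τ to age of acquisition hits configurable targets
(τ ≈ −0.47 frequency, −0.31 degree, −0.26 polysemy, +0.24 length)
through Greiner's relation ρ = sin(πτ/2).

## Worked example

```python
import numpy as np
from lexiviable import (
    generate_multiplex, largest_viable_cluster, smear_aoa,
    growth_trajectory, detect_transition, attribute_ordering,
)

net, attrs, core = generate_multiplex(seed=0)   # N=2000, 4 layers
lvc = largest_viable_cluster(net)
print(f"LVC size: {lvc.size} of {net.n_nodes} words")

normative = detect_transition(growth_trajectory(net, smear_aoa(attrs, seed=1)))
random_g  = detect_transition(growth_trajectory(
    net, attribute_ordering(net, "random", seed=1)))
print(f"normative: explosive={normative.explosive} "
      f"jump={normative.jump} at word {normative.emergence_index}")
print(f"random:    explosive={random_g.explosive} "
      f"jump={random_g.jump} at word {random_g.emergence_index}")
```

Output:

```
LVC size: 650 of 2000 words
normative: explosive=True jump=73 at word 226
random:    explosive=True jump=13 at word 431
```

The planted 200-word core plus the connector backbone form a 650-word
LVC.  Under age-of-acquisition ordering the core arrives first and its
viable cluster appears in one discontinuous jump of 73 words when word
226 is acquired; under random ordering viable structure accretes along
the cross-layer overlap and the first super-threshold step is several
times smaller.

The same pipeline is scriptable from the shell:

```bash
lexiviable synth --seed 0 --out data/
lexiviable detect --edges associations=data/associations.tsv \
    --edges synonyms=data/synonyms.tsv --edges taxonomic=data/taxonomic.tsv \
    --edges phonological=data/phonological.tsv --out results/
lexiviable grow --edges ... --attrs data/attributes.tsv --scheme aoa \
    --iterations 200 --seed 1 --out results/
```

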