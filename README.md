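# hetdeg

Degree-heterogeneity measures for unweighted, undirected complex networks,
with an application to scoring the structural complexity of chaotic
attractors through recurrence networks.

## The problem

Many network statistics try to capture how "irregular" a network is, but
most of them (degree variance, the Albertson index, Estrada's irregularity
`ρ_n`, the Randić index) are built from the degrees `k_i, k_j` of adjacent
node pairs and respond most strongly to star-like topologies. A
complementary question is how *diverse* the node degrees are: how many
distinct degrees the network realizes and how evenly the probability mass
`P(k)` is spread over them. That diversity is what `hetdeg` quantifies, and
it is the natural quantity when comparing networks whose nodes sample an
underlying density — for example recurrence networks built from
dynamical-system trajectories, where the degree of a node mirrors the local
probability density of the attractor.

## The measure

For a graph with `N` nodes and empirical degree distribution `P(k)`, the
heterogeneity index is

```
h² = (1/N) · Σ_k (1 − P(k))²,    summed over k with P(k) ≠ 0.
```

A regular graph has a single degree with `P = 1`, so `h = 0`. The index is
maximal for the *completely heterogeneous* graph: the unique degree
multiset on `N` nodes in which every degree `1..N−1` occurs and exactly one
degree `k*` — `N/2` for even `N`, `(N−1)/2` for odd `N` — occurs twice.
For that extremal graph (which `hetdeg` constructs explicitly),

```
h_het(N)² = 1 − 3/N + (N + 2)/N³,
```

which increases strictly with `N` and tends to 1. The normalized measure

```
Hm = h / h_het(N)  ∈  [0, 1]
```

is 0 for any regular graph and 1 for the completely heterogeneous graph.

The recurrence-network (RN) pipeline turns a scalar time series into such a
graph: delay-embed at dimension `M` with delay `τ` (first minimum of the
autocorrelation), rescale the attractor to the unit cube, connect points
closer than a threshold `ε` in the maximum norm, and compute `Hm` of the
result. `ε` defaults to the percolation transition of the RN (smallest
value at which the giant component covers half the nodes). Since node
degree tracks the local density of trajectory points, `Hm` of the RN is a
single index for the structural complexity of the attractor.

## Worked example

```python
import hetdeg as hd

star = hd.star_graph(50)
er = hd.erdos_renyi(50, 0.1, seed=1)
sf = hd.barabasi_albert(50, 2, seed=1)
het = hd.complete_heterogeneous_graph(50)
for name, g in [("regular (k=4)", hd.regular_graph(50, 4)), ("star", star),
                ("Erdos-Renyi", er), ("scale-free", sf), ("extremal", het)]:
    print(f"{name:14s} Hm = {hd.hm(g):.4f}")

ts = hd.simulate("lorenz", 2400, seed=0)
res = hd.rn_pipeline(ts, m=3, n_nodes=2000)
print(f"lorenz RN: tau={res.tau} epsilon={res.epsilon:.4f} "
      f"edges={res.graph.number_of_edges()} Hm={res.report.hm:.4f}")
```

prints

```
regular (k=4)  Hm = 0.0000
star           Hm = 0.1429
Erdos-Renyi    Hm = 0.3897
scale-free     Hm = 0.4192
extremal       Hm = 1.0000
lorenz RN: tau=20 epsilon=0.0334 edges=9313 Hm=0.1749
```

The first block shows the topology ordering at `N = 50`: a regular graph is
completely homogeneous; the star realizes only two distinct degrees; the
random and scale-free graphs spread probability over many degrees; the
extremal construction reaches the normalization bound exactly. The last
line runs the full time-series pipeline: the Lorenz x-coordinate is
embedded at `M = 3` with the automatically selected delay and threshold,
and the resulting 2000-node recurrence network scores `Hm ≈ 0.17` —
well above an i.i.d.-noise series (`≈ 0.08`), reflecting the strong density
variation across the attractor.

A command-line interface mirrors the library:

```
hetdeg extremal --kind complete-heterogeneous --n 6 --out het6.edges
hetdeg measure het6.edges --out report.csv
hetdeg simulate --system lorenz --length 2400 --seed 0 --out lorenz.dat
hetdeg rn --input lorenz.dat --m 3 --n-nodes 2000 --report-out rn.csv
hetdeg generate --family ba --n 2000 --kmin 5 --seed 1 --out ba.edges
hetdeg reproduce --experiment compare3way --out-dir results/
```

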