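# Methods

This note records the models implemented in `autocmap`, the choices made
where the published method descriptions are ambiguous, and what the test
suite's synthetic data can and cannot establish.

## Auto-contractive map

**Model.** Three layers of N units. Input→hidden connections are
mono-dedicated (vector `v`), hidden→output fully connected (matrix `w`,
diagonal included and trained like any other entry). For a pattern `s` in
[0,1]^N:

    h_i   = s_i (1 − v_i/C)
    net_i = Σ_j h_j (1 − w_ij/C)
    t_i   = h_i (1 − net_i/C)

Updates trap the residual energy and are applied in batch, once per epoch:

    Δv_i  = Σ_p (s_ip − h_ip)(1 − v_i/C) s_ip
    Δw_ij = Σ_p (h_ip − t_ip)(1 − w_ij/C) h_jp
    v ← v + αΔv,  w ← w + αΔw,  α = 1/M.

Both steps of an epoch use the start-of-epoch `v` (signal transfer and the
two adaptations are simultaneous within an epoch). Substituting `h` into
`Δv` gives `Δv_i = (v_i/C)(1 − v_i/C) Σ_p s_ip²`: each `v_i` follows a
discrete logistic, monotonically increasing from its initial value toward
the ceiling `C`, and `α Σ_p s_ip² ≤ 1` guarantees it never overshoots. When
`v_i = C` the hidden layer is silent and all updates vanish — training has
converged. The trained `w` is converted to distances
`d_ij = C − (w_ij + w_ji)/2`, `d_ii = 0`, clamped at 0 against round-off.

**Parameters.**

| parameter | default | meaning |
|---|---|---|
| `C` | `N/2` | contraction ceiling; also the offset in `d = C − w′`. `N²` is exposed as the common alternative convention; a test asserts the mapped MST topology agrees under both. |
| `init` | `1e-4` | constant positive initial value of every connection. |
| `tol` | `1e-6` | stop when the per-epoch relative change of `v` is below this. |
| `max_epochs` | 20000 | hard cap; typical tables converge in a few hundred to a few thousand epochs. |

**Stopping.** Because the `v` dynamics are logistic, the per-epoch change is
tiny both near the start and near convergence. Stopping on "change < tol"
alone would fire at epoch 1 for any near-zero initialisation, so training
stops only once the change is below `tol` *and* no longer increasing, i.e.
past the logistic peak. All-zero inputs (which never move) stop immediately
with `v` at its initial value.

**Record mode.** To map records instead of variables, the variables are
min–max scaled and the transposed table is trained (records become units,
variables become patterns). The transposed values already lie in [0,1]; they
are deliberately *not* re-scaled per record, because per-record rescaling
erases the between-record level differences that make records
distinguishable (measured on the surrogate, it costs roughly 15 percentage
points of blind-test accuracy).

## Pruning trace, H function, maximally regular graph

Each pruning cycle simultaneously removes every node of degree ≤ 1 together
with its incident edges; `Nd_i` (the *gradient*) counts the nodes removed at
cycle i. Pruning stops when no degree-≤1 node remains, so any 2-core
(every node on a cycle) survives untouched. Runs of equal gradient form
classes; every cycle adjacent to a gradient change is a *change state*
(each cycle counted once). Then, for a graph with A edges:

    μ = (nodes removed) / (cycles run)
    φ = mean gradient over the change states
        (the whole-trace mean when the gradient never changes)
    H = μ (φ − 1) / A.

Hand-traceable anchors: the 5-node star removes [4, 1] → μ = φ = 2.5,
H = 2.5·1.5/4 = 0.9375; the 5-node chain removes [2, 2, 1] → μ = 5/3,
φ = 1.5, H ≈ 0.2083. Stars outscore chains at every size — H measures hub
orientation. A graph with no leaves at all (cycle, complete graph) has an
empty trace and H = 0.

Two readings of the defining ratio were considered. `μ·(φ−1)/A` (used here)
ranks stars above chains; the alternative `μ·φ⁻¹/A` inverts that ranking
and contradicts H's role as a hubness measure. Similarly, extending pruning
into 2-cores by removing minimum-degree nodes makes every dense graph
collapse in one sweep — the complete graph then attains the maximal H and
the MRG construction degenerates to the complete graph — so pruning here is
strictly leaf-removal. Consequence: the nominal bound 0 < H < 2 holds on
typical trees but *not* universally (a large star exceeds 2: K(1,45) scores
≈ 11), and the removed-node total equals N only on forests.

**MRG.** Starting from the Kruskal MST (edges scanned in ascending
(weight, node-index) order, making ties reproducible; skipped cycle-forming
edges recorded in encounter order), skipped edges are added back one at a
time, strongest first, recomputing H after each addition. The graph with
the highest H wins; ties resolve to the fewest added edges; with no skipped
edges (N = 2) there is no MRG and the MST is returned flagged.

## ACS metric matrices

All three metrics are symmetric with zero diagonal and entries in [−1, 1]:

* **linear** — Pearson correlation (zero-variance variables get zero rows
  with a warning);
* **prior** — co-occurrence log-odds
  `ln[(Σ x_i x_j + s)(Σ(1−x_i)(1−x_j) + s) / ((Σ x_i(1−x_j) + s)(Σ(1−x_i)x_j + s))]`
  for unit-interval data, smoothing `s = 1/P²` for P records;
* **autocm** — the symmetrized trained `w`.

The prior and autocm matrices are mapped into [−1, 1] by an affine
(*linear*) transformation that centres the off-diagonal entries on their
mean and divides by the maximum absolute deviation. Mapping [min, max] onto
[−1, 1] instead was rejected after measurement: one extreme minimum (any
complementary indicator pair) pushes ~98 % of the remaining entries to the
positive side, the network receives only excitation, and every query
saturates uniformly at ±1. Mean-centring restores the excitation/inhibition
balance the competition needs; rank order is preserved; a constant
off-diagonal maps to zero.

## ACS dynamics

Units start at `rest`; per cycle, unit i receives

    Ecc_i = α Σ_k (Σ_{j: W_k,ij>0} u_j W_k,ij) / N_k,i⁺
    Ini_i = α Σ_k (Σ_{j: W_k,ij<0} u_j W_k,ij) / N_k,i⁻

(fan-in-averaged per matrix over the positive/negative weight counts; an
empty count contributes zero), plus the persistent external drive `β·input`
added to the excitation or inhibition side by its sign. The update is

    net_i = (Max − u_i) E_i + (u_i − Min) I_i − Dec_i (u_i − rest)
    δ_i   = net_i (1 − u_i²)
    u_i  ← clamp(u_i + δ_i, Min, Max)
    Dec_i ← Dec_i exp(−u_i²)        (using the updated u_i)

and iteration stops when `H = Σδ²` < ε. At a fixed point each unit either
solves `net_i = 0` — the closed form
`u* = (Max·E − Min·I + rest·Dec)/(E − I + Dec)` — or sits in a *boundary*
equilibrium: the net input still pushes outward but the barrier factor
`(1 − u²)` silences the update at the bound. `equilibrium_residual()`
reports the gap to the closed form for interior units and zero for boundary
units; tests verify interior residuals shrink with ε (≈ 1e−6 at ε = 1e−18).

| parameter | default | notes |
|---|---|---|
| `alpha` | 0.1 | internal net-input scale; prototype signs are stable across {0.05, 0.1, 0.5} (tested). |
| `beta` | 1.0 | external drive scale; the query unit is driven, not hard-clamped. |
| `rest` | −0.1 | start/decay-target activation; +0.1 variant available via config. |
| `decay0` | 0.1 | initial per-unit decay. |
| `epsilon` | 1e−6 | convergence threshold on H. |

Reported cycle counts depend on (α, β, ε) and are not comparable across
conventions; only the attractor itself is.

## Synthetic data

`synth_two_class` draws within-class multivariate normal data with
user-specified mean shifts (in SD units) and block correlations (validated
positive semi-definite), appending complementary class indicators: the
ground truth for classifier and prototype-recovery tests.
`synth_tree_gaussian` runs a unit-variance Gaussian Markov process over a
tree so correlations decay multiplicatively along paths; the planted tree is
the unique strongest-association spanning tree, the oracle for MST recovery.

`surrogate_study_dataset` stands in for the study's raw table, which is not
redistributable. Construction: per-class means/SDs are taken from the
published group-statistics table (sex at the published 11M/9F and 12M/14F
counts); the published pooled 15×15 correlation matrix fixes the total
covariance; subtracting the between-class part implied by the class means
leaves a within-class covariance that is solved elementwise against the
mixture of per-class SD products under a shared within-class correlation
(projected to the nearest positive semi-definite matrix); each class is then
sampled with *exactly* matching sample moments. The published correlation
matrix contains one asymmetric printed pair — (GestAge, PLATNF), 0.13 vs
0.43 — which is symmetrized to 0.28 and surfaced by
`correlation_transcription_discrepancies()`; the IL-6/IGF-I expression
columns are printed as perfectly collinear and are duplicated verbatim.

**What the surrogate shows, and what it cannot.** Group statistics, the
paired t profiles, per-variable R² and pairwise correlations are reproduced
essentially by construction (pooled correlations to ≈ 0.02). Everything that
depends only on first and second moments therefore transfers. But the
surrogate is Gaussian within class: it carries no skewness, zero-inflation
or nonlinear record geometry. Measured consequences, stable across seeds:

* the record-mode blind test reaches ~66–84 % arithmetic-mean accuracy
  (published on the real data: 86.7 %), and on the surrogate the nonlinear
  map no longer outperforms PCA-LDA — exactly what moment-matched Gaussian
  data should produce;
* the class-prototype queries reproduce most saturated signs (AGA ~9–10 of
  11), and the misses are precisely the variables whose published prototype
  sign *opposes* their published linear correlation with the class (e.g.
  mRNA_IGF2 and PLA_BP2 positive for AGA) — information that printed
  first/second-order summaries simply do not contain;
* the published tree centers of the variable maps (PLA_BP2 for the AGA
  subset, GestAge for IUGR, PLA_IGF2 overall) are logged as soft checks,
  not asserted.

## Numerical choices and degenerate inputs

* Constant variables min–max scale to all-zeros (0/0 guarded).
* Edge ordering everywhere: (weight, smaller index, larger index); identical
  distances therefore give a reproducible lexicographic MST.
* Disconnected graphs prune with a warning (components prune in parallel);
  isolated nodes in a label vote fall back to the global majority.
* A degenerate (constant off-diagonal) metric matrix rescales to zero, not ±1.
* Distances are clamped at zero from below; `v` cannot exceed `C` by
  construction.
* Identical profiles in the paired t return t = 0 (p = 0.5); a constant
  *nonzero* shift has no sample variance and is rejected.
* The silhouette of `kmeans_best` uses squared-Euclidean dissimilarities by
  default, the convention of the classic k-means toolboxes (plain Euclidean
  is available via `silhouette_metric`); k-means itself runs best-of-N
  restarts by within-cluster sum of squares on min–max-scaled inputs.
* PCA-LDA uses 2 components by default, configurable.

## Problem sizes in the test suite

Enumeration oracles run at N ≤ 6 nodes (all V^(V−2) spanning trees checked
against Kruskal); AutoCM property tests use random tables up to 60×15; the
surrogate pipelines run at the study's own size (46×14); the acceptance
script averages its stochastic pipelines over five surrogate draws. The full
suite runs in well under a minute on one CPU.

## Known limitations

* The surrogate cannot certify the nonlinear claims made for the real data
  (record clustering superiority, correlation-opposing prototype signs);
  it certifies the machinery and the moment-level statistics.
* The H bound 0 < H < 2 is not enforced; extreme hubs exceed it.
* ACS boundary equilibria freeze at exactly ±1 once clamped; the reported
  profile is the attractor of the clamped dynamics.
* No missing-data handling anywhere: completeness is a hard precondition.
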