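# autocmap

Semantic connectivity maps and prototype variable profiles for small,
complete tabular biomedical datasets.

Small clinical datasets — here the motivating case is a study of 46 newborns
(26 appropriate-for-gestational-age, AGA; 20 intra-uterine growth restricted,
IUGR) described by placental IGF-system gene expression and protein content,
pro-inflammatory cytokines, gestational age and sex — often carry structure
that pairwise linear statistics cannot see. `autocmap` implements two
complementary non-linear tools for such tables, plus the classical baselines
to compare them against:

* **Auto-contractive map (AutoCM).** A three-layer auto-associative network
  with N units per layer: mono-dedicated input→hidden weights *v* and a full
  hidden→output matrix *w*. Both signal transfers contract by `(1 − weight/C)`
  and both weight updates trap the residual signal energy:

  ```
  h_ip  = s_ip (1 − v_i/C)                  Δv_i  = Σ_p (s_ip − h_ip)(1 − v_i/C) s_ip
  net_ip = Σ_j h_jp (1 − w_ij/C)            Δw_ij = Σ_p (h_ip − t_ip)(1 − w_ij/C) h_jp
  t_ip  = h_ip (1 − net_ip/C)
  ```

  with batch updates `v ← v + αΔv`, `w ← w + αΔw`, learning coefficient
  `α = 1/M` for M patterns and contraction parameter `C ≥ 1` (default `N/2`).
  Each `v_i` grows monotonically to `C`, at which point training has
  converged and the trained `w` is read as a distance matrix
  `d = C − (w + wᵀ)/2` among variables — or among *records*, by training the
  transposed table.
* **Graph post-processing.** The minimum spanning tree (Kruskal) of `d` is
  the "nervous system" of the table; the pruning-based hubness function
  `H = μ(φ−1)/A` scores how hub-oriented a graph is, and the maximally
  regular graph (MRG) adds the MST-skipped edges back, strongest first,
  keeping the variant that maximizes H.
* **Activation and Competition System (ACS).** An associative memory over
  *several* weight matrices at once — linear correlation, a co-occurrence
  log-odds ("prior probability") metric, and the trained AutoCM weights —
  whose units negotiate activations in [−1, 1] under excitation, inhibition
  and adaptive decay. Driving a class unit (e.g. `AGA`) with +1 and running
  to the attractor yields the *prototype profile*: the fuzzy membership of
  every variable in that condition.
* **Baselines.** Per-class summaries, paired t profiles, per-variable R²
  against the class, best-of-N k-means with silhouette/Davies–Bouldin,
  leave-one-out PCA→LDA, and majority-vote scoring of record maps.

The raw per-subject study table is not redistributable; the package ships its
*published* per-class summary statistics and 15×15 correlation matrix, and
`surrogate_study_dataset()` draws a synthetic surrogate whose per-class
sample moments match the published tables exactly (see
`docs/methods.md` for what that surrogate can and cannot reproduce).

## Worked example

```sh
python - <<'EOF'
from autocmap.study import surrogate_study_dataset
surrogate_study_dataset().values.to_csv("study.csv", index_label="record_id")
EOF

autocmap map study.csv --mode records --class-columns AGA,IUGR -o out_records
```

The record-mode command scales the 12 measurement variables, trains AutoCM on
the transposed table (the class indicators never enter this blind test),
builds the MST and MRG over the 46 records, and scores each record by the
majority class of its graph neighbours:

```
Confusion matrix
      AGA  IUGR
AGA    20     6
IUGR    7    13

  AGA: 76.92% correct
  IUGR: 65.00% correct
  arithmetic mean accuracy: 70.96%
  weighted mean accuracy:   71.74%
```

So on this surrogate draw, 20 of 26 AGA and 13 of 20 IUGR newborns sit in a
graph neighbourhood dominated by their own class. Querying the associative
memory for the AGA prototype:

```sh
autocmap prototype study.csv AGA -o out_proto
```

```
ACS prototype
=============
cycles:    125
converged: True
final H:   9.684e-07

  Male         +0.02
  GestAge      +1.00
  PRO          -0.99
  mRNA_BP1     -1.00
  ...
  PLATNF       +1.00
  AGA          +1.00
  IUGR         -1.00
```

Read as fuzzy memberships: the prototypical AGA newborn has high gestational
age and placental TNF-α content and low IGFBP-1/IGFBP-2/IL-6 expression,
while the opposing class unit is fully suppressed. Each activation is the
attractor the unit reached after negotiating with all others through the
three weight matrices; `cycles` is the number of negotiation rounds until
the update energy `H = Σδ²` fell below ε.

In Python, the same objects are available statsmodels-style — a model is
built from data, `fit()`/`run()` return results with a `summary()`:

```python
import autocmap as acm

ds = acm.surrogate_study_dataset()
fit = acm.AutoCM(acm.minmax_scale(ds)).fit()   # AutoCMResults
print(fit.summary())
mrg = acm.maximally_regular_graph(fit.distances())
print(acm.tree_center(mrg.mst))
```

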