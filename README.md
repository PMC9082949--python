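# staplr — hierarchical stacked penalized logistic regression

Multi-view data divides features into named blocks ("views"): in a
multimodal neuroimaging study, features nest inside derived measures, which
nest inside scan types. Practitioners then want two things from a binary
classifier: good prediction, and an answer to *which views matter* — which
measures (and which scan types) need to be acquired at all.

`staplr` implements **stacked penalized logistic regression (StaPLR)** for
tree-structured view hierarchies. One logistic ridge model f^v is trained
per leaf view X⁽ᵛ⁾; its out-of-sample predictions z⁽ᵛ⁾ (10-fold
cross-validated, with the λ-selection loop nested inside) feed a
**nonnegative-lasso** combiner at each internal node s, whose own
cross-validated predictions feed the next level, up to the meta learner at
the root:

    f^stacked(X) = f^meta( f^inter(1)(f^1(X⁽¹⁾), …), …, f^inter(S)(…) ),

every stage applying ψ(intercept + weighted inputs), ψ(x) = eˣ/(1+eˣ).
The L1 penalty with nonnegativity constraints performs *view selection*: a
view with a zero coefficient anywhere on its path to the root is dropped
from the model. A flat hierarchy recovers the original two-level StaPLR.

Because each level is its own logistic model, coefficients are not
comparable *across* branches. The **minority report measure (MRM)** fixes
this: it is the change in the final stacked prediction when one view's
prediction moves from a to b while all other views are clamped at c
(defaults a = 0, b = 1, c = ȳ), computed from the fitted coefficients alone.
With nonnegative weights all MRM values lie in [0, 1) and are directly
comparable across the whole tree.

The package also provides the evaluation protocol of the methodology —
repeated double (nested) 10-fold cross-validation with AUC/accuracy and
per-view selection proportions — a flat logistic **elastic-net benchmark**
(α grid 0…1 in steps of 0.1, 100-value λ path with λ_min/λ_max = 0.01,
per-view nonzero counts and L2 norms), and a **synthetic data generator**
that emulates the hierarchical, wildly-unequal-width, correlated,
imbalanced structure of multimodal MRI data with known ground truth.

## Worked example

```python
from staplr import (SyntheticConfig, generate_dataset, fit_staplr,
                    StaplrConfig, coefficient_table, mrm_all)

config = SyntheticConfig(
    n_subjects=200,
    views={"scan_a": {"measure_1": 20, "measure_2": 8}, "scan_b": {"measure_3": 12}},
    signal_views=("measure_1",), effect_size=2.5, seed=7,
)
dataset, hierarchy, truth = generate_dataset(config)
model = fit_staplr(dataset, hierarchy,
                   StaplrConfig(prediction_folds=5, lambda_folds=5, n_lambda=50, seed=1))
print(coefficient_table(model, "all").query("level != 'base'"))
print(mrm_all(model, dataset).ranked())
```

prints

```
  node     child        level  coefficient
  root    scan_a         meta     5.125419
  root    scan_b         meta     0.000000
scan_a measure_1 intermediate    17.447054
scan_a measure_2 intermediate     0.000000
scan_b measure_3 intermediate     0.000000

     view branch      mrm   a   b     c
measure_1 scan_a 0.856135 0.0 1.0 0.285
measure_2 scan_a 0.000000 0.0 1.0 0.285
measure_3 scan_b 0.000000 0.0 1.0 0.285
```

The stack selected exactly the branch and leaf carrying the simulated
signal (nonzero meta weight 5.13 for `scan_a`, combiner weight 17.4 for
`measure_1`) and dropped everything else; the MRM says moving
`measure_1`'s prediction from 0 to 1 can move the final probability by
0.86, while the unselected views have exactly zero influence.

The `examples/` directory holds one short script per capability: fitting,
MRM importance, nested-CV evaluation vs the elastic net, and the file
formats / CLI. A thin command line is installed as `staplr` with
subcommands `simulate`, `fit`, `predict`, `mrm`, `evaluate`, `benchmark`;
every run writes a `manifest.json` capturing the resolved configuration,
and identical manifests reproduce outputs byte for byte.

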