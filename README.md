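# gmhcrf

Full-covariance Gaussian-mixture hidden conditional random fields
(GM-HCRF) for multi-class classification of sequences of real-valued
feature vectors, with:

- **model core** — log-space forward/backward scoring of per-class
  potential blocks (prior, transition, per-state full-covariance
  Gaussian mixtures), class posteriors via global normalization, and a
  brute-force path-enumeration oracle;
- **gradients** — analytic gradients of the conditional log-likelihood
  from *cached* forward/backward results (exactly one forward and one
  backward pass per (sequence, class) per objective evaluation,
  counter-instrumented), verified against central finite differences;
- **training** — unconstrained parameterization (softmax mixture
  weights, Cholesky-with-log-diagonal covariances) and L-BFGS
  minimization of the ridge-regularized conditional NLL;
- **baselines** — an independent Gaussian-HMM likelihood scorer with the
  exact probability-to-potential mapping (prior = log b, transition =
  log C), the diagonal moment-feature chain variant, and a
  diagonal-covariance constrained trainer;
- **synthetic data** — a seeded per-class GMM-HMM simulator with named
  presets and a Bayes-reference classifier (true parameters);
- **evaluation** — grouped (leave-subjects-out) and stratified k-fold
  cross-validation, confusion matrices with row-percentage convention,
  and a paired Wilcoxon signed-rank comparison of two CV reports.

## CLI

```sh
gmhcrf simulate --preset correlated --n 30 --T 30 --seed 11 --out data.csv
gmhcrf train    --data data.csv --model full --Q 2 --M 1 --l2 0.1 \
                --seed 7 --out model.json
gmhcrf predict  --data data.csv --model-file model.json --out pred.csv
gmhcrf evaluate --data data.csv --k 5 --mode grouped --model full \
                --out report.json --csv-out confusion.csv
gmhcrf compare  --a report_full.json --b report_diag.json
gmhcrf gradcheck --seed 1 --trials 20 --tol 1e-4
```

Exit codes: 0 success, 1 input/validation error, 2 usage error,
3 gradient check failure.  `--config file.json` supplies any
`TrainConfig` field; explicit flags override it.

### File formats

Sequences are CSV with header `seq_id,group_id,label,t,f0..f{D-1}`;
`t` is 0-based and contiguous per sequence; `group_id`/`label` may be
empty.  Models are schema-versioned JSON storing full covariance
matrices; round-trips are lossless.

## Synthetic presets

All generator numbers are spelled out in
`src/gmhcrf/synthetic.py` (module docstring).  In brief, each class is a
2-state Gaussian(-mixture) HMM over D=2 features:

- `separable` — 3 classes whose state means are 6 sigma apart
  (near-perfect Bayes accuracy);
- `correlated` — 2 classes sharing widely separated state means and
  differing almost only in within-state feature correlation
  (+0.9 vs −0.9): diagonal-covariance models lose most of the signal;
- `hard` — 3 heavily overlapping classes with bimodal (M=2) states.

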