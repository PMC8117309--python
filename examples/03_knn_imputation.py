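"""Impute missing survey fields by k-nearest-neighbour matching.

Records with missing values borrow them from the k = 5 most similar
complete records, with similarity measured by the Gower distance
(categorical mismatch + range-scaled numeric differences).
"""

import mrprev as m

spec = m.default_model_spec()
truth = m.default_scenario(spec, seed=1)
records = m.simulate_respondents(truth, m.SparsityProfile(), seed=2)
n_missing = int(records.isna().sum().sum())
print(f"{len(records)} records, {n_missing} missing fields before imputation")

completed, log = m.knn_impute(records, m.ImputationConfig(k=5), seed=3)
print(f"{len(log)} fields imputed; remaining missing: "
      f"{int(completed.isna().sum().sum())}")

entry = log[0]
print(f"example: record {entry['record']} was missing {entry['variable']!r}; "
      f"donors {entry['donors']} at Gower distances "
      f"{[round(d, 3) for d in entry['distances']]} -> {entry['value']!r}")

# observed values are never altered; imputation only fills the gaps,
# after which the records can be tabulated into per-cell counts
counts = m.tabulate(completed, spec.classification, "asian")
print(f"tabulated: {counts.n.sum()} respondents, {counts.y.sum()} obese")
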