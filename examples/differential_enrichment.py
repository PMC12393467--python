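"""Spike-in differential enrichment with permutation FDR.

Generates a synthetic immunoprecipitation experiment: 500 proteins, 4 vs 4
samples, 25 proteins spiked by 2 log2 units in the case group, 10%
left-censored missing values.  Missing entries are imputed from a
down-shifted normal (width 0.3, down-shift 1.8 column SDs), then each
protein is tested with a two-sided Welch t-test and flagged at 5%
permutation-based FDR.
"""

from tbmkit.enrichment import differential, impute_gaussian
from tbmkit.synth import make_synthetic_intensities

data = make_synthetic_intensities(seed=11)
n_missing = int(data.matrix.isna().sum().sum())
print(f"matrix: {data.matrix.shape[0]} proteins x "
      f"{data.matrix.shape[1]} samples, {n_missing} missing values")

complete = impute_gaussian(data.matrix, seed=11)
results = differential(complete, data.groups, seed=11)

flagged = results[results["significant"]]
spiked = set(data.truth.loc[data.truth["spiked"], "protein_id"])
true_pos = flagged.index.isin(spiked).sum()
print(f"flagged at 5% FDR: {len(flagged)} proteins "
      f"({true_pos} of {len(spiked)} spike-ins, "
      f"{len(flagged) - true_pos} others)")
print()
print("top hits by |t|:")
top = results.reindex(results["t"].abs().sort_values(ascending=False).index)
print(top.head(8).round(3).to_string())
print()
print("log2fc is case minus control; q is the permutation-FDR-adjusted")
print("significance; spiked rows should dominate this list.")
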