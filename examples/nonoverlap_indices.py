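"""Compute the five non-overlap effect sizes on a small AB comparison.

Non-overlap indices summarize how completely the intervention-phase scores
dominate the baseline scores, without any distributional assumptions.
"""

from scedbehave import nap, pairwise_oracle, pem, pnd, tau_ab, tau_u

A = [1, 3, 2, 2, 4]  # baseline scores
B = [4, 5, 4, 7, 6, 8]  # intervention scores

for fn in (nap, pnd, pem, tau_ab, tau_u):
    res = fn(A, B)
    print(f"{res.method:7s} = {res.estimate:8.4f}   (n_A={res.n_A}, n_B={res.n_B})")

table = pairwise_oracle(A, B)
counts = {o: sum(x[2] == o for x in table) for o in ("improved", "tied", "deteriorated")}
print("exhaustive pair outcomes:", counts, "of", len(table), "pairs")

# NAP is the share of cross-phase pairs (ties half-weighted) where the
# intervention point beats the baseline point: 1.0 = complete separation,
# 0.5 = chance.  Tau-U additionally subtracts any improving trend already
# present in the baseline.
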