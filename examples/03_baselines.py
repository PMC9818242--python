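"""The printed baseline methods on small worked inputs.

Pearson relevance edge, entropy/mutual information, a StepMiner one-step
threshold with the sparse-quadrant implication test, and chain-rule
evaluation of a discrete Bayesian belief network.
"""

from plbin import (
    DiscreteBBN,
    QuadrantCounts,
    bbn_joint_probability,
    categorical_entropy,
    mutual_information,
    pearson_cc,
    sahoo_test,
    stepminer_threshold,
)

print("Pearson r of (1,2,3) vs (1,3,2):", pearson_cc([1, 2, 3], [1, 3, 2]))
print("entropy of a 1:3 binary split:", round(categorical_entropy([0, 1, 1, 1]), 4), "bits")
x = [0] * 5 + [1] * 5
y = [0, 0, 0, 0, 1, 0, 1, 1, 1, 1]
print("MI of joint counts [[4,1],[1,4]]:", round(mutual_information(x, y), 4), "bits")

fit = stepminer_threshold([1, 1, 1, 5, 5, 5])
print(f"step threshold of (1,1,1,5,5,5): t={fit.threshold} "
      f"(intermediate zone {fit.threshold - 0.5}..{fit.threshold + 0.5})")

stat, err, sig = sahoo_test(QuadrantCounts(40, 15, 40, 1), "IV")
print(f"sparse quadrant IV: statistic={stat:.2f} error_rate={err:.4f} "
      f"significant={sig}  -> implies 'A high => B high'")

bbn = DiscreteBBN(
    ["A", "B", "C"],
    {"A": ("B",), "B": (), "C": ("A", "B")},
    {
        "B": {(0,): 0.4, (1,): 0.6},
        "A": {(1, 1): 0.7, (1, 0): 0.3, (0, 1): 0.4, (0, 0): 0.6},
        "C": {(1, 1, 1): 0.7, (1, 1, 0): 0.3, (1, 0, 1): 0.5, (1, 0, 0): 0.5,
              (0, 1, 1): 0.5, (0, 1, 0): 0.5, (0, 0, 1): 0.5, (0, 0, 0): 0.5},
    },
)
p = bbn_joint_probability(bbn, {"A": 1, "B": 1, "C": 1})
print(f"BBN chain rule P(A=1,B=1,C=1) = 0.6 x 0.7 x 0.7 = {p}")
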