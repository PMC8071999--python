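"""Default JZS Bayes factors for the cue-weighting one-sample tests.

Evaluates the Cauchy(0, sqrt(2)/2)-prior Bayes factor at the two group-level
t statistics for "is the mean weighting index different from 0.5?".
"""

from watermaze import inference

for label, t, n in [("older adults", 3.52, 15), ("younger adults", 1.40, 12)]:
    bf = inference.jzs_bayes_factor(t, n)
    print(f"{label}: t({n - 1}) = {t:.2f}  BF10 = {bf.bf10:.2f}  "
          f"BF01 = {bf.bf01:.2f}  -> {inference.interpret_bf(bf)}")

print("\nBF10 > 10 is strong evidence the group's weighting differs from 0.5;")
print("BF01 between 1 and 3 is only anecdotal support for no difference.")
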