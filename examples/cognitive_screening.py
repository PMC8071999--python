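"""Actuarial cognitive-normality screening from a z-score profile.

A subject is impaired if both tests in one domain, or one test in three
domains, fall more than 1 SD below the age-corrected normative mean.
"""

from watermaze import screening
from watermaze.dataio import ZSCORE_DOMAINS


def profile(sid, **overrides):
    scores = {d: [(f"{d}_test1", 0.2), (f"{d}_test2", 0.1)] for d in ZSCORE_DOMAINS}
    scores.update(overrides)
    return screening.NeuropsychProfile(sid, scores)


cases = [
    profile("intact"),
    profile("amnestic", memory=[("CVLT-II LDFR", -1.3), ("RCFT LDFR", -1.6)]),
    profile("multidomain",
            memory=[("CVLT-II LDFR", -1.2), ("RCFT LDFR", 0.0)],
            language=[("BNT", -1.1), ("Animals", 0.3)],
            visuospatial=[("Block Design", 0.2), ("RCFT Copy", -1.4)]),
    profile("boundary", memory=[("CVLT-II LDFR", -1.0), ("RCFT LDFR", -1.0)]),
]
for p in cases:
    res = screening.classify_cognitive_status(p)
    reasons = f"  [{'; '.join(res.reasons)}]" if res.reasons else ""
    print(f"{p.subject_id:12s} -> {res.status}{reasons}")

print("\nScores exactly at z = -1 do not trigger either rule: the criterion")
print("is 'more than one standard deviation below' the normative mean.")
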