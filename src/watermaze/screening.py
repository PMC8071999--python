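"""Actuarial cognitive-normality classification from a neuropsychological profile.

A subject's battery spans four fixed domains (learning and memory,
attention/executive functioning, language, visuospatial functioning) with
two age-normed z-scores each.  The subject is classified *impaired* if
either rule fires:

1. both scores in a single domain fall more than ``threshold`` standard
   deviations below the normative mean (z strictly below −1 by default), or
2. at least one score falls below the threshold in three or more domains.

The comparison is strict: a score exactly at the threshold does not count
as below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataio import ZSCORE_DOMAINS


@dataclass(frozen=True)
class NeuropsychProfile:
    subject_id: str
    scores: dict[str, list[tuple[str, float]]]  # domain -> [(test, z), (test, z)]

    def __post_init__(self):
        for domain in ZSCORE_DOMAINS:
            if domain not in self.scores:
                raise ValueError(f"profile missing domain {domain!r}")
            if len(self.scores[domain]) != 2:
                raise ValueError(f"domain {domain!r} must have exactly 2 scores")


@dataclass(frozen=True)
class ScreeningResult:
    subject_id: str
    status: str            # 'normal' | 'impaired'
    reasons: tuple[str, ...]


def classify_cognitive_status(profile: NeuropsychProfile,
                              threshold: float = -1.0) -> ScreeningResult:
    """Apply the two-rule actuarial screen to one profile."""
    both_low = []
    any_low = []
    for domain in ZSCORE_DOMAINS:
        zs = [z for _, z in profile.scores[domain]]
        low = [z < threshold for z in zs]  # strictly below: z == threshold passes
        if all(low):
            both_low.append(domain)
        if any(low):
            any_low.append(domain)
    reasons = []
    for d in both_low:
        reasons.append(f"rule 1: both scores below {threshold:g} in {d}")
    if len(any_low) >= 3:
        reasons.append(f"rule 2: at least one score below {threshold:g} "
                       f"in {len(any_low)} domains ({', '.join(any_low)})")
    status = "impaired" if reasons else "normal"
    return ScreeningResult(profile.subject_id, status, tuple(reasons))


def profiles_from_table(df: pd.DataFrame) -> list[NeuropsychProfile]:
    """Group a long-format z-score table into per-subject profiles."""
    profiles = []
    for sid, grp in df.groupby("subject_id", sort=True):
        scores: dict[str, list[tuple[str, float]]] = {}
        for row in grp.itertuples(index=False):
            scores.setdefault(row.domain, []).append((row.test, float(row.z)))
        profiles.append(NeuropsychProfile(str(sid), scores))
    return profiles


def screen_table(df: pd.DataFrame, threshold: float = -1.0) -> pd.DataFrame:
    """Screen every subject in a z-score table; returns screening.csv rows."""
    rows = []
    for profile in profiles_from_table(df):
        res = classify_cognitive_status(profile, threshold)
        rows.append({"subject_id": res.subject_id, "status": res.status,
                     "reasons": "; ".join(res.reasons)})
    return pd.DataFrame(rows, columns=["subject_id", "status", "reasons"])
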