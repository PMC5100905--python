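"""Neuropsychological scoring and cohort inclusion/exclusion rules.

Subtests are standardised against the analysis cohort itself (not external
norms): z = (x - cohort mean) / cohort SD, with timed tests (mazes, colour
trails) sign-flipped so that lower always means worse. Domain compound
scores are the unweighted mean of the domain's subtest z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DomainSpec",
    "DEFAULT_DOMAIN_SPEC",
    "zscore_subtests",
    "compound_scores",
    "svd_eligibility",
    "exclusion_filter",
    "RISK_FACTORS",
]

RISK_FACTORS = (
    "hypertension",
    "hypercholesterolemia",
    "diabetes",
    "obesity",
    "smoking",
    "arterial_disease",
)

#: Exclusion reasons applied in order.
EXCLUSION_ORDER = ("cortical_or_large_subcortical_lesion", "missing_neuropsych", "failed_registration")


@dataclass
class DomainSpec:
    """Mapping of cognitive domains to subtests, plus sign-flip set."""

    domains: dict[str, list[str]]
    inverted_subtests: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        all_subtests = {s for subs in self.domains.values() for s in subs}
        stray = self.inverted_subtests - all_subtests
        if stray:
            raise ValueError(f"inverted subtests not in any domain: {sorted(stray)}")

    @property
    def subtests(self) -> list[str]:
        return [s for subs in self.domains.values() for s in subs]

    @classmethod
    def from_yaml(cls, path) -> "DomainSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            domains={k: list(v) for k, v in raw["domains"].items()},
            inverted_subtests=set(raw.get("inverted_subtests", [])),
        )


#: The memory-clinic battery: executive, visuomotor speed and memory domains.
DEFAULT_DOMAIN_SPEC = DomainSpec(
    domains={
        "executive": [
            "verbal_fluency_animals",
            "verbal_fluency_food",
            "colour_trails_1",
            "colour_trails_2",
        ],
        "speed": ["digit_cancellation", "symbol_digit_modalities", "maze"],
        "memory": [
            "wordlist_immediate_recall",
            "wordlist_delayed_recall",
            "wordlist_recognition",
            "picture_immediate_recall",
            "picture_delayed_recall",
            "picture_recognition",
        ],
    },
    inverted_subtests={"colour_trails_1", "colour_trails_2", "maze"},
)


def zscore_subtests(raw: pd.DataFrame, spec: DomainSpec = DEFAULT_DOMAIN_SPEC) -> pd.DataFrame:
    """Cohort-referenced z-scores per subtest (sample SD, n-1 denominator).

    Timed subtests listed in ``spec.inverted_subtests`` are multiplied by
    -1 after standardisation so that lower z always means poorer
    performance. Missing raw values stay missing.
    """
    cols = [c for c in spec.subtests if c in raw.columns]
    if not cols:
        raise KeyError("no subtest columns found in the raw table")
    z = pd.DataFrame(index=raw.index)
    for col in cols:
        x = pd.to_numeric(raw[col], errors="coerce")
        n = x.notna().sum()
        if n < 2:
            raise ValueError(f"subtest {col!r}: fewer than 2 non-missing values")
        sd = x.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"subtest {col!r}: zero standard deviation")
        zc = (x - x.mean()) / sd
        if col in spec.inverted_subtests:
            zc = -zc
        z[col] = zc
    return z


def compound_scores(z: pd.DataFrame, spec: DomainSpec = DEFAULT_DOMAIN_SPEC) -> pd.DataFrame:
    """Per-domain compound score: mean of the domain's subtest z-scores.

    A subject's domain score is missing unless all of the domain's subtests
    are present (complete battery required for that domain).
    """
    out = pd.DataFrame(index=z.index)
    for domain, subtests in spec.domains.items():
        missing = [s for s in subtests if s not in z.columns]
        if missing:
            raise KeyError(f"domain {domain!r}: subtest columns missing {missing}")
        block = z[subtests]
        score = block.mean(axis=1)
        score[block.isna().any(axis=1)] = np.nan
        out[domain] = score
    return out


def svd_eligibility(rec) -> bool:
    """Operational small-vessel-disease inclusion rule.

    Eligible iff either (1) moderate-to-severe WMH (Fazekas >= 2) or any of
    lacunes / infarcts / microbleeds present, or (2) mild WMH (Fazekas = 1)
    together with at least two of six vascular risk factors (hypertension,
    hypercholesterolemia, diabetes, obesity, smoking, manifest arterial
    disease).
    """
    get = rec.get if hasattr(rec, "get") else lambda k, d=None: getattr(rec, k, d)
    fazekas = get("fazekas")
    if fazekas is None or (isinstance(fazekas, float) and np.isnan(fazekas)):
        raise ValueError("fazekas score missing; eligibility undefined")
    fazekas = int(fazekas)
    findings = any(
        bool(get(k, 0) or 0)
        for k in ("lacunes_present", "infarcts_present", "microbleeds_present")
    )
    if fazekas >= 2 or findings:
        return True
    n_risk = sum(bool(get(k, 0) or 0) for k in RISK_FACTORS)
    return fazekas == 1 and n_risk >= 2


def exclusion_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the cohort exclusion cascade; returns (retained, reasons).

    Drops, in order: subjects with a cortical infarct or a large (>15 mm)
    subcortical infarct/hemorrhage (such lesions can obliterate whole
    tracts), then subjects with missing neuropsychology, then failed
    registrations. ``reasons`` is indexed like ``records`` with NaN for
    retained subjects.
    """
    flag_cols = {
        "cortical_or_large_subcortical_lesion": ["cortical_infarct", "large_subcortical_lesion"],
        "missing_neuropsych": ["missing_neuropsych"],
        "failed_registration": ["failed_registration"],
    }
    reasons = pd.Series(index=records.index, dtype=object)
    excluded = pd.Series(False, index=records.index)
    for reason in EXCLUSION_ORDER:
        hit = pd.Series(False, index=records.index)
        for col in flag_cols[reason]:
            if col in records.columns:
                hit |= records[col].fillna(0).astype(bool)
        newly = hit & ~excluded
        reasons[newly] = reason
        excluded |= hit
    return records[~excluded].copy(), reasons
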