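"""Pairwise association-rule mining over visit records.

For an anchor diagnosis D and every co-occurring code C, patient-level
2x2 counts give support, confidence, lift and a Pearson chi-square test
(1 df, no continuity correction).  Presence is defined per patient, not
per visit: repeating a (patient, code) record never changes a statistic.
Temporal ordering of diagnoses is deliberately not modelled; the rules
describe co-occurrence only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RuleStats:
    antecedent: str
    consequent: str
    n_total: int
    n_d: int
    n_c: int
    n_both: int
    support: float
    confidence: float
    lift: float
    chi2: float
    p_value: float
    defined: bool  # False when a zero margin makes lift/chi2 undefined

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _patient_sets(visits: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated patient x code presence table."""
    need = {"patient_id", "icd9_code"}
    if not need.issubset(visits.columns):
        raise ValueError(f"visit table needs columns {sorted(need)}")
    return visits[["patient_id", "icd9_code"]].drop_duplicates()


def rule_stats(
    visits: pd.DataFrame, d: str, c: str, n_total: int | None = None
) -> RuleStats:
    """2x2-derived statistics for the rule D -> C at patient level.

    ``n_total`` is the size of the screened patient universe; it
    defaults to the number of distinct patients in the table, but should
    be supplied when the records omit diagnosis-free patients (otherwise
    lift is biased upward for the denominator population).
    """
    dedup = _patient_sets(visits)
    patients = dedup["patient_id"].unique()
    if n_total is None:
        n_total = len(patients)
    elif n_total < len(patients):
        raise ValueError("n_total smaller than the number of observed patients")
    if n_total == 0:
        raise ValueError("empty visit table")
    codes = set(dedup["icd9_code"])
    for code in (d, c):
        if code not in codes:
            raise ValueError(f"code {code!r} absent from the visit records")
    with_d = set(dedup.loc[dedup["icd9_code"] == d, "patient_id"])
    with_c = set(dedup.loc[dedup["icd9_code"] == c, "patient_id"])
    n_d, n_c = len(with_d), len(with_c)
    n_both = len(with_d & with_c)
    return _stats_from_counts(d, c, n_total, n_d, n_c, n_both)


def _stats_from_counts(
    d: str, c: str, n_total: int, n_d: int, n_c: int, n_both: int
) -> RuleStats:
    support = n_both / n_total
    defined = 0 < n_d < n_total and 0 < n_c < n_total
    confidence = n_both / n_d if n_d else np.nan
    lift = confidence / (n_c / n_total) if defined else np.nan

    if defined:
        # Pearson chi-square on the 2x2, 1 df, no continuity correction
        a = n_both
        b = n_d - n_both
        cc = n_c - n_both
        dd = n_total - n_d - n_c + n_both
        num = n_total * (a * dd - b * cc) ** 2
        den = n_d * (n_total - n_d) * n_c * (n_total - n_c)
        chi2 = num / den
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = np.nan, np.nan
    return RuleStats(
        d, c, n_total, n_d, n_c, n_both, support, confidence, lift, chi2, p, defined
    )


def mine_rules(
    visits: pd.DataFrame,
    anchor: str,
    min_support: float = 0.0,
    alpha: float = 0.05,
    n_total: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mine D -> C rules for every code co-occurring with the anchor.

    Returns ``(rules, edges)``: rules ranked by lift descending (ties by
    support descending, then code order) with a ``significant`` marker
    at ``p < alpha``; edges as a (source, target, weight, n) TSV-ready
    frame for network tools, weight = lift.  ``n_total`` as in
    :func:`rule_stats`.
    """
    dedup = _patient_sets(visits)
    if dedup.empty:
        cols = [
            "antecedent", "consequent", "n_total", "n_d", "n_c", "n_both",
            "support", "confidence", "lift", "chi2", "p_value", "defined",
            "significant",
        ]
        return pd.DataFrame(columns=cols), pd.DataFrame(
            columns=["source", "target", "weight", "n"]
        )
    if anchor not in set(dedup["icd9_code"]):
        raise ValueError(f"anchor code {anchor!r} absent from the visit records")

    patients = dedup["patient_id"].unique()
    if n_total is None:
        n_total = len(patients)
    elif n_total < len(patients):
        raise ValueError("n_total smaller than the number of observed patients")
    by_code = dedup.groupby("icd9_code")["patient_id"].apply(set)
    with_d = by_code[anchor]
    rows = []
    for code, members in by_code.items():
        if code == anchor:
            continue
        n_both = len(with_d & members)
        st = _stats_from_counts(anchor, code, n_total, len(with_d), len(members), n_both)
        if st.support >= min_support:
            rec = st.to_dict()
            rec["significant"] = bool(st.defined and st.p_value < alpha)
            rows.append(rec)
    rules = pd.DataFrame(rows)
    if not rules.empty:
        rules = rules.sort_values(
            by=["lift", "support", "consequent"],
            ascending=[False, False, True],
            na_position="last",
        ).reset_index(drop=True)
    edges = pd.DataFrame(
        {
            "source": rules["antecedent"],
            "target": rules["consequent"],
            "weight": rules["lift"],
            "n": rules["n_both"],
        }
        if not rules.empty
        else {"source": [], "target": [], "weight": [], "n": []}
    )
    return rules, edges
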