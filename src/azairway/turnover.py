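"""ASV set dynamics between treatment phases and between airway sites.

Per patient and site, ASVs observed in a rarefied table are classified over
a treatment window as retained (present at both ends), cleared (present only
at the window start; no reads at the end) or acquired (present only at the
end). Site overlap partitions the ASVs of a phase into LRT-only / URT-only /
shared, tested with a chi-squared goodness-of-fit test, and cleared/acquired
sets can be tracked as summed relative abundance across all study phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alpha import wilcoxon_paired
from .core import PHASES, FeatureTable, SampleMetadata

__all__ = [
    "TurnoverResult",
    "classify_turnover",
    "classify_cohort_turnover",
    "site_overlap",
    "chisq_gof",
    "tracked_relative_abundance",
    "turnover_balance_test",
]

logger = logging.getLogger(__name__)

#: Window contrasts offered by :func:`turnover_balance_test`.
BALANCE_CONTRASTS = ("cleared_vs_acquired", "acquired_vs_retained", "cleared_vs_retained")


@dataclass
class TurnoverResult:
    """Retained / cleared / acquired ASV sets for one patient-site window."""

    patient_id: str
    site: str
    start_phase: str
    end_phase: str
    retained: frozenset
    cleared: frozenset
    acquired: frozenset

    def __post_init__(self):
        # the three categories must partition start and end presence sets
        assert not (self.retained & self.cleared)
        assert not (self.retained & self.acquired)
        assert not (self.cleared & self.acquired)

    @property
    def present_at_start(self) -> frozenset:
        return self.retained | self.cleared

    @property
    def present_at_end(self) -> frozenset:
        return self.retained | self.acquired

    def cleared_fraction(self) -> float:
        start = self.present_at_start
        return len(self.cleared) / len(start) if start else 0.0

    def to_long(self) -> pd.DataFrame:
        rows = []
        for category, members in (
            ("retained", self.retained),
            ("cleared", self.cleared),
            ("acquired", self.acquired),
        ):
            for asv in sorted(members):
                rows.append(
                    {
                        "patient_id": self.patient_id,
                        "site": self.site,
                        "window": f"{self.start_phase}->{self.end_phase}",
                        "category": category,
                        "asv_id": asv,
                    }
                )
        return pd.DataFrame(rows, columns=["patient_id", "site", "window", "category", "asv_id"])


def _presence_set(table: FeatureTable, sample_id: str) -> frozenset:
    row = table.data.loc[sample_id]
    return frozenset(row.index[row > 0])


def classify_turnover(
    table: FeatureTable,
    meta: SampleMetadata,
    patient_id: str,
    site: str,
    start_phase: str,
    end_phase: str,
) -> TurnoverResult | None:
    """Classify one patient-site window; None (logged) if a sample is missing.

    Presence means at least one read in the (rarefied) table, so windows are
    depth-comparable; cleared = present only at the start, acquired = present
    only at the end, retained = present at both.
    """
    start_sample = meta.sample_for(patient_id, site, start_phase)
    end_sample = meta.sample_for(patient_id, site, end_phase)
    available = set(table.sample_ids)
    if (
        start_sample is None
        or end_sample is None
        or start_sample not in available
        or end_sample not in available
    ):
        logger.info(
            "patient %s site %s: window %s->%s skipped (missing paired sample)",
            patient_id, site, start_phase, end_phase,
        )
        return None
    start_set = _presence_set(table, start_sample)
    end_set = _presence_set(table, end_sample)
    return TurnoverResult(
        patient_id=patient_id,
        site=site,
        start_phase=start_phase,
        end_phase=end_phase,
        retained=start_set & end_set,
        cleared=start_set - end_set,
        acquired=end_set - start_set,
    )


def classify_cohort_turnover(
    table: FeatureTable,
    meta: SampleMetadata,
    site: str,
    start_phase: str,
    end_phase: str,
) -> list[TurnoverResult]:
    """Classify every patient with the paired window available."""
    out = []
    for patient in sorted(meta.data["patient_id"].unique()):
        res = classify_turnover(table, meta, patient, site, start_phase, end_phase)
        if res is not None:
            out.append(res)
    return out


def site_overlap(table: FeatureTable, meta: SampleMetadata, phase: str) -> pd.DataFrame:
    """ASV counts/proportions present in LRT only, URT only, or both sites.

    An ASV counts for a site if it has at least one read in at least one of
    that site's samples in the phase. Returns a three-row frame (category,
    count, proportion); proportions sum to 1.
    """
    phase_meta = meta.data[meta.data["phase"] == phase]
    available = set(table.sample_ids)
    lrt_samples = [s for s in phase_meta[phase_meta["site"] == "LRT"].index if s in available]
    urt_samples = [s for s in phase_meta[phase_meta["site"] == "URT"].index if s in available]
    if not lrt_samples or not urt_samples:
        raise ValueError(f"phase {phase!r} lacks samples at one of the sites")
    lrt = set().union(*(_presence_set(table, s) for s in lrt_samples))
    urt = set().union(*(_presence_set(table, s) for s in urt_samples))
    counts = {
        "LRT_only": len(lrt - urt),
        "URT_only": len(urt - lrt),
        "both": len(lrt & urt),
    }
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no ASVs observed at either site in phase {phase!r}")
    return pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "proportion": [c / total for c in counts.values()],
        }
    )


def chisq_gof(category_counts, expected_proportions=None) -> tuple[float, float]:
    """Pearson chi-squared goodness-of-fit test (df = k - 1).

    Expected proportions default to uniform across the categories.
    """
    observed = np.asarray(list(category_counts), dtype=float)
    if len(observed) < 2:
        raise ValueError("need at least two categories")
    total = observed.sum()
    if total <= 0:
        raise ValueError("zero total count")
    if expected_proportions is None:
        expected = np.full(len(observed), total / len(observed))
    else:
        props = np.asarray(list(expected_proportions), dtype=float)
        if len(props) != len(observed) or not np.isclose(props.sum(), 1.0):
            raise ValueError("expected proportions must match categories and sum to 1")
        expected = props * total
    stat, p = stats.chisquare(observed, expected)
    return float(stat), float(p)


def tracked_relative_abundance(
    table: FeatureTable,
    meta: SampleMetadata,
    asv_set,
    site: str,
) -> pd.DataFrame:
    """Summed relative abundance of an ASV set in every sample of a site.

    Used to follow the community share of a window's cleared or acquired set
    across all five study phases. Returns a long frame (sample_id, phase,
    time_months, value); an empty set gives an all-zero series.
    """
    asv_set = sorted(set(asv_set) & set(table.asv_ids))
    rel = table.relative_abundance()
    site_meta = meta.data[meta.data["site"] == site]
    rows = []
    for sample_id in table.sample_ids:
        if sample_id not in site_meta.index:
            continue
        value = float(rel.loc[sample_id, asv_set].sum()) if asv_set else 0.0
        rows.append(
            {
                "sample_id": sample_id,
                "phase": site_meta.loc[sample_id, "phase"],
                "time_months": site_meta.loc[sample_id, "time_months"],
                "value": value,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "phase", "time_months", "value"])


def summarize_tracked(tracked: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of tracked abundance per phase, in study order."""
    rows = []
    for phase in PHASES:
        vals = tracked.loc[tracked["phase"] == phase, "value"]
        if vals.empty:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"phase": phase, "n": len(vals), "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


def turnover_balance_test(
    results: list[TurnoverResult], contrast: str = "cleared_vs_acquired"
) -> tuple[float, float]:
    """Paired Wilcoxon test on per-patient category counts.

    ``contrast`` picks which two category counts are compared per patient,
    e.g. whether newly acquired ASVs outnumber cleared ones over a window.
    """
    if contrast not in BALANCE_CONTRASTS:
        raise ValueError(f"contrast must be one of {BALANCE_CONTRASTS}")
    if len(results) < 5:
        raise ValueError("need at least 5 patients with paired windows")
    first, second = contrast.split("_vs_")
    x = [len(getattr(r, first)) for r in results]
    y = [len(getattr(r, second)) for r in results]
    try:
        return wilcoxon_paired(x, y)
    except ValueError as exc:
        if "no informative pairs" in str(exc):
            raise ValueError(
                f"no informative pairs: {first} equals {second} for every patient"
            ) from exc
        raise
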