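"""Antibiotic-resistance-gene (ARG) carriage scoring from qPCR copy numbers.

The panel targets seven genes recovered after macrolide exposure in airway
samples: the 23S rRNA methyltransferases erm(B) and erm(F), the ABC-F
ribosomal protection genes mel and msr(E), the efflux pump mef (macrolide
resistance), and the ribosomal protection genes tet(M) and tet(W)
(tetracycline resistance). Copy numbers are normalised to 16S rRNA gene
copies, each gene is min-max scaled across the analysis set so every gene
carries equal weight, and the per-sample cumulative score (0..7) is the sum
of scaled values. Patients are stratified into stable vs increased carriage
by the cohort-median fold change of the cumulative score over treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SampleMetadata

__all__ = [
    "ARG_GENES",
    "ARGPanel",
    "read_arg_panel",
    "normalize_arg",
    "cumulative_arg_score",
    "ResistanceStrata",
    "stratify_resistance",
]

#: The seven-gene qPCR panel.
ARG_GENES = ("erm(B)", "erm(F)", "mel", "msr(E)", "mef", "tet(M)", "tet(W)")


class ARGPanel:
    """Per-sample qPCR copy numbers: 16S rRNA gene plus the ARG panel.

    Parameters
    ----------
    data : pandas.DataFrame
        Indexed by sample id with a positive ``copies_16s`` column and one
        non-negative column per panel gene.
    genes : tuple of str
        Panel genes (defaults to the seven-gene macrolide/tetracycline panel).
    """

    def __init__(self, data: pd.DataFrame, genes: tuple[str, ...] = ARG_GENES):
        if "copies_16s" not in data.columns:
            raise ValueError("ARG panel requires a copies_16s column")
        missing = [g for g in genes if g not in data.columns]
        if missing:
            raise ValueError(f"ARG panel missing gene columns: {missing}")
        if data.index.has_duplicates:
            raise ValueError("duplicate sample ids in ARG panel")
        if (data["copies_16s"] <= 0).any():
            bad = data.index[data["copies_16s"] <= 0].tolist()
            raise ValueError(f"copies_16s must be positive; offending samples: {bad}")
        if (data[list(genes)] < 0).to_numpy().any():
            raise ValueError("gene copy numbers must be non-negative")
        self.genes = tuple(genes)
        self.data = data[["copies_16s", *genes]].astype(float).copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids) -> "ARGPanel":
        return ARGPanel(self.data.loc[list(sample_ids)], self.genes)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    def __repr__(self) -> str:
        return f"<ARGPanel {len(self.data)} samples, {len(self.genes)} genes>"


def read_arg_panel(path, genes: tuple[str, ...] = ARG_GENES) -> ARGPanel:
    """Read an ARG qPCR TSV (sample_id, copies_16s, one column per gene)."""
    return ARGPanel(pd.read_csv(path, sep="\t", index_col="sample_id"), genes)


def normalize_arg(panel: ARGPanel) -> pd.DataFrame:
    """Per-gene copy numbers normalised to 16S rRNA gene copies."""
    return panel.data[list(panel.genes)].div(panel.data["copies_16s"], axis=0)


def cumulative_arg_score(panel: ARGPanel) -> pd.DataFrame:
    """Min-max scale each normalised gene across samples; sum to a 0..7 score.

    Scaling is performed over all samples in the supplied panel (the analysis
    set), so each gene contributes equally to the cumulative score. Genes with
    zero range across the set contribute 0 everywhere. Returns a frame with
    one ``scaled:<gene>`` column per gene plus ``cumulative``.
    """
    if len(panel.data) < 2:
        raise ValueError(
            "min-max scaling needs >= 2 samples; use normalize_arg for raw ratios"
        )
    norm = normalize_arg(panel)
    lo, hi = norm.min(axis=0), norm.max(axis=0)
    rng = hi - lo
    scaled = (norm - lo).div(rng.where(rng > 0, 1.0), axis=1)
    scaled[norm.columns[rng == 0]] = 0.0
    out = scaled.add_prefix("scaled:")
    out["cumulative"] = scaled.sum(axis=1)
    return out


@dataclass
class ResistanceStrata:
    """Median-split patient stratification by cumulative-score fold change."""

    fold_changes: pd.Series  # per patient
    strata: pd.Series  # per patient, "stable" or "increased"
    median_fold_change: float
    mode: str = "ratio"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold_change": self.fold_changes, "stratum": self.strata}
        ).rename_axis("patient_id")


def stratify_resistance(
    panel: ARGPanel,
    meta: SampleMetadata,
    start_phase: str = "StartAZT",
    end_phase: str = "EndAZT",
    site: str = "LRT",
    mode: str = "ratio",
) -> ResistanceStrata:
    """Split patients at the cohort-median change in cumulative ARG score.

    Eligible patients have a ``site`` sample at both ``start_phase`` and
    ``end_phase`` in the panel. ``mode='ratio'`` computes the fold change
    end/start (a zero start score is handled by adding the smallest positive
    cumulative score in the cohort to both terms); ``mode='difference'``
    computes end - start. Patients above the cohort median are labelled
    ``increased``, those at or below ``stable``.
    """
    if mode not in ("ratio", "difference"):
        raise ValueError("mode must be 'ratio' or 'difference'")
    scores = cumulative_arg_score(panel)["cumulative"]
    pairs = {}
    for patient in sorted(meta.data["patient_id"].unique()):
        start = meta.sample_for(patient, site, start_phase)
        end = meta.sample_for(patient, site, end_phase)
        if start in scores.index and end in scores.index:
            pairs[patient] = (scores[start], scores[end])
    if not pairs:
        raise ValueError(
            f"no patients with {site} samples at both {start_phase} and {end_phase}"
        )
    if mode == "difference":
        fc = pd.Series({p: e - s for p, (s, e) in pairs.items()})
    else:
        positive = scores[scores > 0]
        pseudo = float(positive.min()) if not positive.empty else 1.0
        fc = pd.Series(
            {
                p: e / s if s > 0 else (e + pseudo) / (s + pseudo)
                for p, (s, e) in pairs.items()
            }
        )
    median = float(fc.median())
    strata = pd.Series(
        np.where(fc > median, "increased", "stable"), index=fc.index
    )
    if strata.nunique() == 1 and len(strata) >= 2:
        warnings.warn(
            "all fold changes equal: every patient assigned to 'stable'",
            stacklevel=2,
        )
    return ResistanceStrata(fc.sort_index(), strata.sort_index(), median, mode)
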