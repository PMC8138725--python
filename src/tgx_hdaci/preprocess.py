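"""Counts -> control-normalized, replicate-averaged compound profiles.

The processing chain for a targeted-sequencing (TempO-Seq style) exposure
study is:

1. library-size normalization to counts per million (CPM);
2. QC: water-only negative controls must carry < 0.3% of total signal,
   duplicated reference-RNA libraries must correlate within batch;
3. outlier replicates removed when their dissimilarity (1 - Pearson r to
   their replicate-group mean, on the log2 scale) exceeds 0.2;
4. each treated sample ratioed against its matched vehicle (solvent)
   control on the log2 scale, with a 0.5 pseudocount on both sides;
5. surviving replicates of each compound averaged into one profile.

All cutoffs quoted with strict inequalities are applied strictly: signal
share >= 0.3% fails QC, dissimilarity > 0.2 (not >=) removes a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import pearsonr, spearmanr

from .io import CompoundProfile, CountMatrix, SampleMetadata

__all__ = [
    "QCReport",
    "cpm_normalize",
    "normalize_to_control",
    "average_replicates",
    "qc_negative_control",
    "qc_reference_correlation",
    "remove_outliers_by_dissimilarity",
    "cohort_linkage",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_DISSIMILARITY_CUTOFF",
    "NEGATIVE_CONTROL_MAX_FRACTION",
]

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_DISSIMILARITY_CUTOFF = 0.2
NEGATIVE_CONTROL_MAX_FRACTION = 0.003  # water signal must stay strictly below


@dataclass
class QCReport:
    """Aggregated QC outcome for one processing run."""

    negative_control_fraction: float | None = None
    negative_control_pass: bool | None = None
    within_batch_correlations: dict[str, float] = field(default_factory=dict)
    between_batch_correlations: dict[str, float] = field(default_factory=dict)
    outliers_removed: list[tuple[str, float]] = field(default_factory=list)
    dissimilarity_cutoff: float = DEFAULT_DISSIMILARITY_CUTOFF
    dissimilarities: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "negative_control_fraction": self.negative_control_fraction,
            "negative_control_pass": self.negative_control_pass,
            "within_batch_correlations": self.within_batch_correlations,
            "between_batch_correlations": self.between_batch_correlations,
            "outliers_removed": [
                {"sample_id": s, "dissimilarity": d} for s, d in self.outliers_removed
            ],
            "dissimilarity_cutoff": self.dissimilarity_cutoff,
            "dissimilarities": self.dissimilarities,
        }


def cpm_normalize(m: CountMatrix) -> CountMatrix:
    """Scale every sample column of a raw count matrix to sum to 1e6."""
    if m.unit != "raw":
        raise ValueError("cpm_normalize expects a raw count matrix (unit='raw')")
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    cpm = m.values.div(totals, axis=1) * 1e6
    return CountMatrix(cpm, unit="cpm", metadata=m.metadata)


def _meta_map(
    meta: Mapping[str, SampleMetadata] | Sequence[SampleMetadata]
) -> dict[str, SampleMetadata]:
    if isinstance(meta, Mapping):
        return dict(meta)
    return {r.sample_id: r for r in meta}


def normalize_to_control(
    m: CountMatrix,
    meta: Mapping[str, SampleMetadata] | Sequence[SampleMetadata],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-sample log2 ratio of treated CPM to its matched vehicle-control CPM.

    value(g, s) = log2((cpm[g, s] + pc) / (cpm[g, ctrl(s)] + pc)).

    Control, qc and unlabelled samples are dropped from the output; every
    treated sample must reference a control column present in ``m``.
    """
    if m.unit != "cpm":
        raise ValueError("normalize_to_control expects a CPM matrix (unit='cpm')")
    meta = _meta_map(meta)
    out: dict[str, np.ndarray] = {}
    for s in m.samples:
        rec = meta.get(s)
        if rec is None or rec.class_label in ("control", "qc"):
            continue
        if not rec.vehicle_control_id:
            raise ValueError(f"treated sample {s!r} has no vehicle_control_id")
        if rec.vehicle_control_id not in m.values.columns:
            raise ValueError(
                f"control sample {rec.vehicle_control_id!r} (for {s!r}) "
                "absent from count matrix"
            )
        t = m.values[s].to_numpy() + pseudocount
        c = m.values[rec.vehicle_control_id].to_numpy() + pseudocount
        out[s] = np.log2(t / c)
    return pd.DataFrame(out, index=m.values.index)


def average_replicates(
    log2: pd.DataFrame,
    meta: Mapping[str, SampleMetadata] | Sequence[SampleMetadata],
) -> list[CompoundProfile]:
    """Average the surviving replicates of each compound into one profile.

    Order of compounds follows first appearance in ``log2``'s columns; a
    compound reduced to a single surviving replicate is kept with a warning.
    """
    meta = _meta_map(meta)
    genes = tuple(str(g) for g in log2.index)
    groups: dict[str, list[str]] = {}
    for s in log2.columns:
        rec = meta.get(s)
        if rec is None:
            raise ValueError(f"sample {s!r} has no metadata record")
        groups.setdefault(rec.compound, []).append(s)
    profiles = []
    for compound, samples in groups.items():
        if not samples:
            raise ValueError(f"compound {compound!r} has zero surviving replicates")
        if len(samples) == 1:
            logger.warning(
                "compound %r averaged from a single surviving replicate (%s)",
                compound,
                samples[0],
            )
        vals = log2[samples].to_numpy().mean(axis=1)
        profiles.append(
            CompoundProfile(
                compound=compound,
                class_label=meta[samples[0]].class_label,
                genes=genes,
                values=vals,
            )
        )
    return profiles


def qc_negative_control(
    m: CountMatrix, water_sample_ids: Sequence[str]
) -> tuple[float | None, bool | None]:
    """Fraction of total counts carried by water-only libraries.

    Returns (fraction, passed); passed is True only when the share is
    strictly below 0.3%.  With no water samples the check is skipped
    (None, None) with a warning rather than failing.
    """
    water = [s for s in water_sample_ids if s in m.values.columns]
    if not water:
        logger.warning("no water-only samples present; negative-control QC skipped")
        return None, None
    total = float(m.values.to_numpy().sum())
    if total == 0:
        raise ValueError("count matrix is all zero; cannot compute signal share")
    frac = float(m.values[water].to_numpy().sum()) / total
    passed = frac < NEGATIVE_CONTROL_MAX_FRACTION
    if not passed:
        logger.warning(
            "water-only signal share %.5f is not < %.3f", frac,
            NEGATIVE_CONTROL_MAX_FRACTION,
        )
    return frac, passed


def qc_reference_correlation(
    m: CountMatrix,
    pairs: Sequence[tuple[str, str]],
    method: str = "pearson",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, float]:
    """Correlate duplicated reference-RNA libraries on log2(CPM + pc).

    Raw input is CPM-normalized first so the correlation is invariant to
    sequencing depth.  A constant vector makes the correlation undefined;
    such pairs are reported as NaN with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    cpm = m if m.unit == "cpm" else cpm_normalize(m)
    out: dict[str, float] = {}
    for a, b in pairs:
        for s in (a, b):
            if s not in cpm.values.columns:
                raise ValueError(f"sample {s!r} absent from count matrix")
        x = np.log2(cpm.values[a].to_numpy() + pseudocount)
        y = np.log2(cpm.values[b].to_numpy() + pseudocount)
        key = f"{a}|{b}"
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("constant vector in pair %s; correlation undefined", key)
            out[key] = float("nan")
            continue
        r = pearsonr(x, y)[0] if method == "pearson" else spearmanr(x, y)[0]
        out[key] = float(r)
    return out


def remove_outliers_by_dissimilarity(
    log2: pd.DataFrame,
    meta: Mapping[str, SampleMetadata] | Sequence[SampleMetadata],
    cutoff: float = DEFAULT_DISSIMILARITY_CUTOFF,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop replicates that sit far from the rest of their replicate group.

    Dissimilarity of sample s = 1 - Pearson r(s, mean of the *other*
    replicates of its compound), computed on the supplied log2 matrix.  The
    leave-one-out mean is essential: a mean that includes the candidate
    sample is dominated by that sample exactly when its noise is largest,
    driving the correlation back toward 1 and masking the outlier.

    Removal is greedy, one sample per pass: within each replicate group the
    single worst sample whose dissimilarity strictly exceeds ``cutoff`` is
    dropped and the remaining dissimilarities recomputed, because one gross
    outlier contaminates its groupmates' leave-one-out means and would
    otherwise drag faithful replicates out with it.  Samples without a
    replicate partner get dissimilarity 0 (nothing to compare against).  A
    full-cohort average-linkage dendrogram is available separately via
    :func:`cohort_linkage` for visual inspection; the removal rule itself
    does not depend on tree topology.
    """
    if log2.shape[1] < 3:
        raise ValueError("need at least 3 samples for outlier screening")
    meta = _meta_map(meta)
    groups: dict[str, list[str]] = {}
    for s in log2.columns:
        rec = meta.get(s)
        comp = rec.compound if rec is not None else s
        groups.setdefault(comp, []).append(s)
    report = QCReport(dissimilarity_cutoff=cutoff)

    def dissimilarity(s: str, others: list[str]) -> float:
        gmean = log2[others].to_numpy().mean(axis=1)
        x = log2[s].to_numpy()
        if np.ptp(x) == 0 or np.ptp(gmean) == 0:
            return 0.0 if np.allclose(x, gmean) else 1.0
        return 1.0 - float(np.corrcoef(x, gmean)[0, 1])

    removed: list[str] = []
    for compound, samples in groups.items():
        active = list(samples)
        while True:
            scores = {}
            for s in active:
                others = [t for t in active if t != s]
                scores[s] = dissimilarity(s, others) if others else 0.0
            report.dissimilarities.update(scores)
            worst = max(scores, key=scores.get)  # type: ignore[arg-type]
            if scores[worst] <= cutoff or len(active) == 1:
                break
            active.remove(worst)
            removed.append(worst)
            report.outliers_removed.append((worst, scores[worst]))
            logger.warning(
                "removing outlier replicate %r of %r (dissimilarity %.3f > %.3f)",
                worst, compound, scores[worst], cutoff,
            )
    kept = log2.drop(columns=removed)
    return kept, report


def cohort_linkage(log2: pd.DataFrame) -> np.ndarray:
    """Average-linkage, Euclidean-distance linkage matrix over all samples."""
    return linkage(log2.to_numpy().T, method="average", metric="euclidean")
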