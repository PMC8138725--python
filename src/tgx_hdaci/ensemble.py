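"""Corroborating classification prongs: PCA projection and hierarchical
clustering, combined with the probability rule into a three-pronged call.

The shrunken-centroid probability rule is the formal classifier; the PCA and
clustering calls corroborate it.  The combined (ensemble) call therefore
always equals the probability-rule call, and a ``concordant`` flag records
whether all three prongs agreed.

PCA prong: principal components are fitted on the centered (not rescaled)
reference profiles only; queries are projected with the reference loadings so
reference geometry never shifts.  PC1 is oriented so the HDACi class mean is
on the positive side, and the decision threshold is the midpoint of the two
class means on PC1.

Clustering prong: average-linkage, Euclidean-distance agglomerative
clustering of the references plus ONE query at a time, cut into two clusters;
the call is the majority reference class in the query's cluster.  A query
landing in a singleton cluster, or a tied majority, is unclassifiable for
this prong and falls back to the probability-rule call with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .io import CompoundProfile
from .nsc import (
    DEFAULT_PROBABILITY_CUTOFF,
    NEGATIVE_CLASS,
    POSITIVE_CLASS,
    NSCResults,
    classify_nsc,
)

__all__ = [
    "ClassificationResult",
    "PCAClassifier",
    "pca_classify",
    "hclust_classify",
    "classify_compound",
    "classify_compounds",
    "export_heatmap_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class ClassificationResult:
    """Three-pronged call for one compound."""

    compound: str
    nsc_probability_hdaci: float
    nsc_call: str
    pca_call: str
    hclust_call: str
    pc1_score: float
    ensemble_call: str
    concordant: bool

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "nsc_probability_hdaci": self.nsc_probability_hdaci,
            "nsc_call": self.nsc_call,
            "pca_call": self.pca_call,
            "hclust_call": self.hclust_call,
            "pc1_score": self.pc1_score,
            "ensemble_call": self.ensemble_call,
            "concordant": self.concordant,
        }


def _stack(profiles: Sequence[CompoundProfile]) -> np.ndarray:
    genes = profiles[0].genes
    for p in profiles[1:]:
        if p.genes != genes:
            raise ValueError(
                f"profile {p.compound!r} gene list differs from "
                f"{profiles[0].compound!r}"
            )
    return np.vstack([p.values for p in profiles])


class PCAClassifier:
    """PC1-threshold classifier fitted on labeled reference profiles."""

    def __init__(self, reference: Sequence[CompoundProfile]) -> None:
        labels = [p.class_label for p in reference]
        for cls_ in (POSITIVE_CLASS, NEGATIVE_CLASS):
            if labels.count(cls_) < 3:
                raise ValueError(
                    f"PCA prong needs >= 3 reference compounds per class; "
                    f"{cls_!r} has {labels.count(cls_)}"
                )
        self.genes = reference[0].genes
        X = _stack(reference)
        self._pca = PCA(n_components=1).fit(X)  # sklearn centers internally
        scores = self._pca.transform(X)[:, 0]
        y = np.asarray(labels, dtype=object)
        mean_pos = scores[y == POSITIVE_CLASS].mean()
        mean_neg = scores[y == NEGATIVE_CLASS].mean()
        self.flip = -1.0 if mean_pos < mean_neg else 1.0
        mean_pos, mean_neg = self.flip * mean_pos, self.flip * mean_neg
        self.threshold = 0.5 * (mean_pos + mean_neg)
        pooled = scores.std(ddof=1)
        if pooled > 0 and abs(mean_pos - mean_neg) < 0.1 * pooled:
            logger.warning(
                "reference classes barely separated on PC1 "
                "(class-mean gap %.3g < 0.1 pooled SD %.3g); calls may be unstable",
                abs(mean_pos - mean_neg), pooled,
            )
        self.reference_scores = self.flip * scores

    def score(self, profiles: Sequence[CompoundProfile]) -> np.ndarray:
        for p in profiles:
            if p.genes != self.genes:
                raise ValueError(f"query {p.compound!r} gene list mismatch")
        return self.flip * self._pca.transform(_stack(profiles))[:, 0]

    def classify(
        self, profiles: Sequence[CompoundProfile]
    ) -> list[tuple[float, str]]:
        scores = self.score(profiles)
        return [
            (float(s), POSITIVE_CLASS if s > self.threshold else NEGATIVE_CLASS)
            for s in scores
        ]


def pca_classify(
    reference: Sequence[CompoundProfile],
    queries: Sequence[CompoundProfile],
) -> list[tuple[float, str]]:
    """Fit PC1 on references, project queries, call by threshold side."""
    return PCAClassifier(reference).classify(queries)


def hclust_classify(
    reference: Sequence[CompoundProfile],
    query: CompoundProfile,
    method: str = "average",
    metric: str = "euclidean",
) -> str | None:
    """Two-cluster cut over references + one query; majority-class call.

    Returns None when the prong cannot assign a class (singleton query
    cluster or tied majority).
    """
    labels = [p.class_label for p in reference]
    for cls_ in (POSITIVE_CLASS, NEGATIVE_CLASS):
        if labels.count(cls_) < 2:
            raise ValueError(
                f"clustering prong needs >= 2 reference compounds per class"
            )
    X = _stack(list(reference) + [query])
    Z = linkage(X, method=method, metric=metric)
    clusters = fcluster(Z, t=2, criterion="maxclust")
    qc = clusters[-1]
    mates = [lab for lab, c in zip(labels, clusters[:-1]) if c == qc]
    if not mates:
        logger.warning(
            "query %r forms a singleton cluster; clustering prong unclassifiable",
            query.compound,
        )
        return None
    n_pos = mates.count(POSITIVE_CLASS)
    n_neg = mates.count(NEGATIVE_CLASS)
    if n_pos == n_neg:
        logger.warning(
            "tied majority in query %r's cluster; clustering prong unclassifiable",
            query.compound,
        )
        return None
    return POSITIVE_CLASS if n_pos > n_neg else NEGATIVE_CLASS


def joint_tree(profiles: Sequence[CompoundProfile]) -> np.ndarray:
    """All-compounds dendrogram (display only): average linkage, Euclidean."""
    return linkage(_stack(profiles), method="average", metric="euclidean")


def classify_compound(
    model: NSCResults,
    reference: Sequence[CompoundProfile],
    query: CompoundProfile,
    cutoff: float = DEFAULT_PROBABILITY_CUTOFF,
) -> ClassificationResult:
    """Run all three prongs on one panel-aligned query profile.

    The ensemble call equals the probability-rule call; PCA and clustering
    contribute only to the concordance flag.  An unclassifiable clustering
    prong falls back to the probability-rule call (with a warning already
    logged by the prong).
    """
    nsc_call, p_pos = classify_nsc(model, query, cutoff=cutoff)
    pca = PCAClassifier(reference)
    (pc1, pca_call), = pca.classify([query])
    h_call = hclust_classify(reference, query)
    if h_call is None:
        h_call = nsc_call
    concordant = nsc_call == pca_call == h_call
    return ClassificationResult(
        compound=query.compound,
        nsc_probability_hdaci=p_pos,
        nsc_call=nsc_call,
        pca_call=pca_call,
        hclust_call=h_call,
        pc1_score=pc1,
        ensemble_call=nsc_call,
        concordant=concordant,
    )


def classify_compounds(
    model: NSCResults,
    reference: Sequence[CompoundProfile],
    queries: Sequence[CompoundProfile],
    cutoff: float = DEFAULT_PROBABILITY_CUTOFF,
) -> list[ClassificationResult]:
    """Classify each query independently (one-at-a-time clustering prong)."""
    return [classify_compound(model, reference, q, cutoff=cutoff) for q in queries]


def export_heatmap_matrix(
    profiles: Sequence[CompoundProfile],
    panel_genes: Sequence[str],
    calls: dict[str, str] | None = None,
    truth: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Plot-ready genes x compounds table with call/truth annotation rows.

    Rows are the panel genes in panel order, plus annotation rows ``_call``
    and ``_truth``; columns are compounds.  Rendering is left to the caller.
    """
    panel_genes = list(panel_genes)
    cols: dict[str, list] = {}
    for p in profiles:
        idx = {g: i for i, g in enumerate(p.genes)}
        missing = [g for g in panel_genes if g not in idx]
        if missing:
            raise ValueError(
                f"profile {p.compound!r} lacks panel gene(s) {missing}"
            )
        vals = [p.values[idx[g]] for g in panel_genes]
        vals.append((calls or {}).get(p.compound, ""))
        vals.append((truth or {}).get(p.compound, p.class_label))
        cols[p.compound] = vals
    return pd.DataFrame(cols, index=panel_genes + ["_call", "_truth"])
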