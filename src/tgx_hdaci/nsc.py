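"""Nearest shrunken centroid (NSC / PAM-style) classification.

The model, written for gene-expression profiles of chemical exposures, is the
classic shrunken-centroid discriminant.  With classes k = 1..K over n
compounds (n_k per class) and genes i:

* overall centroid  x_bar_i  and class centroids  x_bar_ik  (plain means);
* pooled within-class standard deviation
  s_i^2 = (1/(n-K)) * sum_k sum_{j in k} (x_ij - x_bar_ik)^2;
* fudge factor  s0 = median_i(s_i), stabilizing low-variance genes;
* standardized contrast  d_ik = (x_bar_ik - x_bar_i) / (m_k (s_i + s0))
  with  m_k = sqrt(1/n_k - 1/n);
* soft-thresholding  d'_ik = sign(d_ik) max(|d_ik| - delta, 0)  shrinks the
  contrasts by delta; genes whose contrasts all hit zero drop out of the
  classifier ("surviving genes" are the biomarker panel);
* shrunken centroids  x_bar'_ik = x_bar_i + m_k (s_i + s0) d'_ik;
* discriminant score for a new profile x:
  delta_k(x) = sum_{i surviving} (x_i - x_bar'_ik)^2 / (s_i + s0)^2
               - 2 log pi_k,
  and class probabilities proportional to exp(-delta_k(x)/2).

A compound is called a histone deacetylase inhibitor (HDACi) only when its
HDACi class probability strictly exceeds the cutoff (default 0.90); anything
else is called non-HDACi.  The shrinkage amount is chosen on a grid by
compound-level, class-stratified k-fold cross-validation, targeting a panel
of 50-100 genes at >= 95% CV accuracy.

Usage follows the model/results convention::

    model = NSC.from_profiles(profiles)
    res = model.fit(delta=3.449)
    res.predict_proba(query.values)
    path = model.path(folds=10, seed=17)
    best = select_shrinkage(path)
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CompoundProfile

__all__ = [
    "NSC",
    "NSCResults",
    "ShrinkagePath",
    "soft_threshold",
    "fit_nsc",
    "class_probabilities",
    "classify_nsc",
    "shrinkage_path",
    "select_shrinkage",
    "DEFAULT_PROBABILITY_CUTOFF",
    "POSITIVE_CLASS",
]

logger = logging.getLogger(__name__)

DEFAULT_PROBABILITY_CUTOFF = 0.90
POSITIVE_CLASS = "HDACi"
NEGATIVE_CLASS = "non-HDACi"


def soft_threshold(d, delta: float):
    """sign(d) * max(|d| - delta, 0), elementwise."""
    if delta < 0:
        raise ValueError("shrinkage delta must be >= 0")
    d = np.asarray(d, dtype=float)
    out = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class _Stats:
    """Sufficient statistics of a training set, before any shrinkage."""

    overall: np.ndarray          # (g,)
    centroids: np.ndarray        # (g, K)
    pooled_sd: np.ndarray        # (g,)
    s0: float
    mk: np.ndarray               # (K,)
    priors: np.ndarray           # (K,)
    dstat: np.ndarray            # (g, K)


class NSC:
    """Nearest-shrunken-centroid model over labeled compound profiles.

    Parameters
    ----------
    X : (n_compounds, n_genes) array of log2 control-relative expression.
    y : class label per compound.
    genes : gene symbols (column names of X).
    compounds : compound identifiers (row names), used for CV fold grouping.
    priors : "uniform" (default, matching a balanced reference design) or
        "empirical" (class frequencies).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: Sequence[str],
        genes: Sequence[str],
        compounds: Sequence[str] | None = None,
        priors: str = "uniform",
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (compounds x genes)")
        self.y = np.asarray(list(y), dtype=object)
        self.genes = tuple(str(g) for g in genes)
        if self.X.shape[1] != len(self.genes):
            raise ValueError("X column count does not match gene list")
        if self.X.shape[0] != len(self.y):
            raise ValueError("X row count does not match label list")
        if compounds is None:
            compounds = [f"compound_{j}" for j in range(self.X.shape[0])]
        self.compounds = tuple(str(c) for c in compounds)
        if priors not in ("uniform", "empirical"):
            raise ValueError("priors must be 'uniform' or 'empirical'")
        self.priors_mode = priors
        self.classes = tuple(dict.fromkeys(self.y))  # order of first appearance
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")

    @classmethod
    def from_profiles(
        cls, profiles: Sequence[CompoundProfile], priors: str = "uniform"
    ) -> "NSC":
        if not profiles:
            raise ValueError("no profiles supplied")
        genes = profiles[0].genes
        for p in profiles[1:]:
            if p.genes != genes:
                raise ValueError(
                    f"profile {p.compound!r} gene list differs from "
                    f"{profiles[0].compound!r}; align profiles first"
                )
        X = np.vstack([p.values for p in profiles])
        y = [p.class_label for p in profiles]
        compounds = [p.compound for p in profiles]
        return cls(X, y, genes=genes, compounds=compounds, priors=priors)

    # -- estimation ---------------------------------------------------------

    def _stats(self, rows: np.ndarray | None = None) -> _Stats:
        idx = np.arange(self.X.shape[0]) if rows is None else np.asarray(rows)
        X, y = self.X[idx], self.y[idx]
        n = len(idx)
        K = len(self.classes)
        centroids = np.empty((X.shape[1], K))
        nk = np.empty(K)
        ss = np.zeros(X.shape[1])
        for k, cls_ in enumerate(self.classes):
            mask = y == cls_
            nk[k] = mask.sum()
            if nk[k] < 2:
                raise ValueError(
                    f"class {cls_!r} has {int(nk[k])} member(s); need >= 2"
                )
            Xk = X[mask]
            centroids[:, k] = Xk.mean(axis=0)
            ss += ((Xk - centroids[:, k]) ** 2).sum(axis=0)
        pooled_sd = np.sqrt(ss / (n - K))
        if not np.any(pooled_sd > 0):
            raise ValueError(
                "all pooled within-class SDs are zero; data are degenerate"
            )
        s0 = float(np.median(pooled_sd))
        overall = X.mean(axis=0)
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        if self.priors_mode == "uniform":
            priors = np.full(K, 1.0 / K)
        else:
            priors = nk / n
        denom = pooled_sd + s0
        dstat = (centroids - overall[:, None]) / (mk[None, :] * denom[:, None])
        return _Stats(overall, centroids, pooled_sd, s0, mk, priors, dstat)

    def fit(self, delta: float = 0.0) -> "NSCResults":
        """Estimate centroids and apply shrinkage ``delta``."""
        return NSCResults._from_stats(self, self._stats(), delta)

    # -- cross-validated shrinkage path -------------------------------------

    def _fold_assignment(self, folds: int, seed: int | None) -> dict[str, int]:
        """Compound-level, class-stratified fold assignment."""
        uniq: dict[str, str] = {}
        for comp, lab in zip(self.compounds, self.y):
            if comp in uniq and uniq[comp] != lab:
                raise ValueError(f"compound {comp!r} appears with two labels")
            uniq[comp] = lab
        if folds > len(uniq):
            raise ValueError(
                f"{folds}-fold CV impossible with {len(uniq)} compounds"
            )
        rng = np.random.default_rng(seed)
        assignment: dict[str, int] = {}
        offset = 0
        for cls_ in self.classes:
            members = [c for c, lab in uniq.items() if lab == cls_]
            order = rng.permutation(len(members))
            for pos, j in enumerate(order):
                assignment[members[j]] = (pos + offset) % folds
            offset += len(members)  # stagger classes so folds fill evenly
        return assignment

    def path(
        self,
        grid: Sequence[float] | None = None,
        n_grid: int = 30,
        folds: int = 10,
        cutoff: float = DEFAULT_PROBABILITY_CUTOFF,
        seed: int | None = None,
    ) -> "ShrinkagePath":
        """k-fold CV accuracy and surviving-gene count along a shrinkage grid.

        The default grid is ``n_grid`` evenly spaced values from 0 up to the
        smallest delta that extinguishes every gene (max |d_ik| on the full
        data).  Held-out compounds are called with the strict probability
        rule: positive class iff P > cutoff.
        """
        full = self._stats()
        if grid is None:
            dmax = float(np.abs(full.dstat).max())
            grid = np.linspace(0.0, dmax, n_grid)
        grid = np.asarray(sorted(grid), dtype=float)
        assignment = self._fold_assignment(folds, seed)
        comp_arr = np.asarray(self.compounds, dtype=object)
        fold_of_row = np.array([assignment[c] for c in comp_arr])

        genes_surviving = np.array(
            [int(_survivors(full.dstat, d).sum()) for d in grid]
        )
        correct = np.zeros(len(grid))
        total = 0
        for f in range(folds):
            test = np.where(fold_of_row == f)[0]
            train = np.where(fold_of_row != f)[0]
            if len(test) == 0:
                continue
            stats = self._stats(train)
            total += len(test)
            for gi, d in enumerate(grid):
                res = NSCResults._from_stats(self, stats, float(d))
                proba = res._predict_proba(self.X[test], allow_empty=True)
                calls = res._calls_from_proba(proba, cutoff)
                correct[gi] += (calls == self.y[test]).sum()
        cv_accuracy = correct / total
        return ShrinkagePath(
            thresholds=grid,
            genes_surviving=genes_surviving,
            cv_accuracy=cv_accuracy,
            fold_assignment=assignment,
            folds=folds,
            cutoff=cutoff,
            seed=seed,
        )


def _survivors(dstat: np.ndarray, delta: float) -> np.ndarray:
    return (np.abs(soft_threshold(dstat, delta)) > 0).any(axis=1)


class NSCResults:
    """A fitted (or frozen) shrunken-centroid classifier.

    Carries everything needed to score a profile: shrunken centroids, the
    per-gene standardization denominator (s_i + s0), priors, and the
    surviving-gene mask.  Instances come from :meth:`NSC.fit`, from a saved
    model JSON, or from a packaged biomarker asset.
    """

    def __init__(
        self,
        genes: Sequence[str],
        classes: Sequence[str],
        shrunken_centroids: np.ndarray,
        denom: np.ndarray,
        priors: np.ndarray,
        delta: float = 0.0,
        surviving_mask: np.ndarray | None = None,
        overall_centroid: np.ndarray | None = None,
        class_centroids: np.ndarray | None = None,
        pooled_sd: np.ndarray | None = None,
        s0: float | None = None,
        mk: np.ndarray | None = None,
        dstat: np.ndarray | None = None,
        shrunken_dstat: np.ndarray | None = None,
        name: str = "nsc-model",
        provenance: str = "",
        model: "NSC | None" = None,
    ) -> None:
        self.genes = tuple(str(g) for g in genes)
        self.classes = tuple(str(c) for c in classes)
        self.shrunken_centroids = np.asarray(shrunken_centroids, dtype=float)
        self.denom = np.asarray(denom, dtype=float)
        if np.any(self.denom <= 0):
            raise ValueError("standardization denominators must be positive")
        self.priors = np.asarray(priors, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        self.delta = float(delta)
        if surviving_mask is None:
            surviving_mask = np.ones(len(self.genes), dtype=bool)
        self.surviving_mask = np.asarray(surviving_mask, dtype=bool)
        self.overall_centroid = overall_centroid
        self.class_centroids = class_centroids
        self.pooled_sd = pooled_sd
        self.s0 = s0
        self.mk = mk
        self.dstat = dstat
        self.shrunken_dstat = shrunken_dstat
        self.name = name
        self.provenance = provenance
        self.model = model

    @classmethod
    def _from_stats(cls, model: NSC, stats: _Stats, delta: float) -> "NSCResults":
        dprime = soft_threshold(stats.dstat, delta)
        denom = stats.pooled_sd + stats.s0
        shrunken = stats.overall[:, None] + (
            stats.mk[None, :] * denom[:, None] * dprime
        )
        mask = (np.abs(dprime) > 0).any(axis=1)
        return cls(
            genes=model.genes,
            classes=model.classes,
            shrunken_centroids=shrunken,
            denom=denom,
            priors=stats.priors,
            delta=delta,
            surviving_mask=mask,
            overall_centroid=stats.overall,
            class_centroids=stats.centroids,
            pooled_sd=stats.pooled_sd,
            s0=stats.s0,
            mk=stats.mk,
            dstat=stats.dstat,
            shrunken_dstat=dprime,
            model=model,
        )

    # -- derived views ------------------------------------------------------

    @property
    def surviving_genes(self) -> tuple[str, ...]:
        return tuple(g for g, m in zip(self.genes, self.surviving_mask) if m)

    @property
    def n_surviving(self) -> int:
        return int(self.surviving_mask.sum())

    # -- prediction ---------------------------------------------------------

    def _coerce(self, x) -> np.ndarray:
        if isinstance(x, CompoundProfile):
            if x.genes != self.genes:
                raise ValueError(
                    f"profile {x.compound!r} gene list does not match the model; "
                    "align it with biomarker.subset_profile first"
                )
            x = x.values
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != len(self.genes):
            raise ValueError(
                f"profile has {x.shape[1]} genes, model expects {len(self.genes)}"
            )
        return x

    def discriminant(self, x) -> np.ndarray:
        """delta_k(x) per class, summed over surviving genes."""
        X = self._coerce(x)
        m = self.surviving_mask
        if not m.any():
            raise ValueError("fully shrunken model: no surviving genes")
        return self._discriminant(X)

    def _discriminant(self, X: np.ndarray) -> np.ndarray:
        m = self.surviving_mask
        d = np.empty((X.shape[0], len(self.classes)))
        for k in range(len(self.classes)):
            z = (X[:, m] - self.shrunken_centroids[m, k][None, :]) / self.denom[m][None, :]
            d[:, k] = (z**2).sum(axis=1) - 2.0 * np.log(self.priors[k])
        return d

    def _predict_proba(self, X: np.ndarray, allow_empty: bool = False) -> np.ndarray:
        if not self.surviving_mask.any():
            if allow_empty:
                return np.tile(self.priors, (X.shape[0], 1))
            raise ValueError("fully shrunken model: no surviving genes")
        d = self._discriminant(X)
        # log-sum-exp stabilization: scores can be hundreds of units apart
        z = -0.5 * d
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict_proba(self, x) -> np.ndarray:
        """Class probabilities, rows summing to 1 (softmax over -delta_k/2)."""
        return self._predict_proba(self._coerce(x))

    def _calls_from_proba(self, proba: np.ndarray, cutoff: float) -> np.ndarray:
        """Strict binary probability rule: positive class iff P > cutoff."""
        if POSITIVE_CLASS in self.classes and len(self.classes) == 2:
            pos = self.classes.index(POSITIVE_CLASS)
            neg = [c for c in self.classes if c != POSITIVE_CLASS][0]
            return np.where(proba[:, pos] > cutoff, POSITIVE_CLASS, neg).astype(object)
        return np.asarray([self.classes[j] for j in proba.argmax(axis=1)], dtype=object)

    def predict(self, x, cutoff: float = DEFAULT_PROBABILITY_CUTOFF) -> np.ndarray:
        return self._calls_from_proba(self.predict_proba(x), cutoff)

    # -- reporting ----------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Per-surviving-gene table of shrunken contrasts and centroids."""
        m = self.surviving_mask
        data = {"gene": [g for g, keep in zip(self.genes, m) if keep]}
        for k, cls_ in enumerate(self.classes):
            data[f"centroid[{cls_}]"] = self.shrunken_centroids[m, k]
        data["sd"] = self.denom[m]
        if self.shrunken_dstat is not None:
            for k, cls_ in enumerate(self.classes):
                data[f"d'[{cls_}]"] = self.shrunken_dstat[m, k]
        return pd.DataFrame(data)

    def summary(self) -> str:
        lines = [
            "Nearest Shrunken Centroid Results",
            "=" * 45,
            f"classes:         {', '.join(self.classes)}",
            f"priors:          {np.array2string(self.priors, precision=3)}",
            f"shrinkage delta: {self.delta:.4f}",
            f"fudge factor s0: {'-' if self.s0 is None else format(self.s0, '.4f')}",
            f"genes (total):   {len(self.genes)}",
            f"genes surviving: {self.n_surviving}",
            "=" * 45,
        ]
        frame = self.summary_frame()
        with pd.option_context("display.max_rows", 25, "display.width", 120):
            lines.append(frame.to_string(index=False, float_format="%.3f"))
        return "\n".join(lines)

    # -- persistence (schema shared with packaged biomarker assets) ---------

    def to_dict(self, cutoff: float = DEFAULT_PROBABILITY_CUTOFF) -> dict:
        """Serializable classifier restricted to the surviving panel."""
        m = self.surviving_mask
        return {
            "name": self.name,
            "genes": [g for g, keep in zip(self.genes, m) if keep],
            "classes": list(self.classes),
            "centroids": {
                cls_: [float(v) for v in self.shrunken_centroids[m, k]]
                for k, cls_ in enumerate(self.classes)
            },
            "sd": [float(v) for v in self.denom[m]],
            "priors": [float(p) for p in self.priors],
            "cutoff": cutoff,
            "delta": self.delta,
            "s0": self.s0,
            "provenance": self.provenance,
        }

    def save(self, path: str | Path, cutoff: float = DEFAULT_PROBABILITY_CUTOFF) -> None:
        Path(path).write_text(json.dumps(self.to_dict(cutoff), indent=1) + "\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "NSCResults":
        genes = list(d["genes"])
        classes = list(d["classes"])
        cent = np.column_stack([d["centroids"][c] for c in classes])
        return cls(
            genes=genes,
            classes=classes,
            shrunken_centroids=cent,
            denom=np.asarray(d["sd"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            delta=float(d.get("delta", 0.0)),
            s0=d.get("s0"),
            name=d.get("name", "nsc-model"),
            provenance=d.get("provenance", ""),
        )

    @classmethod
    def load(cls, path: str | Path) -> "NSCResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ShrinkagePath:
    """CV accuracy and panel size along an increasing shrinkage grid."""

    thresholds: np.ndarray
    genes_surviving: np.ndarray
    cv_accuracy: np.ndarray
    fold_assignment: dict[str, int]
    folds: int
    cutoff: float
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta": self.thresholds,
                "genes_surviving": self.genes_surviving,
                "cv_accuracy": self.cv_accuracy,
            }
        )


def select_shrinkage(
    path: ShrinkagePath,
    gene_range: tuple[int, int] = (50, 100),
    min_accuracy: float = 0.95,
) -> float:
    """Choose the shrinkage delta: smallest panel meeting the accuracy floor.

    Among grid points with CV accuracy >= ``min_accuracy`` and surviving-gene
    count inside ``gene_range``, the largest delta (most shrinkage) wins.  If
    no point satisfies both, the accurate point whose panel size is nearest
    the range is returned with a warning.
    """
    if len(path.thresholds) == 0:
        raise ValueError("empty shrinkage path")
    lo, hi = gene_range
    ok = path.cv_accuracy >= min_accuracy
    if not ok.any():
        best = float(path.cv_accuracy.max())
        raise ValueError(
            f"no shrinkage value reaches CV accuracy {min_accuracy:.2f} "
            f"(best achieved: {best:.3f})"
        )
    in_range = ok & (path.genes_surviving >= lo) & (path.genes_surviving <= hi)
    if in_range.any():
        return float(path.thresholds[in_range][-1])
    dist = np.where(
        path.genes_surviving < lo, lo - path.genes_surviving,
        np.where(path.genes_surviving > hi, path.genes_surviving - hi, 0),
    ).astype(float)
    dist[~ok] = np.inf
    # nearest to range; ties broken toward more shrinkage
    best_dist = dist.min()
    candidates = np.where(dist == best_dist)[0]
    idx = candidates[-1]
    warnings.warn(
        f"no shrinkage value gives {lo}-{hi} surviving genes at accuracy "
        f">= {min_accuracy:.2f}; returning delta={path.thresholds[idx]:.4f} "
        f"with {int(path.genes_surviving[idx])} genes",
        stacklevel=2,
    )
    return float(path.thresholds[idx])


# ---------------------------------------------------------------------------
# functional surface (thin wrappers over the model/results objects)
# ---------------------------------------------------------------------------

def fit_nsc(
    profiles: Sequence[CompoundProfile],
    delta: float = 0.0,
    priors: str = "uniform",
) -> NSCResults:
    """Fit the shrunken-centroid classifier on labeled compound profiles."""
    return NSC.from_profiles(profiles, priors=priors).fit(delta)


def class_probabilities(model: NSCResults, profile) -> dict[str, float]:
    """Per-class posterior probabilities for one profile."""
    p = model.predict_proba(profile)[0]
    return {cls_: float(v) for cls_, v in zip(model.classes, p)}


def classify_nsc(
    model: NSCResults,
    profile,
    cutoff: float = DEFAULT_PROBABILITY_CUTOFF,
) -> tuple[str, float]:
    """Binary probability-rule call; returns (call, P(positive class))."""
    proba = model.predict_proba(profile)
    call = model._calls_from_proba(proba, cutoff)[0]
    pos = model.classes.index(POSITIVE_CLASS) if POSITIVE_CLASS in model.classes else 0
    return str(call), float(proba[0, pos])


def shrinkage_path(
    profiles: Sequence[CompoundProfile],
    grid: Sequence[float] | None = None,
    folds: int = 10,
    cutoff: float = DEFAULT_PROBABILITY_CUTOFF,
    seed: int | None = None,
    priors: str = "uniform",
) -> ShrinkagePath:
    """Cross-validated shrinkage path for a set of labeled profiles."""
    return NSC.from_profiles(profiles, priors=priors).path(
        grid=grid, folds=folds, cutoff=cutoff, seed=seed
    )
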