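"""Synthetic exposure-study generator.

Emulates the statistical world the shrunken-centroid classifier assumes: each
compound's log2 control-relative profile is its class centroid (scaled by an
effect size) plus Gaussian per-gene noise, observed through three technical
replicates that are averaged.  Defaults mirror the HDACi reference design —
10 + 10 reference compounds, 4 + 7 external validation compounds, 3
replicates — with class centroids and per-gene SDs taken from the packaged
19-gene panel.  ``effect_scale = 0`` is the null model: compounds drawn
around the zero (no-response) profile.

Layers:

* :func:`simulate_profiles` / :func:`simulate_study` — compound-level log2
  profiles (the classifier's native input);
* :func:`simulate_counts` — an optional count-level layer (control CPM drawn
  log-normal, treated CPM = control * 2^fc, Poisson counts at a given library
  size, with matched vehicle controls, water-only negative controls and
  duplicated reference-RNA QC libraries) for exercising the preprocessing
  chain end to end;
* :func:`make_oracle_instance` — tiny labeled datasets for brute-force
  oracle tests.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .biomarker import load_builtin_biomarker
from .io import CompoundProfile, CountMatrix, SampleMetadata

__all__ = [
    "SimConfig",
    "simulate_profiles",
    "simulate_study",
    "simulate_counts",
    "make_oracle_instance",
]


@dataclass
class SimConfig:
    """Generative parameters for a synthetic exposure study.

    ``gene_sd`` is the between-compound, within-class SD on the log2 scale
    (the quantity the classifier's pooled SD estimates); ``replicate_sd`` is
    within-compound technical noise, attenuated by replicate averaging.
    """

    genes: tuple[str, ...]
    centroid_hdaci: np.ndarray = field(repr=False)
    centroid_non: np.ndarray = field(repr=False)
    gene_sd: np.ndarray = field(repr=False)
    seed: int = 0
    n_hdaci: int = 10
    n_non: int = 10
    n_val_hdaci: int = 4
    n_val_non: int = 7
    n_replicates: int = 3
    replicate_sd: float = 0.5
    effect_scale: float = 1.0
    overall_mean: np.ndarray | None = field(default=None, repr=False)
    n_background: int = 0
    background_sd: float = 1.0
    count_layer: bool = False
    library_size: float = 1e6
    phi: float = 0.0  # negative-binomial overdispersion; 0 = Poisson

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        g = len(self.genes)
        for attr in ("centroid_hdaci", "centroid_non", "gene_sd"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (g,):
                raise ValueError(f"{attr} must have length {g}")
            setattr(self, attr, arr)
        if np.any(self.gene_sd < 0) or self.replicate_sd < 0 or self.background_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        if self.overall_mean is None:
            self.overall_mean = np.zeros(g)
        else:
            self.overall_mean = np.asarray(self.overall_mean, dtype=float)
            if self.overall_mean.shape != (g,):
                raise ValueError("overall_mean must match gene count")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    # -- presets ------------------------------------------------------------

    @classmethod
    def table2(cls, seed: int, **overrides) -> "SimConfig":
        """The packaged-panel world: 19-gene centroids/SDs, 10+10 / 4+7 design."""
        asset = load_builtin_biomarker()
        cfg = cls(
            genes=asset.genes,
            centroid_hdaci=asset.centroid_hdaci,
            centroid_non=asset.centroid_non,
            gene_sd=asset.sd,
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def null(cls, seed: int, **overrides) -> "SimConfig":
        """Zero class effect: every compound drawn around the null profile."""
        overrides = {"effect_scale": 0.0, **overrides}
        return cls.table2(seed, **overrides)

    # -- internals ----------------------------------------------------------

    def _all_genes(self) -> tuple[str, ...]:
        bg = tuple(f"BG{j:04d}" for j in range(1, self.n_background + 1))
        return self.genes + bg

    def _class_mean(self, label: str) -> np.ndarray:
        centroid = self.centroid_hdaci if label == "HDACi" else self.centroid_non
        panel = self.overall_mean + self.effect_scale * (centroid - 0.0)
        return np.concatenate([panel, np.zeros(self.n_background)])

    def _sd_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.gene_sd, np.full(self.n_background, self.background_sd)]
        )


def _draw_cohort(
    cfg: SimConfig,
    rng: np.random.Generator,
    counts: dict[str, int],
    prefix: str,
) -> tuple[list[CompoundProfile], pd.DataFrame, np.ndarray]:
    """Draw one cohort; returns (profiles, truth table, replicate matrix).

    The replicate matrix has one column per (compound, replicate), ordered
    compound-major, holding the replicate-level log2 values used both for the
    profile averages and (optionally) the count layer.
    """
    genes = cfg._all_genes()
    sd = cfg._sd_vector()
    profiles: list[CompoundProfile] = []
    truth_rows = []
    rep_cols = []
    for label, n in counts.items():
        short = "HDACi" if label == "HDACi" else "nonHDACi"
        for j in range(1, n + 1):
            name = f"{prefix}_{short}_{j:02d}"
            mean = cfg._class_mean(label) + rng.normal(0.0, sd)
            reps = mean[:, None] + rng.normal(
                0.0, cfg.replicate_sd, size=(len(genes), cfg.n_replicates)
            )
            profiles.append(
                CompoundProfile(
                    compound=name,
                    class_label=label,
                    genes=genes,
                    values=reps.mean(axis=1),
                )
            )
            truth_rows.append({"compound": name, "class_label": label})
            rep_cols.append(reps)
    truth = pd.DataFrame(truth_rows, columns=["compound", "class_label"])
    reps = np.concatenate(rep_cols, axis=1) if rep_cols else np.empty((len(genes), 0))
    return profiles, truth, reps


def simulate_profiles(
    cfg: SimConfig, prefix: str = "sim"
) -> tuple[list[CompoundProfile], pd.DataFrame]:
    """One cohort of ``n_hdaci`` + ``n_non`` replicate-averaged profiles."""
    rng = np.random.default_rng(cfg.seed)
    profiles, truth, _ = _draw_cohort(
        cfg, rng, {"HDACi": cfg.n_hdaci, "non-HDACi": cfg.n_non}, prefix
    )
    return profiles, truth


def simulate_study(
    cfg: SimConfig,
) -> tuple[list[CompoundProfile], list[CompoundProfile], pd.DataFrame]:
    """Reference cohort plus external validation cohort, one seeded stream.

    Returns (reference profiles, validation profiles, truth table covering
    both cohorts).
    """
    rng = np.random.default_rng(cfg.seed)
    ref, truth_ref, _ = _draw_cohort(
        cfg, rng, {"HDACi": cfg.n_hdaci, "non-HDACi": cfg.n_non}, "ref"
    )
    val, truth_val, _ = _draw_cohort(
        cfg, rng, {"HDACi": cfg.n_val_hdaci, "non-HDACi": cfg.n_val_non}, "val"
    )
    return ref, val, pd.concat([truth_ref, truth_val], ignore_index=True)


# ---------------------------------------------------------------------------
# count layer
# ---------------------------------------------------------------------------

def _poisson_or_nb(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    mu = np.maximum(mu, 0.0)
    if phi <= 0:
        return rng.poisson(mu)
    # NB with Var = mu + phi * mu^2, via gamma-Poisson mixture
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=np.where(mu > 0, mu * phi, 0.0))
    return rng.poisson(lam)


def simulate_counts(
    cfg: SimConfig,
) -> tuple[CountMatrix, list[SampleMetadata], pd.DataFrame]:
    """Count-level study: treated + matched vehicle controls + QC libraries.

    Control expected CPM is drawn log-normal per gene (rescaled to sum 1e6);
    a treated replicate's expected CPM is control * 2^(replicate log2 value);
    observed counts are Poisson (or NB when ``phi`` > 0) at ``library_size``.
    The design includes one vehicle-control replicate per treatment
    replicate index, two water-only libraries (0.1% of the library size, so
    their signal share is < 0.3% by construction) and duplicated
    reference-RNA QC libraries, all in a single batch.

    Returns (raw CountMatrix with metadata attached, metadata records, truth
    table of compound-level mean log2 profiles with one row per gene).
    """
    if not cfg.count_layer:
        raise ValueError("simulate_counts requires cfg.count_layer = True")
    rng = np.random.default_rng(cfg.seed)
    genes = cfg._all_genes()
    G = len(genes)
    L = cfg.library_size
    batch = "B1"

    profiles, truth, reps = _draw_cohort(
        cfg, rng, {"HDACi": cfg.n_hdaci, "non-HDACi": cfg.n_non}, "sim"
    )

    control_cpm = np.exp(rng.normal(np.log(100.0), 1.0, size=G))
    control_cpm *= 1e6 / control_cpm.sum()

    columns: dict[str, np.ndarray] = {}
    records: list[SampleMetadata] = []

    for r in range(1, cfg.n_replicates + 1):
        sid = f"CTRL_{batch}_r{r}"
        columns[sid] = _poisson_or_nb(rng, control_cpm * L / 1e6, cfg.phi)
        records.append(
            SampleMetadata(sid, "vehicle", "control", r, "", batch)
        )

    col = 0
    for p in profiles:
        for r in range(1, cfg.n_replicates + 1):
            sid = f"{p.compound}_r{r}"
            fc = reps[:, col]
            col += 1
            expected = control_cpm * np.exp2(fc)
            columns[sid] = _poisson_or_nb(rng, expected * L / 1e6, cfg.phi)
            records.append(
                SampleMetadata(
                    sid, p.compound, p.class_label, r, f"CTRL_{batch}_r{r}", batch
                )
            )

    for r in (1, 2):  # water-only negative controls: ~0.1% of a library
        sid = f"WATER_r{r}"
        columns[sid] = _poisson_or_nb(rng, control_cpm * (1e-3 * L) / 1e6, cfg.phi)
        records.append(SampleMetadata(sid, "water", "qc", r, "", batch))

    for ref_rna in ("URR", "HBRR"):  # duplicated reference-RNA QC libraries
        expected = np.exp(rng.normal(np.log(100.0), 1.0, size=G))
        expected *= 1e6 / expected.sum()
        for r in (1, 2):
            sid = f"{ref_rna}_r{r}"
            columns[sid] = _poisson_or_nb(rng, expected * L / 1e6, cfg.phi)
            records.append(SampleMetadata(sid, ref_rna, "qc", r, "", batch))

    values = pd.DataFrame(
        {sid: counts for sid, counts in columns.items()}, index=list(genes)
    ).astype(float)
    matrix = CountMatrix(values, unit="raw").with_metadata(records)

    truth_matrix = pd.DataFrame(
        {p.compound: p.values for p in profiles}, index=list(genes)
    )
    truth_matrix.index.name = "gene"
    return matrix, records, truth_matrix


# ---------------------------------------------------------------------------
# oracle fixtures
# ---------------------------------------------------------------------------

def make_oracle_instance(
    n_genes: int = 5, n_samples: int = 6, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Tiny labeled dataset for brute-force cross-checks of the estimator.

    Balanced two-class design with a mild random class shift so d-statistics
    are generically nonzero.  Bounds (<= 6 genes, <= 8 samples) keep hand
    verification feasible.
    """
    if n_genes > 6 or n_samples > 8:
        raise ValueError("oracle instances are capped at 6 genes x 8 samples")
    if n_samples < 4 or n_samples % 2:
        raise ValueError("n_samples must be even and >= 4 (2 per class minimum)")
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    shift = rng.normal(0.0, 1.5, size=n_genes)
    X = np.vstack(
        [
            shift[None, :] + rng.normal(0.0, 1.0, size=(half, n_genes)),
            rng.normal(0.0, 1.0, size=(n_samples - half, n_genes)),
        ]
    )
    y = np.array(["HDACi"] * half + ["non-HDACi"] * (n_samples - half), dtype=object)
    genes = tuple(f"G{i + 1}" for i in range(n_genes))
    return X, y, genes
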