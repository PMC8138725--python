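"""Frozen biomarker panels and panel alignment.

A :class:`BiomarkerAsset` is a self-contained shrunken-centroid classifier:
a gene panel with per-class centroids, a per-gene standardization SD, priors
and a probability cutoff.  The package ships the 19-gene TGx-HDACi panel
(the intersection of the 81-gene HDACi biomarker with the S1500+ sentinel
gene set) as a checksummed, read-only asset; the centroid columns are used
directly as shrunken standardized centroids and the SD column as the
per-gene denominator, so the printed table IS the classifier.

The 81-gene panel is not bundled (its values are not part of this package's
frozen inputs) but any asset in the same JSON schema loads via
:func:`load_asset`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .io import CompoundProfile
from .nsc import NSCResults

__all__ = [
    "BiomarkerAsset",
    "BUILTIN_ASSET_NAME",
    "load_builtin_biomarker",
    "load_asset",
    "asset_to_model",
    "subset_profile",
]

logger = logging.getLogger(__name__)

BUILTIN_ASSET_NAME = "TGx-HDACi-19"
_BUILTIN_FILE = "tgx_hdaci_19.json"


@dataclass(frozen=True)
class BiomarkerAsset:
    """A frozen gene panel with class centroids and standardization SDs."""

    name: str
    genes: tuple[str, ...]
    centroid_hdaci: np.ndarray = field(repr=False)
    centroid_non: np.ndarray = field(repr=False)
    sd: np.ndarray = field(repr=False)
    priors: tuple[float, float] = (0.5, 0.5)
    cutoff: float = 0.9
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        for attr in ("centroid_hdaci", "centroid_non", "sd"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), float))
        n = len(self.genes)
        if len(set(self.genes)) != n:
            raise ValueError("asset gene symbols are not unique")
        for attr in ("centroid_hdaci", "centroid_non", "sd"):
            if getattr(self, attr).shape != (n,):
                raise ValueError(f"asset field {attr} has wrong length")
        if np.any(self.sd <= 0):
            raise ValueError("asset SDs must all be positive")
        if not np.isclose(sum(self.priors), 1.0):
            raise ValueError("asset priors must sum to 1")

    def to_payload(self) -> dict:
        return {
            "name": self.name,
            "classes": ["HDACi", "non-HDACi"],
            "genes": list(self.genes),
            "centroids": {
                "HDACi": [float(v) for v in self.centroid_hdaci],
                "non-HDACi": [float(v) for v in self.centroid_non],
            },
            "sd": [float(v) for v in self.sd],
            "priors": [float(p) for p in self.priors],
            "cutoff": self.cutoff,
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> None:
        payload = self.to_payload()
        payload["sha256"] = _payload_digest(payload)
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _payload_digest(payload: dict) -> str:
    body = {k: v for k, v in payload.items() if k != "sha256"}
    return hashlib.sha256(
        json.dumps(body, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


def _asset_from_payload(payload: dict, verify_checksum: bool) -> BiomarkerAsset:
    if verify_checksum:
        recorded = payload.get("sha256")
        if recorded is None:
            raise ValueError("asset file lacks a sha256 checksum")
        actual = _payload_digest(payload)
        if actual != recorded:
            raise ValueError(
                f"asset checksum mismatch: recorded {recorded[:12]}..., "
                f"computed {actual[:12]}... (asset corrupted?)"
            )
    return BiomarkerAsset(
        name=payload["name"],
        genes=tuple(payload["genes"]),
        centroid_hdaci=payload["centroids"]["HDACi"],
        centroid_non=payload["centroids"]["non-HDACi"],
        sd=payload["sd"],
        priors=tuple(payload.get("priors", (0.5, 0.5))),
        cutoff=float(payload.get("cutoff", 0.9)),
        provenance=payload.get("provenance", ""),
    )


def load_builtin_biomarker() -> BiomarkerAsset:
    """Load the packaged, checksum-verified 19-gene TGx-HDACi panel."""
    text = (
        resources.files("tgx_hdaci").joinpath("assets", _BUILTIN_FILE).read_text()
    )
    return _asset_from_payload(json.loads(text), verify_checksum=True)


def load_asset(path: str | Path, verify_checksum: bool = True) -> BiomarkerAsset:
    """Load a user-supplied panel asset (e.g. the 81-gene biomarker)."""
    return _asset_from_payload(
        json.loads(Path(path).read_text()), verify_checksum=verify_checksum
    )


def asset_to_model(asset: BiomarkerAsset) -> NSCResults:
    """Turn a frozen panel into a ready-to-score classifier.

    The asset centroids are used directly as the shrunken centroids and the
    SD column as the per-gene standardization denominator; no further
    shrinkage is applied, so every panel gene survives.
    """
    return NSCResults(
        genes=asset.genes,
        classes=("HDACi", "non-HDACi"),
        shrunken_centroids=np.column_stack(
            [asset.centroid_hdaci, asset.centroid_non]
        ),
        denom=asset.sd,
        priors=np.asarray(asset.priors, float),
        delta=0.0,
        name=asset.name,
        provenance=asset.provenance,
    )


def subset_profile(
    profile: CompoundProfile,
    asset: BiomarkerAsset | NSCResults,
    max_missing: int = 0,
) -> CompoundProfile:
    """Reorder a profile onto the panel's gene order (the only legal reorder).

    Missing panel genes are a hard error by default; raising ``max_missing``
    allows up to that many absent genes to be imputed as 0 (null response),
    which is logged prominently because a call on a partial panel is a
    weaker claim.
    """
    panel = tuple(asset.genes)
    idx = {g: i for i, g in enumerate(profile.genes)}
    missing = [g for g in panel if g not in idx]
    if len(missing) > max_missing:
        raise ValueError(
            f"profile {profile.compound!r} lacks {len(missing)} panel gene(s) "
            f"(max_missing={max_missing}): {missing}"
        )
    if missing:
        logger.warning(
            "profile %r: %d panel gene(s) missing, imputed as 0 (null response): %s",
            profile.compound, len(missing), missing,
        )
    values = np.array(
        [profile.values[idx[g]] if g in idx else 0.0 for g in panel]
    )
    return CompoundProfile(
        compound=profile.compound,
        class_label=profile.class_label,
        genes=panel,
        values=values,
    )
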