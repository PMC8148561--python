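"""Membership-index drought-tolerance scoring and rank classification.

For each trait and season, genotype performance under stress is summarized
as the ratio of limited-irrigation to full-irrigation genotype means. Traits
that rise under stress (canopy temperature here) are orientation-inverted
(full/limited) so that a larger ratio always means more tolerant. Ratios are
min-max rescaled across genotypes within each trait x season slice to the
membership score

    Fij = (x_ij - x_min) / (x_max - x_min)   in [0, 1],

and the tolerance index Fi is the mean Fij over the trait panel (per season
and over all trait x season slices combined). Genotypes are ranked into five
classes: HT (Fi >= 0.8), T (0.6 <= Fi < 0.8), I (0.4 <= Fi < 0.6),
S (0.2 <= Fi < 0.4) and HS (Fi < 0.2); the 0.8 boundary goes to HT so the
partition is gapless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RankScheme",
    "DEFAULT_SCHEME",
    "DEFAULT_TRAIT_PANEL",
    "stress_ratio",
    "stress_ratio_table",
    "membership_index",
    "tolerance_table",
    "classify_panel",
    "membership_from_observations",
    "fij_from_published",
]

DEFAULT_TRAIT_PANEL = ("GLA", "LAI", "RWC", "CT")


@dataclass(frozen=True)
class RankScheme:
    """Ordered Fi thresholds partitioning [0, 1] into tolerance classes."""

    thresholds: tuple[float, ...] = (0.8, 0.6, 0.4, 0.2)
    labels: tuple[str, ...] = ("HT", "T", "I", "S", "HS")

    def __post_init__(self):
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need one more label than thresholds")
        if any(
            a <= b for a, b in zip(self.thresholds, self.thresholds[1:])
        ):
            raise ValueError("thresholds must be strictly decreasing")

    def classify(self, fi: float) -> str:
        for thr, label in zip(self.thresholds, self.labels):
            if fi >= thr:
                return label
        return self.labels[-1]

    def rank(self, label: str) -> int:
        return self.labels.index(label) + 1


DEFAULT_SCHEME = RankScheme()


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal half-up rounding used for reported scores."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def stress_ratio(
    limited: np.ndarray | pd.Series,
    full: np.ndarray | pd.Series,
    direction: str = "decreases",
) -> np.ndarray | pd.Series:
    """Stress/control ratio, oriented so larger = more tolerant.

    limited/full for stress-decreasing traits; full/limited for
    stress-increasing traits (where a tolerant genotype keeps the trait low
    under stress).
    """
    limited = np.asarray(limited, dtype=float) if not isinstance(limited, pd.Series) else limited
    full = np.asarray(full, dtype=float) if not isinstance(full, pd.Series) else full
    if np.any(np.asarray(limited) < 0) or np.any(np.asarray(full) < 0):
        raise ValueError("trait values must be nonnegative for ratio scoring")
    if direction == "decreases":
        if np.any(np.asarray(full) == 0):
            raise ValueError("zero full-irrigation value in ratio denominator")
        return limited / full
    if direction == "increases":
        if np.any(np.asarray(limited) == 0):
            raise ValueError("zero limited-irrigation value in ratio denominator")
        return full / limited
    raise ValueError("direction must be 'decreases' or 'increases'")


def _detect_directions(
    means: pd.DataFrame, traits: tuple[str, ...]
) -> dict[str, str]:
    """Infer stress direction per trait from the pooled regime contrast."""
    directions = {}
    for trait in traits:
        contrast = (
            means.xs(trait, level="trait")["limited"].mean()
            - means.xs(trait, level="trait")["full"].mean()
        )
        directions[trait] = "increases" if contrast > 0 else "decreases"
        if directions[trait] == "increases":
            logger.info("trait %s rises under stress; ratio inverted to full/limited", trait)
    return directions


def stress_ratio_table(
    observations: pd.DataFrame,
    traits: tuple[str, ...] = DEFAULT_TRAIT_PANEL,
    invert: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Genotype x (trait, season) stress-ratio matrix from plot records.

    Plot values are first averaged to genotype x season x regime means. If
    ``invert`` is None the stress direction of each trait is detected from
    the sign of its pooled regime contrast; otherwise the named traits are
    inverted.
    """
    sub = observations[observations["trait"].isin(traits)]
    missing = set(traits) - set(sub["trait"].unique())
    if missing:
        raise ValueError(f"traits absent from observations: {sorted(missing)}")
    means = sub.pivot_table(
        index=["trait", "genotype", "season"],
        columns="regime",
        values="value",
        aggfunc="mean",
    )
    if invert is None:
        directions = _detect_directions(means, traits)
    else:
        directions = {
            t: ("increases" if t in invert else "decreases") for t in traits
        }
    cols = {}
    for trait in traits:
        block = means.xs(trait, level="trait")
        ratio = stress_ratio(block["limited"], block["full"], directions[trait])
        cols[trait] = ratio.unstack("season")
    out = pd.concat(cols, axis=1, names=["trait", "season"])
    return out


def membership_index(
    ratios: pd.DataFrame, degenerate_value: float = 0.5
) -> pd.DataFrame:
    """Min-max rescale each trait x season column across genotypes.

    A degenerate slice (all genotypes equal) gets ``degenerate_value``
    everywhere, with a warning logged.
    """
    if ratios.shape[0] < 2:
        raise ValueError("need at least 2 genotypes per slice")
    lo, hi = ratios.min(axis=0), ratios.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        logger.warning(
            "degenerate membership slice(s) %s: all genotypes equal; "
            "scores set to %.2f",
            list(ratios.columns[degenerate]),
            degenerate_value,
        )
    safe = span.where(~degenerate, 1.0)
    fij = (ratios - lo) / safe
    fij.loc[:, degenerate] = degenerate_value
    return fij


def tolerance_table(
    fij: pd.DataFrame,
    scheme: RankScheme = DEFAULT_SCHEME,
    decimals: int | None = 3,
) -> pd.DataFrame:
    """Per-genotype tolerance indices and classes from a membership matrix.

    ``fij`` has genotypes as rows and a (trait, season) MultiIndex as
    columns. Per-season Fi is the mean over traits within the season;
    combined Fi is the mean over all trait x season scores. Classification
    always uses unrounded values; ``decimals`` only affects the reported
    scores (half-up, matching 3-decimal published precision).
    """
    if fij.shape[1] == 0:
        raise ValueError("empty trait panel")
    seasons = list(dict.fromkeys(fij.columns.get_level_values("season")))
    out = pd.DataFrame(index=fij.index)
    for season in seasons:
        block = fij.xs(season, axis=1, level="season")
        fi = block.mean(axis=1)
        out[f"Fi_{season}"] = fi
        out[f"class_{season}"] = fi.map(scheme.classify)
    fi_comb = fij.mean(axis=1)
    out["Fi_combined"] = fi_comb
    out["class_combined"] = fi_comb.map(scheme.classify)
    if decimals is not None:
        for col in out.columns:
            if col.startswith("Fi_"):
                out[col] = out[col].map(lambda v: round_half_up(v, decimals))
    return out


def classify_panel(table: pd.DataFrame, scheme: RankScheme = DEFAULT_SCHEME) -> dict:
    """Class counts and cross-season agreement for a tolerance table.

    Returns combined-class genotype counts (every scheme label reported,
    zeros included) and the number of genotypes whose two per-season classes
    coincide (seasonal agreement is only defined for two-season tables).
    """
    counts = {
        label: int((table["class_combined"] == label).sum())
        for label in scheme.labels
    }
    class_cols = [
        c for c in table.columns if c.startswith("class_") and c != "class_combined"
    ]
    agreement = None
    if len(class_cols) == 2:
        agreement = int((table[class_cols[0]] == table[class_cols[1]]).sum())
    return {"counts": counts, "season_agreement": agreement, "n": len(table)}


def membership_from_observations(
    observations: pd.DataFrame,
    traits: tuple[str, ...] = DEFAULT_TRAIT_PANEL,
    invert: tuple[str, ...] | None = None,
    scheme: RankScheme = DEFAULT_SCHEME,
    decimals: int | None = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline from plot records to a tolerance table.

    Returns (fij matrix, tolerance table).
    """
    ratios = stress_ratio_table(observations, traits=traits, invert=invert)
    fij = membership_index(ratios)
    return fij, tolerance_table(fij, scheme=scheme, decimals=decimals)


def fij_from_published(scores: pd.DataFrame) -> pd.DataFrame:
    """Reshape a published membership-score table (columns ``<trait>_<season>``)
    into the genotype x (trait, season) matrix used by this module."""
    score_cols = [
        c
        for c in scores.columns
        if "_" in c and not c.startswith(("Fi_", "class_"))
    ]
    data = {}
    for col in score_cols:
        trait, season = col.rsplit("_", 1)
        data[(trait, season)] = scores.set_index("genotype")[col]
    fij = pd.DataFrame(data)
    fij.columns = pd.MultiIndex.from_tuples(fij.columns, names=["trait", "season"])
    return fij
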