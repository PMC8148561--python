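"""Trait screening: multicollinearity diagnosis and correlation-matrix PCA.

Redundant traits are flagged by tolerance/VIF (tolerance_j = 1 - R2 of trait
j regressed on all other traits; VIF_j = 1/tolerance_j) and iteratively
excluded while any VIF exceeds the threshold (default 10). The remaining
traits go through a PCA of the trait correlation matrix with Kaiser
retention (eigenvalue > 1) and an absolute-loading cutoff (default 0.27 on
the first two components) to pick the interpretive trait panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CollinearityReport",
    "PcaResult",
    "genotype_means",
    "collinearity_diagnose",
    "iterative_exclude",
    "pca",
    "select_traits",
]


@dataclass
class CollinearityReport:
    tolerance: pd.Series  # per trait, in [0, 1]
    vif: pd.Series  # per trait; np.inf flags perfect collinearity
    excluded: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tolerance": self.tolerance, "vif": self.vif})


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending
    explained_pct: np.ndarray
    loadings: pd.DataFrame  # trait x component
    retained: int  # Kaiser rule: eigenvalue > 1
    scores: pd.DataFrame  # row x component


def genotype_means(observations: pd.DataFrame, by_treatment: bool = False) -> pd.DataFrame:
    """Aggregate a long-format plot table to a wide genotype x trait matrix.

    With ``by_treatment=True`` rows are genotype x season x regime mean cells
    (the treatment-combination view used for PCA); otherwise means are over
    all plots per genotype.
    """
    keys = ["genotype", "season", "regime"] if by_treatment else ["genotype"]
    wide = observations.pivot_table(
        index=keys, columns="trait", values="value", aggfunc="mean"
    )
    wide.columns.name = None
    return wide


def _check_matrix(data: pd.DataFrame) -> pd.DataFrame:
    if not np.isfinite(data.to_numpy(dtype=float)).all():
        raise ValueError("non-finite values in trait matrix")
    constant = data.columns[data.std(axis=0, ddof=1) == 0]
    if len(constant):
        raise ValueError(f"constant trait column(s): {list(constant)}")
    return data


def collinearity_diagnose(data: pd.DataFrame) -> CollinearityReport:
    """Tolerance and VIF for every trait column.

    Each trait is regressed on all remaining traits (via the standardized
    least-squares fit, robust to singular designs); tolerance is 1 - R2 and
    VIF its reciprocal, flagged infinite for perfectly collinear traits.
    """
    data = _check_matrix(data)
    if data.shape[1] < 3:
        raise ValueError("need at least 3 traits for collinearity diagnosis")
    if data.shape[0] <= data.shape[1]:
        logger.warning(
            "fewer rows (%d) than traits + 1 (%d); tolerance computed via "
            "least-squares pseudoinverse path",
            data.shape[0],
            data.shape[1] + 1,
        )
    z = (data - data.mean()) / data.std(ddof=1)
    z = z.to_numpy(dtype=float)
    n, p = z.shape
    tol = np.empty(p)
    for j in range(p):
        others = np.delete(z, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, z[:, j], rcond=None)
        resid = z[:, j] - others @ coef
        tol[j] = resid @ resid / (z[:, j] @ z[:, j])
    tol = np.clip(tol, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        vif = np.where(tol > 1e-12, 1.0 / np.maximum(tol, 1e-300), np.inf)
    return CollinearityReport(
        tolerance=pd.Series(tol, index=data.columns, name="tolerance"),
        vif=pd.Series(vif, index=data.columns, name="vif"),
    )


def iterative_exclude(
    data: pd.DataFrame, vif_threshold: float = 10.0
) -> CollinearityReport:
    """Drop the worst-VIF trait (alphabetical tie-break) until max VIF is
    below the threshold; the final report carries the exclusion order."""
    if vif_threshold <= 1:
        raise ValueError("vif_threshold must exceed 1")
    remaining = data.copy()
    excluded: list[str] = []
    while True:
        report = collinearity_diagnose(remaining)
        worst = report.vif.max()
        if worst <= vif_threshold:
            break
        ties = sorted(report.vif.index[report.vif == worst])
        drop = ties[0]
        if len(ties) > 1:
            logger.info("VIF tie among %s; excluding %s (alphabetical)", ties, drop)
        logger.info("excluding trait %s (VIF %.2f)", drop, worst)
        excluded.append(drop)
        remaining = remaining.drop(columns=drop)
    report.excluded = excluded
    return report


def pca(data: pd.DataFrame) -> PcaResult:
    """PCA of the trait correlation matrix.

    Components are ordered by descending eigenvalue; each component's sign is
    fixed so its largest-magnitude loading is positive. Loadings are the
    correlation-matrix eigenvectors (unit length); scores are standardized
    data projected onto them.
    """
    data = _check_matrix(data)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 traits for PCA")
    z = (data - data.mean()) / data.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(dtype=float), rowvar=False)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    # deterministic sign: largest |loading| positive per component
    for k in range(v.shape[1]):
        idx = np.argmax(np.abs(v[:, k]))
        if v[idx, k] < 0:
            v[:, k] = -v[:, k]
    comp_names = [f"PC{k + 1}" for k in range(len(w))]
    loadings = pd.DataFrame(v, index=data.columns, columns=comp_names)
    scores = pd.DataFrame(
        z.to_numpy(dtype=float) @ v, index=data.index, columns=comp_names
    )
    return PcaResult(
        eigenvalues=w,
        explained_pct=100.0 * w / w.sum(),
        loadings=loadings,
        retained=int((w > 1.0).sum()),
        scores=scores,
    )


def select_traits(
    result: PcaResult, loading_threshold: float = 0.27, components: int = 2
) -> list[str]:
    """Traits with |loading| above the threshold on any of the first
    ``components`` axes, in trait order."""
    if components > result.loadings.shape[1]:
        raise ValueError("more components requested than available")
    block = result.loadings.iloc[:, :components].abs()
    mask = (block > loading_threshold).any(axis=1)
    return list(result.loadings.index[mask])
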