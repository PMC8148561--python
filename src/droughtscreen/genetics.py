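"""Combined split-plot ANOVA and genetic parameters.

For a balanced trial with genotypes (G) on subplots, irrigation regimes (I)
on main plots, seasons (S) treated as a random environment and r replicates,
the combined analysis decomposes the total sum of squares into the sources
S, rep(S), I, SxI, rep(IxS), G, SxG, IxG, SxIxG and Error. The genotype and
genotype-by-environment mean squares yield ANOVA (method-of-moments) variance
components, from which the genetic parameters follow:

    h2  = s2g / s2p,   s2p = s2g + s2gxe/e + s2re/(r e)
    GCV = 100 sqrt(s2g) / xbar        PCV = 100 sqrt(s2p) / xbar
    GA  = k h2 sqrt(s2p)              GG  = 100 GA / xbar

with k the standardized selection differential (2.06 at 5% selection
intensity) and e the number of environments. These definitions satisfy the
identity h2 = (GCV/PCV)^2 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SOURCES",
    "AnovaTable",
    "VarianceComponents",
    "GeneticParameters",
    "combined_anova",
    "estimate_variance_components",
    "genetic_parameters",
    "genetic_advance",
    "genetic_gain",
    "genetics_report",
]

SOURCES = (
    "S",
    "rep(S)",
    "I",
    "SxI",
    "rep(IxS)",
    "G",
    "SxG",
    "IxG",
    "SxIxG",
    "Error",
)

GXE_CONVENTIONS = ("pooled", "sxg", "ixg", "sxixg")


@dataclass
class AnovaTable:
    """Mean squares and degrees of freedom per source for one trait."""

    trait: str
    df: pd.Series  # indexed by source
    ss: pd.Series
    ms: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"df": self.df, "ss": self.ss, "ms": self.ms}
        ).reindex(list(SOURCES))

    @classmethod
    def from_mean_squares(
        cls, trait: str, df: dict[str, int], ms: dict[str, float]
    ) -> "AnovaTable":
        """Build a table from published df/MS values (SS back-filled)."""
        dfs = pd.Series(df, dtype=float).reindex(list(SOURCES))
        mss = pd.Series(ms, dtype=float).reindex(list(SOURCES))
        return cls(trait=trait, df=dfs, ss=dfs * mss, ms=mss)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_gxe: float
    sigma2_re: float
    r: int
    e: int
    convention: str
    truncated: list[str] = field(default_factory=list)

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_gxe / self.e + self.sigma2_re / (
            self.r * self.e
        )


@dataclass
class GeneticParameters:
    h2: float  # percent
    gcv: float  # percent
    pcv: float  # percent
    ga: float  # trait units
    gg: float  # percent
    k: float
    grand_mean: float


def _cell_array(observations: pd.DataFrame, trait: str) -> np.ndarray:
    """Pivot long-format plot records for one trait into a balanced
    (season, regime, genotype, rep) array; error on missing/duplicate cells."""
    sub = observations.loc[observations["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    seasons = sorted(sub["season"].unique())
    regimes = sorted(sub["regime"].unique())
    genotypes = sorted(sub["genotype"].unique())
    reps = sorted(sub["rep"].unique())
    expected = len(seasons) * len(regimes) * len(genotypes) * len(reps)
    if len(sub) != expected:
        raise ValueError(
            f"unbalanced design for trait {trait!r}: {len(sub)} plots, "
            f"expected {expected}"
        )
    pivot = sub.set_index(["season", "regime", "genotype", "rep"])["value"]
    if pivot.index.has_duplicates:
        dup = pivot.index[pivot.index.duplicated()][0]
        raise ValueError(f"duplicate plot record for cell {dup}")
    pivot = pivot.reindex(
        pd.MultiIndex.from_product([seasons, regimes, genotypes, reps])
    )
    if pivot.isna().any():
        missing = pivot.index[pivot.isna()][0]
        raise ValueError(f"missing plot record for cell {missing}")
    return pivot.to_numpy().reshape(
        len(seasons), len(regimes), len(genotypes), len(reps)
    )


def combined_anova(observations: pd.DataFrame, trait: str) -> AnovaTable:
    """Combined across-season split-plot ANOVA for one trait.

    Requires a fully balanced table (no imputation is attempted). The source
    decomposition is exact: the Error SS is the remainder of the total SS
    after all modelled sources.
    """
    y = _cell_array(observations, trait)  # (S, I, G, R)
    n_s, n_i, n_g, n_r = y.shape
    m = y.mean()

    m_s = y.mean(axis=(1, 2, 3))
    m_i = y.mean(axis=(0, 2, 3))
    m_g = y.mean(axis=(0, 1, 3))
    m_si = y.mean(axis=(2, 3))
    m_sr = y.mean(axis=(1, 2))
    m_sg = y.mean(axis=(1, 3))
    m_ig = y.mean(axis=(0, 3))
    m_sig = y.mean(axis=3)
    m_sir = y.mean(axis=2)

    ss = {}
    ss["S"] = n_i * n_g * n_r * np.sum((m_s - m) ** 2)
    ss["rep(S)"] = n_i * n_g * np.sum((m_sr - m_s[:, None]) ** 2)
    ss["I"] = n_s * n_g * n_r * np.sum((m_i - m) ** 2)
    ss["SxI"] = n_g * n_r * np.sum(
        (m_si - m_s[:, None] - m_i[None, :] + m) ** 2
    )
    ss["rep(IxS)"] = n_g * np.sum(
        (m_sir - m_si[:, :, None] - m_sr[:, None, :] + m_s[:, None, None]) ** 2
    )
    ss["G"] = n_s * n_i * n_r * np.sum((m_g - m) ** 2)
    ss["SxG"] = n_i * n_r * np.sum(
        (m_sg - m_s[:, None] - m_g[None, :] + m) ** 2
    )
    ss["IxG"] = n_s * n_r * np.sum(
        (m_ig - m_i[:, None] - m_g[None, :] + m) ** 2
    )
    ss["SxIxG"] = n_r * np.sum(
        (
            m_sig
            - m_si[:, :, None]
            - m_sg[:, None, :]
            - m_ig[None, :, :]
            + m_s[:, None, None]
            + m_i[None, :, None]
            + m_g[None, None, :]
            - m
        )
        ** 2
    )
    total = np.sum((y - m) ** 2)
    ss["Error"] = max(total - sum(ss.values()), 0.0)

    df = {
        "S": n_s - 1,
        "rep(S)": n_s * (n_r - 1),
        "I": n_i - 1,
        "SxI": (n_s - 1) * (n_i - 1),
        "rep(IxS)": n_s * (n_i - 1) * (n_r - 1),
        "G": n_g - 1,
        "SxG": (n_s - 1) * (n_g - 1),
        "IxG": (n_i - 1) * (n_g - 1),
        "SxIxG": (n_s - 1) * (n_i - 1) * (n_g - 1),
    }
    df["Error"] = (n_s * n_i * n_g * n_r - 1) - sum(df.values())

    df_s = pd.Series(df, dtype=float).reindex(list(SOURCES))
    ss_s = pd.Series(ss, dtype=float).reindex(list(SOURCES))
    ms_s = ss_s.where(df_s == 0, ss_s / df_s.replace(0, np.nan)).fillna(0.0)
    return AnovaTable(trait=trait, df=df_s, ss=ss_s, ms=ms_s)


def estimate_variance_components(
    anova: AnovaTable, r: int, e: int, convention: str = "pooled"
) -> VarianceComponents:
    """ANOVA (expected-mean-square) estimates of the variance components.

    sigma2_g = (MS_G - MS_GxE) / (r e), sigma2_gxe = (MS_GxE - MS_Error) / r,
    sigma2_re = MS_Error. The G x E mean square is either one of the three
    interaction mean squares or (default) their df-weighted pooled value.
    Negative estimates are truncated to zero and logged.
    """
    if r * e == 0:
        raise ValueError("r and e must be positive")
    if convention not in GXE_CONVENTIONS:
        raise ValueError(
            f"convention must be one of {GXE_CONVENTIONS}, got {convention!r}"
        )
    ms = anova.ms
    if convention == "pooled":
        inter = ["SxG", "IxG", "SxIxG"]
        weights = anova.df[inter]
        if weights.sum() > 0:
            ms_gxe = float((ms[inter] * weights).sum() / weights.sum())
        else:  # single-environment edge case: no interaction stratum
            ms_gxe = float(ms["Error"])
    else:
        ms_gxe = float(ms[{"sxg": "SxG", "ixg": "IxG", "sxixg": "SxIxG"}[convention]])

    ms_g, ms_err = float(ms["G"]), float(ms["Error"])
    truncated = []
    s2g = (ms_g - ms_gxe) / (r * e)
    if s2g < 0:
        truncated.append("sigma2_g")
        s2g = 0.0
    s2gxe = (ms_gxe - ms_err) / r
    if s2gxe < 0:
        truncated.append("sigma2_gxe")
        s2gxe = 0.0
    if truncated:
        logger.info(
            "trait %s: truncated negative variance components %s to zero",
            anova.trait,
            truncated,
        )
    return VarianceComponents(
        sigma2_g=s2g,
        sigma2_gxe=s2gxe,
        sigma2_re=ms_err,
        r=r,
        e=e,
        convention=convention,
        truncated=truncated,
    )


def genetic_parameters(
    vc: VarianceComponents, grand_mean: float, k: float = 2.06
) -> GeneticParameters:
    """Heritability, coefficients of variation, genetic advance and gain."""
    if grand_mean == 0:
        raise ValueError("grand mean must be nonzero")
    s2p = vc.sigma2_p
    if s2p == 0:
        raise ValueError("phenotypic variance is zero; h2 undefined")
    h2 = vc.sigma2_g / s2p
    xbar = abs(grand_mean)
    gcv = 100.0 * np.sqrt(vc.sigma2_g) / xbar
    pcv = 100.0 * np.sqrt(s2p) / xbar
    ga = k * h2 * np.sqrt(s2p)
    gg = 100.0 * ga / xbar
    return GeneticParameters(
        h2=100.0 * h2,
        gcv=float(gcv),
        pcv=float(pcv),
        ga=float(ga),
        gg=float(gg),
        k=k,
        grand_mean=grand_mean,
    )


def genetic_advance(
    h2_pct: float, pcv_pct: float, grand_mean: float, k: float = 2.06
) -> float:
    """GA = k h2 sigma_p from percent-scale summaries (sigma_p backed out of
    the phenotypic coefficient of variation)."""
    sigma_p = pcv_pct / 100.0 * abs(grand_mean)
    return k * (h2_pct / 100.0) * sigma_p


def genetic_gain(ga: float, grand_mean: float) -> float:
    """GG (%) = 100 GA / grand mean."""
    if grand_mean == 0:
        raise ValueError("grand mean must be nonzero")
    return 100.0 * ga / abs(grand_mean)


def genetics_report(
    observations: pd.DataFrame,
    e_convention: str = "season_x_regime",
    gxe_convention: str = "pooled",
    k: float = 2.06,
) -> pd.DataFrame:
    """Per-trait ANOVA + genetic parameters for a full long-format table.

    ``e_convention`` counts environments as season x regime combinations
    (default) or seasons only. Returns one row per trait with the h2, GCV,
    PCV, GA, GG columns plus the variance components behind them.
    """
    rows = []
    for trait in observations["trait"].unique():
        anova = combined_anova(observations, trait)
        sub = observations.loc[observations["trait"] == trait]
        r = sub["rep"].nunique()
        n_seasons = sub["season"].nunique()
        n_regimes = sub["regime"].nunique()
        e = n_seasons if e_convention == "season" else n_seasons * n_regimes
        vc = estimate_variance_components(anova, r=r, e=e, convention=gxe_convention)
        grand_mean = float(sub["value"].mean())
        gp = genetic_parameters(vc, grand_mean, k=k)
        rows.append(
            {
                "trait": trait,
                "grand_mean": grand_mean,
                "sigma2_g": vc.sigma2_g,
                "sigma2_gxe": vc.sigma2_gxe,
                "sigma2_re": vc.sigma2_re,
                "h2": gp.h2,
                "gcv": gp.gcv,
                "pcv": gp.pcv,
                "ga": gp.ga,
                "gg": gp.gg,
            }
        )
    return pd.DataFrame(rows).set_index("trait")
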