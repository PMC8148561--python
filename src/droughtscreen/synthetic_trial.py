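"""Synthetic split-plot trial generator with known simulation truth.

No plot-level data are deposited with the published trial this package
mirrors, so downstream estimators are exercised on simulated trials whose
variance components, genetic correlation structure and stress-direction
effects are known exactly. The default design emulates the published study
conditions: 25 genotypes x 2 seasons x 2 irrigation regimes x 3 replicates,
28 correlated traits, with per-trait means and variance components calibrated
from the published summary tables.

Model per trait t and plot (genotype g, season s, regime i, replicate r):

    y = mu_t + season_s + regime_i + rep(s) + rep(s,i) + G_g + GE_{g,si} + eps

with G drawn from a multivariate normal across traits (correlated through the
genetic correlation matrix), GE and eps independent normals with the
specified variances, and the limited-irrigation regime offset signed by each
trait's stress direction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets

__all__ = [
    "TraitSpec",
    "TrialDesign",
    "TruthManifest",
    "generate_trial",
    "default_design",
    "genetic_correlation_matrix",
    "truth_heritability",
    "leaf_water_content",
    "relative_water_content",
    "leaf_equivalent_water_thickness",
    "water_use_efficiency",
    "intrinsic_water_use_efficiency",
    "stomatal_limitation",
    "leaf_area_index",
]

STRESS_DECREASES = "decreases"
STRESS_INCREASES = "increases"

#: traits that rise rather than fall under limited irrigation
DEFAULT_STRESS_INCREASING = ("CT", "WUE", "WUEi", "Ls")


@dataclass(frozen=True)
class TraitSpec:
    """Simulation truth for one trait.

    Parameters
    ----------
    grand_mean : trait units; mean under full irrigation.
    sigma2_g, sigma2_gxe, sigma2_e : genotypic, genotype-by-environment and
        residual (plot) variance components, trait units squared.
    stress_direction : whether the trait decreases or increases under the
        limited-irrigation regime.
    stress_shift : nonnegative mean offset of the limited regime, applied
        with the sign implied by ``stress_direction``.
    yield_correlation : target genetic correlation with the designated yield
        trait, in [-1, 1].
    lower_bound : physical lower bound of the trait; generated plot values
        are clipped there (None = unbounded). Clipping keeps physically
        nonnegative traits nonnegative when a small mean meets a wide
        Gaussian tail, at the cost of a slight moment bias for such traits.
    """

    name: str
    grand_mean: float
    sigma2_g: float
    sigma2_gxe: float
    sigma2_e: float
    stress_direction: str = STRESS_DECREASES
    stress_shift: float = 0.0
    yield_correlation: float = 0.0
    lower_bound: float | None = None

    def __post_init__(self):
        for comp in ("sigma2_g", "sigma2_gxe", "sigma2_e"):
            if getattr(self, comp) < 0:
                raise ValueError(f"trait {self.name!r}: {comp} must be >= 0")
        if self.stress_direction not in (STRESS_DECREASES, STRESS_INCREASES):
            raise ValueError(
                f"trait {self.name!r}: stress_direction must be "
                f"'{STRESS_DECREASES}' or '{STRESS_INCREASES}'"
            )
        if self.stress_shift < 0:
            raise ValueError(f"trait {self.name!r}: stress_shift must be >= 0")
        if not -1.0 <= self.yield_correlation <= 1.0:
            raise ValueError(
                f"trait {self.name!r}: yield_correlation outside [-1, 1]"
            )


@dataclass(frozen=True)
class TrialDesign:
    """Balanced split-plot trial layout.

    Irrigation regimes sit on main plots and genotypes on subplots; the
    combined analysis treats season x regime combinations as environments
    (``env_convention='season_x_regime'``) unless configured to count seasons
    only. Season, replicate-within-season and main-plot effects are drawn
    once per level with standard deviations expressed as fractions of each
    trait's residual standard deviation.
    """

    n_genotypes: int
    traits: tuple[TraitSpec, ...]
    seasons: tuple[str, ...] = ("S1", "S2")
    regimes: tuple[str, ...] = ("full", "limited")
    n_reps: int = 3
    yield_trait: str = "GY"
    env_convention: str = "season_x_regime"
    season_sd_frac: float = 0.5
    rep_sd_frac: float = 0.25
    mainplot_sd_frac: float = 0.25

    def __post_init__(self):
        if self.n_genotypes < 2:
            raise ValueError("need at least 2 genotypes")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")
        if len(self.seasons) < 1:
            raise ValueError("need at least 1 season")
        if len(self.regimes) != 2:
            raise ValueError("exactly 2 irrigation regimes required")
        if not self.traits:
            raise ValueError("need at least one trait")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names")
        if self.env_convention not in ("season_x_regime", "season"):
            raise ValueError("env_convention must be 'season_x_regime' or 'season'")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def genotype_labels(self) -> list[str]:
        width = max(2, len(str(self.n_genotypes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]

    @property
    def n_environments(self) -> int:
        if self.env_convention == "season":
            return len(self.seasons)
        return len(self.seasons) * len(self.regimes)

    @property
    def rows_per_trait(self) -> int:
        return (
            self.n_genotypes * len(self.seasons) * len(self.regimes) * self.n_reps
        )


@dataclass
class TruthManifest:
    """Record of the simulation truth behind a generated trial."""

    seed: int
    n_genotypes: int
    seasons: list[str]
    regimes: list[str]
    n_reps: int
    n_environments: int
    env_convention: str
    traits: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def truth_heritability(
    sigma2_g: float, sigma2_gxe: float, sigma2_e: float, r: int, e: int
) -> float:
    """Broad-sense heritability implied by true variance components:
    h2 = s2g / (s2g + s2gxe/e + s2e/(r*e)). Returns 0 for a fully degenerate
    (all-zero variance) trait."""
    sigma2_p = sigma2_g + sigma2_gxe / e + sigma2_e / (r * e)
    if sigma2_p == 0:
        return 0.0
    return sigma2_g / sigma2_p


def genetic_correlation_matrix(design: TrialDesign) -> pd.DataFrame:
    """Complete the genetic correlation matrix from the trait-to-yield
    correlations.

    Only trait-yield correlations are user-specified; off-yield pairs are
    filled by the product rule rho_ij = rho_iy * rho_jy, which makes the
    completed matrix rho rho' + diag(1 - rho^2) and hence always positive
    semi-definite for |rho| <= 1. A nearest-PSD projection guards against
    numerical slack.
    """
    names = design.trait_names
    rho = np.array(
        [
            1.0 if t.name == design.yield_trait else t.yield_correlation
            for t in design.traits
        ]
    )
    corr = np.outer(rho, rho)
    np.fill_diagonal(corr, 1.0)
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-8:
        i, j = np.unravel_index(np.argmax(np.abs(corr - np.eye(len(names)))), corr.shape)
        raise ValueError(
            "genetic correlation target is not positive semi-definite "
            f"(offending pair {names[i]!r}, {names[j]!r})"
        )
    corr = _nearest_psd(corr)
    return pd.DataFrame(corr, index=names, columns=names)


def _nearest_psd(corr: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(corr)
    if w.min() >= 0:
        return corr
    w = np.clip(w, 0.0, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    d[d == 0] = 1.0
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def generate_trial(
    design: TrialDesign, seed: int
) -> tuple[pd.DataFrame, TruthManifest]:
    """Simulate one balanced trial.

    Returns a long-format table with columns genotype, season, regime, rep,
    trait, value (``design.rows_per_trait`` rows per trait) and the truth
    manifest. Identical (design, seed) pairs give identical tables.
    """
    n_g = design.n_genotypes
    seasons, regimes = design.seasons, design.regimes
    n_s, n_i, n_r = len(seasons), len(regimes), design.n_reps
    n_t = len(design.traits)
    r, e = design.n_reps, design.n_environments

    master = np.random.SeedSequence(seed)
    shared_ss, *trait_ss = master.spawn(1 + n_t)
    shared = np.random.default_rng(shared_ss)

    corr = genetic_correlation_matrix(design).to_numpy()
    # cholesky with tiny jitter tolerates the PSD boundary (e.g. rho = +/-1)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_t))
    g_sd = np.sqrt([t.sigma2_g for t in design.traits])
    # genotypic effects, correlated across traits: (n_g, n_t)
    g_eff = shared.standard_normal((n_g, n_t)) @ chol.T * g_sd

    e_sd = np.sqrt([t.sigma2_e for t in design.traits])
    season_eff = shared.standard_normal((n_t, n_s)) * (
        design.season_sd_frac * e_sd[:, None]
    )
    rep_eff = shared.standard_normal((n_t, n_s, n_r)) * (
        design.rep_sd_frac * e_sd[:, None, None]
    )
    mainplot_eff = shared.standard_normal((n_t, n_s, n_i, n_r)) * (
        design.mainplot_sd_frac * e_sd[:, None, None, None]
    )

    limited = np.array([reg == "limited" for reg in regimes], dtype=float)
    frames = []
    manifest = TruthManifest(
        seed=int(seed),
        n_genotypes=n_g,
        seasons=list(seasons),
        regimes=list(regimes),
        n_reps=n_r,
        n_environments=e,
        env_convention=design.env_convention,
    )
    genotypes = design.genotype_labels
    for k, trait in enumerate(design.traits):
        rng = np.random.default_rng(trait_ss[k])
        gxe = rng.standard_normal((n_g, n_s, n_i)) * np.sqrt(trait.sigma2_gxe)
        eps = rng.standard_normal((n_g, n_s, n_i, n_r)) * np.sqrt(trait.sigma2_e)
        sign = 1.0 if trait.stress_direction == STRESS_INCREASES else -1.0
        regime_eff = sign * trait.stress_shift * limited  # (n_i,)

        y = (
            trait.grand_mean
            + season_eff[k][None, :, None, None]
            + regime_eff[None, None, :, None]
            + rep_eff[k][None, :, None, :]
            + mainplot_eff[k][None, :, :, :]
            + g_eff[:, k][:, None, None, None]
            + gxe[:, :, :, None]
            + eps
        )
        if trait.lower_bound is not None:
            y = np.maximum(y, trait.lower_bound)
        idx = pd.MultiIndex.from_product(
            [genotypes, seasons, regimes, range(1, n_r + 1)],
            names=["genotype", "season", "regime", "rep"],
        )
        df = pd.DataFrame({"value": y.ravel()}, index=idx).reset_index()
        df.insert(4, "trait", trait.name)
        frames.append(df)

        manifest.traits[trait.name] = {
            "grand_mean": trait.grand_mean,
            "sigma2_g": trait.sigma2_g,
            "sigma2_gxe": trait.sigma2_gxe,
            "sigma2_e": trait.sigma2_e,
            "stress_direction": trait.stress_direction,
            "stress_shift": trait.stress_shift,
            "yield_correlation": trait.yield_correlation,
            "lower_bound": trait.lower_bound,
            "h2_truth": truth_heritability(
                trait.sigma2_g, trait.sigma2_gxe, trait.sigma2_e, r, e
            ),
        }

    table = pd.concat(frames, ignore_index=True)
    return table, manifest


# ---------------------------------------------------------------------------
# default design calibrated from the published summary tables
# ---------------------------------------------------------------------------

#: target genetic correlations with grain yield. The five screened traits use
#: the published trait-yield correlations; the remaining traits use moderate
#: values consistent with the published PCA trend (water-use-efficiency-type
#: traits negative, growth/biomass/yield-component traits positive, phenology
#: weakly positive).
DEFAULT_YIELD_CORRELATIONS = {
    "GLA": 0.446, "LAI": 0.493, "RWC": 0.390, "CT": -0.633, "Gs": 0.306,
    "WUE": -0.45, "WUEi": -0.40, "Ls": -0.45,
    "DH": 0.25, "MD": 0.25, "GFD": 0.25,
    "LWC": 0.40, "LEWT": 0.40, "Pn": 0.40, "Ci": 0.35, "E": 0.35,
    "GLN": 0.40, "FLA": 0.40, "DSW": 0.45, "DLW": 0.45, "TDW": 0.45,
    "NSP": 0.50, "PH": 0.40, "SL": 0.35, "NSS": 0.35, "NG": 0.50, "HW": 0.45,
    "GY": 1.0,
}


def default_design(
    n_genotypes: int = 25, n_reps: int = 3, traits: list[str] | None = None
) -> TrialDesign:
    """Trial design emulating the published study conditions.

    Per trait, the full-irrigation mean and the limited-regime offset come
    from the published season x regime cell means; the genotypic and
    phenotypic variances are set from the published GCV/PCV (so the implied
    heritability matches the published GCV/PCV ratio), and the non-genotypic
    variance is split evenly between the G x E and residual phenotypic
    contributions at r = 3, e = 4.
    """
    summary = datasets.load_trait_summary().set_index("trait")
    params = datasets.load_genetic_parameters().set_index("trait")
    names = traits if traits is not None else list(summary.index)
    r_default, e_default = 3, 4

    specs = []
    for name in names:
        row = summary.loc[name]
        full = (row["mean_full_s1"] + row["mean_full_s2"]) / 2
        lim = (row["mean_limited_s1"] + row["mean_limited_s2"]) / 2
        xbar = row["mean_combined"]
        gcv, pcv = params.loc[name, "gcv"], params.loc[name, "pcv"]
        sigma_g = gcv / 100 * xbar
        sigma_p = pcv / 100 * xbar
        delta = max(sigma_p**2 - sigma_g**2, 0.0)
        specs.append(
            TraitSpec(
                name=name,
                grand_mean=float(full),
                sigma2_g=float(sigma_g**2),
                # split delta = s2gxe/e + s2e/(r e) evenly between the terms
                sigma2_gxe=float(e_default * delta / 2),
                sigma2_e=float(r_default * e_default * delta / 2),
                stress_direction=(
                    STRESS_INCREASES
                    if name in DEFAULT_STRESS_INCREASING
                    else STRESS_DECREASES
                ),
                stress_shift=float(abs(full - lim)),
                yield_correlation=DEFAULT_YIELD_CORRELATIONS.get(name, 0.35),
                lower_bound=0.0,  # every trait here is physically nonnegative
            )
        )
    return TrialDesign(n_genotypes=n_genotypes, traits=tuple(specs), n_reps=n_reps)


# ---------------------------------------------------------------------------
# derived-trait helpers (trivial formulas, kept for realistic simulation)
# ---------------------------------------------------------------------------

def leaf_water_content(fw: float, dw: float) -> float:
    """LWC = 100 (FW - DW) / FW."""
    if fw <= 0:
        raise ValueError("fresh weight must be positive")
    if fw < dw:
        raise ValueError("fresh weight must be >= dry weight")
    return 100.0 * (fw - dw) / fw


def relative_water_content(fw: float, tw: float, dw: float) -> float:
    """RWC = 100 (FW - DW) / (TW - DW)."""
    if tw <= dw:
        raise ValueError("turgid weight must exceed dry weight")
    if fw < dw:
        raise ValueError("fresh weight must be >= dry weight")
    return 100.0 * (fw - dw) / (tw - dw)


def leaf_equivalent_water_thickness(fw: float, dw: float, flag_leaf_area: float) -> float:
    """LEWT = (FW - DW) / flag leaf area."""
    if flag_leaf_area <= 0:
        raise ValueError("flag leaf area must be positive")
    if fw < dw:
        raise ValueError("fresh weight must be >= dry weight")
    return (fw - dw) / flag_leaf_area


def water_use_efficiency(pn: float, e: float) -> float:
    """Instantaneous WUE = Pn / E."""
    if e <= 0:
        raise ValueError("transpiration rate must be positive")
    return pn / e


def intrinsic_water_use_efficiency(pn: float, gs: float) -> float:
    """Intrinsic WUEi = Pn / Gs."""
    if gs <= 0:
        raise ValueError("stomatal conductance must be positive")
    return pn / gs


def stomatal_limitation(ci: float, ca: float) -> float:
    """Stomatal limitation Ls = 1 - Ci/Ca."""
    if ca <= 0:
        raise ValueError("ambient CO2 concentration must be positive")
    return 1.0 - ci / ca


def leaf_area_index(
    green_leaf_area: float,
    plants_per_meter: float,
    n_plants_sampled: float,
    row_spacing_cm: float,
) -> float:
    """LAI = (green leaf area x plants per metre of row) /
    (plants sampled x row spacing in cm)."""
    if n_plants_sampled <= 0 or row_spacing_cm <= 0:
        raise ValueError("plants sampled and row spacing must be positive")
    return (green_leaf_area * plants_per_meter) / (n_plants_sampled * row_spacing_cm)
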