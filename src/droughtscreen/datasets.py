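"""Packaged reference tables.

Small CSV digitizations of published summary tables from a 25-genotype bread
wheat drought-screening trial (two seasons, full vs. limited irrigation,
three replicates). They serve as worked-example inputs and as calibration for
the synthetic trial generator; no plot-level raw data were deposited with the
study, so plot-level inputs are always synthetic.
"""

from importlib import resources

import pandas as pd

__all__ = [
    "load_membership_scores",
    "load_collinearity_report",
    "load_path_table",
    "load_genetic_parameters",
    "load_trait_summary",
    "load_mean_squares",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("droughtscreen").joinpath("fixtures", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, **kwargs)


def load_membership_scores() -> pd.DataFrame:
    """Published per-trait, per-season membership scores (Fij), the seasonal
    and combined tolerance indices (Fi) and rank classes for 25 genotypes.

    Columns: ``<trait>_<season>`` score columns for GLA, LAI, RWC, CT over
    seasons S1/S2, plus ``Fi_S1``, ``Fi_S2``, ``Fi_combined`` and the
    corresponding ``class_*`` labels.
    """
    return _read("table6_membership.csv")


def load_collinearity_report() -> pd.DataFrame:
    """Published multicollinearity diagnosis (tolerance and VIF) for 28
    traits, before and after excluding the days-to-maturity trait."""
    return _read("table4_collinearity.csv")


def load_path_table() -> pd.DataFrame:
    """Published stepwise-regression and path-coefficient table for grain
    yield on the five screened traits (GLA, LAI, RWC, CT, Gs)."""
    return _read("table5_path.csv")


def load_genetic_parameters() -> pd.DataFrame:
    """Published genetic parameters (h2, GCV, PCV, GA, GG) for 28 traits."""
    return _read("table3_genetic_parameters.csv")


def load_trait_summary() -> pd.DataFrame:
    """Published per-season, per-regime genotype-mean summaries for 28 traits
    (the season x regime cell means and the combined grand mean)."""
    return _read("table2_trait_summary.csv")


def load_mean_squares() -> pd.DataFrame:
    """Published combined-ANOVA mean squares for three representative traits
    (DH, CT, GY), long format: trait, source, df, ms."""
    return _read("table1_mean_squares.csv")
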