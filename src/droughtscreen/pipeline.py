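"""End-to-end pipeline driver and structured configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genetics, group_validation, screening, synthetic_trial, tolerance_index, yield_model
from .io import write_long_csv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters; round-trips losslessly through YAML."""

    seed: int = 1
    n_genotypes: int = 25
    n_reps: int = 3
    e_convention: str = "season_x_regime"
    gxe_convention: str = "pooled"
    k: float = 2.06
    vif_threshold: float = 10.0
    loading_threshold: float = 0.27
    n_components: int = 2
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    yield_trait: str = "GY"
    trait_panel: list[str] = field(
        default_factory=lambda: list(tolerance_index.DEFAULT_TRAIT_PANEL)
    )
    invert: list[str] | None = None  # None = auto-detect from regime contrast
    linkage: str = "ward"
    k_groups: int = 5
    mantel_perms: int = 9999
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate",
            "genetics",
            "screening",
            "yield_model",
            "tolerance_index",
            "group_validation",
        ]
    )

    def __post_init__(self):
        if self.e_convention not in ("season_x_regime", "season"):
            raise ValueError(f"invalid e_convention {self.e_convention!r}")
        if self.gxe_convention not in genetics.GXE_CONVENTIONS:
            raise ValueError(f"invalid gxe_convention {self.gxe_convention!r}")
        if self.linkage not in ("ward", "upgma"):
            raise ValueError(f"invalid linkage {self.linkage!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_pipeline(
    config: PipelineConfig,
    observations: pd.DataFrame | None = None,
    out_dir=None,
) -> dict:
    """Run the staged analysis; returns a report dict and optionally writes
    every stage table plus a run log under ``out_dir``.

    Stage order: simulate/ingest -> genetics -> screening -> yield model ->
    tolerance index -> group validation. Any stage error aborts with the
    stage name attached.
    """
    report: dict = {"config": dataclasses.asdict(config), "log": []}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def note(msg: str):
        logger.info(msg)
        report["log"].append(msg)

    stage = "simulate"
    try:
        if observations is None:
            if "simulate" not in config.stages:
                raise ValueError("no input table and simulate stage disabled")
            design = synthetic_trial.default_design(
                n_genotypes=config.n_genotypes, n_reps=config.n_reps
            )
            observations, manifest = synthetic_trial.generate_trial(
                design, seed=config.seed
            )
            note(f"simulated trial: seed {config.seed}, {len(observations)} plot records")
            if out is not None:
                write_long_csv(observations, out / "trial.csv")
                manifest.to_json(out / "truth_manifest.json")

        stage = "genetics"
        if "genetics" in config.stages:
            gen = genetics.genetics_report(
                observations,
                e_convention=config.e_convention,
                gxe_convention=config.gxe_convention,
                k=config.k,
            )
            report["genetics"] = gen
            note(f"genetic parameters for {len(gen)} traits "
                 f"(GxE convention {config.gxe_convention})")
            if out is not None:
                gen.to_csv(out / "genetic_parameters.csv")

        stage = "screening"
        selected = None
        if "screening" in config.stages:
            cells = screening.genotype_means(observations, by_treatment=True)
            candidates = cells.drop(columns=[config.yield_trait], errors="ignore")
            coll = screening.iterative_exclude(candidates, config.vif_threshold)
            note(f"collinearity exclusion order: {coll.excluded}")
            kept = [c for c in candidates.columns if c not in coll.excluded]
            pca_res = screening.pca(cells[kept])
            selected = screening.select_traits(
                pca_res, config.loading_threshold, config.n_components
            )
            note(f"PCA retained {pca_res.retained} components; "
                 f"selected {len(selected)} traits: {selected}")
            report["screening"] = {
                "collinearity": coll.to_frame(),
                "excluded": coll.excluded,
                "eigenvalues": pca_res.eigenvalues,
                "selected_traits": selected,
            }
            if out is not None:
                coll.to_frame().to_csv(out / "collinearity.csv")
                pca_res.loadings.to_csv(out / "pca_loadings.csv")

        stage = "yield_model"
        if "yield_model" in config.stages:
            cells = screening.genotype_means(observations, by_treatment=True)
            if config.yield_trait not in cells.columns:
                raise ValueError(f"yield trait {config.yield_trait!r} absent")
            candidates = selected or [
                c for c in cells.columns if c != config.yield_trait
            ]
            candidates = [c for c in candidates if c != config.yield_trait]
            sw = yield_model.stepwise_regression(
                cells[candidates],
                cells[config.yield_trait],
                alpha_enter=config.alpha_enter,
                alpha_remove=config.alpha_remove,
            )
            note(f"stepwise entered {sw.entered} (R2 {sw.r2:.3f})")
            report["stepwise"] = sw
            if sw.entered:
                path = yield_model.path_analysis(
                    cells[sw.entered], cells[config.yield_trait]
                )
                report["path"] = path
                if out is not None:
                    pd.DataFrame(
                        {
                            "direct": path.direct,
                            "indirect": path.indirect,
                            "correlation": path.correlation,
                            "direct_r2": path.direct_r2,
                        }
                    ).to_csv(out / "path_coefficients.csv")

        stage = "tolerance_index"
        membership = None
        if "tolerance_index" in config.stages:
            panel = tuple(
                t for t in config.trait_panel if t in observations["trait"].unique()
            )
            if not panel:
                raise ValueError("no trait-panel traits present in data")
            fij, membership = tolerance_index.membership_from_observations(
                observations,
                traits=panel,
                invert=tuple(config.invert) if config.invert is not None else None,
            )
            summary = tolerance_index.classify_panel(membership)
            note(f"tolerance classes: {summary['counts']}, "
                 f"season agreement {summary['season_agreement']}")
            report["membership"] = membership
            report["membership_fij"] = fij
            report["class_summary"] = summary
            if out is not None:
                flat = fij.copy()
                flat.columns = [f"{t}_{s}" for t, s in fij.columns]
                flat.join(membership).to_csv(out / "membership.csv")

        stage = "group_validation"
        if "group_validation" in config.stages and membership is not None:
            fij = report["membership_fij"]
            groups = membership["class_combined"]
            dist = group_validation.euclidean_distances(fij)
            dend = group_validation.hierarchical_cluster(
                dist, method=config.linkage, k=config.k_groups
            )
            coords, explained = group_validation.pcoa(dist)
            coph = group_validation.cophenetic_distances(dend)
            mantel_r, mantel_p = group_validation.mantel_test(
                dist, coph, n_perm=config.mantel_perms, seed=config.seed
            )
            note(f"{config.linkage} clustering into {config.k_groups} groups; "
                 f"Mantel r={mantel_r:.3f} (p={mantel_p:.4g})")
            report["validation"] = {
                "dendrogram": dend,
                "pcoa_coords": coords,
                "pcoa_explained": explained,
                "mantel": (mantel_r, mantel_p),
            }
            # discriminant steps need every group populated with >= 2 members
            sizes = groups.value_counts()
            usable = sizes.index[sizes >= 2]
            mask = groups.isin(usable)
            if usable.size >= 2 and mask.sum() - usable.size >= fij.shape[1]:
                disc = group_validation.box_m_and_classify(fij[mask], groups[mask])
                man = group_validation.manova(fij[mask], groups[mask])
                note(f"{disc.classifier} resubstitution error "
                     f"{disc.resubstitution_error_pct:.2f}%; "
                     f"Wilks lambda {man.wilks_lambda:.4f} (p={man.p_value:.3g})")
                report["validation"]["discriminant"] = disc
                report["validation"]["manova"] = man
            else:
                note("discriminant/MANOVA skipped: groups too small")
            if out is not None:
                coords.to_csv(out / "pcoa_coordinates.csv")
                (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if out is not None:
        (out / "run_log.json").write_text(json.dumps(report["log"], indent=2))
    return report
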