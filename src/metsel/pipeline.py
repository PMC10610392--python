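"""End-to-end orchestration of the MET tolerance-index analysis.

Stage order: tolerance indices -> joint ANOVA / genetic parameters / BLUPs
-> AMMI -> WAASB/WAASBY -> MGIDI -> stepwise regression -> clustering + LDA.
Every stage writes CSV (or JSON) outputs into the configured directory and
the run ends with a manifest recording the configuration, package versions,
seed and a SHA-256 checksum per emitted file, so that re-running with the
same config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ammi import AMMI
from .anova import JointANOVA, fit_blup
from .classify import ToleranceLDA, ward_cluster
from .errors import ConfigurationError
from .indices import build_index_environments
from .mgidi import MGIDI
from .simulate import METDataset, SimConfig, TraitSpec, default_config, generate_met
from .smlr import StepwiseOLS, predict_report
from .waasb import classify_quadrants, waasb_from_index_table, waasby

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; either an input CSV path or a simulation config."""

    input_csv: str | None = None
    simulation: SimConfig | None = None
    senses: dict[str, str] = field(default_factory=dict)
    gy_trait: str = "GY"
    mgidi_intensity: float = 0.20
    waasby_weights: tuple[float, float] = (50.0, 50.0)
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    cluster_k: int = 5
    lda_prior_mode: str = "proportional"
    outdir: str = "metsel_out"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ConfigurationError(
                "input_csv/simulation", "exactly one input source required"
            )
        if not 0 < self.mgidi_intensity <= 1:
            raise ConfigurationError("mgidi_intensity", "must be in (0, 1]")
        ty, ts = self.waasby_weights
        if ty < 0 or ts < 0 or ty + ts == 0:
            raise ConfigurationError(
                "waasby_weights", "must be >= 0 and not both 0"
            )
        if self.cluster_k < 2:
            raise ConfigurationError("cluster_k", "must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            traits = tuple(
                TraitSpec(**t) if isinstance(t, dict) else t
                for t in sim.pop("traits", ())
            )
            for key in ("seasons", "conditions"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(traits=traits, **sim)
        if "waasby_weights" in raw:
            raw["waasby_weights"] = tuple(raw["waasby_weights"])
        return cls(simulation=sim, **raw)


@dataclass
class ReportBundle:
    outdir: Path
    outputs: dict[str, Path]
    manifest: dict
    consensus: dict

    @property
    def manifest_path(self) -> Path:
        return self.outdir / "manifest.json"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def emit(name: str, obj) -> None:
        path = outdir / name
        if isinstance(obj, (pd.DataFrame, pd.Series)):
            obj.to_csv(path)
        else:
            path.write_text(obj)
        outputs[name] = path

    if config.simulation is not None:
        met = generate_met(config.simulation)
        logger.info("stage simulate: %s rows", len(met.data))
        emit("met_data.csv", met.data.set_index("genotype"))
        senses = dict(config.senses) or {
            t.name: t.sense for t in config.simulation.traits
        }
    else:
        met = METDataset.from_csv(config.input_csv)
        senses = dict(config.senses)

    # 1. tolerance indices
    index_table = build_index_environments(met)
    logger.info(
        "stage indices: %d rows, environments %s",
        len(index_table.data), list(index_table.env_map),
    )
    emit("index_table.csv", index_table.data.set_index("genotype"))
    emit("environment_map.json", index_table.env_map_json())

    gy = config.gy_trait
    if gy not in index_table.traits:
        raise ConfigurationError("gy_trait", f"{gy!r} not among traits")

    # 2. joint ANOVA, genetic parameters, BLUPs per trait
    anova_rows, param_rows = [], []
    blups = {}
    for trait in index_table.traits:
        res = JointANOVA(index_table, trait).fit()
        tab = res.anova_table.reset_index(names="source")
        tab.insert(0, "trait", trait)
        anova_rows.append(tab)
        row = res.variance_components.as_series()
        row = pd.concat([row, res.genetic_parameters.as_series()])
        row.name = trait
        param_rows.append(row)
        blups[trait] = res.blup()
    anova_all = pd.concat(anova_rows, ignore_index=True)
    params_all = pd.DataFrame(param_rows)
    params_all.index.name = "trait"
    logger.info("stage genparams: %d traits", len(params_all))
    emit("joint_anova.csv", anova_all.set_index("trait"))
    emit("genetic_parameters.csv", params_all)

    # 3. AMMI on the grain-yield index
    ammi_res = AMMI.from_index_table(index_table, gy).fit()
    anova_gy = JointANOVA(index_table, gy).fit().anova_table
    r = index_table.n_reps
    ammi_tab = ammi_res.anova(anova_gy, r)
    logger.info("stage ammi: %d axes", ammi_res.n_axes)
    emit("ammi_anova.csv", ammi_tab)
    coords = ammi_res.biplot_coordinates()
    emit("ammi_biplot_genotypes.csv", coords["genotypes"])
    emit("ammi_biplot_environments.csv", coords["environments"])
    emit("ammi_environment_angles.csv", coords["environment_angles"])

    # 4. WAASB / WAASBY on the grain-yield index (BLUP interaction matrix)
    waasb_res = waasb_from_index_table(index_table, gy, blup=blups[gy])
    emit("waasb_genotypes.csv", waasb_res.genotypes)
    emit("waasb_environments.csv", waasb_res.environments)
    ty, ts = config.waasby_weights
    waasby_res = waasby(waasb_res, ty, ts, sense=senses.get(gy, "increase"))
    emit("waasby.csv", waasby_res.table)
    quad = classify_quadrants(
        waasb_res.genotypes["Y"], waasb_res.genotypes["waasb"]
    )
    emit("waasb_quadrants.csv", quad)
    logger.info("stage waasb: %d genotypes", len(quad))

    # 5. MGIDI on BLUP-based genotype means across all traits
    blup_means = pd.DataFrame(
        {t: b.genotype_means() for t, b in blups.items()}
    )
    mgidi_res = MGIDI(blup_means, senses).fit(config.mgidi_intensity)
    gains = mgidi_res.selection_gains(
        blup_means,
        params_all["h2mg"],
    )
    emit("mgidi_ranking.csv", pd.DataFrame(
        {"MGIDI": mgidi_res.distances, "rank": mgidi_res.ranks}
    ))
    emit("mgidi_gains.csv", gains)
    emit("mgidi_contributions.csv", mgidi_res.factor_contributions())
    emit("mgidi_loadings.csv", pd.concat(
        [mgidi_res.factor_model.loadings,
         mgidi_res.factor_model.communality.rename("communality"),
         mgidi_res.factor_model.uniqueness.rename("uniqueness")], axis=1
    ))
    logger.info("stage mgidi: selected %s", mgidi_res.selected)

    # 6. stepwise regression of GY index on the other trait indices
    from .ammi import two_way_means

    env_means = {
        t: two_way_means(index_table, t).stack() for t in index_table.traits
    }
    pooled = pd.DataFrame(env_means)
    smlr_model = StepwiseOLS(
        pooled.drop(columns=gy), pooled[gy],
        config.alpha_enter, config.alpha_remove,
    ).fit()
    gen_means = pd.DataFrame(
        {t: two_way_means(index_table, t).mean(axis=1)
         for t in index_table.traits}
    )
    if smlr_model.predictors:
        report = predict_report(
            smlr_model, gen_means.drop(columns=gy), gen_means[gy]
        )
        emit("smlr_report.csv", report)
    emit("smlr_model.json", json.dumps(
        {
            "predictors": smlr_model.predictors,
            "intercept": smlr_model.intercept,
            "coefficients": smlr_model.coefficients.to_dict(),
            "partial_r2": smlr_model.partial_r2.to_dict(),
            "total_r2": smlr_model.total_r2,
            "residual_se": smlr_model.resid_se,
        },
        indent=2,
    ))
    logger.info("stage smlr: selected %s", smlr_model.predictors)

    # 7. clustering and LDA validation
    cluster = ward_cluster(gen_means, k=config.cluster_k, gy=gy)
    emit("cluster_labels.csv", cluster.labels.rename("category"))
    emit("heatmap_matrix.csv", cluster.heatmap)
    emit("heatmap_orders.json", json.dumps(
        {"rows": list(cluster.row_order), "columns": list(cluster.col_order)}
    ))
    lda = ToleranceLDA(gen_means, cluster.labels,
                       prior_mode=config.lda_prior_mode).fit()
    resub = lda.classify(gen_means)
    loo = lda.loo()
    emit("lda_resubstitution.csv", resub.table)
    emit("lda_loo.csv", loo.table)
    logger.info(
        "stage classify: resubstitution %.1f%%, LOO %.1f%%",
        resub.percent_correct, loo.percent_correct,
    )

    # consensus across MGIDI, WAASB quadrant IV and LDA-confirmed tolerance
    mgidi_set = set(mgidi_res.selected)
    quad4 = set(quad.index[quad["quadrant"] == "IV"])
    tolerant = {"HT", "T"} if config.cluster_k == 5 else set(
        cluster.cluster_means.index[:2]
    )
    lda_confirmed = set(
        resub.table.index[
            (resub.table["prior"] == resub.table["posterior"])
            & resub.table["prior"].isin(tolerant)
        ]
    )
    consensus = {
        "mgidi_selected": sorted(mgidi_set),
        "waasb_quadrant_iv": sorted(quad4),
        "lda_confirmed_tolerant": sorted(lda_confirmed),
        "intersection": sorted(mgidi_set & quad4 & lda_confirmed),
    }
    emit("consensus.json", json.dumps(consensus, indent=2))

    manifest = {
        "package": "metsel",
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "checksums": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ReportBundle(outdir, outputs, manifest, consensus)


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    if config.simulation is not None:
        d["simulation"] = asdict(config.simulation)
        d["simulation"]["group_effects"] = dict(
            config.simulation.group_effects
        )
    return d


def default_pipeline_config(seed: int = 0, outdir: str = "metsel_out",
                            n_traits: int = 20) -> PipelineConfig:
    """Synthetic run at the study design scale."""
    return PipelineConfig(
        simulation=default_config(seed=seed, n_traits=n_traits),
        outdir=outdir,
        seed=seed,
    )
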