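"""End-to-end orchestration of the chemometric study flow.

Per compartment: Hotelling-T² screening of the bucket table, PLS regression
of AMEn with iterative variable selection, canonical sparse PLS against the
four digestive-efficiency traits, and a ±cutoff relevance network from the
first-component similarity matrix. The per-compartment networks are then
merged into one global network whose metabolites feed the over-
representation analysis. Every stage persists its intermediates as plain
text and the whole run is deterministic given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import io as mio
from . import network as net
from . import pls as mpls
from . import spls as mspls
from .screening import fit_pca, hotelling_screen
from .simulate import SPLS_TRAITS, SyntheticConfig, generate_dataset

logger = logging.getLogger("metadigest")

try:
    __version__ = _pkg_version("metadigest")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Inputs and settings for one full run. Either file paths or a
    synthetic configuration must be supplied."""

    outdir: str | Path = "metadigest_run"
    seed: int = 0
    # file inputs (per compartment) — or synthetic generation
    bucket_paths: dict[str, str] | None = None       # comp -> table TSV
    bucket_sidecars: dict[str, str] | None = None
    assignment_paths: dict[str, str] | None = None
    traits_path: str | None = None
    gmt_path: str | None = None
    synthetic: SyntheticConfig | None = None
    # stage settings
    screening_components: int = 2
    screening_alpha: float = 0.05
    pls_components: int = 2
    cv_folds: int = 7
    vip_threshold: float = 1.0
    spls_components: int = 2
    network_cutoff: float = 0.5
    enrichment_alpha: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.network_cutoff < 1.0:
            raise PipelineConfigError(
                f"network cutoff must lie in [0, 1), got {self.network_cutoff}")
        for name in ("screening_alpha", "enrichment_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise PipelineConfigError(f"{name} must lie in (0, 1), got {v}")
        for name in ("screening_components", "pls_components", "cv_folds",
                     "spls_components"):
            if getattr(self, name) < 1:
                raise PipelineConfigError(f"{name} must be at least 1")
        if self.synthetic is None:
            if not self.bucket_paths or not self.traits_path:
                raise PipelineConfigError(
                    "either synthetic config or bucket/trait paths required")
            for p in [self.traits_path, *(self.bucket_paths or {}).values(),
                      *(self.bucket_sidecars or {}).values(),
                      *(self.assignment_paths or {}).values(),
                      *( [self.gmt_path] if self.gmt_path else [] )]:
                if p and not Path(p).exists():
                    raise PipelineConfigError(f"input file not found: {p}")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        return d

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load settings from a YAML (or JSON — YAML is a superset) file."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        raw.update(overrides)
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        ds = generate_dataset(syn)
        return ds.buckets, ds.traits, ds.assignments, ds.library
    buckets = {
        comp: mio.read_bucket_table(
            path, (config.bucket_sidecars or {}).get(comp), compartment=comp)
        for comp, path in config.bucket_paths.items()}
    traits = mio.read_trait_table(config.traits_path)
    assignments = {
        comp: mio.read_assignment_map(path)
        for comp, path in (config.assignment_paths or {}).items()}
    library = mio.read_gmt(config.gmt_path) if config.gmt_path else {}
    return buckets, traits, assignments, library


def run_pipeline(config: PipelineConfig) -> dict:
    """Run screening → PLS → canonical sPLS → networks → merge → ORA and
    return (and persist) the structured run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    buckets, traits, assignments, library = _load_inputs(config)

    report: dict = {"version": __version__, "config": config.echo(),
                    "compartments": {}}
    networks: list[net.RelevanceNetwork] = []
    y_traits = ["AMEn", *[t for t in SPLS_TRAITS if t != "AMEn"]]
    traits_cc = traits.complete_cases(y_traits)

    for comp, table in buckets.items():
        stage = f"compartment {comp}"
        logger.info("%s: %d sample(s) x %d bucket(s)", stage,
                    *table.data.shape)
        common = [s for s in table.sample_ids if s in set(traits_cc.bird_ids)]
        if len(common) < 3 * config.cv_folds:
            raise RuntimeError(
                f"{stage}: only {len(common)} sample(s) with complete traits")
        table = mio.BucketTable(table.compartment, table.data.loc[common],
                                table.definitions)

        # --- screening ---------------------------------------------------
        pca = fit_pca(table.data, A=config.screening_components)
        screen = hotelling_screen(pca, alpha=config.screening_alpha)
        screen.write(outdir / f"{comp}_outliers.tsv")
        table = table.drop_samples(screen.excluded)
        y = traits_cc.data.loc[table.sample_ids]

        # --- PLS biomarker model -----------------------------------------
        # validity gate: biomarker selection only proceeds when the full
        # pre-selection model is itself significant; post-selection
        # statistics on a non-predictive metabolome would be optimistically
        # biased by the selection itself
        y_amen = y["AMEn"].to_numpy()
        full_cv = mpls.cross_validate(table.data, y_amen,
                                      config.pls_components, config.cv_folds)
        full_anova = mpls.cv_anova(full_cv)
        selection_performed = (full_anova.p_value <= 0.05
                               and full_cv.q2 > 0.0)
        if selection_performed:
            trace, final = mpls.iterative_selection(
                table.data, y_amen, A=config.pls_components,
                K=config.cv_folds, vip_threshold=config.vip_threshold)
        else:
            logger.warning("%s: full PLS model not significant (p=%.3g, "
                           "Q²=%.3f); skipping variable selection", stage,
                           full_anova.p_value, full_cv.q2)
            final = mpls.fit_pls(table.data, y_amen, config.pls_components)
            trace = mpls.SelectionTrace(
                iterations=[mpls.SelectionIteration(
                    variables=list(table.data.columns), q2=full_cv.q2,
                    q2_se=full_cv.q2_se, r2y=final.r2y,
                    cv_anova_p=full_anova.p_value)],
                best_index=0,
                stopped_because="full model not significant; no selection")
        best_vars = trace.best.variables
        A_fin = final.n_components
        cvrep = mpls.cross_validate(table.data[best_vars],
                                    y["AMEn"].to_numpy(), A_fin,
                                    config.cv_folds)
        anova = mpls.cv_anova(cvrep)
        coef_tab = cvrep.coefficient_table()
        coef_tab["VIP"] = mpls.vip(final)
        coef_tab.to_csv(outdir / f"{comp}_pls_coefficients.tsv", sep="\t",
                        float_format="%.12g")
        pd.DataFrame({
            "observed": y["AMEn"].to_numpy(),
            "predicted": final.predict(table.data[best_vars].values),
            "predicted_cv": cvrep.oof_predictions,
        }, index=pd.Index(table.sample_ids, name="sample_id")).to_csv(
            outdir / f"{comp}_pls_observed_predicted.tsv", sep="\t",
            float_format="%.12g")
        amap = assignments.get(comp)
        selected_metabolites = sorted({
            m for b in best_vars for m in (amap.metabolites_for(b) if amap else [])})
        pls_summary = {
            "n_samples": len(table.sample_ids),
            "n_components": A_fin,
            "selection_performed": bool(selection_performed),
            "full_model": {"q2": float(full_cv.q2),
                           "cv_anova_p": float(full_anova.p_value)},
            "r2x": float(final.r2x_cum[-1]),
            "r2y": float(final.r2y),
            "q2": float(cvrep.q2),
            "rmsee": float(cvrep.rmsee),
            "rmsecv": float(cvrep.rmsecv),
            "cv_anova_p": float(anova.p_value),
            "cv_anova_F": float(anova.f_statistic),
            "n_selected": len(best_vars),
            "selected_buckets": best_vars,
            "selected_metabolites": selected_metabolites,
            "selection_trace": trace.to_records(),
        }
        (outdir / f"{comp}_pls_model.json").write_text(
            json.dumps(_jsonable(pls_summary), indent=2, sort_keys=True))

        # --- canonical sPLS ----------------------------------------------
        keep_x = mspls.keep_quarter(table.data.shape[1])
        Y = y[list(SPLS_TRAITS)]
        spls_model = mspls.fit_spls_canonical(table.data, Y,
                                              H=config.spls_components,
                                              keep_x=keep_x)
        sim = mspls.similarity_matrix(spls_model, components=(1,))
        sim.write(outdir / f"{comp}_similarity.tsv")
        spls_summary = {
            "keep_x": keep_x,
            "n_components": spls_model.n_components,
            "x_explained": spls_model.x_explained.tolist(),
            "y_explained": spls_model.y_explained.tolist(),
            "selected_component1": spls_model.selected(1),
        }

        # --- relevance network -------------------------------------------
        network = net.build_network(sim, cutoff=config.network_cutoff,
                                    compartment=comp, assignment=amap)
        net.export_network(network, outdir / f"{comp}_network.graphml",
                           "graphml")
        net.export_network(network, outdir / f"{comp}_network.sif", "sif")
        networks.append(network)

        report["compartments"][comp] = {
            "n_input_samples": len(common),
            "excluded_samples": screen.excluded,
            "hotelling_critical": screen.critical_value,
            "pls": pls_summary,
            "spls": spls_summary,
            "network": {
                "n_bucket_nodes": len(network.bucket_nodes),
                "n_trait_nodes": len(network.trait_nodes),
                "n_edges": network.n_edges,
                "n_nodes": network.graph.number_of_nodes(),
            },
        }

    # --- merge + enrichment ----------------------------------------------
    merged = net.merge_networks(networks, maps=assignments)
    net.export_network(merged, outdir / "merged_network.graphml", "graphml")
    net.export_network(merged, outdir / "merged_network.tsv", "tsv")
    net.node_attribute_table(merged).to_csv(outdir / "merged_nodes.tsv",
                                            sep="\t", float_format="%.12g")
    query = sorted({part
                    for b in merged.bucket_nodes
                    for part in merged.graph.nodes[b]["label"].split(" + ")})
    report["merged_network"] = {
        "n_metabolite_nodes": len(merged.bucket_nodes),
        "n_trait_nodes": len(merged.trait_nodes),
        "n_edges": merged.n_edges,
        "query_metabolites": query,
    }
    if library and query:
        results = enr.ora(query, library)
        enr.write_results(results, outdir / "enrichment.tsv")
        sig = enr.results_table(results, fdr_cutoff=config.enrichment_alpha)
        report["enrichment"] = {
            "n_sets_tested": len(results),
            "significant_sets": sig["set"].tolist(),
            "top": ([{"set": r.name, "match": r.match, "p": r.p_value,
                      "fdr_p": r.fdr_p} for r in results[:5]]),
        }
    else:
        report["enrichment"] = {"n_sets_tested": 0, "significant_sets": [],
                                "top": []}

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2,
                                      sort_keys=True))
    logger.info("pipeline complete; report at %s", report_path)
    return report
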