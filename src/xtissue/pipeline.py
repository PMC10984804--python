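"""End-to-end orchestration of the cross-tissue analysis.

Order of stages: preprocess (TMM -> log2CPM -> expression/protein filter ->
cross-dataset candidate intersection) -> per-tissue correlation edges on the
reference cohort -> shared network -> Louvain communities -> eigengenes on
the intervention cohort -> Time x Tissue interaction and per-tissue paired
tests -> trait correlations -> OPLS / OPLS-DA trait models on the reference
cohort.  Deterministic for a fixed config + seed; every stage writes its
table under the output directory and the run ends with a JSON report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .communities import (
    eigengene_matrix,
    interaction_anova,
    paired_community_test,
    trait_correlation,
)
from .network import (
    CommunityPartition,
    intersect_edges,
    louvain_partition,
    network_summary,
    tissue_edges,
)
from .opls import auroc, cross_validate, fit_opls, fit_oplsda
from .preprocess import filter_genes, intersect_candidates, log2cpm, tmm_factors
from .simulate import (
    SimulationConfig,
    SyntheticCohort,
    config_to_dict,
    generate_intervention_cohort,
    generate_reference_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_external_cohort", "validate_report"]


@dataclass
class PipelineConfig:
    """One config for the whole study flow.

    Either ``simulate`` holds a :class:`SimulationConfig` (synthetic study)
    or the four input paths point at real count/sample/trait files.
    """

    seed: int
    outdir: str | Path | None = None
    simulate: SimulationConfig | None = None
    reference_counts: str | None = None
    reference_samples: str | None = None
    intervention_counts: str | None = None
    intervention_samples: str | None = None
    traits: str | None = None
    protein_list: str | None = None
    min_avg_log2cpm: float = 4.0
    prior_count: float = 0.5
    r_min: float = 0.30
    fdr_max: float = 0.01
    use_abs_r: bool = False
    require_sign_concordance: bool = True
    resolution: float = 1.0
    min_size: int = 10
    n_ortho: int = 1
    n_repeats: int = 1000
    n_permutations: int = 1000
    holdout_fraction: float = 1.0 / 7.0
    trait_tissue: str = "SAT"
    trait_timepoint: str = "pre"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must be in (0, 1]")
        if self.min_size < 1 or self.resolution <= 0:
            raise ValueError("invalid partition parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(simulate=SimulationConfig(**sim) if sim else None, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = config_to_dict(self.simulate)
        d["outdir"] = str(self.outdir) if self.outdir else None
        return d

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # output location is not part of the analysis
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _stage(name: str):
    """Decorator: re-raise stage errors with the stage name and a hint."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(
                    f"pipeline stage '{name}' failed: {exc} "
                    f"(check the inputs/thresholds feeding this stage)"
                ) from exc

        return wrapper

    return deco


@_stage("preprocess")
def _preprocess_tissue(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    tissue: str,
    min_avg_log2cpm: float,
    prior_count: float,
    protein_evidence: set[str] | None,
) -> pd.DataFrame:
    samples = annotations.loc[annotations["tissue"] == tissue, "sample_id"]
    sub = counts[list(samples)]
    factors = tmm_factors(sub)
    expr = log2cpm(sub, factors, prior_count=prior_count)
    return filter_genes(expr, min_avg_log2cpm=min_avg_log2cpm, protein_evidence=protein_evidence)


def _load_cohorts(config: PipelineConfig):
    if config.simulate is not None:
        ss = np.random.SeedSequence(config.seed)
        ref_seed, int_seed = (int(s) for s in ss.generate_state(2) % (2**31))
        ref = generate_reference_cohort(config.simulate, seed=ref_seed)
        inter = generate_intervention_cohort(config.simulate, seed=int_seed)
        return ref, inter
    if not (config.reference_counts and config.intervention_counts):
        raise ValueError("either a simulate block or input paths are required")
    ref = SyntheticCohort.__new__(SyntheticCohort)  # plain container for real data
    ref.counts = io.read_counts(config.reference_counts)
    ref.annotations = io.read_sample_sheet(config.reference_samples)
    ref.traits = io.read_traits(config.traits) if config.traits else pd.DataFrame()
    ref.truth = {}
    inter = SyntheticCohort.__new__(SyntheticCohort)
    inter.counts = io.read_counts(config.intervention_counts)
    inter.annotations = io.read_sample_sheet(config.intervention_samples)
    inter.traits = ref.traits
    inter.truth = {}
    return ref, inter


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow; returns (and optionally writes) the report dict."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    ref, inter = _load_cohorts(config)
    protein = io.read_gene_list(config.protein_list) if config.protein_list else None

    expr = {}
    for label, cohort in (("reference", ref), ("intervention", inter)):
        for tissue in ("SM", "SAT"):
            expr[(label, tissue)] = _preprocess_tissue(
                cohort.counts, cohort.annotations, tissue,
                config.min_avg_log2cpm, config.prior_count, protein,
            )
    candidates = intersect_candidates(list(expr.values()))
    logger.info("%d candidate genes across datasets and tissues", len(candidates))

    edges = {}
    for tissue in ("SM", "SAT"):
        edges[tissue] = tissue_edges(
            expr[("reference", tissue)].loc[candidates],
            r_min=config.r_min,
            fdr_max=config.fdr_max,
            tissue=tissue,
            use_abs_r=config.use_abs_r,
        )
    try:
        net = intersect_edges(
            edges["SM"], edges["SAT"],
            require_sign_concordance=config.require_sign_concordance,
        )
    except ValueError as exc:
        raise RuntimeError(f"pipeline stage 'network' failed: {exc}") from exc
    summary = network_summary(net)
    partition = louvain_partition(
        net, resolution=config.resolution, min_size=config.min_size, seed=config.seed
    )

    inter_expr = pd.concat(
        [expr[("intervention", "SM")], expr[("intervention", "SAT")]], axis=1
    )
    inter_expr = inter_expr.loc[[g for g in candidates if g in inter_expr.index]]
    eig, varexp = eigengene_matrix(inter_expr, partition.membership)
    anova = interaction_anova(eig, inter.annotations)

    trait_tab = (
        trait_correlation(
            eig, inter.annotations, inter.traits,
            timepoint=config.trait_timepoint, tissue=config.trait_tissue,
        )
        if len(inter.traits)
        else pd.DataFrame()
    )

    # Trait models on the reference cohort for the most discordant community
    opls_block = {}
    focus = anova["p_interaction"].idxmin()
    genes_focus = partition.membership.index[partition.membership == focus]
    ref_sat = expr[("reference", "SAT")]
    genes_focus = [g for g in genes_focus if g in ref_sat.index]
    if len(genes_focus) >= 2 and len(ref.traits):
        ann_sat = ref.annotations[ref.annotations["tissue"] == "SAT"]
        Xdf = ref_sat.loc[genes_focus, ann_sat["sample_id"]].T
        tr = ref.traits.set_index("subject_id").loc[ann_sat["subject_id"]]
        y_cont = tr["bmi_like"].to_numpy(dtype=float)
        model = fit_opls(Xdf, y_cont, n_ortho=config.n_ortho)
        cv = cross_validate(
            Xdf, y_cont,
            n_repeats=config.n_repeats,
            n_permutations=config.n_permutations,
            holdout_fraction=config.holdout_fraction,
            seed=config.seed,
            n_ortho=config.n_ortho,
        )
        vips = pd.Series(model.vip, index=model.predictor_ids).sort_values(ascending=False)
        opls_block["bmi_like"] = {
            "community": int(focus),
            "r2y": model.r2y,
            "r2x": model.r2x,
            "q2": cv.q2,
            "q_value": cv.q_value,
            "n_vip_gt1": int((vips > 1).sum()),
            "top_vip": {g: float(v) for g, v in vips.head(10).items()},
        }
        y_bin = tr["t2d_like"].to_numpy(dtype=int)
        if len(np.unique(y_bin)) == 2 and min((y_bin == 0).sum(), (y_bin == 1).sum()) >= 3:
            da = fit_oplsda(Xdf, y_bin, n_ortho=config.n_ortho)
            roc = auroc(da.decision_scores(Xdf), y_bin)
            da_vips = pd.Series(da.vip, index=da.predictor_ids).sort_values(ascending=False)
            opls_block["t2d_like"] = {
                "community": int(focus),
                "r2y": da.r2y,
                "auroc": roc.auroc,
                "n_pos": roc.n_pos,
                "n_neg": roc.n_neg,
                "n_vip_gt1": int((da_vips > 1).sum()),
                "top_vip": {g: float(v) for g, v in da_vips.head(10).items()},
            }

    sizes = partition.membership.value_counts().to_dict()
    report = {
        "network": {
            "n_nodes": summary.n_nodes,
            "n_edges": summary.n_edges,
            "mean_r": summary.mean_r,
            "modularity": partition.modularity,
            "n_communities": int((partition.membership.unique() != 0).sum()),
        },
        "communities": {
            str(cid): {
                "size": int(sizes.get(cid, 0)),
                "variance_explained": float(varexp.get(cid, float("nan"))),
                **{k: float(v) for k, v in anova.loc[cid].items()},
            }
            for cid in anova.index
        },
        "trait_correlations": trait_tab.to_dict(orient="records"),
        "opls": opls_block,
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "xtissue_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        },
    }
    validate_report(report)

    if outdir:
        io.write_edges(net.edges, outdir / "network_edges.tsv")
        io.write_membership(partition.membership, outdir / "communities.tsv")
        io.write_gmt(partition.communities(), outdir / "communities.gmt")
        eig.to_csv(outdir / "eigengenes.csv")
        anova.to_csv(outdir / "interaction_results.tsv", sep="\t")
        if len(trait_tab):
            trait_tab.to_csv(outdir / "trait_correlations.tsv", sep="\t", index=False)
        io.write_json(report, outdir / "report.json")
    return report


def validate_external_cohort(
    membership: pd.Series,
    cohort_expr: pd.DataFrame,
    annotations: pd.DataFrame,
    tissue: str,
) -> tuple[float, pd.DataFrame]:
    """Replicate community regulation in an external paired single-tissue cohort.

    Reports the fraction of network genes present in the cohort, recomputes
    eigengenes on the mapped genes only, and runs a paired pre/post t-test per
    community.  Returns (mapped_fraction, per-community table).
    """
    network_genes = list(membership.index)
    mapped = [g for g in network_genes if g in cohort_expr.index]
    mapped_fraction = len(mapped) / len(network_genes)
    if mapped_fraction < 0.5:
        logger.warning("only %.0f%% of network genes mapped", 100 * mapped_fraction)

    eig, _ = eigengene_matrix(cohort_expr.loc[mapped], membership[mapped])
    ann = annotations[annotations["tissue"] == tissue].set_index("sample_id")
    rows = []
    for cid, scores in eig.iterrows():
        by_tp = {
            tp: pd.Series(
                scores[ann.index[ann["timepoint"] == tp]].to_numpy(),
                index=ann.loc[ann["timepoint"] == tp, "subject_id"],
            )
            for tp in ("pre", "post")
        }
        t, p, fc = paired_community_test(by_tp["pre"], by_tp["post"])
        rows.append({"community": cid, "t": t, "p": p, "fc": fc})
    return mapped_fraction, pd.DataFrame(rows).set_index("community")


_REPORT_SCHEMA = {
    "network": {"n_nodes": int, "n_edges": int, "mean_r": float,
                "modularity": float, "n_communities": int},
    "communities": dict,
    "trait_correlations": list,
    "opls": dict,
    "provenance": {"config_hash": str, "seed": int, "xtissue_version": str},
}


def validate_report(report: dict) -> None:
    """Minimal structural validation of the pipeline report (see docs/report.schema.json)."""

    def check(obj, schema, path="report"):
        if isinstance(schema, dict):
            if not isinstance(obj, dict):
                raise ValueError(f"{path} must be an object")
            for key, sub in schema.items():
                if key not in obj:
                    raise ValueError(f"{path}.{key} is missing")
                check(obj[key], sub, f"{path}.{key}")
        elif schema is float:
            if not isinstance(obj, (int, float)):
                raise ValueError(f"{path} must be numeric")
        elif not isinstance(obj, schema):
            raise ValueError(f"{path} must be {schema.__name__}")

    check(report, _REPORT_SCHEMA)
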