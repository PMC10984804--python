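"""Relate community expression to clinical traits.

(1) Pearson correlation of intervention-cohort eigengenes (pre-training SAT
slice) against the trait table; (2) OPLS regression of the most discordant
community's reference-SAT expression against the BMI-like trait, with VIP,
Monte-Carlo cross-validated Q2 and a permutation q-value; (3) OPLS-DA
against the binary T2D-like trait with AUROC.  Writes trait tables and
model summaries under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from xtissue import io
from xtissue.communities import eigengene_matrix, trait_correlation
from xtissue.opls import auroc, cross_validate, fit_opls, fit_oplsda

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
DATA = Path("results/data")
EXPR = Path("results/expression")
NET = Path("results/network")
OUT = Path("results")
CV_REPEATS = 1000
CV_PERMUTATIONS = 1000


def main() -> None:
    membership = pd.read_csv(NET / "communities.tsv", sep="\t", index_col=0)["community"]
    annotations = io.read_sample_sheet(DATA / "intervention_samples.csv")
    traits = io.read_traits(DATA / "intervention_traits.csv")
    eig = pd.read_csv(OUT / "eigengenes.csv", index_col=0)
    eig.index.name = "community"

    tab = trait_correlation(eig, annotations, traits, tissue="SAT", timepoint="pre")
    tab.to_csv(OUT / "trait_correlations.tsv", sep="\t", index=False)
    strong = tab[tab["p"] < 0.05].sort_values("p")
    print("eigengene-trait correlations with p < 0.05 (pre-training SAT):")
    print(strong.round(4).to_string(index=False) if len(strong) else "  none")

    inter = pd.read_csv(OUT / "interaction_results.tsv", sep="\t", index_col=0)
    target = int(inter["p_interaction"].idxmin())
    genes = membership.index[membership == target]
    print(f"\nOPLS models for community {target} ({len(genes)} genes), reference SAT:")

    expr = pd.read_csv(EXPR / "reference_SAT_log2cpm.tsv.gz", sep="\t", index_col=0)
    samples = io.read_sample_sheet(DATA / "reference_samples.csv")
    ann_sat = samples[samples["tissue"] == "SAT"]
    X = expr.loc[[g for g in genes if g in expr.index], ann_sat["sample_id"]].T
    tr = io.read_traits(DATA / "reference_traits.csv").set_index("subject_id")
    tr = tr.loc[ann_sat["subject_id"]]

    model = fit_opls(X, tr["bmi_like"].to_numpy(), n_ortho=1)
    cv = cross_validate(
        X, tr["bmi_like"].to_numpy(), n_repeats=CV_REPEATS,
        n_permutations=CV_PERMUTATIONS, seed=SEED, n_ortho=1,
    )
    vips = pd.Series(model.vip, index=model.predictor_ids).sort_values(ascending=False)
    print(
        f"  BMI-like: R2Y = {model.r2y:.2f}, Q2 = {cv.q2:.2f}, "
        f"q-value = {cv.q_value:.3g}, {int((vips > 1).sum())} genes with VIP > 1"
    )

    da = fit_oplsda(X, tr["t2d_like"].to_numpy(), n_ortho=1)
    roc = auroc(da.decision_scores(X), tr["t2d_like"].to_numpy())
    da_vips = pd.Series(da.vip, index=da.predictor_ids).sort_values(ascending=False)
    print(
        f"  T2D-like (OPLS-DA): R2Y = {da.r2y:.2f}, AUROC = {roc.auroc:.2f} "
        f"({roc.n_pos} cases / {roc.n_neg} controls)"
    )

    vip_table = pd.DataFrame({"vip_bmi": vips, "vip_t2d": da_vips}).sort_values(
        "vip_bmi", ascending=False
    )
    vip_table["vip_gt1"] = vip_table["vip_bmi"] > 1
    vip_table.to_csv(OUT / "opls_vip.tsv", sep="\t")
    io.write_json(
        {
            "community": target,
            "bmi_like": {"r2y": model.r2y, "r2x": model.r2x, "q2": cv.q2,
                         "q_value": cv.q_value, "n": len(X)},
            "t2d_like": {"r2y": da.r2y, "auroc": roc.auroc,
                         "n_pos": roc.n_pos, "n_neg": roc.n_neg},
        },
        OUT / "opls_summary.json",
    )


if __name__ == "__main__":
    main()
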