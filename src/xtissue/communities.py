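"""Community eigengenes and the exercise / trait statistics computed on them.

An eigengene is the first principal component of a community's standardized
expression across samples — one score per sample summarizing the community.
The exercise analysis is a fully within-subject 2x2 (Time x Tissue)
repeated-measures ANOVA on eigengenes; trait analysis is Pearson correlation
of eigengenes against clinical traits on one tissue x timepoint slice.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "eigengene",
    "eigengene_matrix",
    "interaction_anova",
    "paired_community_test",
    "trait_correlation",
]


def eigengene(expr_subset: pd.DataFrame) -> tuple[pd.Series, float]:
    """First-PC scores (one per sample, unit norm) of one community's genes.

    Genes (rows) are standardized to mean 0 / SD 1 across samples before the
    SVD.  The sign is chosen so the scores correlate non-negatively with the
    community's mean standardized expression; if that mean is identically
    zero (e.g. two genes that are exact negatives) the tie-break is a
    positive loading on the first gene.

    Returns (scores, variance_explained).
    """
    if expr_subset.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = expr_subset.std(axis=1, ddof=1)
    const = sd <= 0
    if const.any():
        logger.warning("dropping %d constant gene(s) from eigengene", int(const.sum()))
        expr_subset = expr_subset.loc[~const]
        sd = sd[~const]
    if expr_subset.shape[0] < 2:
        raise ValueError("community has fewer than 2 non-constant genes")

    z = (expr_subset.sub(expr_subset.mean(axis=1), axis=0)).div(sd, axis=0).to_numpy()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    variance_explained = float(s[0] ** 2 / np.sum(s**2))

    mean_profile = z.mean(axis=0)
    align = float(scores @ mean_profile)
    if align < 0:
        scores = -scores
    elif align == 0 and u[0, 0] < 0:
        scores = -scores
    return pd.Series(scores, index=expr_subset.columns, name="eigengene"), variance_explained


def eigengene_matrix(
    expr: pd.DataFrame, membership: pd.Series | Mapping[str, int]
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes of every community with >= 2 genes present in ``expr``.

    ``membership`` maps gene -> community id; id 0 ("unassigned") is skipped.
    Returns (community x sample scores, per-community variance explained).
    """
    membership = pd.Series(dict(membership)) if not isinstance(membership, pd.Series) else membership
    rows, varexp = {}, {}
    for cid in sorted(set(membership.values)):
        if cid == 0:
            continue
        genes = membership.index[membership == cid]
        genes = [g for g in genes if g in expr.index]
        if len(genes) < 2:
            logger.warning("community %s has <2 genes in the matrix; skipped", cid)
            continue
        scores, ve = eigengene(expr.loc[genes])
        rows[cid] = scores
        varexp[cid] = ve
    if not rows:
        raise ValueError("no community had >= 2 genes in the expression matrix")
    eig = pd.DataFrame(rows).T
    eig.index.name = "community"
    return eig, pd.Series(varexp, name="variance_explained")


def _complete_design(
    scores: pd.Series, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Subject x (tissue, timepoint) table of eigengene values; complete subjects only."""
    ann = annotations.set_index("sample_id")
    df = pd.DataFrame(
        {
            "score": scores,
            "subject": ann.loc[scores.index, "subject_id"],
            "tissue": ann.loc[scores.index, "tissue"],
            "timepoint": ann.loc[scores.index, "timepoint"],
        }
    )
    wide = df.pivot_table(
        index="subject", columns=["tissue", "timepoint"], values="score", aggfunc="first"
    )
    needed = [(t, tp) for t in ("SM", "SAT") for tp in ("pre", "post")]
    missing_cols = [c for c in needed if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"design is missing cells: {missing_cols}")
    complete = wide[needed].dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.warning("excluding %d incomplete subject(s)", dropped)
    if len(complete) < 3:
        raise ValueError("fewer than 3 complete subjects")
    return complete[needed]


def _one_sample_t(x: np.ndarray) -> tuple[float, float]:
    """(t, two-sided p) of mean(x)=0; degenerate zero-variance handled explicitly."""
    n = len(x)
    m = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return (0.0, 1.0) if m == 0 else (np.inf * np.sign(m), 0.0)
    t = m / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def interaction_anova(
    eig: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Two-way fully within-subject (Time, Tissue, Time x Tissue) ANOVA per community.

    Each effect is tested against its own subject-by-effect error stratum
    (the exact 2x2 repeated-measures decomposition).  Also reports, per
    tissue, the mean paired eigengene change post - pre (``fc_sm``/``fc_sat``)
    with its paired t-test p.

    ``eig`` is community x sample; ``annotations`` must provide a complete
    2x2 tissue-by-timepoint design per subject (incomplete subjects are
    dropped with a warning; fewer than 3 complete subjects is an error).
    """
    out = []
    for cid, scores in eig.iterrows():
        wide = _complete_design(scores, annotations)
        y = wide.to_numpy()  # columns: SM-pre, SM-post, SAT-pre, SAT-post
        n = y.shape[0]
        sm_pre, sm_post, sat_pre, sat_post = y.T

        grand = y.mean()
        subj_mean = y.mean(axis=1)
        time_mean = np.array([(sm_post + sat_post).mean() / 2, (sm_pre + sat_pre).mean() / 2])
        tissue_mean = np.array([(sm_pre + sm_post).mean() / 2, (sat_pre + sat_post).mean() / 2])

        # cell means indexed [tissue, time]: [[SM-pre, SM-post], [SAT-pre, SAT-post]]
        cell = np.array([[sm_pre.mean(), sm_post.mean()], [sat_pre.mean(), sat_post.mean()]])

        ss_time = 2 * n * np.sum((time_mean - grand) ** 2)
        ss_tissue = 2 * n * np.sum((tissue_mean - grand) ** 2)
        tis_m = cell.mean(axis=1)  # per-tissue mean
        tim_m = cell.mean(axis=0)  # per-time mean
        inter = cell - tis_m[:, None] - tim_m[None, :] + grand
        ss_inter = n * np.sum(inter**2)

        # error strata: subject x effect interactions
        subj_time = np.stack([(sm_pre + sat_pre) / 2, (sm_post + sat_post) / 2], axis=1)
        ss_err_time = 2 * np.sum(
            (subj_time - subj_mean[:, None] - tim_m[None, :] + grand) ** 2
        )
        subj_tissue = np.stack([(sm_pre + sm_post) / 2, (sat_pre + sat_post) / 2], axis=1)
        ss_err_tissue = 2 * np.sum(
            (subj_tissue - subj_mean[:, None] - tis_m[None, :] + grand) ** 2
        )
        cells = np.stack([[sm_pre, sm_post], [sat_pre, sat_post]])  # tissue x time x subj
        resid = (
            cells
            - cell[:, :, None]
            - subj_time.T[None, :, :]
            - subj_tissue.T[:, None, :]
            + tim_m[None, :, None]
            + tis_m[:, None, None]
            + subj_mean[None, None, :]
            - grand
        )
        ss_err_inter = np.sum(resid**2)

        df_err = n - 1

        def f_and_p(ss_effect: float, ss_error: float) -> tuple[float, float]:
            if ss_error <= 1e-300:
                return (0.0, 1.0) if ss_effect <= 1e-300 else (np.inf, 0.0)
            f = (ss_effect / 1.0) / (ss_error / df_err)
            return float(f), float(stats.f.sf(f, 1, df_err))

        f_time, p_time = f_and_p(ss_time, ss_err_time)
        f_tissue, p_tissue = f_and_p(ss_tissue, ss_err_tissue)
        f_inter, p_inter = f_and_p(ss_inter, ss_err_inter)

        d_sm = sm_post - sm_pre
        d_sat = sat_post - sat_pre
        _, p_sm = _one_sample_t(d_sm)
        _, p_sat = _one_sample_t(d_sat)

        out.append(
            {
                "community": cid,
                "n_subjects": n,
                "F_time": f_time,
                "p_time": p_time,
                "F_tissue": f_tissue,
                "p_tissue": p_tissue,
                "F_interaction": f_inter,
                "p_interaction": p_inter,
                "fc_sm": float(d_sm.mean()),
                "p_sm": p_sm,
                "fc_sat": float(d_sat.mean()),
                "p_sat": p_sat,
            }
        )
    return pd.DataFrame(out).set_index("community")


def paired_community_test(
    eig_pre: pd.Series, eig_post: pd.Series, pairing: Mapping[str, str] | None = None
) -> tuple[float, float, float]:
    """Paired two-sided t-test of post - pre eigengene scores.

    ``eig_pre``/``eig_post`` are indexed by subject (or by sample with
    ``pairing`` mapping post-sample -> pre-sample).  Returns (t, p, fc) with
    fc = mean difference.  Zero-variance nonzero differences return p = 0.
    """
    if pairing is not None:
        eig_post = pd.Series(
            {pre: eig_post[post] for post, pre in pairing.items()}
        )
    unmatched = [s for s in eig_post.index if s not in eig_pre.index]
    if unmatched:
        raise ValueError(f"unmatched subject(s): {unmatched}")
    common = [s for s in eig_pre.index if s in eig_post.index]
    if len(common) < 3:
        raise ValueError("need at least 3 pairs")
    d = (eig_post[common] - eig_pre[common]).to_numpy(dtype=float)
    t, p = _one_sample_t(d)
    return t, p, float(d.mean())


def trait_correlation(
    eig: pd.DataFrame,
    annotations: pd.DataFrame,
    traits: pd.DataFrame,
    timepoint: str = "pre",
    tissue: str = "SAT",
    trait_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r of each community eigengene against each trait, one tissue x timepoint slice.

    Missing trait values are dropped pairwise; associations with a
    zero-variance trait are skipped with a warning.  Returns a long table
    (community, trait, r, p, n).
    """
    ann = annotations[(annotations["tissue"] == tissue) & (annotations["timepoint"] == timepoint)]
    sample_to_subject = dict(zip(ann["sample_id"], ann["subject_id"]))
    samples = [s for s in eig.columns if s in sample_to_subject]
    if len(samples) < 4:
        raise ValueError("need at least 4 subjects in the requested slice")
    tr = traits.set_index("subject_id")
    if trait_cols is None:
        trait_cols = [
            c for c in tr.columns if pd.api.types.is_numeric_dtype(tr[c])
        ]
    rows = []
    for cid, scores in eig.iterrows():
        subj = pd.Series(
            scores[samples].to_numpy(), index=[sample_to_subject[s] for s in samples]
        )
        for trait in trait_cols:
            joined = pd.DataFrame({"eig": subj, "trait": tr[trait]}).dropna()
            if len(joined) < 4:
                logger.warning("trait %s: fewer than 4 paired observations; skipped", trait)
                continue
            if joined["trait"].std(ddof=1) == 0:
                logger.warning("trait %s has zero variance; skipped", trait)
                continue
            r, p = stats.pearsonr(joined["eig"], joined["trait"])
            rows.append(
                {"community": cid, "trait": trait, "r": float(r), "p": float(p), "n": len(joined)}
            )
    return pd.DataFrame(rows)
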