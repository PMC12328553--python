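"""End-to-end analysis chains shared by the CLI and the analysis scripts.

Each pipeline takes validated input tables (or generates synthetic ones),
runs the corresponding module chain, and returns a JSON-serializable report
that embeds the configuration and seeds needed to reproduce it.
"""

from __future__ import annotations

from typing import Any

import pandas as pd

from . import __version__, creativity, features, geometry, pairs, ratings
from .synthetic import SynthConfig, gen_associations, gen_choices, gen_ratings


def stimulus_feature_table(**kwargs) -> pd.DataFrame:
    return features.feature_table(geometry.catalog(), **kwargs)


def run_exp1(
    matrix: pd.DataFrame,
    feature_tbl: pd.DataFrame | None = None,
    k: int = 3,
    restarts: int = 100,
    seed: int = 0,
) -> dict[str, Any]:
    """Rating chain: ICC, clustering, profiles, correlations, OLS, LMM."""
    ft = feature_tbl if feature_tbl is not None else stimulus_feature_table()
    ft = ft.reindex(matrix.columns)
    icc = ratings.icc_consistency_avg(matrix)
    assignment = ratings.cluster_raters(
        matrix, k=k, restarts=restarts, seed=seed, dcm=ft["dcm"]
    )
    profiles = ratings.group_profiles(matrix, assignment)
    group_icc = {
        g: ratings.icc_consistency_avg(matrix.loc[assignment.members(g)])
        for g in profiles.index
    }
    corr_r, corr_p = ratings.rating_feature_correlations(
        profiles, ft[list(features.FEATURE_COLUMNS)]
    )
    ols = ratings.ols_group_regression(profiles, ft)
    lmm = ratings.lmm_random_intercept(ratings.to_long(matrix), ft, assignment.labels)
    icc_lmm, marg, cond = ratings.lmm_variance_summary(
        lmm.sigma2, lmm.tau00, sigma2_fixed=lmm.sigma2_fixed
    )
    return {
        "version": __version__,
        "config": {"k": k, "restarts": restarts, "seed": seed},
        "n_raters": len(matrix),
        "icc_consistency_avg": icc,
        "explained_variance": assignment.explained_variance,
        "group_sizes": assignment.sizes,
        "group_icc": group_icc,
        "group_profiles": {g: profiles.loc[g].to_dict() for g in profiles.index},
        "feature_correlations_r": corr_r.to_dict(),
        "feature_correlations_p": corr_p.to_dict(),
        "ols": {
            "params": ols.params.to_dict(),
            "pvalues": ols.pvalues.to_dict(),
            "r_squared": ols.r_squared.to_dict(),
        },
        "lmm": {
            "fixed_effects": lmm.fixed_effects.to_dict(),
            "sigma2": lmm.sigma2,
            "tau00": lmm.tau00,
            "icc": icc_lmm,
            "marginal_r2": marg,
            "conditional_r2": cond,
            "converged": lmm.converged,
        },
        "_labels": assignment.labels,  # for downstream use; stripped on write
    }


def run_exp2a(choices: pd.DataFrame, reference: str = "AR") -> dict[str, Any]:
    """Choice chain: orders, distribution, Borda (cohort and per group), BT."""
    orders, excluded = pairs.derive_orders(choices)
    transitive = [o for o in orders if o.transitive]
    props, top = pairs.order_distribution(transitive)
    counts = pairs.pair_counts(choices, exclude=excluded)
    bt = pairs.bt_fit(counts, reference=reference)
    group_borda = {}
    for first in top.index:
        members = [o for o in transitive if o.ranking[0] == first]
        if members:
            group_borda[first] = pairs.borda_scores(members).to_dict()
    return {
        "version": __version__,
        "n_participants": int(choices["participant_id"].nunique()),
        "n_excluded_intransitive": len(excluded),
        "excluded": list(excluded),
        "order_proportions": props.to_dict(),
        "top_choice_shares": top.to_dict(),
        "borda_overall": pairs.borda_scores(transitive).to_dict(),
        "borda_by_top_choice_group": group_borda,
        "pair_counts": counts.to_dict(),
        "bt_abilities": bt.abilities.to_dict(),
        "bt_reference": bt.reference,
        "bt_converged": bt.converged,
    }


def run_exp2b(
    records: pd.DataFrame,
    groups: pd.Series,
    lexicon: dict[str, str] | None = None,
    b: int = 10_000,
    seed: int = 0,
) -> dict[str, Any]:
    """Association chain: canonicalize, score, group tests."""
    canon = creativity.canonicalize_records(records, lexicon=lexicon)
    freq = creativity.frequency_table(canon)
    scores = creativity.originality_scores(canon, freq)
    # silent participants keep zero fluency and originality
    scores = scores.reindex(groups.index).fillna(0.0)
    scores["fluency"] = scores["fluency"].astype(int)
    scores["group"] = groups

    def contrast(metric: str, g1: str, g2: str) -> dict[str, Any]:
        v1 = scores.loc[scores["group"] == g1, metric].to_numpy()
        v2 = scores.loc[scores["group"] == g2, metric].to_numpy()
        perm = creativity.permutation_test(
            list(v1) + list(v2),
            [g1] * len(v1) + [g2] * len(v2),
            b=b,
            seed=seed,
            alternative="greater",
        )
        out = {
            "means": {g1: float(v1.mean()), g2: float(v2.mean())},
            "observed_diff": perm.observed,
            "perm_p": perm.p_value,
            "perm_n": perm.n_permutations,
            "perm_exhaustive": perm.exhaustive,
        }
        if len(v1) >= 2 and len(v2) >= 2:
            t, df, p, d = creativity.welch_t(v1, v2)
            out["welch"] = {"t": t, "df": df, "p_one_sided": p, "cohen_d": d}
        return out

    mean_fluency = float(scores["fluency"].mean())
    return {
        "version": __version__,
        "config": {"permutations": b, "seed": seed},
        "n_participants": len(scores),
        "n_associations": int(scores["fluency"].sum()),
        "mean_fluency": mean_fluency,
        "mean_fluency_by_group": scores.groupby("group")["fluency"].mean().to_dict(),
        "mean_originality_by_group": scores.groupby("group")["originality"]
        .mean()
        .to_dict(),
        "fluency_G_vs_A": contrast("fluency", "G", "A"),
        "fluency_L_vs_A": contrast("fluency", "L", "A"),
        "originality_G_vs_A": contrast("originality", "G", "A"),
        "fluency_originality_r": creativity.fluency_originality_correlation(scores),
        "top_tokens_by_prompt": {
            prompt: freq[prompt].sort_values(ascending=False).head(3).to_dict()
            for prompt in freq.index.get_level_values(0).unique()
        },
    }


def simulate_all(cfg: SynthConfig) -> dict[str, Any]:
    """Generate all three synthetic datasets from one config."""
    ft = stimulus_feature_table()
    matrix, labels, clip_rate = gen_ratings(cfg, ft)
    choices = gen_choices(cfg)
    records, assoc_labels = gen_associations(cfg)
    return {
        "features": ft,
        "ratings": matrix,
        "rating_labels": labels,
        "clip_rate": clip_rate,
        "choices": choices,
        "associations": records,
        "association_labels": assoc_labels,
    }
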