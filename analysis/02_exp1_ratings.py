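"""Rating experiment on synthetic raters: consistency, groups, regression.

Simulates 118 raters (33/40/45 in three preference groups whose mean profiles
follow the published per-group regression coefficients), then runs the full
chain: ICC(C,k), k-means group discovery, per-group feature correlations and
OLS, and the random-intercept mixed model with its variance decomposition.
Writes results/exp1_report.json.
"""

import sys
from pathlib import Path

import pandas as pd

from spiralpref import io
from spiralpref.pipelines import run_exp1, stimulus_feature_table
from spiralpref.synthetic import SynthConfig, gen_ratings

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    features = stimulus_feature_table()
    cfg = SynthConfig(master_seed=seed)
    matrix, true_labels, clip_rate = gen_ratings(cfg, features)
    io.write_ratings(matrix, OUT / "ratings.csv")
    report = run_exp1(matrix, feature_tbl=features, seed=seed)
    labels = report.pop("_labels")
    io.write_report(report, OUT / "exp1_report.json")

    agree = (labels.reindex(true_labels.index) == true_labels).mean()
    print(f"simulated {len(matrix)} raters (clip rate {clip_rate:.1%}, seed {seed})")
    print(f"ICC(C,{len(matrix)}) = {report['icc_consistency_avg']:.3f}")
    print(
        f"k-means (k=3) explains {report['explained_variance']:.0%} of variance; "
        f"group sizes {report['group_sizes']} (label agreement {agree:.0%})"
    )
    ols = pd.DataFrame(report["ols"]["params"]).round(2)
    print("\nper-group OLS coefficients (width, path length, DCM):")
    print(ols.to_string())
    lmm = report["lmm"]
    print(
        f"\nmixed model: sigma2 = {lmm['sigma2']:.2f}, tau00 = {lmm['tau00']:.2f}, "
        f"ICC = {lmm['icc']:.2f}, marginal R2 = {lmm['marginal_r2']:.3f}, "
        f"conditional R2 = {lmm['conditional_r2']:.3f}"
    )
    print(
        "\nGroup A's ratings fall with DCM (they like balanced spirals) while "
        "group G's rise with it; path length splits the same way with "
        "opposite signs."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
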