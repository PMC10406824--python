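"""Environmental differentiation: null HD relationships and the factor PCA.

Finding: habitat heterogeneity is unrelated to habitat area (R^2 = .04,
p = .49) and population size is unrelated to HD (R^2 = .09, p = .32),
matching the study.  The correlation PCA of the 22 numeric environmental
variables (12 populations, alpine site excluded, ordinal slope exposure
excluded) puts ~50% of variance on the first two components, and its second
axis carries the (negative) rank association with population size.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tmontanum import load_fixtures, ordination
from tmontanum import regression as reg
from tmontanum.pipeline import ENV_PCA_VARS

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fx = load_fixtures()
    t1, t2 = fx.table1, fx.table2
    data = pd.DataFrame({
        "lnN": np.log(t1["population_size"]),
        "ln_area": np.log(t1["habitat_area_m2"]),
        "HD": t2["HD"],
    })
    for resp, pred in (("HD", "ln_area"), ("lnN", "HD")):
        fit = reg.fit_ols(data[resp], data[[pred]])
        print(f"{resp} ~ {pred}: R2 = {fit.r2:.2f}, p = {fit.pvalues[pred]:.2f}")

    keep = [p for p in t2.index if p != "KW"]
    env = t2.loc[keep, [v for v in ENV_PCA_VARS if v in t2.columns]]
    res = ordination.pca(env)
    frac = res.variance_fraction
    print(f"\nenvironmental PCA: PC1+PC2 explain {100 * frac[:2].sum():.1f}% "
          "of variation")
    corr = ordination.axis_correlations(
        res, pd.DataFrame({"population_size": t1.loc[keep, "population_size"]}),
        method="spearman", n_perm=1000, seed=1, n_components=3)
    OUT.mkdir(exist_ok=True)
    res.scores.round(4).to_csv(OUT / "02_env_pca_scores.tsv", sep="\t")
    corr.round(4).to_csv(OUT / "02_env_pca_size_correlations.tsv", sep="\t",
                         index=False)
    print(corr.to_string(index=False))


if __name__ == "__main__":
    main()
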