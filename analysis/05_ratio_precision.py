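#!/usr/bin/env python
"""Precision of the Salmo / (Salmo + Coregonus) relative-abundance estimate.

Computes per-sample fractions per locus (grab replicates pooled, totals < 20
omitted), the site means and their difference (the settling differential),
the variance F test between methods on site-centered values, the two-way
ANOVA on site and method, time correlations, and inter-locus agreement.
Writes results under results/ratio/.
"""

import json
import sys
from pathlib import Path

from scipy import stats

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, load_study_matrix

from ednabench.ratios import (
    center_by_site,
    compute_fractions,
    time_correlations,
    two_way_anova,
    variance_f_test,
)


def main() -> None:
    out = RESULTS / "ratio"
    out.mkdir(parents=True, exist_ok=True)
    matrix = load_study_matrix()

    fractions = compute_fractions(matrix, "Salmo", "Coregonus", min_total=20)
    fractions.to_csv(out / "fractions.tsv", sep="\t", index=False)
    retained = fractions[fractions["retained"]]
    site_means = retained.groupby("site")["fraction"].agg(["mean", "sem", "size"])
    print("site means of the Salmo fraction:")
    print(site_means.to_string())

    centered = center_by_site(fractions)
    comp = centered.loc[centered["method"] == "composite", "centered"]
    grab = centered.loc[centered["method"] == "grab", "centered"]
    ftest = variance_f_test(comp, grab)
    print(f"\nvariance F (composite/grab) = {ftest['F']:.3f}, "
          f"df = ({ftest['df_a']}, {ftest['df_b']}), p = {ftest['p']:.3f}")

    anova = two_way_anova(retained["fraction"], retained["site"],
                          retained["method"])
    anova.to_csv(out / "anova.tsv", sep="\t")
    print("\ntwo-way ANOVA (Type II):")
    print(anova.to_string())

    tc = time_correlations(fractions)
    wide = retained.pivot_table(index="sample_id", columns="locus",
                                values="fraction").dropna()
    r, p = stats.pearsonr(wide.iloc[:, 0], wide.iloc[:, 1])
    print(f"\ntime correlations per site:\n{tc.to_string()}")
    print(f"\ninter-locus agreement: Pearson r = {r:.3f} (n = {len(wide)})")

    (out / "tests.json").write_text(json.dumps({
        "site_means": site_means["mean"].to_dict(),
        "variance_f": ftest,
        "anova_site_p": float(anova.loc["site", "p"]),
        "anova_method_p": float(anova.loc["method", "p"]),
        "interlocus_r": {"r": float(r), "p": float(p), "n": int(len(wide))},
    }, indent=2))


if __name__ == "__main__":
    main()
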