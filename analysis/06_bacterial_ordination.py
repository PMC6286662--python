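#!/usr/bin/env python
"""Ordination of bacterial profiles and the cold-storage bloom signal.

Log-ratio transforms the top-50 bacterial family proportions, runs the
correlation PCA, computes the Spearman correlation matrix of family
abundances, and quantifies the bloom family's association with sample
initiation time (earliest bottles store longest and bloom hardest).  Writes
scores, loadings and statistics under results/ordination/.
"""

import json
import sys
from pathlib import Path

from scipy import stats

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, load_study_matrix

from ednabench.filtering import to_cpm, top_n_by_abundance
from ednabench.ordination import pca_top_taxa, spearman_matrix


def main() -> None:
    out = RESULTS / "ordination"
    out.mkdir(parents=True, exist_ok=True)
    matrix = load_study_matrix()
    bact = matrix.select_locus("16S-bact")

    pca = pca_top_taxa(bact, top_n_taxa=50, transform="logratio")
    pca.scores.iloc[:, :5].to_csv(out / "pca_scores.tsv", sep="\t")
    pca.loadings.iloc[:, :5].to_csv(out / "pca_loadings.tsv", sep="\t")
    top2 = pca.variance_explained[:2].sum()
    print(f"correlation PCA of top 50 families: top two axes explain "
          f"{top2:.1f}% of variance "
          f"({pca.variance_explained[0]:.1f}% + {pca.variance_explained[1]:.1f}%)")

    cpm = to_cpm(top_n_by_abundance(bact, 30))
    rho_matrix = spearman_matrix(cpm)
    rho_matrix.to_csv(out / "spearman_top30.tsv", sep="\t")

    share = to_cpm(bact)["Flavobacteriaceae"]
    times = bact.meta_for(share.index)["initiation_time_min"].astype(float)
    rho, p = stats.spearmanr(share, times)
    print(f"Flavobacteriaceae share vs initiation time: Spearman rho = "
          f"{rho:.3f} (p = {p:.2e}, n = {len(share)}) - storage bloom "
          f"displaces other reads in early-initiated bottles")

    (out / "stats.json").write_text(json.dumps({
        "pca_top2_variance_pct": float(top2),
        "bloom_time_spearman": {"rho": float(rho), "p": float(p),
                                "n": int(len(share))},
    }, indent=2))


if __name__ == "__main__":
    main()
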