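#!/usr/bin/env python
"""Apply the count-table retention rules to the simulated deployment.

12S taxa are censored for sequencer cross-talk (run total >= 10 and at least
one non-singleton sample), then all loci pass the run-wide minimum-count
filter (>= 10 reads).  Writes the filtered table and the censor/removal
reports under results/filtering/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, load_study_matrix

from ednabench.filtering import censor_crosstalk, filter_min_run_count
from ednabench.io import write_count_table


def main() -> None:
    out = RESULTS / "filtering"
    out.mkdir(parents=True, exist_ok=True)
    matrix = load_study_matrix()

    twelves = matrix.select_locus("12S")
    censored, censor_report = censor_crosstalk(twelves, 10, return_report=True)
    keep = [t for t in matrix.taxa
            if matrix.taxon_meta.at[t, "locus"] != "12S" or t in censored.taxa]
    filtered, removal = filter_min_run_count(matrix.select_taxa(keep), 10,
                                             return_report=True)
    censor_report.to_csv(out / "censored_12s_taxa.tsv", sep="\t")
    removal.to_csv(out / "below_min_count.tsv", sep="\t")
    write_count_table(filtered, out / "counts_filtered.tsv",
                      out / "sample_meta.tsv", out / "taxon_meta.tsv")
    print(f"{len(matrix.taxa)} taxa in; {len(censor_report)} censored as 12S "
          f"cross-talk; {len(removal)} below the run-wide minimum; "
          f"{len(filtered.taxa)} retained")


if __name__ == "__main__":
    main()
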