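"""Shared plumbing for the numbered analysis drivers: locate the repository,
load the simulated study data (simulating it on first use), and write tables
under results/."""

from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
RESULTS = REPO / "results"
DATA = RESULTS / "data"

SEED = 11  # one deployment, analyzed by every driver


def load_study_matrix(paper_variant: bool = True):
    """Load the simulated deployment written by 01_simulate_study.py, or
    simulate it now if the tables are absent."""
    from ednabench.io import read_count_table, write_count_table
    from ednabench.simulate import default_study_scenario, simulate_counts

    tag = "paper" if paper_variant else "balanced"
    counts = DATA / f"counts_{tag}.tsv"
    if not counts.exists():
        DATA.mkdir(parents=True, exist_ok=True)
        scenario = default_study_scenario(seed=SEED, paper_variant=paper_variant)
        matrix, truth = simulate_counts(scenario)
        write_count_table(matrix, counts, DATA / f"sample_meta_{tag}.tsv",
                          DATA / f"taxon_meta_{tag}.tsv")
        truth["particles"].to_csv(DATA / f"truth_particles_{tag}.tsv", sep="\t")
        return matrix
    return read_count_table(counts, DATA / f"sample_meta_{tag}.tsv",
                            DATA / f"taxon_meta_{tag}.tsv")
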