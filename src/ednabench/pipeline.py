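"""End-to-end study analysis: filtering -> metrics -> ratios -> ordination.

`run_study_analysis` takes a count matrix (real or simulated) and executes the
full comparison of composite vs grab sampling, returning a results bundle of
DataFrames and test statistics.  `run_pipeline` wraps it with file I/O and a
machine-readable run manifest so an identical run can be re-executed.
"""

from __future__ import annotations

import json
import logging
import platform
from contextlib import contextmanager
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .filtering import (
    CountMatrix,
    censor_crosstalk,
    filter_min_run_count,
    to_cpm,
    top_n_by_abundance,
)
from .metrics import (
    detection_rates,
    dispersion_to_centroid,
    morisita_matrix,
    pool_grab_replicates,
    rarefy_richness,
    time_match_pairs,
)
from .ordination import pca_top_taxa
from .ratios import (
    center_by_site,
    compute_fractions,
    time_correlations,
    two_way_anova,
    variance_f_test,
)

logger = logging.getLogger(__name__)

EUK_LOCI = ("12S", "COI", "16S-euk")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


def _euk_matrix(matrix: CountMatrix) -> CountMatrix:
    tm = matrix.taxon_meta
    labels = [t for t in matrix.taxa if tm.at[t, "locus"] in EUK_LOCI]
    return matrix.select_taxa(labels)


def sampler_total_richness(
    matrix: CountMatrix, rarefy_to: int | None = None
) -> pd.DataFrame:
    """Pooled per-sampler taxon totals rarefied to a common depth.

    Samples of the larger method at each site are parity-trimmed so both
    methods pool the same number of bottles; each sampler's summed count
    vector is rarefied to the smallest sampler total (or ``rarefy_to``).
    """
    from .metrics import _parity_trim

    meta = matrix.meta_for()
    pooled: dict[str, np.ndarray] = {}
    info: dict[str, dict] = {}
    for site, site_meta in meta.groupby("site"):
        sets = {}
        for method, mm in site_meta.groupby("method"):
            order = mm.sort_values(["initiation_time_min", "replicate"],
                                   na_position="first")
            sets[method] = list(order.index)
        small = min(len(v) for v in sets.values())
        for method, names in sets.items():
            names = _parity_trim(names, small) if len(names) > small else names
            sampler = site_meta.loc[names[0], "sampler"]
            pooled[sampler] = matrix.counts.loc[names].sum(axis=0).to_numpy()
            info[sampler] = {"site": site, "method": method, "n_samples": len(names)}
    depth = rarefy_to if rarefy_to is not None else min(int(v.sum()) for v in pooled.values())
    rows = []
    for sampler, vec in pooled.items():
        res = rarefy_richness(vec, depth)
        rows.append(
            {"sampler": sampler, **info[sampler], "total_counts": int(vec.sum()),
             "observed_richness": int((vec > 0).sum()),
             "rarefied_to": depth, "expected_richness": res.expected_richness,
             "standard_error": res.standard_error}
        )
    return pd.DataFrame(rows).set_index("sampler").sort_index()


def run_study_analysis(
    matrix: CountMatrix,
    seed: int = 0,
    n_permutations: int = 9999,
    top_n_bacteria: int = 150,
    pca_top_n: int = 50,
    min_run_count: int = 10,
    crosstalk_min_total: int = 10,
    ratio_min_total: int = 20,
    anova_ss_type: int = 2,
    pca_transform: str = "logratio",
) -> dict:
    """Execute the composite-vs-grab comparison on one count matrix.

    Steps: 12S cross-talk censoring and run-wide minimum-count filtering;
    eukaryotic Morisita dispersion on time-matched samples; bacterial
    dispersion on the top families; parity-trimmed detection rates; pooled
    per-sampler rarefaction richness; the Salmo/(Salmo+Coregonus) precision
    analysis (variance F test, two-way ANOVA, time correlations, inter-locus
    agreement); bacterial log-ratio PCA; and the bloom-taxon storage-time
    correlation.  Returns a dict of DataFrames and statistics.
    """
    results: dict = {}

    # ---- filtering ---------------------------------------------------------
    with _stage("filtering"):
        tm = matrix.taxon_meta
        twelves = matrix.select_locus("12S")
        censored, censor_report = censor_crosstalk(
            twelves, min_total=crosstalk_min_total, return_report=True
        )
        keep = [t for t in matrix.taxa
                if tm.at[t, "locus"] != "12S" or t in censored.taxa]
        filtered = filter_min_run_count(matrix.select_taxa(keep), min_run_count)
        results["censored_12s_taxa"] = censor_report
        results["n_taxa_after_filtering"] = len(filtered.taxa)

    # ---- eukaryotic dispersion on time-matched samples ---------------------
    with _stage("eukaryotic dispersion"):
        euk = _euk_matrix(filtered)
        pooled = pool_grab_replicates(euk)
        pairs, unpaired = time_match_pairs(pooled)
        matched = [c for c, _ in pairs] + [g for _, g in pairs]
        results["time_matched_pairs"] = pairs
        euk_matched = pooled.select_samples(matched)
        groups = euk_matched.meta_for()["method"]
        d_euk = morisita_matrix(euk_matched.counts, groups)
        disp_euk = dispersion_to_centroid(
            d_euk, groups, n_permutations=n_permutations, seed=seed
        )
        results["euk_dispersion"] = disp_euk

    # ---- bacterial dispersion ---------------------------------------------
    with _stage("bacterial dispersion"):
        bact = filtered.select_locus("16S-bact")
        bact_top = top_n_by_abundance(bact, top_n_bacteria)
        bact_pooled = pool_grab_replicates(bact_top)
        bact_matched = bact_pooled.select_samples(
            [s for s in matched if s in bact_pooled.counts.index]
        )
        bgroups = bact_matched.meta_for()["method"]
        d_bact = morisita_matrix(bact_matched.counts, bgroups)
        results["bact_dispersion"] = dispersion_to_centroid(
            d_bact, bgroups, n_permutations=n_permutations, seed=seed + 1
        )

    # ---- detection rates and richness -------------------------------------
    with _stage("detection and richness"):
        results["detection_rates"] = detection_rates(euk, parity_trim=True)
        results["sampler_richness"] = sampler_total_richness(euk)

    # ---- ratio precision analysis ------------------------------------------
    with _stage("ratio analysis"):
        fractions = compute_fractions(
            filtered, "Salmo", "Coregonus", min_total=ratio_min_total
        )
        results["fractions"] = fractions
        retained = fractions[fractions["retained"]]
        results["site_mean_fraction"] = retained.groupby("site")["fraction"].mean()
        centered = center_by_site(fractions)
        comp = centered.loc[centered["method"] == "composite", "centered"]
        grab = centered.loc[centered["method"] == "grab", "centered"]
        results["variance_f"] = variance_f_test(comp, grab)
        results["anova"] = two_way_anova(
            retained["fraction"], retained["site"], retained["method"],
            ss_type=anova_ss_type,
        )
        results["time_correlations"] = time_correlations(fractions)
        wide = retained.pivot_table(index="sample_id", columns="locus",
                                    values="fraction")
        if wide.shape[1] == 2:
            both = wide.dropna()
            if len(both) >= 3:
                from scipy import stats as _st

                r, p = _st.pearsonr(both.iloc[:, 0], both.iloc[:, 1])
                results["interlocus_r"] = {"r": float(r), "p": float(p), "n": len(both)}

    # ---- bacterial ordination and bloom signal -----------------------------
    with _stage("ordination"):
        pca = pca_top_taxa(bact, top_n_taxa=pca_top_n, transform=pca_transform)
        results["bact_pca"] = pca
        results["pca_top2_variance_pct"] = float(pca.variance_explained[:2].sum())

        bloom_labels = (
            [t for t in bact.taxa if tm.at[t, "is_bloom"]]
            if "is_bloom" in tm.columns else []
        )
        if bloom_labels:
            cpm = to_cpm(bact)
            share = cpm[bloom_labels[0]]
            times = bact.meta_for(share.index)["initiation_time_min"].astype(float)
            from scipy import stats as _st

            rho, p = _st.spearmanr(share, times)
            results["bloom_time_spearman"] = {
                "taxon": bloom_labels[0], "rho": float(rho), "p": float(p),
                "n": len(share),
            }

    # ---- per-locus sequencing effort ---------------------------------------
    with _stage("locus counts"):
        locus_counts = {}
        for locus in ("16S-bact", "12S", "COI", "16S-euk"):
            cols = [t for t in matrix.taxa if tm.at[t, "locus"] == locus]
            if cols:
                per_sample = matrix.counts[cols].sum(axis=1)
                locus_counts[locus] = {
                    "mean": float(per_sample.mean()), "sd": float(per_sample.std(ddof=1))
                }
        results["per_sample_locus_counts"] = locus_counts
    return results


def run_pipeline(config, out_dir) -> dict:
    """Run the study analysis per a :class:`PipelineConfig`, writing outputs
    and a manifest sufficient to re-execute the identical run."""
    from .config import PipelineConfig
    from .io import read_count_table, write_count_table
    from .simulate import default_study_scenario, simulate_counts

    if not isinstance(config, PipelineConfig):
        raise TypeError("config must be a PipelineConfig")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.counts_path:
        matrix = read_count_table(
            config.counts_path, config.sample_meta_path, config.taxon_meta_path
        )
    else:
        scenario = default_study_scenario(
            seed=config.seed, paper_variant=config.paper_variant
        )
        matrix, _truth = simulate_counts(scenario)
        write_count_table(
            matrix,
            out_dir / "simulated_counts.tsv",
            out_dir / "simulated_sample_meta.tsv",
            out_dir / "simulated_taxon_meta.tsv",
        )

    results = run_study_analysis(
        matrix,
        seed=config.seed,
        n_permutations=config.n_permutations,
        top_n_bacteria=config.top_n_bacteria,
        pca_top_n=config.pca_top_n,
        min_run_count=config.min_run_count,
        crosstalk_min_total=config.crosstalk_min_total,
        ratio_min_total=config.ratio_min_total,
        anova_ss_type=config.anova_ss_type,
        pca_transform=config.pca_transform,
    )

    results["fractions"].to_csv(out_dir / "fractions.tsv", sep="\t", index=False)
    results["detection_rates"].to_csv(out_dir / "detection_rates.tsv", sep="\t",
                                      index=False)
    results["sampler_richness"].to_csv(out_dir / "sampler_richness.tsv", sep="\t")
    results["anova"].to_csv(out_dir / "anova.tsv", sep="\t")
    disp = results["euk_dispersion"]
    disp.distances.to_frame().assign(group=disp.groups).to_csv(
        out_dir / "euk_dispersion_distances.tsv", sep="\t"
    )

    stats_json = {
        "variance_f": results["variance_f"],
        "euk_dispersion": {
            "t": disp.t_statistic, "permutation_p": disp.permutation_p,
            "mannwhitney_p": disp.mannwhitney_p,
            "group_means": disp.group_means.to_dict(),
            "n_permutations": disp.n_permutations, "seed": disp.seed,
        },
        "bact_dispersion": {
            "t": results["bact_dispersion"].t_statistic,
            "permutation_p": results["bact_dispersion"].permutation_p,
        },
        "site_mean_fraction": results["site_mean_fraction"].to_dict(),
        "interlocus_r": results.get("interlocus_r"),
        "pca_top2_variance_pct": results["pca_top2_variance_pct"],
        "bloom_time_spearman": results.get("bloom_time_spearman"),
        "per_sample_locus_counts": results["per_sample_locus_counts"],
    }
    (out_dir / "statistics.json").write_text(json.dumps(stats_json, indent=2))

    manifest = {
        "ednabench_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
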