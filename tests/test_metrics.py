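"""Morisita, rarefaction, pooling/pairing, detection rates, dispersion."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from ednabench.metrics import (
    DissimilarityMatrix,
    _parity_trim,
    accumulation_curve,
    detection_rates,
    dispersion_to_centroid,
    morisita_dissimilarity,
    morisita_matrix,
    pool_grab_replicates,
    rarefy_richness,
    time_match_pairs,
)


class TestMorisita:
    def test_disjoint_supports_give_exactly_one(self):
        assert morisita_dissimilarity([10, 0], [0, 10]) == pytest.approx(1.0)

    def test_identical_doubletons_give_zero(self):
        # lambda = 1 for (2,0); C = 2*4 / (2*2*2) = 1
        assert morisita_dissimilarity([2, 0], [2, 0]) == pytest.approx(0.0)

    def test_small_counts_can_exceed_unity_overlap(self):
        # (5,5) vs (5,5): lambda = 4/9, C = 1.125 -> dissimilarity -0.125
        assert morisita_dissimilarity([5, 5], [5, 5]) == pytest.approx(-0.125)

    def test_symmetry(self):
        x, y = [3, 7, 1], [4, 0, 9]
        assert morisita_dissimilarity(x, y) == pytest.approx(
            morisita_dissimilarity(y, x))

    @pytest.mark.parametrize("bad_x,bad_y", [([0, 1], [5, 5]), ([1.5, 2], [3, 3])])
    def test_input_validation(self, bad_x, bad_y):
        with pytest.raises(ValueError):
            morisita_dissimilarity(bad_x, bad_y)

    def test_sample_size_robustness(self):
        """Dissimilarity of x vs k*x tends to 0 as both totals grow: the
        stated reason for choosing this index when effort differs by method."""
        base = np.array([6, 3, 1])
        # proportional composition at 10x depth difference, increasing totals
        ds = [abs(morisita_dissimilarity(m * base, 10 * m * base))
              for m in (1, 10, 100, 1000)]
        assert all(b <= a + 1e-12 for a, b in zip(ds, ds[1:]))
        assert ds[-1] < 1e-3

    def test_matches_vegan_oracle(self):
        """Cross-check the whole pairwise matrix against vegan's vegdist."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.integers(0, 30, size=(5, 8)),
                              index=[f"s{i}" for i in range(5)])
        counts.iloc[:, 0] += 2  # keep totals comfortably >= 2
        ours = morisita_matrix(counts).values
        rows = ";".join(",".join(map(str, r)) for r in counts.to_numpy())
        rscript = (
            "suppressMessages(library(vegan));"
            f"m <- do.call(rbind, lapply(strsplit(strsplit('{rows}', ';')[[1]], ','), as.numeric));"
            "cat(as.vector(vegdist(m, method='morisita')))"
        )
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        theirs = np.array([float(v) for v in out.stdout.split()])
        iu = np.triu_indices(5, k=1)
        # vegdist returns the lower triangle column-wise == our upper by symmetry
        assert np.allclose(np.sort(ours[iu]), np.sort(theirs), atol=1e-10)


def _enumerate_rarefaction(counts, n):
    """Exhaustive oracle: mean and variance of richness over all C(N, n)
    subsets of the individual reads."""
    reads = [i for i, c in enumerate(counts) for _ in range(c)]
    rich = [len(set(sub)) for sub in itertools.combinations(reads, n)]
    mean = sum(rich) / len(rich)
    var = sum((r - mean) ** 2 for r in rich) / len(rich)
    return mean, var


class TestRarefaction:
    def test_two_one_at_depth_two(self):
        # all 3 pairs of reads: richness {1, 2, 2} -> mean 5/3
        res = rarefy_richness([2, 1], 2)
        assert res.expected_richness == pytest.approx(5 / 3)

    def test_full_depth_recovers_observed_with_zero_se(self):
        res = rarefy_richness([4, 3, 2], 9)
        assert res.expected_richness == pytest.approx(3.0)
        assert res.standard_error == pytest.approx(0.0, abs=1e-9)

    def test_depth_one_gives_one(self):
        assert rarefy_richness([5, 2, 9], 1).expected_richness == pytest.approx(1.0)

    @pytest.mark.parametrize("counts", [(2, 1), (3, 2, 1), (5, 4, 3), (1, 1, 1, 1),
                                        (7, 2, 2, 1), (6, 6)])
    def test_matches_exhaustive_enumeration(self, counts):
        """Hypergeometric formula == brute-force subset enumeration, N <= 12,
        for both the mean and the variance."""
        total = sum(counts)
        for n in range(1, total + 1):
            mean, var = _enumerate_rarefaction(counts, n)
            res = rarefy_richness(list(counts), n)
            assert res.expected_richness == pytest.approx(mean, abs=1e-9)
            assert res.standard_error == pytest.approx(math.sqrt(var), abs=1e-6)

    def test_invalid_depths_error(self):
        with pytest.raises(ValueError):
            rarefy_richness([2, 1], 4)
        with pytest.raises(ValueError):
            rarefy_richness([2, 1], 0)

    def test_accumulation_curve_values_and_monotonicity(self):
        curve = accumulation_curve([2, 1], step=1)
        assert [r.expected_richness for r in curve] == pytest.approx([1, 5 / 3, 2])
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 50, size=8)
        rich = [r.expected_richness for r in accumulation_curve(counts, step=10)]
        assert all(b >= a - 1e-12 for a, b in zip(rich, rich[1:]))

    def test_single_taxon_curve_is_flat(self):
        curve = accumulation_curve([30], step=10)
        assert all(r.expected_richness == pytest.approx(1.0) for r in curve)


def _grab_meta(names, site="downstream"):
    rows = {}
    for name in names:
        sampler, rest = name.split("_", 1)
        t, rep = (rest.split("(") + [None])[:2]
        rows[name] = dict(sampler=sampler, site=site,
                          method="grab" if rep else "composite",
                          initiation_time_min=int(t),
                          replicate=int(rep.rstrip(")")) if rep else None)
    return pd.DataFrame.from_dict(rows, orient="index")


class TestPoolingAndPairing:
    def test_triplicate_sums_and_composite_passthrough(self):
        names = ["A_0", "B_0(1)", "B_0(2)", "B_0(3)"]
        counts = pd.DataFrame({"t": [9, 1, 2, 3]}, index=names)
        m = make_matrix({"t": counts["t"]})
        m.sample_meta = _grab_meta(names)
        out = pool_grab_replicates(m)
        assert out.counts.loc["B_0", "t"] == 6
        assert out.counts.loc["A_0", "t"] == 9

    def test_incomplete_replicate_set_pools_with_warning(self, caplog):
        names = ["B_0(1)", "B_0(2)", "B_0(3)", "B_720(1)", "B_720(2)"]
        m = make_matrix({"t": [1, 1, 1, 2, 2]})
        m.counts.index = pd.Index(names)
        m.sample_meta = _grab_meta(names)
        with caplog.at_level("WARNING"):
            out = pool_grab_replicates(m)
        assert out.counts.loc["B_720", "t"] == 4 and "unequal" in caplog.text

    def test_time_matching_and_unpaired(self):
        names = ["A_720", "A_900", "B_720(1)"]
        m = make_matrix({"t": [1, 1, 1]})
        m.counts.index = pd.Index(names)
        m.sample_meta = _grab_meta(names)
        pooled = pool_grab_replicates(m)
        pairs, unpaired = time_match_pairs(pooled, tolerance_min=1)
        assert pairs == [("A_720", "B_720")]
        assert unpaired == ["A_900"]

    def test_jittered_times_and_ambiguity(self):
        # grab initiated 1 min after the composite: paired at tolerance 1,
        # unpaired at tolerance 0
        names = ["A_720", "B_721(1)"]
        m = make_matrix({"t": [1, 1]})
        m.counts.index = pd.Index(names)
        m.sample_meta = _grab_meta(names)
        pooled = pool_grab_replicates(m)
        assert len(time_match_pairs(pooled, 1)[0]) == 1
        assert len(time_match_pairs(pooled, 0)[0]) == 0
        # two grab events inside the tolerance is ambiguous
        names = ["A_720", "B_719(1)", "B_721(1)"]
        m = make_matrix({"t": [1, 1, 1]})
        m.counts.index = pd.Index(names)
        m.sample_meta = _grab_meta(names)
        with pytest.raises(ValueError, match="tolerance"):
            time_match_pairs(pool_grab_replicates(m), 5)


class TestDetectionRates:
    def _matrix(self, n_comp, n_grab_bottles, site="downstream"):
        names = [f"A_{i * 180}" for i in range(n_comp)]
        n_events = n_grab_bottles // 3
        names += [f"B_{i * 720}({r})" for i in range(n_events) for r in (1, 2, 3)]
        counts = pd.DataFrame({"tax": [1] * len(names)}, index=names)
        m = make_matrix({"tax": counts["tax"]})
        m.sample_meta = _grab_meta(names, site)
        return m, names

    def test_parity_trim_22_to_15_drops_3_and_4(self):
        names = [f"A_{i}" for i in range(22)]
        assert _parity_trim(names, 15) == names[3:18]

    def test_parity_trim_22_to_18_drops_2_and_2(self):
        names = [f"A_{i}" for i in range(22)]
        assert _parity_trim(names, 18) == names[2:20]

    def test_rates_use_trimmed_denominator(self):
        m, names = self._matrix(22, 15)
        # taxon detected only in the first 3 composites, which are trimmed away
        m.counts["tax"] = [1 if n in names[:3] else 0 for n in m.counts.index]
        rates = detection_rates(m, parity_trim=True)
        comp = rates[rates["method"] == "composite"].iloc[0]
        assert comp["n_samples"] == 15 and comp["rate"] == 0.0

    def test_simple_rate_arithmetic(self):
        m, names = self._matrix(5, 15)
        grab_names = [n for n in names if n.startswith("B")]
        m.counts["tax"] = [1 if n in grab_names[:3] else 0 for n in m.counts.index]
        rates = detection_rates(m, parity_trim=False)
        grab = rates[rates["method"] == "grab"].iloc[0]
        assert grab["rate"] == pytest.approx(3 / 15)

    def test_trim_below_target_errors(self):
        with pytest.raises(ValueError):
            _parity_trim(["a", "b"], 3)


class TestDispersion:
    def _euclidean_D(self, points, groups):
        n = len(points)
        d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(n)]
        return DissimilarityMatrix(labels, d), pd.Series(groups, index=labels)

    def test_euclidean_geometry_oracle(self):
        """Distances from a Euclidean dissimilarity equal plain Euclidean
        distances to the group centroid in the original coordinates."""
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        groups = ["a"] * 5 + ["b"] * 5
        D, g = self._euclidean_D(pts, groups)
        res = dispersion_to_centroid(D, g, n_permutations=99, seed=0)
        for label, grp in zip(D.labels, groups):
            members = pts[[i for i, x in enumerate(groups) if x == grp]]
            expect = np.linalg.norm(pts[D.labels.index(label)] - members.mean(0))
            assert res.distances[label] == pytest.approx(expect, abs=1e-8)

    def test_identical_group_members_have_zero_distance(self):
        pts = np.array([[1.0, 1.0]] * 3 + [[0.0, 0.0], [2.0, 0.0], [1.0, 3.0]])
        D, g = self._euclidean_D(pts, ["a"] * 3 + ["b"] * 3)
        res = dispersion_to_centroid(D, g, n_permutations=99, seed=0)
        assert np.allclose(res.distances[:3], 0.0, atol=1e-8)

    def test_group_relabeling_preserves_distance_multiset(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 3))
        D, g = self._euclidean_D(pts, ["a"] * 6 + ["b"] * 6)
        res1 = dispersion_to_centroid(D, g, n_permutations=49, seed=0)
        g2 = pd.Series(["b"] * 6 + ["a"] * 6, index=D.labels)
        res2 = dispersion_to_centroid(D, g2, n_permutations=49, seed=0)
        assert np.allclose(np.sort(res1.distances), np.sort(res2.distances))

    def test_singleton_group_rejected(self):
        pts = np.random.default_rng(0).normal(size=(5, 2))
        D, g = self._euclidean_D(pts, ["a"] * 4 + ["b"])
        with pytest.raises(ValueError, match="size 1"):
            dispersion_to_centroid(D, g, n_permutations=9)

    def test_nonsymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))

    def test_negative_eigenvalue_correction_on_morisita(self):
        """Morisita dissimilarities are non-Euclidean; distances must still be
        finite, non-negative reals."""
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(0, 50, size=(10, 6)) + 1)
        counts.index = [f"s{i}" for i in range(10)]
        D = morisita_matrix(counts)
        g = pd.Series(["a"] * 5 + ["b"] * 5, index=D.labels)
        res = dispersion_to_centroid(D, g, n_permutations=99, seed=1)
        assert np.isfinite(res.distances).all() and (res.distances >= 0).all()

    def test_permutation_p_calibration_under_null(self):
        """With both groups drawn from one distribution the permutation p is
        approximately uniform: the rejection rate at alpha=0.3 stays near 0.3."""
        rng = np.random.default_rng(123)
        hits = 0
        reps = 60
        for _ in range(reps):
            pts = rng.normal(size=(12, 2))
            D, g = self._euclidean_D(pts, ["a"] * 6 + ["b"] * 6)
            res = dispersion_to_centroid(D, g, n_permutations=199,
                                         seed=int(rng.integers(2**31)))
            hits += res.permutation_p <= 0.3
        rate = hits / reps
        assert 0.15 <= rate <= 0.45  # 0.3 within Monte-Carlo error
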