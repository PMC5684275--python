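import itertools

import numpy as np
import pandas as pd
import pytest

from zlink import homology, tables
from zlink.tables import Log2Profile


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "scaffold", "start", "end", "score"])


class TestBestHitPerGene:
    def test_keeps_max_score(self):
        hits = hits_frame([("g1", "s1", 0, 100, 80), ("g1", "s2", 0, 100, 95)])
        best = homology.best_hit_per_gene(hits)
        assert len(best) == 1 and best.iloc[0]["score"] == 95

    def test_single_hit_unchanged(self):
        hits = hits_frame([("g1", "s1", 0, 100, 80)])
        assert len(homology.best_hit_per_gene(hits)) == 1

    def test_tie_breaks_to_lexicographic_scaffold(self):
        hits = hits_frame([("g1", "s2", 0, 100, 90), ("g1", "s1", 0, 100, 90)])
        assert homology.best_hit_per_gene(hits).iloc[0]["scaffold"] == "s1"

    def test_min_score_filter(self):
        hits = hits_frame([("g1", "s1", 0, 100, 49), ("g2", "s1", 0, 100, 50)])
        best = homology.best_hit_per_gene(hits)
        assert list(best["gene"]) == ["g2"]


def oracle_resolve(hits, max_overlap=20):
    """Independent fixpoint characterisation on one scaffold: a hit survives
    iff no surviving strictly-better hit overlaps it by > max_overlap.
    Found by checking every subset (feasible for <= 6 hits)."""
    recs = list(hits.itertuples(index=True))

    def ov(a, b):
        return min(a.end, b.end) - max(a.start, b.start)

    def better(a, b):  # same priority order as the sweep: score desc, gene asc
        return (-a.score, a.gene) < (-b.score, b.gene)

    for keep in itertools.chain.from_iterable(
        itertools.combinations(recs, k) for k in range(len(recs), -1, -1)
    ):
        keep_set = set(r.Index for r in keep)
        ok = all(
            not (ov(a, b) > max_overlap)
            for a, b in itertools.combinations(keep, 2)
        ) and all(
            any(better(k, r) and ov(k, r) > max_overlap for k in keep)
            for r in recs if r.Index not in keep_set
        )
        if ok:
            return sorted(r.gene for r in keep)
    raise AssertionError("no fixpoint subset found")


class TestResolveOverlaps:
    def test_large_overlap_keeps_higher_score(self):
        hits = hits_frame([("g1", "s1", 0, 100, 90), ("g2", "s1", 50, 150, 70)])
        kept = homology.resolve_overlaps(hits)
        assert list(kept["gene"]) == ["g1"]

    def test_exact_20bp_overlap_keeps_both(self):
        hits = hits_frame([("g1", "s1", 0, 100, 90), ("g2", "s1", 80, 180, 70)])
        assert len(homology.resolve_overlaps(hits)) == 2

    def test_chain_matches_exhaustive_resolution(self):
        # a-b overlap 30, b-c overlap 30, a-c disjoint; scores 50/90/60
        hits = hits_frame([
            ("a", "s1", 0, 100, 50),
            ("b", "s1", 70, 170, 90),
            ("c", "s1", 140, 240, 60),
        ])
        kept = homology.resolve_overlaps(hits)
        assert sorted(kept["gene"]) == oracle_resolve(hits)
        assert list(kept["gene"]) == ["b"]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_small_cases_match_exhaustive(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        rows = []
        for i in range(n):
            start = int(rng.integers(0, 300))
            rows.append((f"g{i}", "s1", start, start + int(rng.integers(30, 150)),
                         int(rng.integers(50, 200))))
        hits = hits_frame(rows)
        kept = homology.resolve_overlaps(hits)
        assert sorted(kept["gene"]) == oracle_resolve(hits)


class TestAssignChromosome:
    GENE_MAP = pd.DataFrame({
        "gene": ["g1", "g2", "g3", "g4", "g5"],
        "chromosome": ["chr1", "chr1", "chr5", "chr5", "chr2"],
        "start": [0, 10_000, 0, 10_000, 0],
    })

    def test_majority_wins(self):
        hits = hits_frame([("g1", "s", 0, 100, 60), ("g2", "s", 200, 300, 60),
                           ("g3", "s", 400, 500, 200)])
        assert homology.assign_chromosome(hits, self.GENE_MAP)["s"] == "chr1"

    def test_count_tie_broken_by_score_sum(self):
        hits = hits_frame([("g1", "s", 0, 100, 100), ("g3", "s", 200, 300, 80)])
        assert homology.assign_chromosome(hits, self.GENE_MAP)["s"] == "chr1"

    def test_double_tie_unassigned(self):
        hits = hits_frame([("g1", "s", 0, 100, 90), ("g3", "s", 200, 300, 90)])
        assert pd.isna(homology.assign_chromosome(hits, self.GENE_MAP)["s"])

    def test_invariant_to_input_order(self, default_sim):
        hits = homology.resolve_overlaps(
            homology.best_hit_per_gene(default_sim["hits"]))
        a = homology.assign_chromosome(hits, default_sim["gene_map"])
        shuffled = hits.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = homology.assign_chromosome(shuffled, default_sim["gene_map"])
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_simulated_assignment_is_accurate(self, default_sim):
        """No cross-chromosome contamination among true hits -> every
        assignment matches the scaffold's true chromosome."""
        hits = homology.resolve_overlaps(
            homology.best_hit_per_gene(default_sim["hits"]))
        assignment = homology.assign_chromosome(hits, default_sim["gene_map"])
        truth = default_sim["truth"].scaffolds["chromosome"]
        assigned = assignment.dropna()
        assert (assigned == truth.reindex(assigned.index)).mean() == 1.0


def _profile_and_assignment(simdata, male_pct_cap=99.5):
    filtered = tables.prefilter_scaffolds(simdata["coverage"],
                                          male_pct_cap=male_pct_cap)
    profile = tables.log2_fm(filtered)
    assignment = simdata["truth"].scaffolds["chromosome"].reindex(
        profile.ratio.index)
    return profile, assignment


class TestChromosomeCoverage:
    def test_planted_neo_z_flagged_exactly(self, default_sim):
        profile, assignment = _profile_and_assignment(default_sim)
        report = homology.test_chromosome_coverage(profile, assignment, "chr1")
        assert report.neo_z == ["chr18"]
        autosomes = report.table[report.table["chromosome"] != "chr18"]
        assert (autosomes["p_z_lower"] < 0.05).all()

    def test_no_neo_z_no_flags(self, noisefree_sim):
        profile, assignment = _profile_and_assignment(noisefree_sim,
                                                      male_pct_cap=None)
        report = homology.test_chromosome_coverage(profile, assignment, "chr1")
        assert report.neo_z == []

    def test_small_groups_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(25)]
        profile = Log2Profile(pd.Series(
            np.concatenate([rng.normal(-1, 0.05, 12), rng.normal(0, 0.05, 13)]),
            index=ids))
        assignment = pd.Series(["chr1"] * 12 + ["chr2"] * 10 + ["chr3"] * 3,
                               index=ids)
        with pytest.warns(UserWarning, match="chr3"):
            report = homology.test_chromosome_coverage(profile, assignment, "chr1")
        assert list(report.table["chromosome"]) == ["chr2"]


class TestSlidingProfile:
    def _inputs(self, ratios):
        n = len(ratios)
        ids = [f"s{i}" for i in range(n)]
        profile = Log2Profile(pd.Series(ratios, index=ids, dtype=float))
        assignment = pd.Series("chr1", index=ids)
        hits = hits_frame([(f"g{i}", ids[i], 0, 100, 100) for i in range(n)])
        gene_map = pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)],
            "chromosome": "chr1",
            "start": np.arange(n) * 1000,
        })
        return profile, assignment, hits, gene_map

    def test_constant_series(self):
        out = homology.sliding_profile(*self._inputs([-0.5] * 15), "chr1")
        assert np.allclose(out["moving_average"].dropna(), -0.5)

    def test_first_window_mean(self):
        ratios = [-1.0] * 10 + [0.0] * 5
        out = homology.sliding_profile(*self._inputs(ratios), "chr1")
        assert out["moving_average"].iloc[9] == pytest.approx(-1.0)

    def test_matches_independent_rolling_mean(self):
        rng = np.random.default_rng(3)
        ratios = rng.normal(0, 0.5, 40)
        out = homology.sliding_profile(*self._inputs(ratios), "chr1")
        for i in range(9, 40):
            expected = np.mean(out["log2_fm"].to_numpy()[i - 9:i + 1])
            assert out["moving_average"].iloc[i] == pytest.approx(expected)

    def test_short_series_whole_average(self):
        with pytest.warns(UserWarning, match="whole-set"):
            out = homology.sliding_profile(*self._inputs([0.0, -1.0, -0.5]), "chr1")
        assert np.allclose(out["moving_average"], -0.5)
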