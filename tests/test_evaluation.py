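"""Study runner and non-parametric statistics against enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from occluwear import evaluation as ev
from occluwear import synthetic_teeth as st


# ---------------------------------------------------------------------------
# enumeration oracles (independent of scipy's implementations)
# ---------------------------------------------------------------------------


def ranks(values):
    """Average ranks, ties shared."""
    values = np.asarray(values, float)
    order = np.argsort(values)
    r = np.empty(len(values))
    i = 0
    sorted_v = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        r[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return r


def friedman_statistic_oracle(table):
    """Friedman chi-square from first principles (tie-corrected)."""
    table = np.asarray(table, float)
    n, k = table.shape
    r = np.vstack([ranks(row) for row in table])
    ssbn = ((r.sum(axis=0) - n * (k + 1) / 2) ** 2).sum()
    chisq = 12.0 * ssbn / (n * k * (k + 1))
    ties = 0.0
    for row in table:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts ** 3 - counts).sum()
    correction = 1 - ties / (n * k * (k ** 2 - 1))
    return chisq / correction


def friedman_permutation_p(table):
    """Exact permutation p-value over all within-block orderings."""
    table = np.asarray(table, float)
    n, k = table.shape
    observed = friedman_statistic_oracle(table)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for assignment in itertools.product(perms, repeat=n):
        permuted = np.vstack([table[i, list(p)]
                              for i, p in enumerate(assignment)])
        stat = friedman_statistic_oracle(permuted)
        total += 1
        if stat >= observed - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_p(x, y):
    """Two-sided exact signed-rank p by enumerating all sign flips."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    r = ranks(np.abs(d))
    w_plus = r[d > 0].sum()
    n = len(d)
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append((r * np.asarray(signs)).sum())
    dist = np.asarray(dist)
    p = 2 * min((dist <= w_plus + 1e-12).mean(),
                (dist >= w_plus - 1e-12).mean())
    return min(p, 1.0)


def mannwhitney_u_oracle(x, y):
    """U statistic by direct pair counting."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return gt + 0.5 * eq


def kruskal_statistic_oracle(groups):
    """Kruskal-Wallis H from first principles (tie-corrected)."""
    pooled = np.concatenate(groups)
    r = ranks(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rg = r[start:start + len(g)]
        h += rg.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    return h / correction


# ---------------------------------------------------------------------------
# statistics vs oracles
# ---------------------------------------------------------------------------


class TestStatisticsAgainstOracles:
    def test_friedman_statistic_matches_enumeration(self):
        table = np.array([[1.0, 2.0, 3.5],
                          [2.0, 3.0, 4.0],
                          [1.5, 2.5, 5.0]])
        stat, p, degenerate = ev.friedman(*table.T)
        assert not degenerate
        assert stat == pytest.approx(friedman_statistic_oracle(table),
                                     abs=1e-12)
        # permutation p at this table size is exactly enumerable
        assert friedman_permutation_p(table) == pytest.approx(1 / 36,
                                                              abs=1e-12)

    def test_friedman_identical_columns_degenerate(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p, degenerate = ev.friedman(col, col, col)
        assert stat == 0.0
        assert p == 1.0
        assert degenerate

    def test_wilcoxon_doubling_pairs_exact(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        expected = wilcoxon_exact_p(x, y)
        assert expected == pytest.approx(2 / 32, abs=1e-12)
        assert sps.wilcoxon(x, y).pvalue == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_wilcoxon_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = x + rng.normal(size=8) * 0.8 + 0.3
        assert sps.wilcoxon(x, y, mode="exact").pvalue == pytest.approx(
            wilcoxon_exact_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_mannwhitney_statistic_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(size=7) + 0.4
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        assert res.statistic == pytest.approx(mannwhitney_u_oracle(x, y),
                                              abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_kruskal_statistic_matches_rank_formula(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(size=5), rng.normal(size=4) + 0.5,
                  rng.normal(size=6) - 0.2]
        res = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(
            kruskal_statistic_oracle(groups), abs=1e-10)


# ---------------------------------------------------------------------------
# bland-altman
# ---------------------------------------------------------------------------


class TestBlandAltman:
    def test_identical_sessions(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = ev.bland_altman(x, x)
        assert ba["bias"] == 0.0
        assert ba["max_abs_difference"] == 0.0
        assert ba["t_test_p"] == 1.0

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ba = ev.bland_altman(x, x + 0.5)
        assert ba["bias"] == pytest.approx(0.5)
        assert ba["loa_low"] == pytest.approx(0.5)
        assert ba["loa_high"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# study runner (desk scale)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def mini_rows():
    """Full six-technique battery on a 6-tooth replica at coarse meshes."""
    replica = st.study_replica(n_teeth=6, seed=5, mesh_resolution=3000)
    config = ev.StudyConfig(seed=5)
    return replica, ev.run_study(replica, config)


class TestRunStudy:
    def test_six_rows_per_tooth(self, mini_rows):
        replica, rows = mini_rows
        df = ev._results_frame(rows)
        counts = df.groupby("tooth_id")["technique"].count()
        assert (counts == 6).all()
        assert set(df["technique"]) == {"GS", "PC_A", "PC_C", "CC_B",
                                        "CC_C", "CC_D"}

    def test_gs_rows_have_zero_difference(self, mini_rows):
        _, rows = mini_rows
        df = ev._results_frame(rows)
        gs = df[df["technique"] == "GS"]
        assert (gs["difference_from_gs"] == 0.0).all()

    def test_user_mode_overlap_recorded_within_grid(self, mini_rows):
        _, rows = mini_rows
        df = ev._results_frame(rows)
        chosen = df[df["technique"].isin(["PC_C", "CC_C"])]["chosen_overlap"]
        ok = chosen.dropna()
        assert len(ok) > 0
        assert ((ok >= 0.15 - 1e-9) & (ok <= 0.80 + 1e-9)).all()

    def test_zero_wear_replica_measures_zero_everywhere(self):
        spec = st.premolar_spec(random_seed=11, mesh_resolution=2000)
        pair = st.make_crown_pair(spec, st.WearSpec(occlusal_depth=0.0,
                                                    random_seed=0),
                                  displacement_seed=2)
        tooth = st.StudyTooth(tooth_id=0, tooth_type="premolar",
                              crowding="aligned", nominal_depth=0.0,
                              pair=pair)
        rows = ev.run_study([tooth], ev.StudyConfig(
            seed=3, techniques=("CC_D",)))
        for r in rows:
            assert r.error is None
            assert r.measured_volume == pytest.approx(0.0, abs=1e-3)

    def test_battery_runs_on_study_frame(self, study_frame):
        report = ev.nonparametric_battery(study_frame)
        assert 0.0 <= report.friedman_p <= 1.0
        assert report.bonferroni_alpha == pytest.approx(0.05 / 3)
        for p in report.pairwise_wilcoxon.values():
            assert 0.0 <= p <= 1.0
        for t, d in report.per_technique.items():
            assert d["max_abs_diff"] >= d["median_abs_diff"] >= 0.0

    def test_reproducibility_deterministic_config_gives_zero(self):
        """With identical seeds both sessions are bit-identical, so every
        repeat difference is exactly zero (GS does not depend on the
        init draw at all)."""
        replica = st.study_replica(n_teeth=3, seed=9, mesh_resolution=2000)
        config = ev.StudyConfig(seed=9, reproducibility_subset=3)
        out = ev.reproducibility_run(replica, config)
        assert out["GS"]["max_abs_difference"] == 0.0
        assert out["GS"]["t_test_p"] == 1.0


def test_write_report_artifacts(tmp_path, study_rows):
    stats = ev.nonparametric_battery(study_rows)
    ev.write_report(study_rows, stats, None, tmp_path)
    assert (tmp_path / "results.csv").is_file()
    assert (tmp_path / "stats.json").is_file()
    assert (tmp_path / "technique_differences.png").is_file()
    assert (tmp_path / "summary.md").is_file()
    df = pd.read_csv(tmp_path / "results.csv")
    assert len(df) == 4 * 36  # GS + three techniques per tooth
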