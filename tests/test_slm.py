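"""Sex-cell hypermethylated locus calling: screen, merge, test, classify."""

import numpy as np
import pandas as pd
import pytest

from slmkit import io, simulate, slm
from slmkit.intervals import interval_recovery, merge_within_gap, overlap_pairs
from conftest import make_methylome

SEX = ["meiocyte", "microspore", "pollen"]


def _window_frame(rows):
    """rows: (chrom, start, {context: fraction})."""
    out = []
    for chrom, start, fracs in rows:
        for ctx, frac in fracs.items():
            out.append((chrom, start, start + 50, ctx, 1, 1, 1, frac, True))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "context",
                                      "n_sites", "meth", "total", "fraction",
                                      "covered"])


def _groups_for_diffs(diffs):
    """One window whose sex-minus-leaf differences equal `diffs` per context."""
    leaf_frac = {"CG": 0.25, "CHG": 0.25, "CHH": 0.25}  # binary-exact base
    sex_frac = {ctx: leaf_frac[ctx] + d for ctx, d in diffs.items()}
    gw = {"leaf": _window_frame([("chr1", 0, leaf_frac)])}
    for g in SEX:
        gw[g] = _window_frame([("chr1", 0, sex_frac)])
    return gw


class TestScreenWindows:
    @pytest.mark.parametrize("diffs,passes", [
        ({"CG": 0.10, "CHG": 0.08, "CHH": 0.05}, True),   # sum 0.23 > 0.2
        ({"CG": 0.25, "CHG": 0.10, "CHH": -0.01}, False),  # CHH diff <= 0
        ({"CG": 0.05, "CHG": 0.05, "CHH": 0.05}, False),   # sum 0.15
    ])
    def test_screening_rule(self, diffs, passes):
        got = slm.screen_windows(_groups_for_diffs(diffs), SEX, "leaf")
        assert (len(got) == 1) == passes

    def test_sum_rule_is_strict_at_the_boundary(self):
        # binary-exact fractions so the sum comparison is exact: 0.125 +
        # 0.03125 + 0.03125 == 0.1875 == sum_diff_min -> must fail
        diffs = {"CG": 0.125, "CHG": 0.03125, "CHH": 0.03125}
        params = slm.SlmParams(sum_diff_min=0.1875)
        got = slm.screen_windows(_groups_for_diffs(diffs), SEX, "leaf", params)
        assert len(got) == 0

    def test_uncovered_window_excluded(self):
        gw = _groups_for_diffs({"CG": 0.2, "CHG": 0.2, "CHH": 0.2})
        # leaf loses its CHH record for the window -> window not screenable
        leaf = gw["leaf"]
        gw["leaf"] = leaf[leaf["context"] != "CHH"]
        with pytest.warns(UserWarning):
            got = slm.screen_windows(gw, SEX, "leaf")
        assert len(got) == 0

    def test_sex_average_is_unweighted_mean(self):
        gw = _groups_for_diffs({"CG": 0.0, "CHG": 0.0, "CHH": 0.0})
        # one sex group high, two at leaf level: mean diff = 0.3/3 = 0.1 per ctx
        gw["meiocyte"] = _window_frame([("chr1", 0, {"CG": 0.55, "CHG": 0.55, "CHH": 0.55})])
        got = slm.screen_windows(gw, SEX, "leaf")
        assert len(got) == 1
        assert got.loc[0, "diff_CG"] == pytest.approx(0.1)

    def test_somatic_in_sex_rejected(self):
        with pytest.raises(ValueError):
            slm.screen_windows({}, ["leaf"], "leaf")


class TestMergeCandidates:
    def test_gap_within_100_merges(self):
        w = pd.DataFrame({"chrom": "chr1", "start": [100, 200], "end": [150, 250]})
        m = slm.merge_candidates(w)
        assert m[["start", "end"]].values.tolist() == [[100, 250]]

    def test_gap_beyond_100_and_short_dropped(self):
        w = pd.DataFrame({"chrom": "chr1", "start": [100, 260], "end": [150, 310]})
        m = slm.merge_candidates(w)
        assert len(m) == 0  # 110-bp gap; each 50-bp window < min_len

    def test_gap_exactly_100_inclusive(self):
        w = pd.DataFrame({"chrom": "chr1", "start": [100, 250], "end": [150, 300]})
        m = slm.merge_candidates(w)
        assert m[["start", "end"]].values.tolist() == [[100, 300]]

    def test_merge_matches_bruteforce_graph(self, rng):
        starts = np.sort(rng.choice(np.arange(0, 5000, 50), 40, replace=False))
        w = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 50})
        got = merge_within_gap(w, gap=100)
        # brute force: connected components of the "within gap" relation
        intervals = sorted(zip(starts, starts + 50))
        comps, cur = [], list(intervals[0])
        for s, e in intervals[1:]:
            if s - cur[1] <= 100:
                cur[1] = max(cur[1], e)
            else:
                comps.append(tuple(cur))
                cur = [s, e]
        comps.append(tuple(cur))
        assert [tuple(r) for r in got[["start", "end"]].values] == comps


class TestConsistencyAndClassify:
    def _pooled(self, fracs, total=100):
        return {g: pd.DataFrame({"meth": [int(f * total)], "total": [total]})
                for g, f in fracs.items()}

    def test_all_sex_above_somatic(self):
        pooled = self._pooled({"leaf": 0.2, "meiocyte": 0.4, "microspore": 0.35,
                               "pollen": 0.5})
        assert slm.consistency_filter(pooled, "leaf", SEX).all()

    def test_one_sex_below_somatic_fails(self):
        pooled = self._pooled({"leaf": 0.2, "meiocyte": 0.4, "microspore": 0.15,
                               "pollen": 0.5})
        assert not slm.consistency_filter(pooled, "leaf", SEX).any()

    def test_equality_fails_strictly(self):
        pooled = self._pooled({"leaf": 0.2, "meiocyte": 0.2, "microspore": 0.4,
                               "pollen": 0.5})
        assert not slm.consistency_filter(pooled, "leaf", SEX).any()

    def test_zero_coverage_sex_group_fails(self):
        pooled = self._pooled({"leaf": 0.2, "meiocyte": 0.4, "microspore": 0.3,
                               "pollen": 0.5})
        pooled["pollen"] = pd.DataFrame({"meth": [0], "total": [0]})
        assert not slm.consistency_filter(pooled, "leaf", SEX).any()

    @pytest.mark.parametrize("chh,chg,label", [
        (0.02, 0.05, slm.SLM_LIKE),
        (0.06, 0.02, slm.SLH_LIKE),   # CHH above its cap
        (0.02, 0.15, slm.SLH_LIKE),   # CHG above its cap
        (0.05, 0.02, slm.SLH_LIKE),   # boundary: "lower than" is strict
        (float("nan"), 0.02, slm.SLH_LIKE),
    ])
    def test_classification(self, chh, chg, label):
        assert slm.classify_locus(chh, chg) == label


def _engineered_groups(n_pos=334, lo=200, hi=400):
    """Dense sites every 3 bp, contexts cycling; sex hyper inside [lo, hi)."""
    contexts = ["CG", "CHG", "CHH"]
    rows_leaf, rows_sex = [], []
    for i in range(n_pos):
        pos = 3 * i + 1
        ctx = contexts[i % 3]
        inside = lo <= pos - 1 < hi
        rows_leaf.append(("chr1", pos, "+", ctx, 0, 20))
        rows_sex.append(("chr1", pos, "+", ctx, 16 if inside else 0, 20))
    groups = {"leaf": make_methylome(rows_leaf)}
    for g in SEX:
        groups[g] = make_methylome(rows_sex)
    return groups


class TestCallSlm:
    def test_single_planted_region_yields_one_locus(self):
        groups = _engineered_groups()
        loci, summary = slm.call_slm(groups, SEX, "leaf")
        assert summary["n_total"] == 1
        assert loci.loc[0, "start"] == 200 and loci.loc[0, "end"] == 400
        assert loci.loc[0, "label"] == slm.SLM_LIKE
        assert loci.loc[0, "n_windows"] == 4

    def test_planted_recovery_on_synthetic_study(self, small_cfg, small_sim,
                                                 small_groups):
        _, _, truth = small_sim
        loci, summary = slm.call_slm(small_groups, list(small_cfg.sex_cell_types),
                                     small_cfg.somatic)
        planted = truth.planted_of("SLM", "SLH")
        rec = interval_recovery(loci, planted)
        assert rec["precision"] >= 0.9
        assert rec["recall"] >= 0.8
        # no locus overlapping a planted SLH may be classified SLM-like
        slh = truth.planted_of("SLH")
        pairs = overlap_pairs(loci, slh)
        assert (loci.loc[pairs["a_index"].unique(), "label"] == slm.SLH_LIKE).all()

    def test_label_partition(self, small_cfg, small_groups):
        loci, summary = slm.call_slm(small_groups, list(small_cfg.sex_cell_types),
                                     small_cfg.somatic)
        assert summary["n_total"] == summary["n_SLM_like"] + summary["n_SLH_like"]
        assert set(loci["label"]) <= {slm.SLM_LIKE, slm.SLH_LIKE}
        assert (loci["length"] >= slm.SlmParams().min_len).all()

    def test_threshold_monotonicity(self, small_cfg, small_groups):
        sex, soma = list(small_cfg.sex_cell_types), small_cfg.somatic
        base, _ = slm.call_slm(small_groups, sex, soma)
        stricter_diff, _ = slm.call_slm(small_groups, sex, soma,
                                        slm.SlmParams(sum_diff_min=0.5))
        stricter_p, _ = slm.call_slm(small_groups, sex, soma,
                                     slm.SlmParams(p_max=1e-10))
        key = lambda df: set(map(tuple, df[["chrom", "start", "end"]].values))
        assert key(stricter_diff) <= key(base)
        assert key(stricter_p) <= key(base)

    def test_null_simulation_calls_nothing(self):
        cfg = simulate.SimConfig(seed=5, n_chrom=1, chrom_length=120_000,
                                 n_genes=10, n_tes=15, n_planted_slm=0,
                                 n_planted_slh=0, n_planted_dmr=0)
        genome, feats, truth = simulate.simulate_genome(cfg)
        meth = simulate.simulate_methylome(genome, feats, truth, cfg)
        groups = {ct: io.coverage_filter(io.merge_replicates(reps))
                  for ct, reps in meth.items()}
        loci, summary = slm.call_slm(groups, list(cfg.sex_cell_types), cfg.somatic)
        assert summary["n_total"] == 0


def test_params_validation():
    with pytest.raises(ValueError):
        slm.SlmParams(sum_diff_min=3.5)
    with pytest.raises(ValueError):
        slm.SlmParams(p_max=-0.1)
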