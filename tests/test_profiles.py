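"""Window pooling, interval quantification and end-anchored metaprofiles."""

import numpy as np
import pandas as pd
import pytest

from slmkit import profiles
from conftest import make_methylome


def brute_window_counts(methylome, window, context):
    out = {}
    for r in methylome.itertuples():
        if r.context != context:
            continue
        key = (r.chrom, (r.pos - 1) // window)
        m, t = out.get(key, (0, 0))
        out[key] = (m + r.meth, t + r.total)
    return out


class TestWindowMethylation:
    def test_single_site_fraction(self):
        t = make_methylome([("chr1", 4, "+", "CHH", 3, 10)])
        w = profiles.window_methylation(t, window=50)
        assert len(w) == 1
        assert w.loc[0, ["start", "end"]].tolist() == [0, 50]
        assert w.loc[0, "fraction"] == pytest.approx(0.3)

    def test_window_boundary_splits_sites(self):
        # pos0 49 and 50 are 1-based 50 and 51: adjacent windows
        t = make_methylome([("chr1", 50, "+", "CHH", 1, 2),
                            ("chr1", 51, "+", "CHH", 1, 2)])
        w = profiles.window_methylation(t, window=50)
        assert sorted(w["start"]) == [0, 50]

    def test_zero_total_window_flagged_not_dropped(self):
        t = make_methylome([("chr1", 4, "+", "CHH", 0, 0)])
        w = profiles.window_methylation(t, window=50)
        assert len(w) == 1 and not w.loc[0, "covered"]
        assert np.isnan(w.loc[0, "fraction"])

    def test_matches_bruteforce(self, random_methylome):
        w = profiles.window_methylation(random_methylome, window=37)
        for ctx in ("CG", "CHG", "CHH"):
            brute = brute_window_counts(random_methylome, 37, ctx)
            sub = w[w["context"] == ctx]
            got = {(r.chrom, r.start // 37): (r.meth, r.total)
                   for r in sub.itertuples()}
            assert got == brute

    def test_conservation_of_counts(self, random_methylome):
        w = profiles.window_methylation(random_methylome, window=50)
        for ctx in ("CG", "CHG", "CHH"):
            sub = random_methylome[random_methylome["context"] == ctx]
            wsub = w[w["context"] == ctx]
            assert wsub["meth"].sum() == sub["meth"].sum()
            assert wsub["total"].sum() == sub["total"].sum()

    def test_invalid_window(self, random_methylome):
        with pytest.raises(ValueError):
            profiles.window_methylation(random_methylome, window=0)


class TestIntervalQuantify:
    def test_single_site_interval(self):
        t = make_methylome([("chr1", 4, "+", "CHH", 3, 10)])
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        q = profiles.interval_quantify(t, iv, contexts=("CHH",))
        assert q.loc[0, "fraction"] == pytest.approx(0.3)
        assert q.loc[0, "n_sites"] == 1

    def test_partition_additivity(self, random_methylome):
        tiles = pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(0, 10_000, 100),
                              "end": np.arange(100, 10_100, 100)})
        q = profiles.interval_quantify(random_methylome, tiles)
        whole = profiles.interval_quantify(
            random_methylome, pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                            "end": [10_000]}))
        for ctx in ("CG", "CHG", "CHH"):
            part = q[q["context"] == ctx]
            assert part["meth"].sum() == whole[whole["context"] == ctx]["meth"].iloc[0]
            assert part["total"].sum() == whole[whole["context"] == ctx]["total"].iloc[0]

    def test_matches_bruteforce_random_intervals(self, random_methylome, rng):
        starts = rng.integers(0, 9_500, size=200)
        iv = pd.DataFrame({"chrom": "chr1", "start": starts,
                           "end": starts + rng.integers(1, 500, size=200)})
        q = profiles.interval_quantify(random_methylome, iv)
        for ctx in ("CG", "CHG", "CHH"):
            sub = random_methylome[random_methylome["context"] == ctx]
            got = q[q["context"] == ctx].set_index("interval")
            for idx, row in iv.iterrows():
                inside = sub[(sub["pos"] - 1 >= row["start"]) & (sub["pos"] - 1 < row["end"])]
                assert got.loc[idx, "meth"] == inside["meth"].sum()
                assert got.loc[idx, "total"] == inside["total"].sum()

    def test_interval_beyond_chromosome_end(self, random_methylome):
        iv = pd.DataFrame({"chrom": ["chr1"], "start": [9_000], "end": [11_000]})
        with pytest.raises(ValueError, match="beyond chromosome end"):
            profiles.interval_quantify(random_methylome, iv,
                                       chrom_sizes={"chr1": 10_000})

    def test_substantial_mask(self, random_methylome):
        iv = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 9_990],
                           "end": [2_000, 10_000]})
        q = profiles.interval_quantify(random_methylome, iv)
        mask = profiles.substantial_mask(q, min_covered=4)
        assert bool(mask.loc[0])  # 2-kb interval has plenty of covered sites


def _uniform_methylome(n=4000, frac=0.5, chrom_len=20_000):
    gen = np.random.default_rng(5)
    pos = np.sort(gen.choice(np.arange(1, chrom_len + 1), n, replace=False))
    total = np.full(n, 10)
    return pd.DataFrame({"chrom": "chr1", "pos": pos,
                         "strand": gen.choice(["+", "-"], n),
                         "context": gen.choice(["CG", "CHG", "CHH"], n),
                         "meth": int(frac * 10), "total": total})


def _features(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand",
                                       "kind", "superfamily", "length"])


class TestEndsMetaprofile:
    def test_uniform_methylome_flat(self):
        meth = _uniform_methylome()
        feats = _features([("f1", "chr1", 5_000, 9_000, "+", "gene", "", 4_000),
                           ("f2", "chr1", 12_000, 15_000, "-", "gene", "", 3_000)])
        prof = profiles.ends_metaprofile(meth, feats, span=2_000, bin_width=100)
        covered = prof[prof["total"] > 0]
        assert np.allclose(covered["fraction"], 0.5)

    def test_single_plus_feature_reduces_to_interval_fractions(self, random_methylome):
        feats = _features([("f1", "chr1", 3_000, 9_000, "+", "gene", "", 6_000)])
        prof = profiles.ends_metaprofile(random_methylome, feats, span=900,
                                         bin_width=300)
        iv = pd.DataFrame({"chrom": "chr1",
                           "start": np.arange(2_100, 3_900, 300),
                           "end": np.arange(2_400, 4_200, 300)})
        q = profiles.interval_quantify(random_methylome, iv)
        pooled = q.groupby("interval")[["meth", "total"]].sum()
        for b, idx in zip(range(-3, 3), pooled.index):
            sub = prof[prof["bin"] == b]
            assert sub["meth"].sum() == pooled.loc[idx, "meth"]
            assert sub["total"].sum() == pooled.loc[idx, "total"]

    def test_minus_strand_orientation(self):
        # one covered cytosine 120 bp inside the 5' end of a minus-strand feature
        t = make_methylome([("chr1", 881, "+", "CHH", 5, 10)])  # pos0 880
        feats = _features([("f1", "chr1", 0, 1_000, "-", "TE", "Gypsy", 1_000)])
        prof = profiles.ends_metaprofile(t, feats, span=300, bin_width=100,
                                         contexts=("CHH",))
        hit = prof[prof["total"] > 0]
        assert list(hit["bin"]) == [1]  # (999 - 880) = 119 -> second inside bin

    def test_antiskew_excludes_short_features(self):
        # two features; the short one must not contribute beyond its length
        t = make_methylome([("chr1", 151, "+", "CHH", 10, 10),    # inside f1 @150
                            ("chr1", 2_151, "+", "CHH", 0, 10)])  # inside f2 @150
        feats = _features([("f1", "chr1", 0, 1_000, "+", "TE", "", 1_000),
                           ("f2", "chr1", 2_000, 2_120, "+", "TE", "", 120)])
        prof = profiles.ends_metaprofile(t, feats, span=300, bin_width=100,
                                         contexts=("CHH",))
        bin1 = prof[prof["bin"] == 1].iloc[0]
        # f2 (120 bp) does not span bin [100,200): site at rel 151 excluded
        assert bin1["fraction"] == pytest.approx(1.0)
        assert bin1["n_features"] == 1

    def test_antiskew_rule_idle_for_long_features(self, random_methylome):
        feats = _features([("f1", "chr1", 2_000, 8_000, "+", "gene", "", 6_000),
                           ("f2", "chr1", 8_500, 9_900, "+", "gene", "", 1_400)])
        span, bw = 1_000, 100  # both features longer than the span
        prof = profiles.ends_metaprofile(random_methylome, feats, span=span,
                                         bin_width=bw)
        # naive per-bin pooling with no anti-skew rule
        for b in range(-span // bw, span // bw):
            for ctx in ("CG", "CHG", "CHH"):
                m = t = 0
                for f in feats.itertuples():
                    lo, hi = f.start + b * bw, f.start + (b + 1) * bw
                    sub = random_methylome[
                        (random_methylome["context"] == ctx) &
                        (random_methylome["pos"] - 1 >= lo) &
                        (random_methylome["pos"] - 1 < hi)]
                    m += sub["meth"].sum()
                    t += sub["total"].sum()
                row = prof[(prof["bin"] == b) & (prof["context"] == ctx)].iloc[0]
                assert row["meth"] == m and row["total"] == t

    def test_empty_features_rejected(self, random_methylome):
        with pytest.raises(ValueError):
            profiles.ends_metaprofile(random_methylome, _features([]))


class TestFlankProfile:
    def test_uniform_methylome_flat(self):
        meth = _uniform_methylome()
        feats = _features([("f1", "chr1", 5_000, 9_000, "+", "TE", "Gypsy", 4_000),
                           ("f2", "chr1", 12_000, 15_000, "-", "TE", "Copia", 3_000)])
        prof = profiles.flank_profile(meth, feats, flank=200, body_bins=10)
        covered = prof[prof["total"] > 0]
        assert np.allclose(covered["fraction"], 0.5)

    def test_degenerate_single_body_bin(self, random_methylome):
        feats = _features([("f1", "chr1", 2_000, 8_000, "+", "TE", "", 6_000)])
        prof = profiles.flank_profile(random_methylome, feats, flank=0, body_bins=1)
        q = profiles.interval_quantify(
            random_methylome, pd.DataFrame({"chrom": ["chr1"], "start": [2_000],
                                            "end": [8_000]}))
        for ctx in ("CG", "CHG", "CHH"):
            row = prof[(prof["bin"] == 0) & (prof["context"] == ctx)].iloc[0]
            ref = q[q["context"] == ctx].iloc[0]
            assert row["meth"] == ref["meth"] and row["total"] == ref["total"]

    def test_planted_flank_hypermethylation_detected(self):
        # CHH high in 200-bp flanks, low in body
        rows = []
        for pos0 in range(800, 2_200, 10):
            inside = 1_000 <= pos0 < 2_000
            rows.append(("chr1", pos0 + 1, "+", "CHH", 2 if inside else 8, 10))
        t = make_methylome(rows)
        feats = _features([("f1", "chr1", 1_000, 2_000, "+", "TE", "", 1_000)])
        prof = profiles.flank_profile(t, feats, flank=200, body_bins=5,
                                      contexts=("CHH",))
        body = prof[(prof["segment"] == "body") & (prof["total"] > 0)]
        flank = prof[(prof["segment"] != "body") & (prof["total"] > 0)]
        assert flank["fraction"].min() > body["fraction"].max()

    def test_short_feature_contributes_proportionally(self):
        t = make_methylome([("chr1", 101, "+", "CHH", 1, 2)])
        feats = _features([("f1", "chr1", 100, 103, "+", "TE", "", 3)])
        prof = profiles.flank_profile(t, feats, flank=0, body_bins=10,
                                      contexts=("CHH",))
        assert prof["total"].sum() == 2  # never dropped
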