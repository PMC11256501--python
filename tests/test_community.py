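"""Rarefaction, guild extraction and CLAM niche classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from soilch4.community import (
    DEFAULT_GUILDS,
    CountTable,
    CuratedGuildList,
    clam_classify,
    extract_guilds,
    rarefy,
    relative_abundance,
)


def make_table(counts: dict, taxonomy: dict | None = None, metadata=None):
    df = pd.DataFrame(counts).T  # rows = samples
    tax = pd.Series(taxonomy or {t: f"d__D;p__P;c__C;o__O;f__F;g__{t}" for t in df.columns})
    return CountTable(counts=df, taxonomy=tax, metadata=metadata)


class TestRarefy:
    def test_retained_samples_total_exactly_depth(self):
        t = make_table({"s1": {"a": 20_000, "b": 15_000}, "s2": {"a": 5_000, "b": 1_000}})
        rare, dropped = rarefy(t, depth=29_300, seed=0)
        assert dropped == ["s2"]
        assert (rare.sample_totals == 29_300).all()

    def test_sample_at_exact_depth_unchanged(self):
        t = make_table({"s1": {"a": 20_000, "b": 9_300}})
        rare, dropped = rarefy(t, depth=29_300, seed=0)
        assert dropped == []
        assert rare.counts.loc["s1", "a"] == 20_000
        assert rare.counts.loc["s1", "b"] == 9_300

    def test_hypergeometric_expectation(self):
        """Subsampling (9000, 1000) to 1000 must average 900 of taxon a."""
        t = make_table({"s": {"a": 9_000, "b": 1_000}})
        n_rep = 10_000
        vals = np.empty(n_rep)
        for i in range(n_rep):
            rare, _ = rarefy(t, depth=1_000, seed=i)
            vals[i] = rare.counts.loc["s", "a"]
        var = sps.hypergeom(10_000, 9_000, 1_000).var()
        se = np.sqrt(var / n_rep)
        assert abs(vals.mean() - 900.0) < 3 * se

    def test_counts_never_exceed_original(self):
        rng = np.random.default_rng(5)
        counts = {f"s{i}": {f"t{j}": int(rng.integers(0, 500)) for j in range(30)}
                  for i in range(6)}
        t = make_table(counts)
        depth = int(t.sample_totals.min())
        rare, _ = rarefy(t, depth=depth, seed=1)
        assert (rare.counts.to_numpy() <= t.counts.loc[rare.counts.index].to_numpy()).all()

    def test_seeded_reproducibility(self):
        t = make_table({"s1": {"a": 9_000, "b": 1_000}})
        a, _ = rarefy(t, depth=1_000, seed=42)
        b, _ = rarefy(t, depth=1_000, seed=42)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            rarefy(make_table({"s1": {"a": 10}}), depth=0)


class TestRelativeAbundance:
    def test_even_split(self):
        t = make_table({"s1": {"a": 50, "b": 50}})
        rel = relative_abundance(t)
        assert rel.loc["s1", "a"] == pytest.approx(0.5, abs=1e-12)

    def test_rows_sum_to_one_and_scale_invariance(self):
        t1 = make_table({"s1": {"a": 3, "b": 7, "c": 10}})
        t2 = make_table({"s1": {"a": 30, "b": 70, "c": 100}})
        r1, r2 = relative_abundance(t1), relative_abundance(t2)
        assert r1.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-12)
        pd.testing.assert_frame_equal(r1, r2)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance(make_table({"s1": {"a": 0, "b": 0}}))


class TestGuildExtraction:
    def test_methylocystis_lands_in_methanotroph_subtable(self):
        t = make_table(
            {"s1": {"x": 10, "y": 90}},
            taxonomy={
                "x": "d__Bacteria;p__Pr;c__Alpha;o__Rhiz;f__Methylocystaceae;g__Methylocystis",
                "y": "d__Bacteria;p__Pr;c__Alpha;o__Other;f__F;g__Other",
            },
        )
        res = extract_guilds(t)
        assert list(res.methanotrophs.counts.columns) == ["x"]
        assert res.match_report.iloc[0]["guild"] == "methanotroph"

    def test_class_level_token_matches(self):
        t = make_table(
            {"s1": {"x": 5, "y": 95}},
            taxonomy={
                "x": "d__Archaea;p__Crenarchaeota;c__Bathyarchaeia;o__;f__;g__",
                "y": "d__Bacteria;p__P;c__C;o__O;f__F;g__G",
            },
        )
        res = extract_guilds(t)
        assert list(res.methanogens.counts.columns) == ["x"]

    def test_empty_guild_list_gives_empty_subtables(self):
        t = make_table({"s1": {"a": 10}})
        res = extract_guilds(t, CuratedGuildList(methanogens=(), methanotrophs=()))
        assert res.methanogens.counts.shape[1] == 0
        assert res.methanotrophs.counts.shape[1] == 0

    def test_constructed_guild_share_is_recovered_exactly(self):
        # guild taxa hold exactly 2.6 % of reads in every sample
        t = make_table(
            {"s1": {"m": 26, "o": 974}, "s2": {"m": 52, "o": 1948}},
            taxonomy={
                "m": "d__Archaea;p__E;c__C;o__O;f__F;g__Methanobacterium",
                "o": "d__Bacteria;p__P;c__C;o__O;f__F;g__Other",
            },
        )
        res = extract_guilds(t)
        assert res.summed_relative_abundance["methanogens"].tolist() == pytest.approx(
            [0.026, 0.026], abs=1e-12
        )

    def test_extraction_is_idempotent(self):
        t = make_table(
            {"s1": {"m": 26, "o": 974}},
            taxonomy={
                "m": "d__Archaea;p__E;c__C;o__O;f__F;g__Methanosarcina",
                "o": "d__Bacteria;p__P;c__C;o__O;f__F;g__Other",
            },
        )
        once = extract_guilds(t).methanogens
        twice = extract_guilds(once).methanogens
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_name_in_both_guilds_rejected(self):
        with pytest.raises(ValueError):
            CuratedGuildList(methanogens=("Methanox",), methanotrophs=("methanox",))


def exact_clam_oracle(ya, yb, m, n, alpha=0.05, specialization=2 / 3,
                      coverage_limit=10, npoints=20):
    """Brute-force CLAM label from first principles: exact binomial tails
    computed by direct summation of the pmf (no survival-function call)."""
    t = ya + yb
    if t < coverage_limit:
        return "too rare"
    level = alpha / npoints
    u = specialization / (1 - specialization)
    qa = u * m / (u * m + n)
    qb = u * n / (u * n + m)

    def tail(y, size, q):
        # P(Y >= y) by direct pmf summation
        ks = np.arange(y, size + 1)
        from math import comb
        return float(sum(comb(size, int(k)) * q**k * (1 - q) ** (size - k) for k in ks))

    if tail(ya, t, qa) <= level:
        return "specialist-A"
    if tail(yb, t, qb) <= level:
        return "specialist-B"
    return "generalist"


class TestClam:
    def test_canonical_examples(self):
        ya = pd.Series({"zero": 0, "monoA": 500, "even": 500})
        yb = pd.Series({"zero": 0, "monoA": 0, "even": 500})
        res = clam_classify(ya, yb)
        assert res.labels["zero"] == "too rare"
        assert res.labels["monoA"] == "specialist-A"
        assert res.labels["even"] == "generalist"

    def test_labels_partition_and_counts_sum(self):
        rng = np.random.default_rng(9)
        ya = pd.Series(rng.integers(0, 100, 50), index=[f"t{i}" for i in range(50)])
        yb = pd.Series(rng.integers(0, 100, 50), index=ya.index)
        res = clam_classify(ya, yb)
        assert sum(res.counts.values()) == 50
        assert set(res.labels.unique()) <= {
            "generalist", "specialist-A", "specialist-B", "too rare"
        }

    def test_swapping_groups_swaps_specialists(self):
        rng = np.random.default_rng(10)
        ya = pd.Series(rng.integers(0, 200, 80), index=[f"t{i}" for i in range(80)])
        yb = pd.Series(rng.integers(0, 200, 80), index=ya.index)
        fwd = clam_classify(ya, yb).labels
        rev = clam_classify(yb, ya).labels
        swap = {"specialist-A": "specialist-B", "specialist-B": "specialist-A"}
        assert (rev == fwd.map(lambda s: swap.get(s, s))).all()

    def test_agrees_with_exact_binomial_oracle_small_counts(self):
        """Exhaustive agreement for all (yA, yB) with yA + yB <= 60,
        embedded in a fixed background community setting the group totals."""
        bg_a, bg_b = 50_000, 40_000
        pairs = [(a, b) for tot in range(0, 61) for a in range(tot + 1)
                 for b in [tot - a]]
        ya = pd.Series([a for a, _ in pairs], index=range(len(pairs)))
        yb = pd.Series([b for _, b in pairs], index=range(len(pairs)))
        # add one anchor taxon so totals are fixed regardless of the grid
        ya.loc["anchor"] = bg_a - ya.sum()
        yb.loc["anchor"] = bg_b - yb.sum()
        res = clam_classify(ya, yb)
        m, n = bg_a, bg_b
        for i, (a, b) in enumerate(pairs):
            assert res.labels[i] == exact_clam_oracle(a, b, m, n), (a, b)

    def test_unadjusted_alpha_is_selectable(self):
        ya = pd.Series({"t": 10, "pad": 1000})
        yb = pd.Series({"t": 0, "pad": 1000})
        strict = clam_classify(ya, yb, adjust_alpha=True)
        loose = clam_classify(ya, yb, adjust_alpha=False)
        assert strict.individual_alpha == pytest.approx(0.05 / 20)
        assert loose.individual_alpha == pytest.approx(0.05)
        # a 10:0 split has tail (2/3)^10 ~= 0.017: rejects at 0.05, not at 0.0025
        assert loose.labels["t"] == "specialist-A"
        assert strict.labels["t"] == "generalist"

    def test_per_group_coverage_rule(self):
        ya = pd.Series({"t": 9, "pad": 1000})
        yb = pd.Series({"t": 2, "pad": 1000})
        total = clam_classify(ya, yb, coverage_rule="total")
        per_group = clam_classify(ya, yb, coverage_rule="per_group")
        assert total.labels["t"] != "too rare"  # pooled 11 >= 10
        assert per_group.labels["t"] == "too rare"  # neither group reaches 10

    def test_overlapping_sample_groups_rejected(self):
        t = make_table({"s1": {"a": 5, "b": 5}, "s2": {"a": 3, "b": 7}})
        with pytest.raises(ValueError):
            clam_classify(t, t)

    def test_invalid_alpha_rejected(self):
        ya = pd.Series({"a": 5})
        with pytest.raises(ValueError):
            clam_classify(ya, ya.copy(), alpha=1.5)
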