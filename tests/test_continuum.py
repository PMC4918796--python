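import numpy as np
import pandas as pd
import pytest

from fluvidiv.continuum import (
    TermProfile,
    core_otus,
    core_read_proportion,
    first_occurrence_counts,
    fit_continuum,
    freshwater_proportions,
    habitat_term_proportion,
    read_terms_tsv,
    term_proportions,
    tribe_heatmap_matrix,
    tributary_rkm,
    write_terms_tsv,
)
from fluvidiv.otu_io import OTUTable, TaxonomyMap


def _table(n_samples, presence):
    """presence: dict otu -> set of sample indices holding 1 read (else 0)."""
    idx = [f"s{i}" for i in range(n_samples)]
    df = pd.DataFrame(0, index=idx, columns=sorted(presence))
    for otu, where in presence.items():
        for i in where:
            df.iloc[i, df.columns.get_loc(otu)] = 1
    return OTUTable(df)


def _meta(n_samples, fraction="FL", system="mainstem"):
    idx = [f"s{i}" for i in range(n_samples)]
    return pd.DataFrame(
        {"site_id": idx, "fraction": [fraction] * n_samples, "system": [system] * n_samples},
        index=pd.Index(idx, name="sample_id"),
    )


class TestCoreCommunity:
    def test_ceil_threshold_at_ninety_percent(self):
        # 10 samples: present in 9 -> core; present in 8 -> not (ceil(0.9*10)=9)
        t = _table(10, {"in9": set(range(9)), "in8": set(range(8))})
        core = core_otus(t, _meta(10), "FL", q=0.90)
        assert core.otu_ids == frozenset({"in9"})
        assert core.n_samples == 10

    def test_tributary_samples_excluded(self):
        t = _table(10, {"main_only": set(range(5)), "everywhere": set(range(10))})
        meta = _meta(10)
        meta.loc[[f"s{i}" for i in range(5, 10)], "system"] = "tributary"
        core = core_otus(t, meta, "FL", q=1.0)
        # occupancy computed over the 5 mainstem samples only
        assert core.otu_ids == frozenset({"main_only", "everywhere"})
        assert core.n_samples == 5

    def test_minimal_q_takes_all_observed(self):
        t = _table(4, {"a": {0}, "b": {1, 2}})
        core = core_otus(t, _meta(4), "FL", q=1e-9)
        assert core.otu_ids == frozenset({"a", "b"})

    def test_empty_table_gives_empty_core(self):
        t = OTUTable(pd.DataFrame(index=["s0", "s1"], columns=[], dtype=np.int64))
        core = core_otus(t, _meta(2), "FL")
        assert len(core) == 0

    def test_read_proportion(self):
        counts = pd.Series({"a": 45, "b": 10, "c": 5})
        core_all = core_otus(_table(1, {"a": {0}, "b": {0}, "c": {0}}), _meta(1), "FL")
        assert core_read_proportion(counts, core_all) == 1.0
        some = core_all.__class__("FL", 0.9, frozenset({"a"}), 1)
        assert core_read_proportion(counts, some) == pytest.approx(45 / 60)
        none = core_all.__class__("FL", 0.9, frozenset(), 1)
        assert core_read_proportion(counts, none) == 0.0

    def test_proportion_monotone_in_q(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(0, 5, size=(8, 30)),
            index=[f"s{i}" for i in range(8)],
            columns=[f"o{i}" for i in range(30)],
        )
        t = OTUTable(df)
        meta = _meta(8)
        sample = t.sample("s0")
        props = [
            core_read_proportion(sample, core_otus(t, meta, "FL", q=q))
            for q in (0.2, 0.5, 0.75, 0.9, 1.0)
        ]
        assert all(a >= b for a, b in zip(props, props[1:]))


class TestFirstOccurrence:
    def test_toy_attribution_and_conservation(self):
        df = pd.DataFrame(
            {"u": [2, 0, 1], "v": [0, 3, 3], "w": [0, 0, 1], "x": [1, 1, 1]},
            index=["s0", "s1", "s2"],
        )
        t = OTUTable(df)
        counts = first_occurrence_counts(t, ["s0", "s1", "s2"])
        # s0 first sees u and x; s1 sees v; s2 sees w
        assert counts.tolist() == [2, 1, 1]
        assert counts.iloc[0] == int((t.sample("s0") >= 1).sum())
        assert counts.sum() == int((t.counts >= 1).any(axis=0).sum())

    def test_site_pooling_via_metadata(self):
        df = pd.DataFrame(
            {"u": [1, 0, 0], "v": [0, 1, 1]}, index=["a1", "a2", "b1"]
        )
        t = OTUTable(df)
        meta = pd.DataFrame(
            {"site_id": ["A", "A", "B"], "fraction": ["FL"] * 3, "system": ["mainstem"] * 3},
            index=pd.Index(["a1", "a2", "b1"], name="sample_id"),
        )
        counts = first_occurrence_counts(t, ["A", "B"], meta)
        assert counts.tolist() == [2, 0]


class TestContinuumFit:
    def test_perfect_line(self):
        fit = fit_continuum([1.0, 3.0, 5.0, 7.0], [0.0, 1.0, 2.0, 3.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=5)
        y = 2.0 - 3.0 * x + rng.normal(scale=0.2, size=5)
        fit = fit_continuum(y, x)
        xm = np.column_stack([np.ones(5), x])
        b = np.linalg.solve(xm.T @ xm, xm.T @ y)
        resid = y - xm @ b
        r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
        assert fit.intercept == pytest.approx(b[0])
        assert fit.slope == pytest.approx(b[1])
        assert fit.r_squared == pytest.approx(r2)

    def test_constant_response(self):
        fit = fit_continuum([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_pairwise_deletion_and_minimum_n(self):
        y = pd.Series([1.0, np.nan, 3.0, 4.0], index=list("abcd"))
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert fit_continuum(y, x).n == 3
        with pytest.raises(ValueError):
            fit_continuum(y[:3], x[:3])  # only 2 complete pairs


class TestAnnotationProportions:
    def test_freshwater_partition(self):
        tax = TaxonomyMap(
            lineage={o: "x" for o in "abc"},
            freshwater_level={"a": "tribe", "b": "clade_lineage", "c": "none"},
        )
        counts = pd.Series({"a": 50, "b": 30, "c": 20})
        fw = freshwater_proportions(counts, tax)
        assert fw == pytest.approx((0.5, 0.3, 0.2))
        assert sum(fw) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            freshwater_proportions(pd.Series({"a": 0}), tax)

    def test_tribe_heatmap_ranking(self):
        tax = TaxonomyMap(
            lineage={o: "x" for o in "abcd"},
            freshwater_level={o: "tribe" for o in "abcd"},
            tribe={"a": "acI-B1", "b": "LD12", "c": "acI-B1", "d": "betI-A"},
        )
        df = pd.DataFrame(
            {"a": [10, 0], "b": [5, 5], "c": [0, 10], "d": [1, 1]},
            index=["s1", "s2"],
        )
        t = OTUTable(df)
        mat = tribe_heatmap_matrix(t, tax, top_n=2)
        # brute-force ranking oracle: total reads acI-B1=20, LD12=10, betI-A=2
        assert list(mat.index) == ["acI-B1", "LD12"]
        assert mat.loc["acI-B1", "s1"] == pytest.approx(10 / 16)
        assert ((mat >= 0) & (mat <= 1)).all().all()
        assert (mat.sum(axis=0) <= 1 + 1e-12).all()

    def test_single_tribe_community(self):
        tax = TaxonomyMap(
            lineage={"a": "x"}, freshwater_level={"a": "tribe"}, tribe={"a": "LD12"}
        )
        t = OTUTable(pd.DataFrame({"a": [7]}, index=["s"]))
        assert tribe_heatmap_matrix(t, tax, top_n=3).loc["LD12", "s"] == 1.0


class TestHabitatTerms:
    def test_hand_computed_two_otu_mix(self):
        profile = TermProfile(
            weights={"a": {"soil": 3.0, "lake": 1.0}, "b": {"soil": 1.0, "river": 1.0}}
        )
        counts = pd.Series({"a": 10, "b": 30, "unprofiled": 100})
        # a: soil share 0.75 -> 7.5 reads; b: 0.5 -> 15 reads; denom = 40
        assert habitat_term_proportion(counts, profile, "soil") == pytest.approx(22.5 / 40)
        props = term_proportions(counts, profile)
        assert props.sum() == pytest.approx(1.0, abs=1e-12)

    def test_pure_term(self):
        profile = TermProfile(weights={"a": {"soil": 2.0}})
        assert habitat_term_proportion(pd.Series({"a": 5}), profile, "soil") == 1.0

    def test_unknown_term_and_empty_denominator(self):
        profile = TermProfile(weights={"a": {"soil": 1.0}})
        with pytest.raises(KeyError):
            habitat_term_proportion(pd.Series({"a": 1}), profile, "volcano")
        with pytest.raises(ValueError):
            term_proportions(pd.Series({"other": 5}), profile)

    def test_terms_tsv_round_trip(self, tmp_path):
        profile = TermProfile(weights={"a": {"soil": 0.8, "lake": 0.2}, "b": {"river": 1.0}})
        p = tmp_path / "terms.tsv"
        write_terms_tsv(profile, p)
        back = read_terms_tsv(p)
        assert back.normalized("a") == pytest.approx({"soil": 0.8, "lake": 0.2})
        assert back.terms == profile.terms


def test_tributary_rkm():
    assert tributary_rkm(0.0) == 2780.0
    assert tributary_rkm(780.0) == 2000.0
    with pytest.raises(ValueError):
        tributary_rkm(-5.0)
    with pytest.raises(ValueError):
        tributary_rkm(3000.0)
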