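"""Occupancy algebra, enrichment ratios, G/C groups, and diversity statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from virocycle import dispersal
from virocycle.dispersal import (
    bray_curtis,
    compare_groups_kw_dunn,
    ecosystem_venn,
    enrichment_ratios,
    exclusive_viruses,
    gc_percent,
    occupancy_matrix,
    permanova,
    shannon,
    shared_fraction,
)
from virocycle.errors import ValidationError
from virocycle.samples import Ecosystem, Fraction, SampleRecord


def _samples():
    mk = lambda sid, eco, frac=Fraction.NA: SampleRecord(sid, eco, frac)
    return [
        mk("f1", Ecosystem.FOAM, Fraction.UM5_02),
        mk("m1", Ecosystem.SML, Fraction.UM5_02),
        mk("m2", Ecosystem.SML, Fraction.VIROME),
        mk("w1", Ecosystem.SSW, Fraction.UM5_02),
        mk("a1", Ecosystem.AEROSOL),
        mk("r1", Ecosystem.RAIN, Fraction.VIROME),
        mk("ctrl", Ecosystem.CONTROL),
    ]


def test_occupancy_or_aggregation_and_control_exclusion():
    presence = pd.DataFrame(
        {
            "f1": [True, False],
            "m1": [False, True],
            "m2": [True, False],
            "w1": [False, False],
            "a1": [False, False],
            "r1": [False, True],
            "ctrl": [True, True],  # must not matter
        },
        index=["v1", "v2"],
    )
    occ = occupancy_matrix(presence, _samples())
    assert "control" not in occ.columns
    assert set(occ.columns[occ.loc["v1"]]) == {"foam", "SML"}
    assert set(occ.columns[occ.loc["v2"]]) == {"SML", "rain"}
    # dropping the control column entirely gives the same occupancy
    occ2 = occupancy_matrix(presence.drop(columns=["ctrl"]), _samples())
    assert occ.equals(occ2)


def test_venn_disjoint_and_identical():
    occ = pd.DataFrame(
        {"foam": [True] * 3 + [False] * 4, "SML": [False] * 3 + [True] * 4},
        index=[f"v{i}" for i in range(7)],
    )
    regions = ecosystem_venn(occ, ["foam", "SML"])
    assert regions[frozenset({"foam"})] == 3
    assert regions[frozenset({"SML"})] == 4
    assert regions[frozenset({"foam", "SML"})] == 0

    same = pd.DataFrame({"a": [True] * 5, "b": [True] * 5, "c": [True] * 5})
    regions = ecosystem_venn(same, ["a", "b", "c"])
    assert regions[frozenset({"a", "b", "c"})] == 5
    assert sum(regions.values()) == 5


def test_venn_matches_subset_enumeration_oracle(rng):
    sets = ["foam", "SML", "SSW", "aerosol", "rain"]
    occ = pd.DataFrame(
        rng.random((50, 5)) < 0.4, columns=sets, index=[f"v{i}" for i in range(50)]
    )
    regions = ecosystem_venn(occ, sets)
    # oracle: classify each virus by its exact membership pattern
    oracle: dict[frozenset, int] = {}
    for _, row in occ.iterrows():
        key = frozenset(s for s in sets if row[s])
        if key:
            oracle[key] = oracle.get(key, 0) + 1
    for key, count in regions.items():
        assert count == oracle.get(key, 0)
    assert sum(regions.values()) == int(occ.any(axis=1).sum())


def test_exclusive_viruses():
    occ = pd.DataFrame(
        {"rain": [True, True, False], "aerosol": [False, True, True], "SML": [False] * 3},
        index=["only_rain", "rain_aer", "only_aer"],
    )
    assert exclusive_viruses(occ, "rain") == ["only_rain"]
    assert exclusive_viruses(occ, "SML") == []


def test_shared_fraction_examples():
    occ = pd.DataFrame(
        {
            "rain": [True] * 112 + [False] * 200,
            "SML": [True] * 112 + [True] * 200,
        },
        index=[f"v{i}" for i in range(312)],
    )
    pct, shared = shared_fraction(occ, ["rain"], ["SML"], total=1813)
    assert shared == 112
    assert round(pct, 1) == 6.2
    with pytest.raises(ValidationError):
        shared_fraction(occ, ["rain"], ["SML"], total=0)


def test_enrichment_ratios_bruteforce_and_scale_invariance(rng):
    samples = _samples()
    cols = [r.sample_id for r in samples if not r.is_control]
    abund = pd.DataFrame(
        rng.random((8, len(cols))) * 10, index=[f"v{i}" for i in range(8)], columns=cols
    )
    abund[abund < 2] = 0.0  # some absences
    table = enrichment_ratios(abund, samples)
    # brute-force max-then-divide oracle for the R/S pairing, virome fraction
    sub = table[(table["pairing"] == "R/S") & (table["denominator_fraction"] == "virome_lt02um")]
    for _, row in sub.iterrows():
        num = abund.loc[row["virus"], ["r1"]].max()
        den = abund.loc[row["virus"], ["m2"]].max()
        if num > 0 and den > 0:
            assert row["ratio"] == pytest.approx(num / den)
            assert row["reported"] == (num / den >= 1.0)
        else:
            assert math.isnan(row["ratio"])
    # normalization-scale invariance: recomputing under scale 1e3 vs 1e6
    table_scaled = enrichment_ratios(abund * 1e-3, samples)
    merged = table.merge(table_scaled, on=["virus", "pairing", "denominator_fraction"])
    finite = merged.dropna()
    assert np.allclose(finite["ratio_x"], finite["ratio_y"])


def test_gc_percent_basics():
    assert gc_percent("GGCC") == 100.0
    assert gc_percent("ATAT") == 0.0
    assert gc_percent("GCGCNNNN") == 100.0  # ambiguity codes excluded
    with pytest.raises(ValidationError):
        gc_percent("")


@given(hs.text(alphabet="ACGTN", min_size=1, max_size=200))
@settings(max_examples=100, deadline=None)
def test_gc_percent_matches_tally_oracle(seq):
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        with pytest.raises(ValidationError):
            gc_percent(seq)
    else:
        assert gc_percent(seq) == pytest.approx(100 * gc / (gc + at))
        assert gc_percent(seq) + (100 * at / (gc + at)) == pytest.approx(100.0)


def test_kw_identical_groups():
    res = compare_groups_kw_dunn({"a": [1.0, 1.0], "b": [1.0, 1.0]})
    assert res.h == 0.0 and res.p == 1.0


def test_kw_closed_form_three_groups():
    """H for {1,2,3}/{10,11,12}/{20,21,22}: rank sums 6/15/24 give H = 7.2."""
    res = compare_groups_kw_dunn(
        {"a": [1, 2, 3], "b": [10, 11, 12], "c": [20, 21, 22]}
    )
    assert res.h == pytest.approx(7.2)
    assert res.df == 2


def test_kw_invariant_under_monotone_transform(rng):
    groups = {g: rng.normal(size=8).tolist() for g in "abc"}
    h1 = compare_groups_kw_dunn(groups).h
    h2 = compare_groups_kw_dunn({g: list(np.exp(v)) for g, v in groups.items()}).h
    assert h1 == pytest.approx(h2)


def test_dunn_adjustment_and_z(rng):
    groups = {"a": [1, 2, 3, 4], "b": [10, 11, 12, 13], "c": [5, 6, 7, 8]}
    res = compare_groups_kw_dunn(groups)
    assert (res.dunn["p_adj"] >= res.dunn["p_raw"] - 1e-15).all()
    assert (res.dunn["p_adj"] <= 1.0).all()
    # z for a vs b from the rank-mean formula, no ties
    ranks = {"a": [1, 2, 3, 4], "b": [9, 10, 11, 12], "c": [5, 6, 7, 8]}
    n = 12
    s2 = n * (n + 1) / 12.0
    z_oracle = (np.mean(ranks["a"]) - np.mean(ranks["b"])) / math.sqrt(s2 * (2 / 4))
    row = res.dunn[(res.dunn["group_a"] == "a") & (res.dunn["group_b"] == "b")]
    assert row["z"].iloc[0] == pytest.approx(z_oracle)


def test_shannon_uniform_and_errors():
    assert shannon([5, 5, 5, 5]) == pytest.approx(math.log(4))
    assert shannon([1, 0, 0]) == 0.0
    with pytest.raises(ValidationError):
        shannon([0, 0])


def test_bray_curtis_identical_and_disjoint():
    m = pd.DataFrame([[1.0, 2.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 3.0]])
    bc = bray_curtis(m)
    assert bc.iloc[0, 1] == 0.0
    assert bc.iloc[0, 2] == 1.0
    assert np.allclose(bc, bc.T)
    assert (np.diag(bc) == 0).all()


def test_permanova_matches_skbio_oracle(rng):
    skbio = pytest.importorskip("skbio")
    x = pd.DataFrame(
        rng.poisson(10, (12, 8)).astype(float), index=[f"s{i}" for i in range(12)]
    )
    x.iloc[:6] += rng.poisson(5, (6, 8))
    bc = bray_curtis(x.div(x.sum(axis=1), axis=0))
    labels = ["g1"] * 6 + ["g2"] * 6
    f_obs, _ = permanova(bc, labels, permutations=99, rng=np.random.default_rng(0))
    dm = skbio.DistanceMatrix(bc.to_numpy(), ids=list(x.index))
    res = skbio.stats.distance.permanova(dm, grouping=labels, permutations=99)
    assert f_obs == pytest.approx(res["test statistic"], rel=1e-9)


def test_permanova_p_bounds(rng):
    x = pd.DataFrame(rng.poisson(10, (8, 5)).astype(float))
    bc = bray_curtis(x.div(x.sum(axis=1), axis=0))
    _, p = permanova(bc, ["a"] * 4 + ["b"] * 4, permutations=99, rng=rng)
    assert 1 / 100 <= p <= 1.0


def test_diversity_suite_drops_empty_samples(rng):
    x = pd.DataFrame(
        rng.poisson(5, (6, 4)).astype(float), index=[f"s{i}" for i in range(6)]
    )
    x.iloc[5] = 0.0
    res = dispersal.diversity_suite(
        x, {f"s{i}": ("a" if i < 3 else "b") for i in range(6)},
        permutations=99, rng=rng,
    )
    assert "s5" not in res.shannon.index
    assert res.bray_curtis.shape == (5, 5)
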