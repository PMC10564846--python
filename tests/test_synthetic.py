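"""Generator contracts: determinism, target recovery, boundary decoys."""

import numpy as np
import pandas as pd
import pytest

from virocycle import detection, synthetic
from virocycle.crispr import extract_spacers, filter_and_cluster, match_protospacers
from virocycle.errors import ParameterError, ValidationError


def test_genomes_deterministic():
    a = synthetic.gen_genomes(3, 2, seed=5, viral_length_range=(10_000, 12_000),
                              host_length=12_000)
    b = synthetic.gen_genomes(3, 2, seed=5, viral_length_range=(10_000, 12_000),
                              host_length=12_000)
    assert a[0] == b[0] and a[1] == b[1]
    assert a[2].viruses.equals(b[2].viruses)


def test_genome_gc_targets():
    viruses, hosts, truth = synthetic.gen_genomes(
        4, 2, gc_by_class={"marine": 0.40, "rain_only": 0.60},
        class_of_virus=["marine", "rain_only", "marine", "rain_only"],
        seed=11, viral_length_range=(10_000, 12_000), host_length=15_000,
    )
    for _, row in truth.viruses.iterrows():
        assert abs(row["gc_realized"] - row["gc_target"]) <= 0.02
        assert 10_000 <= row["length"] <= 12_000
    for hid, seq in hosts.items():
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        target = truth.hosts.set_index("host").loc[hid, "gc_target"]
        assert abs(gc - target) <= 0.02


def test_single_genome_gc_construction():
    viruses, _, truth = synthetic.gen_genomes(
        1, 1, gc_by_class={"x": 0.50}, seed=3,
        viral_length_range=(10_000, 10_000), host_length=12_000,
    )
    seq = next(iter(viruses.values()))
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert gc == pytest.approx(0.50, abs=0.02)


def test_infeasible_gc_rejected():
    with pytest.raises(ParameterError):
        synthetic.gen_genomes(1, 1, gc_by_class={"x": 1.5}, seed=0)


def test_read_coverage_presence_and_decoys():
    lengths = {"v": 10_000}
    design = pd.DataFrame(
        [
            {"target": "v", "sample": "present", "breadth": 0.80, "identity": 0.95},
            {"target": "v", "sample": "breadth_decoy", "breadth": 0.74, "identity": 0.95},
            {"target": "v", "sample": "identity_decoy", "breadth": 0.90, "identity": 0.85},
        ]
    )
    aln, truth = synthetic.gen_read_coverage(lengths, design, seed=1)
    pm = detection.presence_matrix(aln, lengths)
    assert bool(pm.loc["v", "present"])
    assert not pm.loc["v", ["breadth_decoy", "identity_decoy"]].any()
    t = truth.set_index("sample")["expected_present"]
    assert t["present"] and not t["breadth_decoy"] and not t["identity_decoy"]
    # realized breadth within one read of the design target
    prof = detection.coverage_profile(
        detection.filter_reads_by_identity(aln["present"], 0.9), "v", 10_000
    )
    assert prof.breadth == pytest.approx(0.80, abs=0.02)


def test_read_coverage_unknown_genome():
    with pytest.raises(ValidationError):
        synthetic.gen_read_coverage(
            {"v": 1000},
            pd.DataFrame([{"target": "x", "sample": "s", "breadth": 0.8, "identity": 0.9}]),
        )


def test_crispr_reads_truth_recovery(small_community):
    viruses, hosts, _ = small_community
    reads, dr, truth = synthetic.gen_crispr_reads(
        hosts, viruses, n_spacers=10, divergences=(0.0,), seed=2
    )
    raw = extract_spacers(reads, dr)
    centroids = filter_and_cluster(raw)
    matches = match_protospacers(centroids, viruses, 0.80)
    # every zero-divergence spacer is recovered and matched at identity 1.0
    assert set(truth["spacer"]) <= set(raw)
    assert len(matches) >= len(truth)
    by_spacer = {m["spacer"]: m for _, m in matches.iterrows()}
    for _, t in truth.iterrows():
        m = by_spacer[t["spacer"]]
        assert m["scaffold"] == t["source_virus"]
        assert m["identity"] == 1.0


def test_crispr_divergence_sits_on_boundary(small_community):
    viruses, hosts, _ = small_community
    reads, dr, truth = synthetic.gen_crispr_reads(
        hosts, viruses, n_spacers=6, divergences=(0.2,), seed=4
    )
    assert np.allclose(truth["identity"], 0.80)
    raw = extract_spacers(reads, dr)
    matches = match_protospacers(filter_and_cluster(raw), viruses, 0.80)
    # 20 % divergence is matched (inclusive boundary)
    assert set(matches["scaffold"]) >= set(truth["source_virus"])
    assert (matches["identity"] >= 0.80).all()


def test_crispr_negative_reads_only(small_community):
    viruses, hosts, _ = small_community
    reads, dr, _ = synthetic.gen_crispr_reads(
        hosts, viruses, n_spacers=1, seed=6, n_negative_reads=10
    )
    assert extract_spacers(reads[1:], dr) == []


def test_crispr_parameter_guards(small_community):
    viruses, hosts, _ = small_community
    with pytest.raises(ParameterError):
        synthetic.gen_crispr_reads(hosts, viruses, dr_length=15)
    with pytest.raises(ParameterError):
        synthetic.gen_crispr_reads(hosts, viruses, spacer_length=61)


def test_trajectories_deterministic_and_bounded():
    a, _ = synthetic.gen_trajectories(50, 0.6, 0.3, seed=8)
    b, _ = synthetic.gen_trajectories(50, 0.6, 0.3, seed=8)
    assert a.equals(b)
    with pytest.raises(ParameterError):
        synthetic.gen_trajectories(1, 1.2, 0.3)
    with pytest.raises(ParameterError):
        synthetic.gen_trajectories(1, 0.2, 0.5)  # loading > sea, not allowed
    df, _ = synthetic.gen_trajectories(1, 0.2, 0.5, loading_over_land=True, seed=1)
    assert len(df) == 120


def test_freezing_zero_spectrum():
    spec = pd.DataFrame({"temperature": [-5.0, -5.1, -5.2], "inp_per_well": [0.0] * 3})
    assay, _ = synthetic.gen_freezing_assay(spec, seed=0)
    assert (assay["frozen"] == 0).all()


def test_freezing_half_at_ln2():
    """lambda = ln 2 per well -> P(frozen) = 0.5 exactly; check by Monte Carlo."""
    lam = np.log(2)
    spec = pd.DataFrame({"temperature": [-10.0], "inp_per_well": [lam]})
    fracs = [
        synthetic.gen_freezing_assay(spec, wells=24, seed=s)[0]["frozen"].iloc[0] / 24
        for s in range(300)
    ]
    assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)


def test_freezing_validates_spectrum():
    with pytest.raises(ParameterError):
        synthetic.gen_freezing_assay(
            pd.DataFrame({"temperature": [-5.0, -6.0], "inp_per_well": [1.0, 0.5]})
        )
    with pytest.raises(ParameterError):
        synthetic.gen_freezing_assay(
            pd.DataFrame({"temperature": [-5.0], "inp_per_well": [-1.0]})
        )


def test_count_table_correlation_convergence():
    df, truth = synthetic.gen_count_table(1000, {("vlp", "prok"): 0.7}, seed=3)
    r = np.corrcoef(df["vlp_sml"], df["prok_sml"])[0, 1]
    assert r == pytest.approx(0.7, abs=0.05)


def test_count_table_collinear_and_schema():
    df, _ = synthetic.gen_count_table(10, {("vlp", "prok"): 1.0}, seed=3)
    r = np.corrcoef(df["vlp_sml"], df["prok_sml"])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)
    for col in ("vlp_sml", "vlp_ssw", "prok_sml", "prok_ssw", "euk_sml", "euk_ssw",
                "vlp_foam", "vlp_prc", "station", "date"):
        assert col in df.columns
    assert len(df) == 10


def test_count_table_infeasible_targets():
    with pytest.raises(ParameterError):
        synthetic.gen_count_table(
            10, {("vlp", "prok"): 0.9, ("vlp", "euk"): 0.9, ("prok", "euk"): -0.9}
        )


def test_variant_pileups_truth():
    ref = "ACGT" * 100
    pileups, truth = synthetic.gen_variant_pileups(
        ref, {"s1": [(10, "A", 0.3)], "s2": [(10, "A", 0.2)]}, depth=100
    )
    assert len(truth) == 2
    col = pileups["s1"].iloc[0]
    assert col["A"] == 30 and col[ref[9]] == 70
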