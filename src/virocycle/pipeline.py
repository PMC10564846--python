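"""End-to-end orchestration: synthetic community -> all analysis stages.

``run_pipeline`` executes detection -> dispersal -> host linkage ->
CRISPR -> variants -> trajectories -> INP -> field statistics on a
seed-deterministic synthetic study, collects every stage's tables into a
:class:`ReportBundle`, and ``write_report`` serializes them (TSV + JSON
manifest) at fixed precision so identical configs reproduce byte-identical
outputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import crispr as crispr_mod
from . import datasets, detection, dispersal, field_stats, kmer, synthetic, variants
from . import trajectories as traj_mod
from .config import RunConfig, derive_seed
from .errors import VirocycleError
from .samples import Ecosystem, Fraction, SampleRecord, analysis_samples

#: Synthetic study layout: two samples per open-water ecosystem, one snow,
#: one handling control.  Foam/SML carry both size fractions.
_SYNTH_SAMPLES = [
    ("foam_1", Ecosystem.FOAM, Fraction.UM5_02),
    ("foam_2", Ecosystem.FOAM, Fraction.VIROME),
    ("sml_1", Ecosystem.SML, Fraction.UM5_02),
    ("sml_2", Ecosystem.SML, Fraction.VIROME),
    ("ssw_1", Ecosystem.SSW, Fraction.UM5_02),
    ("ssw_2", Ecosystem.SSW, Fraction.VIROME),
    ("aer_1", Ecosystem.AEROSOL, Fraction.NA),
    ("aer_2", Ecosystem.AEROSOL, Fraction.NA),
    ("rain_1", Ecosystem.RAIN, Fraction.UM5_02),
    ("rain_2", Ecosystem.RAIN, Fraction.VIROME),
    ("snow_1", Ecosystem.SNOW, Fraction.NA),
    ("ctrl_1", Ecosystem.CONTROL, Fraction.NA),
]


def synthetic_sample_sheet() -> list[SampleRecord]:
    return [
        SampleRecord(sample_id=sid, ecosystem=eco, fraction=frac,
                     station=None, date=_dt.date(2020, 2, 15))
        for sid, eco, frac in _SYNTH_SAMPLES
    ]


def synthetic_occupancy_truth(n_viruses: int) -> tuple[dict[str, tuple[str, ...]], list[str]]:
    """Deterministic truth occupancy and G/C class per virus.

    Roughly: a marine core shared by foam/SML/SSW, a couple of
    everywhere-viruses, a rain-only subset with elevated G/C, one
    aerosol-only virus, and marine partial-occupancy viruses.
    """
    occupancy: dict[str, tuple[str, ...]] = {}
    classes: list[str] = []
    for v in range(n_viruses):
        vid = f"virus_{v:03d}"
        r = v % 10
        if r < 5:
            occ = ("foam", "SML", "SSW")  # marine core
            cls = "marine"
        elif r == 5:
            occ = ("foam", "SML", "SSW", "aerosol", "rain", "snow")
            cls = "marine"
        elif r == 6:
            occ = ("rain",)  # rain-only, elevated G/C
            cls = "rain_only"
        elif r == 7:
            occ = ("aerosol",)
            cls = "marine"
        elif r == 8:
            occ = ("foam", "SML", "SSW", "rain")  # marine-rain overlap
            cls = "marine"
        else:
            occ = ("SML", "SSW")
            cls = "marine"
        occupancy[vid] = occ
        classes.append(cls)
    return occupancy, classes


@dataclass
class ReportBundle:
    config: RunConfig
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage on a synthetic study defined by the configuration."""
    config.validate()
    if not config.synthetic:
        raise VirocycleError(
            "real-data mode is not wired end-to-end; run stages individually"
        )
    thr = config.thresholds
    bundle = ReportBundle(config=config)
    stage_counts: dict[str, int] = {}

    samples = synthetic_sample_sheet()
    analysis = analysis_samples(samples)
    samples_by_eco: dict[str, list[str]] = {}
    for rec in analysis:
        samples_by_eco.setdefault(rec.ecosystem.value, []).append(rec.sample_id)

    # --- community -----------------------------------------------------
    occupancy_truth, classes = synthetic_occupancy_truth(config.n_viruses)
    viruses, hosts, genome_truth = synthetic.gen_genomes(
        n_viral=config.n_viruses,
        n_host=config.n_hosts,
        seed=derive_seed(config.seed, "genomes"),
        viral_length_range=(10_000, 15_000),
        host_length=20_000,
        class_of_virus=classes,
    )
    stage_counts["genomes"] = len(viruses) + len(hosts)

    # --- detection -----------------------------------------------------
    design = synthetic.design_from_occupancy(
        occupancy_truth, samples_by_eco, seed=derive_seed(config.seed, "coverage")
    )
    aln_by_sample, coverage_truth = synthetic.gen_read_coverage(
        {v: len(s) for v, s in viruses.items()},
        design,
        seed=derive_seed(config.seed, "reads"),
    )
    lengths = {v: len(s) for v, s in viruses.items()}
    for rec in analysis:
        aln_by_sample.setdefault(
            rec.sample_id,
            pd.DataFrame(columns=list(detection.ALN_COLUMNS)),
        )
    presence = detection.presence_matrix(
        aln_by_sample, lengths,
        min_identity=thr.read_identity, min_breadth=thr.viral_breadth,
    )
    raw_cov = detection.mean_coverage_matrix(
        aln_by_sample, lengths, min_identity=thr.read_identity
    )
    lib_sizes = {s: max(1, len(a)) * 1000.0 for s, a in aln_by_sample.items()}
    abundance = detection.normalize_coverage(raw_cov, lib_sizes)
    stage_counts["detection"] = int(presence.to_numpy().sum())
    bundle.tables["presence"] = presence.reset_index(names="virus")
    bundle.tables["abundance"] = abundance.reset_index(names="virus")

    # --- dispersal -----------------------------------------------------
    occ = dispersal.occupancy_matrix(presence, samples)
    venn = dispersal.ecosystem_venn(occ, ["foam", "SML", "SSW"])
    marine_core = venn[frozenset({"foam", "SML", "SSW"})]
    rain_only = dispersal.exclusive_viruses(occ, "rain")
    shared_pct, shared_n = dispersal.shared_fraction(
        occ, ["rain", "snow"], ["foam", "SML", "SSW"], total=config.n_viruses
    )
    ratios = dispersal.enrichment_ratios(abundance, samples)
    gc_by_virus = {v: dispersal.gc_percent(s) for v, s in viruses.items()}
    gc_groups = dispersal.gc_group_table(gc_by_virus, occ, rain_only=rain_only)
    gc_cmp = (
        dispersal.compare_groups_kw_dunn(gc_groups) if len(gc_groups) >= 2 else None
    )
    stage_counts["dispersal"] = int(occ.to_numpy().sum())
    bundle.tables["occupancy"] = occ.reset_index(names="virus")
    bundle.tables["enrichment_ratios"] = ratios
    bundle.tables["gc_content"] = pd.DataFrame(
        {"virus": list(gc_by_virus), "gc_percent": list(gc_by_virus.values())}
    )
    bundle.summary["venn_marine_core"] = marine_core
    bundle.summary["rain_only"] = len(rain_only)
    bundle.summary["shared_precipitation_marine_pct"] = round(shared_pct, 1)
    bundle.summary["shared_precipitation_marine_n"] = shared_n
    if gc_cmp is not None:
        bundle.summary["gc_kw_p"] = gc_cmp.p

    # --- host linkage (d2*) -------------------------------------------
    vprof = {v: kmer.kmer_profile(s, seq_id=v) for v, s in viruses.items()}
    hprof = {h: kmer.kmer_profile(s, seq_id=h) for h, s in hosts.items()}
    edges = kmer.assign_hosts(vprof, hprof, threshold=thr.d2star)
    best = edges[edges["is_best"]].set_index("virus")["host"] if len(edges) else pd.Series(dtype=str)
    truth_host = genome_truth.viruses.set_index("virus")["host"]
    correct = sum(best.get(v) == truth_host[v] for v in truth_host.index)
    stage_counts["linkage"] = len(edges)
    bundle.tables["host_links"] = edges
    bundle.summary["host_recovery"] = correct / len(truth_host)

    # --- CRISPR --------------------------------------------------------
    reads, dr, spacer_truth = synthetic.gen_crispr_reads(
        hosts, viruses,
        n_spacers=min(10, config.n_viruses),
        divergences=(0.0, 0.1),
        seed=derive_seed(config.seed, "crispr"),
    )
    raw_spacers = crispr_mod.extract_spacers(
        reads, dr, max_mismatch=thr.dr_max_mismatches, max_spacer_len=thr.spacer_max_len
    )
    centroids = crispr_mod.filter_and_cluster(
        raw_spacers, min_len=thr.spacer_min_len, max_len=thr.spacer_max_len
    )
    matches = crispr_mod.match_protospacers(
        centroids, viruses, min_identity=thr.protospacer_identity
    )
    stage_counts["crispr"] = len(matches)
    bundle.tables["spacer_matches"] = matches.drop(columns=["spacer"])
    recovered_sources = set(matches["scaffold"]) if len(matches) else set()
    bundle.summary["crispr_sources_recovered"] = len(
        recovered_sources & set(spacer_truth["source_virus"])
    )
    bundle.summary["crispr_sources_truth"] = spacer_truth["source_virus"].nunique()

    # --- variants ------------------------------------------------------
    focal = "virus_000"
    var_design = {
        "foam_1": [(101, "T", 0.3), (202, "C", 0.4), (303, "G", 0.5)],
        "aer_1": [(101, "T", 0.25), (202, "C", 0.35)],
        "rain_1": [(101, "T", 0.2)],
    }
    # alternate bases must differ from the simulated reference
    ref_seq = viruses[focal]
    var_design = {
        s: [(p, _other_base(ref_seq[p - 1]), f) for p, _, f in sites]
        for s, sites in var_design.items()
    }
    pileups, var_truth = synthetic.gen_variant_pileups(
        ref_seq, var_design, seed=derive_seed(config.seed, "variants"),
        scaffold_id=focal,
    )
    calls = {
        s: variants.call_variants(p, {focal: ref_seq}, sample_id=s)
        for s, p in pileups.items()
    }
    regions, site_table = variants.overlap_variants(calls)
    stage_counts["variants"] = int(sum(len(c) for c in calls.values()))
    bundle.tables["variant_sites"] = site_table
    bundle.summary["variant_triple_overlap"] = regions.get(
        frozenset(var_design), 0
    )

    # --- trajectories --------------------------------------------------
    tj_rows = []
    truth_tj = {}
    for event, (sea, loading) in {"event_1": (0.64, 0.10), "event_2": (0.72, 0.35)}.items():
        df, tt = synthetic.gen_trajectories(
            n_tj=5, sea_frac=sea, loading_frac=loading,
            seed=derive_seed(config.seed, f"tj_{event}"),
            window_hours=thr.trajectory_window_h,
        )
        df["traj_id"] = event + "_" + df["traj_id"]
        tj_rows.append(df)
        truth_tj.update({tid: event for tid in (event + "_" + tt["traj_id"])})
    tj_df = pd.concat(tj_rows, ignore_index=True)
    tj_summary = traj_mod.event_summary(
        tj_df, events=truth_tj,
        window_hours=thr.trajectory_window_h, wind_threshold=thr.loading_wind_ms,
    )
    stage_counts["trajectories"] = len(tj_summary)
    bundle.tables["trajectory_summary"] = tj_summary

    # --- INP -----------------------------------------------------------
    temps = np.round(np.arange(-5.0, -15.0001, -0.1), 1)
    lam = 2.0 * (np.exp(0.45 * (-5.0 - temps)) - 1.0) / 80.0
    spectrum = pd.DataFrame({"temperature": temps, "inp_per_well": lam})
    assay_df, inp_truth = synthetic.gen_freezing_assay(
        spectrum, seed=derive_seed(config.seed, "inp")
    )
    assay = field_stats.FreezingAssay(
        temperatures=assay_df["temperature"].to_numpy(),
        frozen=assay_df["frozen"].to_numpy(),
        total_wells=int(assay_df["total"].iloc[0]),
    )
    inp = field_stats.inp_spectrum(assay)
    stage_counts["inp"] = len(inp)
    bundle.tables["inp_spectrum"] = inp

    # --- field statistics on the bundled station table -----------------
    counts = datasets.station_counts()
    ef = field_stats.ef_table(counts)
    vhr = field_stats.virus_host_ratio_table(counts)
    euk, vlp = datasets.sml_pairs("euk_sml", "vlp_sml")
    corr = field_stats.correlate(euk, vlp, "pearson")
    stage_counts["field_stats"] = len(ef)
    bundle.tables["ef_table"] = ef
    bundle.tables["virus_host_ratios"] = vhr
    bundle.summary["sml_euk_vlp_pearson_r"] = round(corr.corr, 3)

    # --- manifest ------------------------------------------------------
    bundle.manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_counts": stage_counts,
        "valid": True,
    }
    return bundle


def _other_base(ref: str) -> str:
    return {"A": "G", "C": "T", "G": "A", "T": "C"}[ref.upper()]


def write_report(bundle: ReportBundle, out_dir) -> list[Path]:
    """Write every table as TSV plus a JSON summary/manifest.

    Floating-point cells are written at 10 significant digits with a '.'
    decimal separator; re-running an identical config reproduces
    byte-identical files.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable directory
        raise VirocycleError(f"cannot create output directory {out}: {exc}") from exc
    written: list[Path] = []
    for name, table in bundle.tables.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    summary = {
        "summary": bundle.summary,
        "manifest": bundle.manifest,
        "tables": {name: len(t) for name, t in bundle.tables.items()},
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=_json_default))
    written.append(path)
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def checksum_outputs(paths) -> dict[str, str]:
    """SHA-256 per written file, for determinism checks."""
    return {
        Path(p).name: hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in paths
    }
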