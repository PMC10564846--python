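"""Ground-truth-bearing synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the analysis assumes —
an ecosystem-structured viral community with a marine core, a small
air/rain overlap, and a rain-only subset with elevated G/C; partial
genome coverage with read identities spread around the 90 % cut; CRISPR
cassettes whose spacers derive from the simulated viruses at 0/10/20 %
divergence; trajectories with prescribed sea-time and loading fractions;
Poisson freezing assays from a prescribed INP spectrum; and station
count tables with prescribed Pearson correlations.  Every generator is
seed-deterministic and returns its truth table alongside the data.

Host and virus genomes are drawn from per-host order-4 Markov chains:
the d2* statistic removes the fitted order-2 background, so the
detectable host signal must live in the higher-order word structure that
an order-4 chain provides.  Each transition row is renormalized so that
the G+C emission probability equals the class target exactly, which pins
realized G/C to the target irrespective of the chain's perturbations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .crispr import reverse_complement
from .errors import ParameterError, ValidationError

_BASES = np.array(list("ACGT"))

#: Default G/C targets per class, anchored to the observed spread of marine
#: viral scaffolds (~0.35-0.47) versus the rain-only subset (~0.60).
DEFAULT_GC_BY_CLASS = {"marine": 0.40, "rain_only": 0.60}


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------


def _markov_transition(
    gc: float, k_signal: float, rng: np.random.Generator, order: int = 4
) -> np.ndarray:
    """Per-host order-``order`` transition matrix with exact G/C emission.

    Rows start from the class base composition, get a log-normal
    perturbation of scale ``k_signal`` (the host signature), and are then
    rescaled so every row emits G or C with probability exactly ``gc``.
    """
    if not (0.0 < gc < 1.0):
        raise ParameterError(f"infeasible G/C target {gc}")
    n_ctx = 4**order
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    p = base * np.exp(k_signal * rng.standard_normal((n_ctx, 4)))
    gc_mass = p[:, 1] + p[:, 2]
    at_mass = p[:, 0] + p[:, 3]
    p[:, [1, 2]] *= (gc / gc_mass)[:, None]
    p[:, [0, 3]] *= ((1 - gc) / at_mass)[:, None]
    return p


def _sample_chain(
    trans: np.ndarray, length: int, rng: np.random.Generator, order: int = 4
) -> np.ndarray:
    """Sample an integer-coded sequence from an order-r chain."""
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    seq = np.empty(length, dtype=np.int64)
    # seed the first `order` bases from the row-averaged composition
    comp = np.cumsum(trans.mean(axis=0))
    ctx = 0
    for i in range(length):
        if i < order:
            b = int(np.searchsorted(comp, u[i] * comp[-1], side="right"))
        else:
            b = int(np.searchsorted(cum[ctx], u[i] * cum[ctx, -1], side="right"))
        b = min(b, 3)
        seq[i] = b
        ctx = (ctx * 4 + b) % (4**order)
    return seq


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    n_mut = int(round(rate * codes.size))
    if n_mut == 0:
        return out
    pos = rng.choice(codes.size, size=n_mut, replace=False)
    shift = rng.integers(1, 4, size=n_mut)
    out[pos] = (out[pos] + shift) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


@dataclass
class GenomeTruth:
    viruses: pd.DataFrame  # virus, host, class, gc_target, gc_realized, length
    hosts: pd.DataFrame    # host, class, gc_target, length


def gen_genomes(
    n_viral: int,
    n_host: int,
    gc_by_class: Optional[Mapping[str, float]] = None,
    k_signal: float = 1.0,
    seed: int = 0,
    viral_length_range: tuple[int, int] = (10_000, 50_000),
    host_length: int = 40_000,
    mutation_rate: float = 0.05,
    class_of_virus: Optional[Sequence[str]] = None,
    markov_order: int = 4,
) -> tuple[dict[str, str], dict[str, str], GenomeTruth]:
    """Simulate host genomes and host-derived viral scaffolds.

    Hosts cycle through the G/C classes; each virus is resampled from its
    true host's chain (hosts assigned round-robin within the virus's
    class) and then point-mutated at ``mutation_rate``.  Viral lengths are
    uniform over ``viral_length_range`` (>10 kb, the catalog cut-off).
    """
    if n_viral < 1 or n_host < 1:
        raise ParameterError("need at least one virus and one host")
    gc_by_class = dict(gc_by_class or DEFAULT_GC_BY_CLASS)
    for cls, gc in gc_by_class.items():
        if not (0.0 < gc < 1.0):
            raise ParameterError(f"infeasible G/C target {gc} for class {cls}")
    classes = list(gc_by_class)
    rng = np.random.default_rng(seed)

    host_rows, hosts = [], {}
    host_trans = {}
    hosts_of_class: dict[str, list[str]] = {c: [] for c in classes}
    for h in range(n_host):
        cls = classes[h % len(classes)]
        hid = f"host_{h:03d}"
        trans = _markov_transition(gc_by_class[cls], k_signal, rng, markov_order)
        codes = _sample_chain(trans, host_length, rng, markov_order)
        hosts[hid] = _decode(codes)
        host_trans[hid] = trans
        hosts_of_class[cls].append(hid)
        host_rows.append(
            {"host": hid, "class": cls, "gc_target": gc_by_class[cls], "length": host_length}
        )

    virus_rows, viruses = [], {}
    per_class_counter = {c: 0 for c in classes}
    for v in range(n_viral):
        if class_of_virus is not None:
            cls = class_of_virus[v]
            if cls not in gc_by_class:
                raise ParameterError(f"virus class {cls!r} has no G/C target")
        else:
            cls = classes[v % len(classes)] if len(classes) > 1 else classes[0]
        pool = hosts_of_class[cls] or list(hosts)
        hid = pool[per_class_counter[cls] % len(pool)] if cls in per_class_counter else pool[0]
        per_class_counter[cls] = per_class_counter.get(cls, 0) + 1
        length = int(rng.integers(viral_length_range[0], viral_length_range[1] + 1))
        codes = _sample_chain(host_trans[hid], length, rng, markov_order)
        codes = _mutate(codes, mutation_rate, rng)
        vid = f"virus_{v:03d}"
        seq = _decode(codes)
        viruses[vid] = seq
        gc_real = (seq.count("G") + seq.count("C")) / length
        virus_rows.append(
            {
                "virus": vid,
                "host": hid,
                "class": cls,
                "gc_target": gc_by_class[cls],
                "gc_realized": gc_real,
                "length": length,
            }
        )
    truth = GenomeTruth(viruses=pd.DataFrame(virus_rows), hosts=pd.DataFrame(host_rows))
    return viruses, hosts, truth


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Read coverage / alignment tables
# ---------------------------------------------------------------------------


def gen_read_coverage(
    genome_lengths: Mapping[str, int],
    design: pd.DataFrame,
    seed: int = 0,
    read_length: int = 150,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Emit alignment-record tables realizing a coverage design.

    ``design`` rows: target, sample, breadth, identity (and optionally
    depth, default 1).  The first ``round(breadth * L)`` bases are tiled
    with non-overlapping reads whose edit distance realizes the requested
    identity, so realized breadth matches the design to within one read.
    The returned truth table adds the presence call expected under the
    default thresholds (identity >= 0.90, breadth >= 0.75).
    """
    for t in design["target"].unique():
        if t not in genome_lengths:
            raise ValidationError(f"design references unknown genome {t!r}")
    rng = np.random.default_rng(seed)
    by_sample: dict[str, list[dict]] = {}
    truth_rows = []
    for _, row in design.iterrows():
        target, sample = row["target"], row["sample"]
        breadth, ident = float(row["breadth"]), float(row["identity"])
        depth = int(row["depth"]) if "depth" in row.index and not pd.isna(row.get("depth")) else 1
        length = genome_lengths[target]
        covered = int(round(breadth * length))
        rows = by_sample.setdefault(sample, [])
        i = 0
        for _ in range(depth):
            pos = 0
            while pos < covered:
                alen = min(read_length, covered - pos)
                rows.append(
                    {
                        "read_id": f"{sample}:{target}:{i}",
                        "target_id": target,
                        "start": pos,
                        "aligned_length": alen,
                        "edit_distance": int(round((1.0 - ident) * alen)),
                    }
                )
                pos += alen
                i += 1
        realized_breadth = covered / length
        truth_rows.append(
            {
                "target": target,
                "sample": sample,
                "breadth": realized_breadth,
                "identity": ident,
                "expected_present": ident >= 0.90 and realized_breadth >= 0.75,
            }
        )
    columns = ["read_id", "target_id", "start", "aligned_length", "edit_distance"]
    aln = {
        s: pd.DataFrame(rows, columns=columns) for s, rows in by_sample.items()
    }
    return aln, pd.DataFrame(truth_rows)


def design_from_occupancy(
    occupancy: Mapping[str, Sequence[str]],
    samples_by_ecosystem: Mapping[str, Sequence[str]],
    seed: int = 0,
    breadth_range: tuple[float, float] = (0.80, 0.95),
    identity_range: tuple[float, float] = (0.95, 1.00),
) -> pd.DataFrame:
    """Coverage design realizing a truth occupancy map with noise off.

    ``occupancy`` maps virus id to the ecosystems it truly occupies; the
    virus receives qualifying coverage in every sample of each occupied
    ecosystem and no coverage elsewhere.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for virus, ecosystems in occupancy.items():
        for eco in ecosystems:
            for sample in samples_by_ecosystem.get(eco, ()):  # controls absent
                rows.append(
                    {
                        "target": virus,
                        "sample": sample,
                        "breadth": float(rng.uniform(*breadth_range)),
                        "identity": float(rng.uniform(*identity_range)),
                    }
                )
    return pd.DataFrame(rows, columns=["target", "sample", "breadth", "identity"])


# ---------------------------------------------------------------------------
# CRISPR cassettes
# ---------------------------------------------------------------------------


def gen_crispr_reads(
    hosts: Mapping[str, str],
    viruses: Mapping[str, str],
    n_spacers: int = 10,
    divergences: Sequence[float] = (0.0,),
    dr_length: int = 25,
    spacer_length: int = 30,
    n_negative_reads: int = 5,
    seed: int = 0,
) -> tuple[list[str], str, pd.DataFrame]:
    """Reads carrying DR-spacer-DR cassettes with known spacer provenance.

    Spacers are verbatim substrings of the simulated viral genomes with a
    per-spacer divergence applied as ``round(div * length)`` point
    mutations, so a 0.2 divergence lands exactly on the 80 % identity
    boundary.  The consensus DR is generated to occur in no viral
    scaffold (on either strand).  Negative reads contain no DR.
    """
    if dr_length < 16:
        raise ParameterError("direct repeat must be >= 16 bp")
    if not (20 <= spacer_length <= 60):
        raise ParameterError("spacer length must lie in [20, 60]")
    rng = np.random.default_rng(seed)
    vids = sorted(viruses)
    # DR absent from every scaffold, either strand
    for _ in range(1000):
        dr = "".join(rng.choice(list("ACGT"), size=dr_length))
        rc = reverse_complement(dr)
        if not any(dr in v or rc in v for v in viruses.values()):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise ValidationError("could not construct a scaffold-free DR")

    reads, rows = [], []
    for i in range(n_spacers):
        vid = vids[i % len(vids)]
        seq = viruses[vid]
        start = int(rng.integers(0, len(seq) - spacer_length))
        proto = seq[start : start + spacer_length]
        div = float(divergences[i % len(divergences)])
        n_mut = int(round(div * spacer_length))
        codes = np.array([("ACGT").index(b) for b in proto])
        if n_mut:
            pos = rng.choice(spacer_length, size=n_mut, replace=False)
            codes[pos] = (codes[pos] + rng.integers(1, 4, size=n_mut)) % 4
        spacer = "".join("ACGT"[c] for c in codes)
        reads.append(dr + spacer + dr)
        rows.append(
            {
                "spacer_id": f"truth_{i}",
                "spacer": spacer,
                "source_virus": vid,
                "position": start,
                "divergence": div,
                "identity": 1.0 - n_mut / spacer_length,
            }
        )
    for _ in range(n_negative_reads):
        reads.append("".join(rng.choice(list("ACGT"), size=3 * dr_length)))
    return reads, dr, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def gen_trajectories(
    n_tj: int,
    sea_frac: float,
    loading_frac: float,
    seed: int = 0,
    window_hours: int = 96,
    total_hours: int = 120,
    loading_over_land: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hourly backward trajectories with exact prescribed fractions.

    Within the first ``window_hours`` points of every trajectory the
    realized sea and loading fractions equal the prescribed values exactly
    (counts rounded to integers); loading points are a subset of sea
    points unless ``loading_over_land`` is enabled.
    """
    for name, v in (("sea_frac", sea_frac), ("loading_frac", loading_frac)):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name}={v} outside [0, 1]")
    n_sea = int(round(sea_frac * window_hours))
    n_loading = int(round(loading_frac * window_hours))
    if n_loading > n_sea and not loading_over_land:
        raise ParameterError(
            "loading fraction exceeds sea fraction; enable loading_over_land to allow"
        )
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for t in range(n_tj):
        tid = f"tj_{t:03d}"
        sea_idx = set(rng.choice(window_hours, size=n_sea, replace=False).tolist())
        loading_pool = (
            np.arange(window_hours)
            if loading_over_land
            else np.array(sorted(sea_idx), dtype=int)
        )
        loading_idx = set(
            rng.choice(loading_pool, size=n_loading, replace=False).tolist()
        ) if n_loading else set()
        lat, lon = 58.9, 11.0
        for h in range(total_hours):
            lat += float(rng.normal(0, 0.2))
            lon += float(rng.normal(0, 0.3))
            sea = h in sea_idx if h < window_hours else False
            loading = h in loading_idx if h < window_hours else False
            rows.append(
                {
                    "traj_id": tid,
                    "hours_before": h,
                    "lat": round(lat, 4),
                    "lon": round(lon, 4),
                    "altitude": 100.0 if loading else 1500.0,
                    "blh": 1000.0,
                    "wind": 5.0 if loading else 2.0,
                    "land": not sea,
                }
            )
        truth_rows.append(
            {
                "traj_id": tid,
                "sea_fraction": n_sea / window_hours,
                "loading_fraction": n_loading / window_hours,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Freezing assays
# ---------------------------------------------------------------------------


def gen_freezing_assay(
    spectrum: pd.DataFrame,
    wells: int = 24,
    v_well_ul: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate cumulative frozen-well counts from a prescribed INP spectrum.

    ``spectrum`` has columns ``temperature`` (degrees C, 0.1 K cadence) and
    ``inp_per_well`` (cumulative expected INP per well, nondecreasing with
    cooling).  At each 0.1 K step every still-liquid well freezes with
    probability 1 - exp(-delta_lambda), the Poisson probability that the
    incremental expected INP count is nonzero.
    """
    if wells < 1:
        raise ParameterError("need at least one well")
    lam = np.asarray(spectrum["inp_per_well"], dtype=float)
    temps = np.asarray(spectrum["temperature"], dtype=float)
    order = np.argsort(temps)[::-1]  # warm -> cold
    lam, temps = lam[order], temps[order]
    if (lam < 0).any():
        raise ParameterError("negative INP spectrum values")
    if np.any(np.diff(lam) < 0):
        raise ParameterError("cumulative INP spectrum must be nondecreasing with cooling")
    rng = np.random.default_rng(seed)
    frozen = np.zeros(lam.size, dtype=int)
    n_frozen = 0
    prev = 0.0
    for i, l in enumerate(lam):
        d = l - prev
        prev = l
        p = 1.0 - math.exp(-d)
        n_frozen += int(rng.binomial(wells - n_frozen, p)) if n_frozen < wells else 0
        frozen[i] = n_frozen
    assay = pd.DataFrame({"temperature": temps, "frozen": frozen, "total": wells})
    truth = pd.DataFrame(
        {"temperature": temps, "inp_per_well": lam, "c_well_per_ml": lam / (v_well_ul / 1000.0)}
    )
    return assay, truth


# ---------------------------------------------------------------------------
# Station count tables
# ---------------------------------------------------------------------------

_SPECIMENS = ("vlp", "prok", "euk")
_DEFAULT_MEANS = {"vlp": 2.0e7, "prok": 8.0e5, "euk": 4.0e3}


def gen_count_table(
    n_stations: int,
    target_corr: Optional[Mapping[tuple[str, str], float]] = None,
    seed: int = 0,
    means: Optional[Mapping[str, float]] = None,
    cv: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal station counts with prescribed pairwise Pearson targets.

    The Pearson targets apply to the counts themselves; they are mapped to
    the latent Gaussian correlation via the exact log-normal moment
    relation (all specimens share the coefficient of variation ``cv``, so
    a target of 1.0 yields exactly collinear columns).  SML and SSW
    compartments are generated independently with the same structure.
    """
    if n_stations < 2:
        raise ParameterError("need at least two stations")
    means = dict(means or _DEFAULT_MEANS)
    targets = dict(target_corr or {})
    a2 = math.log1p(cv * cv)  # variance of the latent normal
    corr_z = np.eye(3)
    for i, si in enumerate(_SPECIMENS):
        for j, sj in enumerate(_SPECIMENS):
            if i >= j:
                continue
            rho_x = targets.get((si, sj), targets.get((sj, si), 0.0))
            arg = 1.0 + rho_x * math.expm1(a2)
            if arg <= 0:
                raise ParameterError(f"infeasible Pearson target {rho_x} at cv={cv}")
            rho_z = math.log(arg) / a2
            if abs(rho_z) > 1.0 + 1e-12:
                raise ParameterError(f"infeasible Pearson target {rho_x} at cv={cv}")
            corr_z[i, j] = corr_z[j, i] = min(1.0, max(-1.0, rho_z))
    vals, vecs = np.linalg.eigh(corr_z)
    if vals.min() < -1e-9:
        raise ParameterError("correlation targets are not positive semi-definite")
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0, None)))
    rng = np.random.default_rng(seed)
    a = math.sqrt(a2)
    data = {"station": [str(i + 1) for i in range(n_stations)],
            "date": ["2020-02-01"] * n_stations}
    for comp in ("sml", "ssw"):
        z = rng.standard_normal((n_stations, 3)) @ root.T
        for j, spec in enumerate(_SPECIMENS):
            data[f"{spec}_{comp}"] = means[spec] * np.exp(a * z[:, j] - a2 / 2.0)
    df = pd.DataFrame(data)
    for spec in _SPECIMENS:
        df[f"{spec}_foam"] = np.nan
        if spec != "euk":
            df[f"{spec}_prc"] = np.nan
    truth_rows = [
        {
            "pair": f"{si}-{sj}",
            "target": targets.get((si, sj), targets.get((sj, si), 0.0)),
            "latent": corr_z[i, j],
        }
        for i, si in enumerate(_SPECIMENS)
        for j, sj in enumerate(_SPECIMENS)
        if i < j
    ]
    return df, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Variant pileups (haplotype mixtures)
# ---------------------------------------------------------------------------


def gen_variant_pileups(
    reference: str,
    variants_by_sample: Mapping[str, Sequence[tuple[int, str, float]]],
    depth: int = 100,
    seed: int = 0,
    scaffold_id: str = "virus_000",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Deterministic pileups realizing known variant sites per sample.

    ``variants_by_sample`` maps sample id to (1-based position, alternate
    base, alternate frequency) triples; every other position is
    monomorphic reference at the given depth.  Alternate counts are
    rounded deterministically, so the construction truth is exact.
    """
    pileups = {}
    truth_rows = []
    all_pos = sorted({p for sites in variants_by_sample.values() for p, _, _ in sites})
    for sample, sites in variants_by_sample.items():
        site_map = {(p): (alt, f) for p, alt, f in sites}
        rows = []
        for pos in all_pos:
            if not (1 <= pos <= len(reference)):
                raise ValidationError(f"variant position {pos} outside reference")
            ref = reference[pos - 1].upper()
            counts = {b: 0 for b in "ACGT"}
            if pos in site_map:
                alt, f = site_map[pos]
                if alt == ref:
                    raise ValidationError("alternate equals reference base")
                n_alt = int(round(f * depth))
                counts[alt] = n_alt
                counts[ref] = depth - n_alt
                truth_rows.append(
                    {"sample": sample, "pos": pos, "ref": ref, "alt": alt,
                     "alt_freq": n_alt / depth}
                )
            else:
                counts[ref] = depth
            rows.append({"scaffold": scaffold_id, "pos": pos, **counts})
        pileups[sample] = pd.DataFrame(rows)
    return pileups, pd.DataFrame(truth_rows)
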