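"""Ecosystem-level synthesis of presence calls and abundances.

Occupancy sets per ecosystem, Venn region counts, exclusivity, shared
fractions, rain/aerosol enrichment ratios against sea-surface maxima,
G/C-content group comparisons (Kruskal-Wallis + Dunn), and community
diversity (Shannon, Bray-Curtis, PERMANOVA).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import ParameterError, ValidationError
from .samples import Ecosystem, SampleRecord

# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------


def occupancy_matrix(
    presence: pd.DataFrame,
    samples: Sequence[SampleRecord],
) -> pd.DataFrame:
    """Collapse a virus x sample presence matrix to virus x ecosystem.

    A virus occupies an ecosystem if it is present in any of that
    ecosystem's samples (OR aggregation).  Control samples never
    contribute.
    """
    eco_of = {}
    for rec in samples:
        if rec.is_control:
            continue
        eco_of[rec.sample_id] = rec.ecosystem.value
    unknown = [s for s in presence.columns if s not in eco_of]
    known = [s for s in presence.columns if s in eco_of]
    if not known and unknown:
        raise ValidationError(f"no sample in the sheet matches presence columns {unknown}")
    for s in unknown:
        # column must belong to a control or be absent from the sheet
        if not any(r.sample_id == s for r in samples):
            raise ValidationError(f"presence column {s!r} has no sample-sheet entry")
    ecosystems = sorted({eco_of[s] for s in known})
    out = pd.DataFrame(False, index=presence.index, columns=ecosystems)
    for s in known:
        eco = eco_of[s]
        out[eco] = out[eco] | presence[s].astype(bool)
    return out


def ecosystem_venn(occupancy: pd.DataFrame, sets: Sequence[str]) -> dict[frozenset, int]:
    """Counts for every region of the Venn diagram over the given sets.

    Keys are frozensets naming the ecosystems a region belongs to (the
    exact membership pattern); the empty region is omitted, so counts sum
    to the number of viruses occupying at least one of the sets.
    """
    if len(sets) < 2:
        raise ValidationError("need at least two sets for a Venn partition")
    for s in sets:
        if s not in occupancy.columns:
            raise ValidationError(f"unknown ecosystem {s!r} in Venn request")
    sub = occupancy[list(sets)].astype(bool)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(sets, r):
            inside = sub[list(combo)].all(axis=1)
            outside_cols = [s for s in sets if s not in combo]
            if outside_cols:
                outside = ~sub[outside_cols].any(axis=1)
            else:
                outside = pd.Series(True, index=sub.index)
            regions[frozenset(combo)] = int((inside & outside).sum())
    return regions


def exclusive_viruses(occupancy: pd.DataFrame, ecosystem: str) -> list[str]:
    """Viruses detected in the named ecosystem and nowhere else."""
    if ecosystem not in occupancy.columns:
        raise ValidationError(f"unknown ecosystem {ecosystem!r}")
    others = [c for c in occupancy.columns if c != ecosystem]
    mask = occupancy[ecosystem] & ~occupancy[others].any(axis=1)
    return list(occupancy.index[mask])


def shared_fraction(
    occupancy: pd.DataFrame,
    set_a: Sequence[str],
    set_b: Sequence[str],
    total: int,
) -> tuple[float, int]:
    """Percentage of the catalog occupying both set A and set B.

    Returns (percentage, shared count); the percentage uses the full
    dereplicated catalog size as denominator and is displayed at one
    decimal by callers.
    """
    if total < 1:
        raise ValidationError("total must be >= 1")
    in_a = occupancy[list(set_a)].any(axis=1)
    in_b = occupancy[list(set_b)].any(axis=1)
    shared = int((in_a & in_b).sum())
    return 100.0 * shared / total, shared


# ---------------------------------------------------------------------------
# Enrichment ratios (rain/aerosol over foam/SML ecosystem maxima)
# ---------------------------------------------------------------------------

_DEFAULT_PAIRINGS = (
    ("rain", "foam"),
    ("rain", "SML"),
    ("aerosol", "foam"),
    ("aerosol", "SML"),
)


def enrichment_ratios(
    abundance: pd.DataFrame,
    samples: Sequence[SampleRecord],
    pairings: Sequence[tuple[str, str]] = _DEFAULT_PAIRINGS,
    denominator_fractions: Sequence[str] = ("um5_02", "virome_lt02um"),
) -> pd.DataFrame:
    """Per-virus coverage ratios of atmospheric over sea-surface maxima.

    The numerator is the maximum sum-normalized coverage of the virus
    across all samples of the atmospheric ecosystem (rain or aerosol); the
    denominator is the maximum across the sea-surface ecosystem's samples
    of the stated size fraction.  The maximum is taken as the highest
    possible abundance of the virus in that ecosystem.  A ratio is
    undefined (NaN) when either side has no detection; the reported flag
    marks ratios >= 1.
    """
    by_eco_frac: dict[tuple[str, str], list[str]] = {}
    by_eco: dict[str, list[str]] = {}
    for rec in samples:
        if rec.is_control or rec.sample_id not in abundance.columns:
            continue
        by_eco.setdefault(rec.ecosystem.value, []).append(rec.sample_id)
        by_eco_frac.setdefault((rec.ecosystem.value, rec.fraction.value), []).append(
            rec.sample_id
        )
    rows = []
    for num_eco, den_eco in pairings:
        num_cols = by_eco.get(num_eco, [])
        for frac in denominator_fractions:
            den_cols = by_eco_frac.get((den_eco, frac), [])
            if not num_cols or not den_cols:
                continue
            num_max = abundance[num_cols].max(axis=1)
            den_max = abundance[den_cols].max(axis=1)
            ratio = np.where((num_max > 0) & (den_max > 0), num_max / den_max, np.nan)
            for virus, r in zip(abundance.index, ratio):
                rows.append(
                    {
                        "virus": virus,
                        "pairing": f"{num_eco[0].upper()}/{'S' if den_eco == 'SML' else 'F'}",
                        "denominator_fraction": frac,
                        "ratio": r,
                        "reported": bool(r >= 1.0) if np.isfinite(r) else False,
                    }
                )
    return pd.DataFrame(rows, columns=["virus", "pairing", "denominator_fraction", "ratio", "reported"])


# ---------------------------------------------------------------------------
# G/C content
# ---------------------------------------------------------------------------


def gc_percent(sequence: str) -> float:
    """Percent G+C over unambiguous bases; ambiguity codes are excluded."""
    if not sequence:
        raise ValidationError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValidationError("sequence has no unambiguous A/C/G/T bases")
    return 100.0 * gc / (gc + at)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn's post hoc
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    h: float
    df: int
    p: float
    dunn: pd.DataFrame  # pair_a, pair_b, z, p_raw, p_adj


def compare_groups_kw_dunn(
    values_by_group: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise z post hoc.

    Dunn's z uses rank means over the pooled average-rank transform with
    the tie-corrected pooled variance; adjusted p multiplies the raw p by
    the number of comparisons (capped at 1).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2 or any(v.size == 0 for v in groups.values()):
        raise ValidationError("need >= 2 groups, each non-empty")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = st.kruskal(*groups.values())
    names = list(groups)
    ranks = st.rankdata(pooled)
    n_total = pooled.size
    # split ranks back into groups
    rank_means = {}
    i = 0
    for g in names:
        n_g = groups[g].size
        rank_means[g] = ranks[i : i + n_g].mean()
        i += n_g
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    s2 = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        s2 -= tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for ga, gb in pairs:
        na, nb = groups[ga].size, groups[gb].size
        se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
        z = (rank_means[ga] - rank_means[gb]) / se if se > 0 else 0.0
        p_raw = 2.0 * st.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        elif adjust == "none":
            p_adj = p_raw
        else:
            raise ParameterError(f"unknown adjustment {adjust!r}")
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p_raw": p_raw, "p_adj": p_adj})
    return GroupComparison(
        h=float(h), df=len(groups) - 1, p=float(p), dunn=pd.DataFrame(rows)
    )


def gc_group_table(
    gc_by_virus: Mapping[str, float],
    occupancy: pd.DataFrame,
    rain_only: Optional[Iterable[str]] = None,
) -> dict[str, np.ndarray]:
    """Assemble G/C values per detection group for the group comparison.

    A virus contributes its single catalog G/C value once per group it is
    detected in; ``rain_only`` (exclusively-rain viruses) is a subset of
    the rain_total group.
    """
    groups: dict[str, list[float]] = {}
    for eco in occupancy.columns:
        key = "rain_total" if eco == "rain" else eco
        vals = [gc_by_virus[v] for v in occupancy.index[occupancy[eco]] if v in gc_by_virus]
        if vals:
            groups[key] = vals
    if rain_only is None and "rain" in occupancy.columns:
        rain_only = exclusive_viruses(occupancy, "rain")
    if rain_only:
        vals = [gc_by_virus[v] for v in rain_only if v in gc_by_virus]
        if vals:
            groups["rain_only"] = vals
    return {g: np.asarray(v) for g, v in groups.items()}


# ---------------------------------------------------------------------------
# Diversity: Shannon, Bray-Curtis, PERMANOVA
# ---------------------------------------------------------------------------


def shannon(counts: Sequence[float]) -> float:
    """Shannon-Wiener H' (natural log) on relative abundances."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundances")
    total = x.sum()
    if total == 0:
        raise ValidationError("sample with zero total abundance")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between rows (samples)."""
    x = matrix.to_numpy(dtype=float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(den > 0, num / den, 0.0)
    return pd.DataFrame(bc, index=matrix.index, columns=matrix.index)


def permanova(
    distances: pd.DataFrame,
    grouping: Sequence,
    permutations: int = 999,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F with a label-permutation p-value.

    pseudo-F = (SS_between / (g-1)) / (SS_within / (n-g)) computed from
    squared distances; p = (#{F_perm >= F_obs} + 1) / (permutations + 1).
    """
    d2 = distances.to_numpy(dtype=float) ** 2
    labels = np.asarray(grouping)
    n = d2.shape[0]
    if labels.size != n:
        raise ValidationError("grouping length must match distance matrix")
    uniq = np.unique(labels)
    g = uniq.size
    if g < 2:
        raise ValidationError("need >= 2 groups for PERMANOVA")
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def ss_within(lbl: np.ndarray) -> float:
        ss = 0.0
        for u in uniq:
            idx = np.flatnonzero(lbl == u)
            if idx.size > 1:
                sub = d2[np.ix_(idx, idx)]
                ss += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        return ss

    ssw = ss_within(labels)
    ssb = ss_total - ssw
    f_obs = (ssb / (g - 1)) / (ssw / (n - g)) if ssw > 0 else np.inf

    rng = rng or np.random.default_rng()
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        ssw_p = ss_within(perm)
        ssb_p = ss_total - ssw_p
        f_p = (ssb_p / (g - 1)) / (ssw_p / (n - g)) if ssw_p > 0 else np.inf
        if f_p >= f_obs:
            count += 1
    p = (count + 1) / (permutations + 1)
    return float(f_obs), float(p)


@dataclass
class DiversityResult:
    shannon: pd.Series
    bray_curtis: pd.DataFrame
    permanova_f: float
    permanova_p: float


def diversity_suite(
    abundance: pd.DataFrame,
    grouping: Mapping[str, str],
    permutations: int = 999,
    rng: Optional[np.random.Generator] = None,
) -> DiversityResult:
    """Alpha diversity, Bray-Curtis matrix, and PERMANOVA over samples.

    ``abundance`` is samples x taxa (nonnegative); samples with zero total
    are excluded with a warning-level effect (dropped from all outputs).
    """
    totals = abundance.sum(axis=1)
    kept = abundance[totals > 0]
    h = kept.apply(shannon, axis=1)
    rel = kept.div(kept.sum(axis=1), axis=0)
    bc = bray_curtis(rel)
    labels = [grouping[s] for s in kept.index]
    f, p = permanova(bc, labels, permutations=permutations, rng=rng)
    return DiversityResult(shannon=h, bray_curtis=bc, permanova_f=f, permanova_p=p)
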