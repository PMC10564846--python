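"""Frequency-based SNP calling from pileup counts and cross-sample overlap.

Variant analysis supports the dispersal argument: a virus whose reads in
foam, aerosol, and rain carry the same nucleotide polymorphisms at the
same positions is the same viral population travelling between
ecosystems.  Thresholds are explicit and conservative (depth >= 10,
alternate frequency >= 0.10, alternate count >= 4); substitutions only.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

_BASES = ("A", "C", "G", "T")


def read_pileup(path) -> pd.DataFrame:
    """Read a pileup TSV: scaffold, 1-based position, A, C, G, T counts."""
    df = pd.read_csv(path, sep="\t")
    expected = {"scaffold", "pos", "A", "C", "G", "T"}
    if not expected.issubset(df.columns):
        raise ValidationError(f"pileup table missing columns {expected - set(df.columns)}")
    return df


def call_variants(
    pileup: pd.DataFrame,
    reference: Mapping[str, str],
    sample_id: str = "",
    min_depth: int = 10,
    min_alt_freq: float = 0.10,
    min_alt_count: int = 4,
) -> pd.DataFrame:
    """Emit substitution calls from per-position base counts.

    The reference base comes from the scaffold sequence (not the pileup
    majority).  At each column with depth >= ``min_depth``, every
    non-reference base with frequency >= ``min_alt_freq`` and count >=
    ``min_alt_count`` becomes a call.
    """
    rows = []
    for _, col in pileup.iterrows():
        counts = {b: int(col[b]) for b in _BASES}
        depth = sum(counts.values())
        if "depth" in col.index and not pd.isna(col["depth"]) and int(col["depth"]) != depth:
            raise ValidationError(
                f"stated depth differs from base-count sum at {col['scaffold']}:{col['pos']}"
            )
        scaffold = col["scaffold"]
        pos = int(col["pos"])
        if scaffold not in reference:
            raise ValidationError(f"no reference sequence for scaffold {scaffold}")
        ref_seq = reference[scaffold]
        if not (1 <= pos <= len(ref_seq)):
            raise ValidationError(f"position {pos} outside scaffold {scaffold}")
        ref = ref_seq[pos - 1].upper()
        if depth < min_depth:
            continue
        for base in _BASES:
            if base == ref:
                continue
            c = counts[base]
            freq = c / depth
            if c >= min_alt_count and freq >= min_alt_freq:
                rows.append(
                    {
                        "scaffold": scaffold,
                        "pos": pos,
                        "ref": ref,
                        "alt": base,
                        "alt_freq": freq,
                        "alt_count": c,
                        "sample": sample_id,
                    }
                )
    return pd.DataFrame(
        rows, columns=["scaffold", "pos", "ref", "alt", "alt_freq", "alt_count", "sample"]
    )


def overlap_variants(
    calls_by_sample: Mapping[str, pd.DataFrame],
) -> tuple[dict[frozenset, int], pd.DataFrame]:
    """Venn region counts and per-site membership over variant call sets.

    A site is shared between samples when position and alternate base are
    both identical (same scaffold coordinate system required).
    """
    scaffolds = set()
    site_sets: dict[str, set] = {}
    for sample, calls in calls_by_sample.items():
        if len(calls):
            scaffolds.update(calls["scaffold"].unique())
        site_sets[sample] = set(zip(calls["pos"], calls["alt"])) if len(calls) else set()
    if len(scaffolds) > 1:
        raise ValidationError(f"variant overlap across mixed scaffolds: {sorted(scaffolds)}")
    samples = list(calls_by_sample)
    all_sites = sorted(set().union(*site_sets.values()))
    membership = {
        site: frozenset(s for s in samples if site in site_sets[s]) for site in all_sites
    }
    regions: dict[frozenset, int] = {}
    for r in range(1, len(samples) + 1):
        for combo in itertools.combinations(samples, r):
            key = frozenset(combo)
            regions[key] = sum(1 for m in membership.values() if m == key)
    table = pd.DataFrame(
        [
            {
                "pos": pos,
                "alt": alt,
                **{s: (pos, alt) in site_sets[s] for s in samples},
                "n_samples": len(membership[(pos, alt)]),
            }
            for pos, alt in all_sites
        ]
    )
    return regions, table
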