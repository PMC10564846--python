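"""CRISPR direct-repeat-guided spacer extraction and protospacer matching.

Spacers are read out of raw reads between consecutive occurrences of an
array's consensus direct repeat (DR; Hamming matching, <=3 mismatches,
no indels), length- and homopolymer-filtered (20-60 bp), clustered at
99 % identity, then matched against viral scaffolds by an exhaustive
ungapped scan with an inclusive 80 % identity cut-off.  The scan is
exact at desk scale, unlike the seeded short-read heuristic a BLAST run
would use, so borderline gapped hits may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .kmer import encode
from .samples import Ecosystem, SampleRecord

_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class CrisprArray:
    array_id: str
    dr: str                      # consensus direct repeat, >=16 bp
    source_sample: Optional[str] = None
    evidence_level: int = 4

    def __post_init__(self):
        if len(self.dr) < 16:
            raise ParameterError(
                f"direct repeat of array {self.array_id} shorter than 16 bp"
            )
        if set(self.dr.upper()) - set("ACGT"):
            raise ValidationError(f"ambiguous bases in DR of array {self.array_id}")


def hamming_hits(sequence: str, pattern: str, max_mismatch: int) -> list[int]:
    """Start positions where pattern matches with <= max_mismatch substitutions."""
    s = encode(sequence)
    p = encode(pattern)
    m = p.size
    n = s.size - m + 1
    if n <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = (windows != p).sum(axis=1)  # ambiguous bases count as mismatches
    return list(np.flatnonzero(mism <= max_mismatch))


def remove_viral_dr(
    arrays: Sequence[CrisprArray], scaffolds: Mapping[str, str]
) -> tuple[list[CrisprArray], list[str]]:
    """Drop arrays whose DR occurs verbatim (100 % identity) in any scaffold.

    Such repeats are likely viral in origin and would produce self-matches.
    Returns (kept arrays, dropped array ids).
    """
    kept, dropped = [], []
    upper = {sid: s.upper() for sid, s in scaffolds.items()}
    for arr in arrays:
        dr = arr.dr.upper()
        dr_rc = reverse_complement(dr)
        hit = any(dr in s or dr_rc in s for s in upper.values())
        (dropped if hit else kept).append(arr if not hit else arr.array_id)
    return kept, dropped


def extract_spacers(
    reads: Iterable[str],
    dr: str,
    max_mismatch: int = 3,
    max_spacer_len: int = 60,
) -> list[str]:
    """Substrings between consecutive DR hits in each read (both strands).

    DR hits allow up to ``max_mismatch`` substitutions (no indels); only
    inter-DR segments of length <= ``max_spacer_len`` are emitted, and
    partial cassettes at read ends are ignored.
    """
    m = len(dr)
    spacers: list[str] = []
    for read in reads:
        for strand_seq in (read, reverse_complement(read)):
            hits = hamming_hits(strand_seq, dr, max_mismatch)
            # greedy non-overlapping DR occurrences, left to right
            occ: list[int] = []
            for h in hits:
                if not occ or h >= occ[-1] + m:
                    occ.append(h)
            for a, b in zip(occ, occ[1:]):
                gap = strand_seq[a + m : b]
                if 0 < len(gap) <= max_spacer_len:
                    spacers.append(gap.upper())
    return spacers


def _is_homopolymeric(seq: str, max_base_frac: float = 0.90, max_run: int = 15) -> bool:
    s = seq.upper()
    n = len(s)
    if n == 0:
        return True
    if max(s.count(b) for b in "ACGT") >= max_base_frac * n:
        return True
    run, best = 1, 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best >= max_run


def _ungapped_identity(a: str, b: str) -> float:
    """Best ungapped identity between two spacers: matches / shorter length.

    All offsets of the shorter inside the longer are tried on both strands.
    """
    if len(a) > len(b):
        a, b = b, a
    best = 0
    ca = encode(a)
    for query in (ca, encode(reverse_complement(a))):
        cb = encode(b)
        wins = np.lib.stride_tricks.sliding_window_view(cb, query.size)
        best = max(best, int((wins == query).sum(axis=1).max()))
    return best / len(a)


def filter_and_cluster(
    spacers: Sequence[str],
    min_len: int = 20,
    max_len: int = 60,
    cluster_identity: float = 0.99,
) -> list[str]:
    """Length/homopolymer filter then greedy longest-first 99 % clustering.

    A spacer joins the first existing centroid with identity >=
    ``cluster_identity`` (matches over the shorter length at the best
    ungapped offset, either strand); otherwise it founds a new centroid.
    Returns the centroid sequences.
    """
    ok = [
        s.upper()
        for s in spacers
        if min_len <= len(s) <= max_len and not _is_homopolymeric(s)
    ]
    centroids: list[str] = []
    for s in sorted(set(ok), key=lambda x: (-len(x), x)):
        for c in centroids:
            if _ungapped_identity(s, c) >= cluster_identity:
                break
        else:
            centroids.append(s)
    return centroids


def match_protospacers(
    spacers: Sequence[str],
    scaffolds: Mapping[str, str],
    min_identity: float = 0.80,
) -> pd.DataFrame:
    """Full-length ungapped spacer-to-scaffold matches at >=80 % identity.

    Every offset on both strands of every scaffold is scored; identity =
    matches / spacer length.  All qualifying scaffolds are reported with
    the best-scoring position per (spacer, scaffold, strand best).
    """
    rows = []
    enc_scaffolds = {
        sid: (encode(s), encode(reverse_complement(s))) for sid, s in scaffolds.items()
    }
    for i, sp in enumerate(spacers):
        q = encode(sp)
        m = q.size
        for sid, (fwd, rev) in enc_scaffolds.items():
            best = None
            for strand, enc_s in (("+", fwd), ("-", rev)):
                if enc_s.size < m:
                    continue
                wins = np.lib.stride_tricks.sliding_window_view(enc_s, m)
                matches = (wins == q).sum(axis=1)
                j = int(np.argmax(matches))
                ident = matches[j] / m
                pos = j if strand == "+" else enc_s.size - m - j
                if best is None or ident > best[0]:
                    best = (ident, strand, pos, m - int(matches[j]))
            if best is not None and best[0] >= min_identity:
                rows.append(
                    {
                        "spacer_id": f"spacer_{i}",
                        "spacer": sp,
                        "scaffold": sid,
                        "strand": best[1],
                        "position": best[2],
                        "identity": float(best[0]),
                        "mismatches": best[3],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "spacer_id",
            "spacer",
            "scaffold",
            "strand",
            "position",
            "identity",
            "mismatches",
        ],
    )


def build_network(
    matches: pd.DataFrame,
    arrays_by_spacer: Mapping[str, CrisprArray],
    samples: Sequence[SampleRecord],
    scaffold_ecosystems: Mapping[str, frozenset],
) -> pd.DataFrame:
    """Bipartite spacer-origin -> scaffold edge list with ecosystem flags.

    ``scaffold_ecosystems`` maps scaffold id to the set of ecosystems the
    scaffold was detected in; an edge is flagged cross-ecosystem when the
    spacer's source ecosystem is disjoint from the scaffold's.
    """
    eco_of_sample = {r.sample_id: r.ecosystem.value for r in samples}
    rows = []
    for _, m in matches.iterrows():
        sp = m["spacer_id"]
        if sp not in arrays_by_spacer:
            raise ValidationError(f"match references unknown array for {sp}")
        arr = arrays_by_spacer[sp]
        src_eco = eco_of_sample.get(arr.source_sample)
        scaffold_ecos = {
            e.value if isinstance(e, Ecosystem) else e
            for e in scaffold_ecosystems.get(m["scaffold"], frozenset())
        }
        rows.append(
            {
                "array_id": arr.array_id,
                "spacer_id": sp,
                "scaffold": m["scaffold"],
                "identity": m["identity"],
                "array_ecosystem": src_eco,
                "scaffold_ecosystems": ",".join(sorted(scaffold_ecos)),
                "cross_ecosystem": src_eco is not None and src_eco not in scaffold_ecos,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "array_id",
            "spacer_id",
            "scaffold",
            "identity",
            "array_ecosystem",
            "scaffold_ecosystems",
            "cross_ecosystem",
        ],
    )
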