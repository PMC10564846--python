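"""Markov-background-corrected oligonucleotide dissimilarity (d2*).

Each sequence gets a k-mer profile (default k = 6) with expected word
counts under an order-r Markov model (default r = 2) fitted to the
sequence itself.  d2* measures the correlation of the background-centred
word counts between two sequences and maps it to a dissimilarity in
[0, 1]; virus-host assignment keeps pairs at d2* <= 0.3 and flags the
minimum-distance host per virus.

Counting runs over the sequence and its reverse complement (both-strand
convention) so the statistic is strand-insensitive.  A pseudocount on
transition and context counts keeps expectations positive on short
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedStatisticError, ValidationError

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def encode(sequence: str) -> np.ndarray:
    """Encode A/C/G/T to 0..3; ambiguity codes become -1 (skipped windows)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[arr]


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    valid = out >= 0
    out[valid] = _COMPLEMENT[out[valid]]
    return out


def _count_words(codes: np.ndarray, k: int) -> np.ndarray:
    """Count k-mer occurrences; windows containing ambiguous bases skipped."""
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(4**k, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        vals = vals * 4 + np.where(c >= 0, c, 0)
        valid &= c >= 0
    return np.bincount(vals[valid], minlength=4**k)


@dataclass
class KmerProfile:
    seq_id: str
    k: int
    r: int
    counts: np.ndarray    # observed word counts X_w, length 4^k
    expected: np.ndarray  # E_w under the fitted order-r background
    both_strands: bool = True

    @property
    def n_words(self) -> int:
        return int(self.counts.sum())


def kmer_profile(
    sequence: str,
    k: int = 6,
    r: int = 2,
    both_strands: bool = True,
    pseudocount: float = 0.5,
    seq_id: str = "",
) -> KmerProfile:
    """Observed and Markov-expected k-mer counts for one sequence.

    The order-r transition probabilities and the r-mer context marginal are
    fitted to the (both-strand) sequence with a pseudocount; expected counts
    are E_w = N * P(w) with N the number of counted words and P(w) the
    Markov word probability.
    """
    if r > k - 2:
        raise ParameterError(f"Markov order r={r} must be <= k-2 (k={k})")
    if len(sequence) <= k:
        raise ValidationError("sequence shorter than word length")
    codes = encode(sequence)
    strands = [codes]
    if both_strands:
        strands.append(reverse_complement_codes(codes))

    x = np.zeros(4**k, dtype=np.int64)
    trans = np.zeros((4**r, 4), dtype=np.float64)
    ctx_counts = np.zeros(4**r, dtype=np.float64)
    for s in strands:
        x += _count_words(s, k)
        t = _count_words(s, r + 1).reshape(4**r, 4)
        trans += t
        ctx_counts += _count_words(s, r) if r > 0 else np.array([s.size])

    trans = trans + pseudocount
    trans_p = trans / trans.sum(axis=1, keepdims=True)
    ctx_counts = ctx_counts + pseudocount
    ctx_p = ctx_counts / ctx_counts.sum()

    n_words = int(x.sum())
    words = np.arange(4**k, dtype=np.int64)
    ctx_mask = 4**r - 1
    # P(w) = P(first r bases) * prod over emissions of T[context, base]
    logp = np.log(ctx_p[words >> (2 * (k - r))] if r > 0 else np.full(4**k, 1.0))
    if r == 0:
        logp = np.zeros(4**k)
    for i in range(r, k):
        ctx = (words >> (2 * (k - i))) & ctx_mask
        base = (words >> (2 * (k - 1 - i))) & 3
        logp += np.log(trans_p[ctx, base])
    expected = n_words * np.exp(logp)
    return KmerProfile(
        seq_id=seq_id, k=k, r=r, counts=x, expected=expected, both_strands=both_strands
    )


def d2star(pa: KmerProfile, pb: KmerProfile) -> float:
    """d2* dissimilarity between two profiles, clamped to [0, 1].

    With centred counts Xt_w = X_w - E^A_w and Yt_w = Y_w - E^B_w:
    D2* = sum_w Xt_w Yt_w / sqrt(E^A_w E^B_w) and
    d2* = 0.5 * (1 - D2* / (||Xt/sqrt(E^A)|| * ||Yt/sqrt(E^B)||)).
    """
    if (pa.k, pa.r, pa.both_strands) != (pb.k, pb.r, pb.both_strands):
        raise ParameterError("profiles computed with different parameters")
    xa = pa.counts - pa.expected
    xb = pb.counts - pb.expected
    denom_a = np.sqrt(pa.expected)
    denom_b = np.sqrt(pb.expected)
    ua = xa / denom_a
    ub = xb / denom_b
    na = np.sqrt((ua * ua).sum())
    nb = np.sqrt((ub * ub).sum())
    if na == 0 or nb == 0:
        raise UndefinedStatisticError("zero normalization term in d2*")
    d2s = (ua * ub).sum()
    d = 0.5 * (1.0 - d2s / (na * nb))
    return float(min(1.0, max(0.0, d)))


def assign_hosts(
    virus_profiles: Mapping[str, KmerProfile],
    host_profiles: Mapping[str, KmerProfile],
    threshold: float = 0.30,
) -> pd.DataFrame:
    """All virus-host edges at d2* <= threshold, best edge flagged per virus.

    Ties on the minimum distance break by lexicographic host id.  An empty
    host set yields an empty edge table.
    """
    rows = []
    host_ids = sorted(host_profiles)
    for vid, vp in virus_profiles.items():
        dists = [(hid, d2star(vp, host_profiles[hid])) for hid in host_ids]
        passing = [(hid, d) for hid, d in dists if d <= threshold]
        if not passing:
            continue
        best_hid = min(passing, key=lambda t: (t[1], t[0]))[0]
        for hid, d in passing:
            rows.append(
                {"virus": vid, "host": hid, "d2star": d, "is_best": hid == best_hid}
            )
    return pd.DataFrame(rows, columns=["virus", "host", "d2star", "is_best"])
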