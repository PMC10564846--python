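"""Presence calling and normalized abundance from read alignments or depth tables.

The mapping contract for viral scaffolds is: reads aligned at >=90 %
identity; a scaffold counts as present in a sample when at least 75 % of
its positions carry depth >= 1 after the identity filter.  MAGs use a
stricter contract (>=98 % identity, >=90 % breadth).  Identity is defined
explicitly as (aligned_length - edit_distance) / aligned_length over the
aligned portion, which makes the mapper's score-function cut-off
inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Column convention for alignment record tables.
ALN_COLUMNS = ("read_id", "target_id", "start", "aligned_length", "edit_distance")


def identity(aln: pd.DataFrame) -> pd.Series:
    """Per-record alignment identity; soft-clipped bases are excluded."""
    if "edit_distance" not in aln.columns:
        raise ValidationError("alignment records lack edit_distance")
    return (aln["aligned_length"] - aln["edit_distance"]) / aln["aligned_length"]


def subtract_controls(aln: pd.DataFrame, control_read_ids: Iterable[str]) -> pd.DataFrame:
    """Drop every alignment whose read also mapped to a negative control."""
    ids = set(control_read_ids)
    if not ids:
        return aln
    keep = ~aln["read_id"].isin(ids)
    return aln[keep].reset_index(drop=True)


def filter_reads_by_identity(aln: pd.DataFrame, min_identity: float = 0.90) -> pd.DataFrame:
    """Keep alignments with identity >= min_identity (inclusive)."""
    if not (0.0 < min_identity <= 1.0):
        raise ValidationError(f"min_identity={min_identity} outside (0, 1]")
    return aln[identity(aln) >= min_identity].reset_index(drop=True)


@dataclass
class CoverageProfile:
    """Per-target coverage summary after identity filtering."""

    target_id: str
    target_length: int
    depth: np.ndarray  # per-base, 0-based

    @property
    def breadth(self) -> float:
        return float(np.count_nonzero(self.depth >= 1)) / self.target_length

    @property
    def mean_depth(self) -> float:
        return float(self.depth.sum()) / self.target_length


def coverage_profile(
    source: pd.DataFrame,
    target_id: str,
    target_length: int,
    kind: str = "alignments",
) -> CoverageProfile:
    """Build a coverage profile from alignments or a per-base depth table.

    ``kind="alignments"``: rows with 0-based ``start`` and ``aligned_length``
    are accumulated as half-open spans.  ``kind="depth"``: a 3-column
    samtools-depth dialect table (target, 1-based position, depth); positions
    absent from the table are depth 0.
    """
    depth = np.zeros(target_length, dtype=np.int64)
    if kind == "alignments":
        sub = source[source["target_id"] == target_id]
        starts = sub["start"].to_numpy(dtype=np.int64)
        lengths = sub["aligned_length"].to_numpy(dtype=np.int64)
        ends = starts + lengths
        if len(starts) and (starts.min() < 0 or ends.max() > target_length):
            raise ValidationError(f"alignment span outside target {target_id}")
        diff = np.zeros(target_length + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        depth = np.cumsum(diff[:-1])
    elif kind == "depth":
        sub = source[source.iloc[:, 0] == target_id]
        pos = sub.iloc[:, 1].to_numpy(dtype=np.int64)  # 1-based
        if len(pos) and (pos.min() < 1 or pos.max() > target_length):
            raise ValidationError(f"depth position outside target {target_id}")
        depth[pos - 1] = sub.iloc[:, 2].to_numpy(dtype=np.int64)
    else:
        raise ValidationError(f"unknown coverage source kind {kind!r}")
    if (depth < 0).any():
        raise ValidationError("negative depth encountered")
    return CoverageProfile(target_id=target_id, target_length=target_length, depth=depth)


def read_depth_table(path) -> pd.DataFrame:
    """Read a samtools-depth dialect TSV (target, 1-based pos, depth)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["target_id", "pos", "depth"])
    return df


def load_sam(path) -> pd.DataFrame:
    """Load a minimal SAM into the alignment-record table convention.

    Uses the CIGAR-consumed reference span as aligned length and the NM tag
    as edit distance; unmapped and NM-less records are skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or not rec.has_tag("NM"):
                continue
            rows.append(
                {
                    "read_id": rec.query_name,
                    "target_id": rec.reference_name,
                    "start": rec.reference_start,
                    "aligned_length": rec.reference_length,
                    "edit_distance": rec.get_tag("NM"),
                }
            )
    return pd.DataFrame(rows, columns=list(ALN_COLUMNS))


def call_viral_presence(profile: CoverageProfile, min_breadth: float = 0.75) -> bool:
    """Viral scaffold presence: breadth >= 75 % at depth >= 1 (inclusive)."""
    return profile.breadth >= min_breadth


def call_mag_presence(profile: CoverageProfile, min_breadth: float = 0.90) -> bool:
    """MAG presence: breadth >= 90 % under the <=2 %-error mapping contract."""
    return profile.breadth >= min_breadth


def presence_matrix(
    alignments_by_sample: Mapping[str, pd.DataFrame],
    target_lengths: Mapping[str, int],
    min_identity: float = 0.90,
    min_breadth: float = 0.75,
    control_read_ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Boolean target x sample presence matrix from per-sample alignments."""
    control_ids = set(control_read_ids or ())
    targets = list(target_lengths)
    out = pd.DataFrame(False, index=targets, columns=list(alignments_by_sample))
    for sample, aln in alignments_by_sample.items():
        aln = subtract_controls(aln, control_ids)
        aln = filter_reads_by_identity(aln, min_identity)
        for t in targets:
            prof = coverage_profile(aln, t, target_lengths[t])
            out.loc[t, sample] = prof.breadth >= min_breadth
    return out


def mean_coverage_matrix(
    alignments_by_sample: Mapping[str, pd.DataFrame],
    target_lengths: Mapping[str, int],
    min_identity: float = 0.90,
) -> pd.DataFrame:
    """Raw mean per-base depth per (target, sample) after identity filtering."""
    targets = list(target_lengths)
    out = pd.DataFrame(0.0, index=targets, columns=list(alignments_by_sample))
    for sample, aln in alignments_by_sample.items():
        aln = filter_reads_by_identity(aln, min_identity)
        for t in targets:
            prof = coverage_profile(aln, t, target_lengths[t])
            out.loc[t, sample] = prof.mean_depth
    return out


def normalize_coverage(
    raw: pd.DataFrame,
    library_sizes: Union[pd.Series, Mapping[str, float]],
    scale: float = 1e6,
) -> pd.DataFrame:
    """Sum-normalize mean coverage by per-sample sequencing depth.

    entry(t, s) = raw(t, s) / library_size(s) * scale, with the per-million
    convention by default; all downstream ratios pair samples under the same
    convention and are therefore scale-invariant.
    """
    lib = pd.Series(library_sizes, dtype=float).reindex(raw.columns)
    if lib.isna().any():
        missing = list(lib.index[lib.isna()])
        raise ValidationError(f"missing library size for sample(s): {missing}")
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValidationError(f"non-positive library size for sample(s): {bad}")
    return raw.div(lib, axis=1) * scale
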