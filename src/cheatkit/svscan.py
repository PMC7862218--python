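"""Windowed clipped/discordant-read scan for large structural variants.

Large deletions, insertions and rearrangements leave two signatures in a
short-read alignment that small-variant callers miss: reads whose CIGAR
carries clip or indel operations (breakpoint-spanning reads) and read
pairs whose SAM flag marks an anomalous pair configuration (breakpoint-
straddling pairs). This module extracts that "alternate" read class,
profiles its coverage in fixed-width genomic windows relative to total
coverage, and ranks windows by the difference in alternate-read fraction
between two samples (typically an ancestor and an evolved clone). The
output is a full ranked table for visual inspection — deliberately no
cut-off is applied and no breakpoint assembly is attempted.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Sequence

import pandas as pd

try:  # pysam is required for file input, optional for in-memory use
    import pysam
except ImportError:  # pragma: no cover
    pysam = None

#: SAM flags treated as discordant-pair evidence. Matching is exact set
#: membership of the full integer flag, not bit-level decomposition: the
#: scan targets these specific pair configurations (mate-unmapped pairs,
#: same-strand pairs, and paired reads without the proper-pair bit).
DISCORDANT_FLAGS = frozenset({67, 131, 115, 179, 81, 161, 97, 145, 65, 129, 113, 177})

#: CIGAR operations that mark a read as alternate: soft clip, hard clip,
#: insertion, deletion.
ALT_CIGAR_OPS = frozenset("SHID")

#: CIGAR operations that consume reference bases and therefore contribute
#: to per-base coverage over the read's reference span.
REF_CONSUMING_OPS = frozenset("MDN=X")

#: Integer CIGAR op codes (pysam convention) to characters.
CIGAR_CODE_TO_CHAR = "MIDNSHP=X"

ALTERNATE = "ALTERNATE"
NORMAL = "NORMAL"


class UnmappedRecordError(ValueError):
    """Raised when an unmapped record reaches a mapped-only operation."""


@dataclasses.dataclass(frozen=True)
class AlignmentObservation:
    """One mapped read, reduced to the fields the scan consults.

    Parameters
    ----------
    flag : int
        SAM bitflag.
    contig : str
        Reference sequence name.
    pos : int
        0-based leftmost aligned position.
    cigar : tuple of (str, int)
        Ordered CIGAR operations as (operation character, length).
    mapq : int
        Mapping quality.
    """

    flag: int
    contig: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative alignment position: {self.pos}")
        for op, length in self.cigar:
            if op not in "MIDNSHP=X":
                raise ValueError(f"unknown CIGAR operation {op!r}")
            if length <= 0:
                raise ValueError(f"non-positive CIGAR length for {op}")

    @property
    def reference_span(self) -> int:
        """Number of reference bases the alignment covers (M/D/N/=/X)."""
        return sum(n for op, n in self.cigar if op in REF_CONSUMING_OPS)

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the alignment on the reference."""
        return self.pos + self.reference_span


@dataclasses.dataclass(frozen=True)
class WindowProfile:
    """Per-window alternate and total coverage.

    ``alt_fraction`` is ``None`` when the window has zero total coverage;
    a division by zero is never performed.
    """

    contig: str
    window_start: int
    window_end: int
    alt_coverage: int
    total_coverage: int

    @property
    def alt_fraction(self) -> float | None:
        if self.total_coverage == 0:
            return None
        return self.alt_coverage / self.total_coverage


def flag_is_discordant(flag: int) -> bool:
    """True iff ``flag`` is one of the 12 discordance-indicating flags.

    Exact set membership of the full integer flag; no bitmask matching.
    """
    if flag < 0:
        raise ValueError(f"SAM flag must be non-negative, got {flag}")
    return flag in DISCORDANT_FLAGS


def classify_alignment(obs: AlignmentObservation) -> str:
    """Label a mapped read ``ALTERNATE`` or ``NORMAL``.

    A read is alternate when its CIGAR contains any soft/hard clip,
    insertion or deletion operation, or when its flag is in
    :data:`DISCORDANT_FLAGS` (union of the two criteria).
    """
    if not obs.contig or not obs.cigar:
        raise UnmappedRecordError("record has no contig/CIGAR; unmapped records are excluded")
    if any(op in ALT_CIGAR_OPS for op, _ in obs.cigar):
        return ALTERNATE
    if flag_is_discordant(obs.flag):
        return ALTERNATE
    return NORMAL


def tile_windows(contig_length: int, window: int = 100) -> list[tuple[int, int]]:
    """Non-overlapping half-open windows [0,w), [w,2w), … over a contig.

    The final window is truncated at the contig end.
    """
    if contig_length <= 0:
        raise ValueError(f"contig_length must be positive, got {contig_length}")
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    return [(s, min(s + window, contig_length)) for s in range(0, contig_length, window)]


def _window_size(windows: Sequence[tuple[int, int]]) -> int:
    if not windows:
        raise ValueError("empty window list")
    return windows[0][1] - windows[0][0]


def window_profiles(
    observations: Iterable[AlignmentObservation],
    windows: Sequence[tuple[int, int]],
    contig: str | None = None,
    min_mapq: int = 0,
) -> list[WindowProfile]:
    """Profile alternate vs total coverage of one contig in tiled windows.

    Each mapped read contributes per-base depth over its contiguous
    reference span (CIGAR M/D/N/=/X, deletion and skip gaps included);
    insertions and clips consume no reference and add nothing. Alternate
    coverage counts only reads classified :data:`ALTERNATE`.

    Parameters
    ----------
    observations :
        Mapped reads of a single contig (any order).
    windows :
        The tiling from :func:`tile_windows`; must be uniform except for
        a truncated final window, starting at 0.
    contig :
        If given, observations on other contigs raise an error.
    min_mapq :
        Optional mapping-quality floor (default 0 = off; this stage of
        the scan intentionally keeps low-MAPQ reads).
    """
    w = _window_size(windows)
    if windows[0][0] != 0:
        raise ValueError("window tiling must start at position 0")
    contig_end = windows[-1][1]

    alt = [0] * len(windows)
    total = [0] * len(windows)
    seen_contig: str | None = contig

    for obs in observations:
        if seen_contig is None:
            seen_contig = obs.contig
        elif obs.contig != seen_contig:
            raise ValueError(
                f"window list is for contig {seen_contig!r} but read maps to {obs.contig!r}"
            )
        if obs.mapq < min_mapq:
            continue
        label = classify_alignment(obs)
        start, end = obs.pos, min(obs.reference_end, contig_end)
        if start >= contig_end:
            raise ValueError(f"read at {obs.pos} falls outside the tiled contig (len {contig_end})")
        first, last = start // w, (end - 1) // w
        for i in range(first, last + 1):
            ws, we = windows[i]
            overlap = min(end, we) - max(start, ws)
            if overlap > 0:
                total[i] += overlap
                if label == ALTERNATE:
                    alt[i] += overlap

    name = seen_contig if seen_contig is not None else ""
    return [
        WindowProfile(name, ws, we, alt[i], total[i])
        for i, (ws, we) in enumerate(windows)
    ]


def read_observations(
    path: str,
    include_secondary: bool = False,
) -> tuple[dict[str, int], dict[str, list[AlignmentObservation]]]:
    """Read a SAM/BAM file into per-contig :class:`AlignmentObservation` lists.

    Returns ``(contig lengths from the header, observations by contig)``.
    Unmapped records are skipped; secondary/supplementary alignments are
    excluded by default. Only flag, contig, position, MAPQ and CIGAR are
    consulted.
    """
    if pysam is None:  # pragma: no cover
        raise ImportError("pysam is required to read SAM/BAM files")
    mode = "r" if path.endswith(".sam") else "rb"
    by_contig: dict[str, list[AlignmentObservation]] = {}
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        lengths = dict(zip(af.references, af.lengths))
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name is None:
                continue
            if not include_secondary and (rec.is_secondary or rec.is_supplementary):
                continue
            cigar = tuple(
                (CIGAR_CODE_TO_CHAR[code], length) for code, length in (rec.cigartuples or ())
            )
            if not cigar:
                continue
            by_contig.setdefault(rec.reference_name, []).append(
                AlignmentObservation(
                    flag=rec.flag,
                    contig=rec.reference_name,
                    pos=rec.reference_start,
                    cigar=cigar,
                    mapq=rec.mapping_quality,
                )
            )
    return lengths, by_contig


def profiles_from_alignment_file(
    path: str,
    window: int = 100,
    min_mapq: int = 0,
    include_secondary: bool = False,
) -> dict[str, list[WindowProfile]]:
    """Window profiles for every contig of a SAM/BAM file.

    Contig lengths are taken from the header; secondary and supplementary
    alignments are excluded by default.
    """
    lengths, by_contig = read_observations(path, include_secondary=include_secondary)
    out: dict[str, list[WindowProfile]] = {}
    for contig, length in lengths.items():
        windows = tile_windows(length, window)
        out[contig] = window_profiles(
            by_contig.get(contig, []), windows, contig=contig, min_mapq=min_mapq
        )
    return out


def compare_profiles(
    profiles_a: Sequence[WindowProfile],
    profiles_b: Sequence[WindowProfile],
) -> pd.DataFrame:
    """Rank windows by |alternate-fraction difference| between two samples.

    One row per window where both samples have defined fractions (nonzero
    total coverage); ordered by descending absolute difference, ties
    broken by (contig, window start). No threshold is applied — the full
    ranked table is emitted for downstream inspection.

    Returns a DataFrame with BED-compatible columns
    ``contig, start, end, alt_frac_a, alt_frac_b, abs_diff, rank``.
    """
    if len(profiles_a) != len(profiles_b):
        raise ValueError("profile sets have different window counts")
    rows = []
    for pa, pb in zip(profiles_a, profiles_b):
        if (pa.contig, pa.window_start, pa.window_end) != (
            pb.contig,
            pb.window_start,
            pb.window_end,
        ):
            raise ValueError(
                f"mismatched tilings: {pa.contig}:{pa.window_start} vs {pb.contig}:{pb.window_start}"
            )
        fa, fb = pa.alt_fraction, pb.alt_fraction
        if fa is None or fb is None:
            continue
        rows.append((pa.contig, pa.window_start, pa.window_end, fa, fb, abs(fa - fb)))
    df = pd.DataFrame(
        rows, columns=["contig", "start", "end", "alt_frac_a", "alt_frac_b", "abs_diff"]
    )
    df = df.sort_values(
        by=["abs_diff", "contig", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def compare_alignment_files(
    path_a: str,
    path_b: str,
    window: int = 100,
    min_mapq: int = 0,
    include_secondary: bool = False,
) -> pd.DataFrame:
    """End-to-end scan of two alignment files: profile, compare, rank."""
    prof_a = profiles_from_alignment_file(
        path_a, window=window, min_mapq=min_mapq, include_secondary=include_secondary
    )
    prof_b = profiles_from_alignment_file(
        path_b, window=window, min_mapq=min_mapq, include_secondary=include_secondary
    )
    if set(prof_a) != set(prof_b):
        raise ValueError("the two alignment files reference different contigs")
    tables = [compare_profiles(prof_a[c], prof_b[c]) for c in sorted(prof_a)]
    df = pd.concat(tables, ignore_index=True)
    df = df.sort_values(
        by=["abs_diff", "contig", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df
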