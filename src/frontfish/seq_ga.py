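"""Sliding-window GA-content profiling of nucleotide sequences.

GA-rich stretches in 3'UTRs act as RNA localization elements and are the
regions antisense morpholinos are designed against. The profile reports,
for every fully contained window (default 30 nt, step 1), the percentage
of G plus A bases; supra-threshold runs are merged into candidate GA-rich
regions in 0-based half-open sequence coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

_VALID = set("ACGTUN")


@dataclass
class GAProfile:
    """Percent G+A per sliding window along a sequence."""

    positions: np.ndarray  # 0-based window start indices
    percent_ga: np.ndarray
    window_nt: int

    def __len__(self) -> int:
        return len(self.positions)


def ga_window_profile(sequence: str, window_nt: int = 30) -> GAProfile:
    """Percent GA content in every fully contained sliding window.

    The sequence may mix case and use U for T; N counts as neither G nor A
    (but still occupies its window position). A sequence of length n yields
    n - window_nt + 1 values at step 1.
    """
    if window_nt < 1:
        raise ValidationError("window_nt must be at least 1")
    seq = sequence.strip().upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValidationError(f"invalid nucleotide {ch!r} at position {i}")
    if len(seq) < window_nt:
        raise ValidationError(
            f"sequence length {len(seq)} is shorter than the {window_nt}-nt window"
        )
    is_ga = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_ga = ((is_ga == ord("G")) | (is_ga == ord("A"))).astype(int)
    cumsum = np.concatenate([[0], np.cumsum(is_ga)])
    counts = cumsum[window_nt:] - cumsum[:-window_nt]
    positions = np.arange(len(seq) - window_nt + 1)
    return GAProfile(
        positions=positions,
        percent_ga=100.0 * counts / window_nt,
        window_nt=window_nt,
    )


def call_ga_rich_regions(
    profile: GAProfile, threshold_percent: float, min_span_nt: int = 0
) -> list[tuple[int, int]]:
    """Maximal GA-rich intervals in sequence coordinates (0-based half-open).

    Consecutive windows at or above ``threshold_percent`` form runs; each
    run spans from the first window's start to the last window's end.
    Overlapping spans are merged, then spans shorter than ``min_span_nt``
    are discarded.
    """
    if not 0 <= threshold_percent <= 100:
        raise ValidationError("threshold_percent must be within [0, 100]")
    above = profile.percent_ga >= threshold_percent
    intervals: list[list[int]] = []
    run_start = None
    for idx, flag in enumerate(above):
        if flag and run_start is None:
            run_start = idx
        elif not flag and run_start is not None:
            intervals.append([int(profile.positions[run_start]),
                              int(profile.positions[idx - 1]) + profile.window_nt])
            run_start = None
    if run_start is not None:
        intervals.append([int(profile.positions[run_start]),
                          int(profile.positions[len(above) - 1]) + profile.window_nt])
    merged: list[list[int]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged if e - s >= min_span_nt]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence}."""
    from Bio import SeqIO

    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValidationError(f"no FASTA records found in {path}")
    return records
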