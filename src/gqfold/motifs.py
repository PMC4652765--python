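"""G-quadruplex motif scanning.

A putative G-quadruplex (GQ) motif is four runs ("tracts") of at least
``min_g_tract_length`` consecutive guanines separated by three loops of
``min_loop_length``..``max_loop_length`` arbitrary nucleotides — the classic
G3N1-7 pattern at the defaults.  The scanner enumerates motifs on both strands
and reports them in forward-strand, 0-based half-open coordinates suitable for
BED output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = ["ScanParams", "GQMotif", "scan_g_quadruplex", "reverse_complement"]

_VALID_CHARS = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the G3N1-7-style scan.

    Defaults encode the canonical pattern: G-tracts of ≥3 guanines and loops
    of 1–7 nucleotides.  ``overlap_policy`` controls whether every valid
    decomposition is reported (``all_maximal``) or a left-to-right
    non-overlapping subset (``greedy_nonoverlapping``).
    """

    min_g_tract_length: int = 3
    min_loop_length: int = 1
    max_loop_length: int = 7
    scan_both_strands: bool = True
    overlap_policy: str = "all_maximal"

    def __post_init__(self) -> None:
        if self.min_g_tract_length < 2:
            raise ValueError("min_g_tract_length must be >= 2")
        if not (1 <= self.min_loop_length <= self.max_loop_length):
            raise ValueError("need 1 <= min_loop_length <= max_loop_length")
        if self.overlap_policy not in ("all_maximal", "greedy_nonoverlapping"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")


@dataclass(frozen=True)
class GQMotif:
    """A located GQ motif.

    ``start``/``end`` are 0-based half-open on the forward strand.  Tract and
    loop attributes are given in the motif's own 5'→3' order; for a minus-
    strand motif ``g_tract_starts`` therefore hold forward-strand coordinates
    of each tract's leftmost base listed in descending order.
    """

    sequence_id: str
    start: int
    end: int
    strand: str
    g_tract_starts: tuple[int, int, int, int]
    g_tract_lengths: tuple[int, int, int, int]
    loop_lengths: tuple[int, int, int]
    loop_sequences: tuple[str, str, str]
    motif_length: int = field(default=0)

    def __post_init__(self) -> None:
        expected = sum(self.g_tract_lengths) + sum(self.loop_lengths)
        if self.motif_length == 0:
            object.__setattr__(self, "motif_length", expected)
        if self.motif_length != self.end - self.start or self.motif_length != expected:
            raise ValueError("motif length arithmetic violated")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def loop_profile(self) -> str:
        """Loop-length triplet as the conventional name, e.g. ``"1-4-4"``."""
        return "-".join(str(n) for n in self.loop_lengths)


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper().strip()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"sequence contains invalid characters {sorted(bad)}; expected A/C/G/T/N"
        )
    return seq


def _g_run_lengths(seq: str) -> list[int]:
    """run[i] = number of consecutive G starting at i (0 if seq[i] != G)."""
    n = len(seq)
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if seq[i] == "G" else 0
    return run


def _enumerate_decompositions(
    seq: str, params: ScanParams
) -> Iterator[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Yield every valid (tract_starts, tract_lengths) decomposition.

    Tract lengths range over min_g_tract_length..(remaining G run); loop
    lengths are implied by consecutive tract placement and constrained to the
    configured window.  Loops may themselves contain G.
    """
    n = len(seq)
    run = _g_run_lengths(seq)
    tmin = params.min_g_tract_length
    lmin, lmax = params.min_loop_length, params.max_loop_length

    def extend(starts: list[int], lengths: list[int]) -> Iterator:
        if len(starts) == 4:
            yield tuple(starts), tuple(lengths)
            return
        prev_end = starts[-1] + lengths[-1]
        for loop in range(lmin, lmax + 1):
            s = prev_end + loop
            if s >= n:
                break
            for tl in range(tmin, run[s] + 1):
                yield from extend(starts + [s], lengths + [tl])

    for s0 in range(n):
        for tl0 in range(tmin, run[s0] + 1):
            yield from extend([s0], [tl0])


def _build_motif(
    seq_id: str,
    strand_seq: str,
    n: int,
    strand: str,
    starts: Sequence[int],
    lengths: Sequence[int],
) -> GQMotif:
    loops = []
    loop_seqs = []
    for i in range(3):
        a = starts[i] + lengths[i]
        b = starts[i + 1]
        loops.append(b - a)
        loop_seqs.append(strand_seq[a:b])
    s, e = starts[0], starts[3] + lengths[3]
    if strand == "+":
        fwd_starts = tuple(starts)
        start, end = s, e
    else:
        # map each tract's interval from the reverse-complement frame
        fwd_starts = tuple(n - (st + ln) for st, ln in zip(starts, lengths))
        start, end = n - e, n - s
    return GQMotif(
        sequence_id=seq_id,
        start=start,
        end=end,
        strand=strand,
        g_tract_starts=fwd_starts,  # type: ignore[arg-type]
        g_tract_lengths=tuple(lengths),  # type: ignore[arg-type]
        loop_lengths=tuple(loops),  # type: ignore[arg-type]
        loop_sequences=tuple(loop_seqs),  # type: ignore[arg-type]
    )


def _greedy_filter(
    decomps: list[tuple[tuple[int, ...], tuple[int, ...]]],
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Leftmost motif wins, then resume past its end (non-overlapping)."""
    ordered = sorted(
        decomps, key=lambda d: (d[0][0], d[0][3] + d[1][3], d[1])
    )
    kept: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    cursor = -1
    for starts, lengths in ordered:
        if starts[0] <= cursor:
            continue
        kept.append((starts, lengths))
        cursor = starts[3] + lengths[3] - 1
    return kept


def scan_g_quadruplex(
    sequence: str,
    params: ScanParams | None = None,
    sequence_id: str = "seq",
) -> list[GQMotif]:
    """Scan a DNA sequence for GQ motifs.

    Parameters
    ----------
    sequence
        DNA over A/C/G/T/N, case-insensitive.  ``N`` never counts as guanine
        but is allowed inside loops.
    params
        Scan parameters; defaults to the canonical G3N1-7 rule.
    sequence_id
        Identifier stored on each reported motif.

    Returns
    -------
    Motifs sorted by ``(start, strand)``.  Minus-strand motifs are found by
    scanning the reverse complement and reported in forward-strand
    coordinates.
    """
    params = params or ScanParams()
    seq = _validate_sequence(sequence)
    if not seq:
        return []
    motifs: list[GQMotif] = []
    strands = ["+", "-"] if params.scan_both_strands else ["+"]
    for strand in strands:
        strand_seq = seq if strand == "+" else reverse_complement(seq)
        decomps = list(_enumerate_decompositions(strand_seq, params))
        if params.overlap_policy == "greedy_nonoverlapping":
            decomps = _greedy_filter(decomps)
        for starts, lengths in decomps:
            motifs.append(
                _build_motif(sequence_id, strand_seq, len(seq), strand, starts, lengths)
            )
    motifs.sort(key=lambda m: (m.start, m.strand, m.end, m.g_tract_lengths))
    return motifs
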