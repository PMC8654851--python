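"""Cleavage-site detection from the read-end pileup signature.

A genuine cut produces forward-read 5' ends piling at the breakpoint and
reverse-read 5' ends at breakpoint-1.  The caller scores every genomic
position with the sum of read ends in a 10-bp window centered on it,
keeps positions above a threshold that also show ends in both orientations,
collapses overlapping candidates, and then asks whether a protospacer+PAM
placement on either strand explains the candidate: the placement's implied
breakpoint (3 bp upstream of the PAM) must fall within a small tolerance of
the candidate position.  The reported cut position is the placement-implied
breakpoint; the reported score is the window sum recomputed there.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .align_io import ReadEndTrack, SiteRecord, SiteSet
from .sequences import IUPAC, hamming, matches_iupac, revcomp, seq_to_uint8
from .synthetic_data import CUT_OFFSET, PAM_LEN, PROTOSPACER_LEN, GuideRNA

log = logging.getLogger(__name__)


class ContextError(ValueError):
    """Candidate lies too close to a contig end to attempt guide matching."""


@dataclass
class CallerParams:
    """Tunable knobs of the caller.

    ``window_width`` must be even; the window is realised half-open as
    [c - w/2, c + w/2), i.e. positions c-5 ... c+4 for the default w=10.
    ``cut_offset`` is fixed at 3 bp for Cas9 blunt cuts.
    """

    window_width: int = 10
    min_score: int = 5
    require_bidirectional: bool = True
    max_mismatches: int = 7
    pam_search_flank: int = 6
    cut_offset: int = CUT_OFFSET
    position_tolerance: int = 2
    min_context: int = 30

    def __post_init__(self) -> None:
        if self.window_width < 2 or self.window_width % 2:
            raise ValueError("window_width must be even and >= 2")
        if self.min_score < 0 or self.max_mismatches < 0 or self.position_tolerance < 0:
            raise ValueError("min_score, max_mismatches, position_tolerance must be >= 0")


@dataclass(frozen=True)
class GuideMatch:
    """A protospacer+PAM placement explaining a candidate position."""

    chrom: str
    strand: str
    protospacer_start: int
    mismatches: int
    matched_sequence: str  # protospacer-oriented 23-mer (20-mer + PAM)
    cut_position: int


def window_score(
    track: ReadEndTrack, chrom: str, position: int, window_width: int = 10
) -> int:
    """Sum of read ends (both strands) in [position - w/2, position + w/2)."""
    if chrom not in track.chroms():
        if track.total_mapped == 0:
            return 0
        raise KeyError(f"chromosome {chrom!r} not present in track")
    h = window_width // 2
    return track.range_sum(chrom, position - h, position + h)


def _collapse_plateaus(pos: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse each run of consecutive equal-score positions to its center.

    A clean cut gives identical window sums at every position whose window
    covers both pileups, a flat-topped plateau centered on the breakpoint;
    its central position (lower median for even runs) is the best breakpoint
    estimate and is what gets reported.
    """
    if len(pos) == 0:
        return pos, score
    run_break = np.flatnonzero((np.diff(pos) != 1) | (np.diff(score) != 0))
    starts = np.concatenate(([0], run_break + 1))
    ends = np.concatenate((run_break + 1, [len(pos)]))
    centers = [(s + e - 1) // 2 for s, e in zip(starts, ends)]
    return pos[centers], score[centers]


def detect_candidates(
    track: ReadEndTrack,
    params: CallerParams | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[tuple[str, int, int]]:
    """Genome-wide candidate cut positions as (chrom, position, window score).

    Positions whose window score reaches ``min_score`` (and, when
    ``require_bidirectional``, whose window holds at least one end in each
    orientation) are candidates; plateau runs collapse to their center, and
    candidates within ``window_width`` of a stronger one are suppressed
    (tie -> leftmost).
    """
    params = params or CallerParams()
    h = params.window_width // 2
    out: list[tuple[str, int, int]] = []
    for chrom in track.chroms():
        pos, fwd, rev = track.positions_and_counts(chrom)
        if len(pos) == 0:
            continue
        length = (
            int(chrom_lengths[chrom]) if chrom_lengths and chrom in chrom_lengths
            else int(pos.max()) + h + 1
        )
        dense_f = np.zeros(length + 1, dtype=np.int64)
        dense_r = np.zeros(length + 1, dtype=np.int64)
        valid = pos < length
        dense_f[pos[valid]] = fwd[valid]
        dense_r[pos[valid]] = rev[valid]
        cs_f = np.concatenate(([0], np.cumsum(dense_f)))
        cs_r = np.concatenate(([0], np.cumsum(dense_r)))
        c = np.arange(length, dtype=np.int64)
        lo = np.clip(c - h, 0, length)
        hi = np.clip(c + h, 0, length)
        win_f = cs_f[hi] - cs_f[lo]
        win_r = cs_r[hi] - cs_r[lo]
        win = win_f + win_r
        mask = win >= params.min_score
        if params.require_bidirectional:
            mask &= (win_f >= 1) & (win_r >= 1)
        cand = np.flatnonzero(mask)
        if len(cand) == 0:
            continue
        cand, cand_score = _collapse_plateaus(cand, win[cand])
        # non-maximum suppression: score desc, then leftmost
        order = np.lexsort((cand, -cand_score))
        kept: list[int] = []
        kept_scores: list[int] = []
        for i in order:
            p = int(cand[i])
            if all(abs(p - q) >= params.window_width for q in kept):
                kept.append(p)
                kept_scores.append(int(cand_score[i]))
        for p, s in sorted(zip(kept, kept_scores)):
            out.append((chrom, p, s))
    return out


def match_guide(
    genome: Mapping[str, str],
    chrom: str,
    position: int,
    guide: GuideRNA,
    params: CallerParams | None = None,
) -> GuideMatch | None:
    """Best protospacer+PAM placement whose implied breakpoint explains ``position``.

    All placements on both strands with an implied breakpoint within
    ``position_tolerance`` of the candidate are scored; among those whose PAM
    matches the pattern and whose Hamming distance to the guide is at most
    ``max_mismatches``, the winner minimises (mismatches, |implied breakpoint
    - candidate|, + strand first, leftmost).  Returns None when no placement
    qualifies.
    """
    params = params or CallerParams()
    seq = genome[chrom]
    if position < params.min_context or position > len(seq) - params.min_context:
        raise ContextError(
            f"candidate {chrom}:{position} has less than {params.min_context} bp context"
        )
    tol = params.position_tolerance
    candidates: list[tuple[tuple[int, int, int, int], GuideMatch]] = []

    for delta in range(-tol, tol + 1):
        # + strand: breakpoint = s + 17  =>  s = position + delta - 17
        s = position + delta - (PROTOSPACER_LEN - params.cut_offset)
        if 0 <= s and s + PROTOSPACER_LEN + PAM_LEN <= len(seq):
            proto = seq[s : s + PROTOSPACER_LEN]
            pam = seq[s + PROTOSPACER_LEN : s + PROTOSPACER_LEN + PAM_LEN]
            if matches_iupac(pam, guide.pam_pattern):
                mm = hamming(proto, guide.protospacer)
                if mm <= params.max_mismatches:
                    cut = s + PROTOSPACER_LEN - params.cut_offset
                    candidates.append(
                        (
                            (mm, abs(cut - position), 0, s),
                            GuideMatch(chrom, "+", s, mm, proto + pam, cut),
                        )
                    )
        # - strand: breakpoint = s + 3  =>  s = position + delta - 3
        s = position + delta - params.cut_offset
        if s - PAM_LEN >= 0 and s + PROTOSPACER_LEN <= len(seq):
            proto = revcomp(seq[s : s + PROTOSPACER_LEN])
            pam = revcomp(seq[s - PAM_LEN : s])
            if matches_iupac(pam, guide.pam_pattern):
                mm = hamming(proto, guide.protospacer)
                if mm <= params.max_mismatches:
                    cut = s + params.cut_offset
                    candidates.append(
                        (
                            (mm, abs(cut - position), 1, s),
                            GuideMatch(chrom, "-", s, mm, proto + pam, cut),
                        )
                    )
    if not candidates:
        return None
    return min(candidates, key=lambda kv: kv[0])[1]


def call_cut_sites(
    track: ReadEndTrack,
    genome: Mapping[str, str],
    guide: GuideRNA,
    params: CallerParams | None = None,
    keep_unmatched: bool = False,
    name: str = "calls",
) -> SiteSet:
    """Full calling pipeline: detect candidates, match the guide, emit a SiteSet.

    Output is sorted by (chrom, cut position); for every emitted site the
    stored score equals the window sum recomputed at its cut position.
    Unmatched candidates are dropped unless ``keep_unmatched`` (then flagged
    with strand '.' and no mismatch count).
    """
    params = params or CallerParams()
    lengths = {c: len(genome[c]) for c in genome}
    candidates = detect_candidates(track, params, chrom_lengths=lengths)
    best: dict[tuple[str, int, str], SiteRecord] = {}
    for chrom, pos, cand_score in candidates:
        try:
            match = match_guide(genome, chrom, pos, guide, params)
        except ContextError:
            match = None
        if match is None:
            if not keep_unmatched:
                continue
            rec = SiteRecord(
                chrom=chrom,
                cut_position=pos,
                strand=".",
                score=cand_score,
                mismatches=None,
                matched_sequence=None,
                candidate_position=pos,
            )
        else:
            cut = match.cut_position
            h = params.window_width // 2
            rec = SiteRecord(
                chrom=chrom,
                cut_position=cut,
                strand=match.strand,
                score=window_score(track, chrom, cut, params.window_width),
                mismatches=match.mismatches,
                matched_sequence=match.matched_sequence,
                fwd_ends_in_window=track.range_sum(chrom, cut - h, cut + h, "+"),
                rev_ends_in_window=track.range_sum(chrom, cut - h, cut + h, "-"),
                candidate_position=pos,
            )
        key = (rec.chrom, rec.cut_position, rec.strand)
        if key not in best or rec.score > best[key].score:
            best[key] = rec
    records = sorted(best.values(), key=lambda r: (r.chrom, r.cut_position, r.strand))
    for i, rec in enumerate(records):
        rec.label = f"site_{i:04d}"
    return SiteSet(name, records)


def enumerate_genome_matches(
    genome: Mapping[str, str], guide: GuideRNA, max_mismatches: int
) -> list[tuple[str, int, str, int]]:
    """Exhaustive scan for protospacer placements with a matching PAM.

    Returns (chrom, protospacer_start, strand, mismatches) for every 20-mer
    on either strand followed by a PAM-pattern match, at Hamming distance at
    most ``max_mismatches`` from the guide.  Positions refer to the forward
    interval [start, start+20) occupied by the protospacer.
    """
    hits: list[tuple[str, int, str, int]] = []
    pam = guide.pam_pattern
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        L = len(seq)
        if L < PROTOSPACER_LEN + PAM_LEN:
            continue
        arr = seq_to_uint8(seq)

        # + strand: protospacer [s, s+20), PAM [s+20, s+23)
        n = L - PROTOSPACER_LEN - PAM_LEN + 1
        mm = np.zeros(n, dtype=np.int16)
        for j, base in enumerate(guide.protospacer):
            mm += arr[j : j + n] != ord(base)
        ok = np.ones(n, dtype=bool)
        for k, sym in enumerate(pam):
            col = arr[PROTOSPACER_LEN + k : PROTOSPACER_LEN + k + n]
            allowed = np.zeros(n, dtype=bool)
            for b in IUPAC[sym]:
                allowed |= col == ord(b)
            ok &= allowed
        for s in np.flatnonzero(ok & (mm <= max_mismatches)):
            hits.append((chrom, int(s), "+", int(mm[s])))

        # - strand: protospacer occupies [s, s+20) read in reverse complement,
        # PAM occupies [s-3, s); equivalently the forward sequence must match
        # revcomp(protospacer) at [s, s+20) and revcomp(PAM) at [s-3, s).
        n = L - PROTOSPACER_LEN - PAM_LEN + 1  # s ranges over [3, L-20]
        rc_proto = revcomp(guide.protospacer)
        rc_pam = revcomp(pam)
        mm = np.zeros(n, dtype=np.int16)
        for j, base in enumerate(rc_proto):
            mm += arr[PAM_LEN + j : PAM_LEN + j + n] != ord(base)
        ok = np.ones(n, dtype=bool)
        for k, sym in enumerate(rc_pam):
            col = arr[k : k + n]
            allowed = np.zeros(n, dtype=bool)
            for b in IUPAC[sym]:
                allowed |= col == ord(b)
            ok &= allowed
        for i in np.flatnonzero(ok & (mm <= max_mismatches)):
            hits.append((chrom, int(i) + PAM_LEN, "-", int(mm[i])))

    hits.sort()
    return hits
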