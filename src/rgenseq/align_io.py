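"""Alignment and interval I/O.

This module reduces coordinate-sorted alignments to the only quantity the
cut-site caller consumes: strand-aware counts of read 5'-end positions
(:class:`ReadEndTrack`).  Because the library chemistry is amplification-free,
reads with identical 5' ends are genuine independent molecules, so no
duplicate marking is performed anywhere.

Site lists travel as BED6+ TSV: the first six columns are standard BED
(``end`` must equal ``start + 1`` — a cleavage site is a single breakpoint),
followed by the mismatch count and the matched protospacer+PAM sequence.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


class SiteParseError(ValueError):
    """Raised for malformed site files; message carries the line number."""


@dataclass
class SiteRecord:
    """One detected (or planted) cleavage site.

    ``cut_position`` is the 0-based breakpoint coordinate: the first base 3'
    of the blunt cut on the forward genomic strand.  ``strand`` is the strand
    of the matched protospacer ('.' when unmatched).  ``score`` is the
    read-end window sum at the breakpoint.
    """

    chrom: str
    cut_position: int
    strand: str = "."
    score: int = 0
    mismatches: int | None = None
    matched_sequence: str | None = None
    label: str = ""
    # caller-side extras, not serialised to BED
    fwd_ends_in_window: int = 0
    rev_ends_in_window: int = 0
    candidate_position: int | None = None


@dataclass
class SiteSet:
    """A named collection of cleavage-site calls from one experiment or method."""

    name: str
    records: list[SiteRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SiteRecord]:
        return iter(self.records)

    def sorted(self) -> "SiteSet":
        recs = sorted(self.records, key=lambda r: (r.chrom, r.cut_position))
        return SiteSet(self.name, recs)

    def chroms(self) -> set[str]:
        return {r.chrom for r in self.records}


class ReadEndTrack:
    """Sparse per-chromosome, per-strand counts of read 5'-end positions."""

    def __init__(self) -> None:
        self._counts: dict[str, dict[str, Counter]] = {}
        self.total_mapped: int = 0

    def add_end(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        if strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if count <= 0:
            return
        per_chrom = self._counts.setdefault(chrom, {"+": Counter(), "-": Counter()})
        per_chrom[strand][pos] += count
        self.total_mapped += count

    def chroms(self) -> list[str]:
        return sorted(self._counts)

    def counter(self, chrom: str, strand: str) -> Counter:
        return self._counts.get(chrom, {"+": Counter(), "-": Counter()})[strand]

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (positions, counts) arrays for one chromosome and strand."""
        c = self.counter(chrom, strand)
        if not c:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        pos = np.fromiter(sorted(c), count=len(c), dtype=np.int64)
        cnt = np.fromiter((c[p] for p in pos), count=len(pos), dtype=np.int64)
        return pos, cnt

    def range_sum(self, chrom: str, start: int, end: int, strand: str | None = None) -> int:
        """Total read ends in the half-open interval [start, end)."""
        strands = STRANDS if strand is None else (strand,)
        total = 0
        for s in strands:
            c = self.counter(chrom, s)
            # sparse tracks are small per window; direct iteration is fine
            if len(c) > 4 * (end - start):
                total += sum(c.get(p, 0) for p in range(start, end))
            else:
                total += sum(n for p, n in c.items() if start <= p < end)
        return total

    def positions_and_counts(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Merged (positions, forward counts, reverse counts) for a chromosome."""
        pf, cf = self.arrays(chrom, "+")
        pr, cr = self.arrays(chrom, "-")
        pos = np.union1d(pf, pr)
        fwd = np.zeros(len(pos), dtype=np.int64)
        rev = np.zeros(len(pos), dtype=np.int64)
        fwd[np.searchsorted(pos, pf)] = cf
        rev[np.searchsorted(pos, pr)] = cr
        return pos, fwd, rev

    def copy(self) -> "ReadEndTrack":
        t = ReadEndTrack()
        for chrom, per in self._counts.items():
            for strand in STRANDS:
                for p, n in per[strand].items():
                    t.add_end(chrom, strand, p, n)
        return t

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadEndTrack):
            return NotImplemented
        a = {c: {s: dict(self.counter(c, s)) for s in STRANDS} for c in self.chroms()}
        b = {c: {s: dict(other.counter(c, s)) for s in STRANDS} for c in other.chroms()}
        return a == b and self.total_mapped == other.total_mapped


def load_read_starts(alignment_file: str | Path, min_mapq: int = 20) -> ReadEndTrack:
    """Reduce a coordinate-sorted SAM/BAM file to read 5'-end counts.

    For a forward-strand alignment the 5' end is the leftmost aligned
    reference position; for a reverse-strand alignment it is the rightmost
    aligned reference position.  Soft clips do not shift the recorded end —
    the reference-aligned span is used.  Unmapped, secondary, supplementary
    and low-MAPQ records are excluded.
    """
    path = Path(alignment_file)
    if not path.exists():
        raise FileNotFoundError(path)
    track = ReadEndTrack()
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(
                f"{path} must be coordinate-sorted (header SO:coordinate; run "
                f"'samtools sort' and index it); found SO:{so or 'absent'}"
            )
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if aln.is_reverse:
                track.add_end(aln.reference_name, "-", aln.reference_end - 1)
            else:
                track.add_end(aln.reference_name, "+", aln.reference_start)
    return track


def subsample_track(track: ReadEndTrack, fraction: float, seed: int) -> ReadEndTrack:
    """Retain each read end independently with probability ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    out = ReadEndTrack()
    if fraction == 0.0:
        return out
    for chrom in track.chroms():
        for strand in STRANDS:
            c = track.counter(chrom, strand)
            for pos in sorted(c):
                kept = int(rng.binomial(c[pos], fraction)) if fraction < 1.0 else c[pos]
                if kept:
                    out.add_end(chrom, strand, pos, kept)
    return out


def nested_subsample_tracks(
    track: ReadEndTrack, fractions: Iterable[float], seed: int
) -> dict[float, ReadEndTrack]:
    """Subsample at several fractions so each smaller sample is a subset of the next.

    Every individual read end draws one uniform variate u; the end is retained
    at fraction f iff u < f, which makes retention nested across fractions by
    construction (the saturation-curve property is then exact, not stochastic).
    """
    fracs = list(fractions)
    if any(not 0.0 <= f <= 1.0 for f in fracs):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {f: ReadEndTrack() for f in fracs}
    for chrom in track.chroms():
        for strand in STRANDS:
            c = track.counter(chrom, strand)
            for pos in sorted(c):
                u = rng.random(c[pos])
                for f in fracs:
                    kept = c[pos] if f >= 1.0 else int((u < f).sum())
                    if kept:
                        out[f].add_end(chrom, strand, pos, kept)
    return out


_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tmismatches\tmatched_seq"


def write_sites(path: str | Path, sites: SiteSet) -> None:
    """Write a site set as BED6+2 TSV (0-based half-open, one breakpoint per row)."""
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for r in sites.sorted():
            mm = "." if r.mismatches is None else str(r.mismatches)
            seq = r.matched_sequence or "."
            fh.write(
                f"{r.chrom}\t{r.cut_position}\t{r.cut_position + 1}\t{r.label or '.'}"
                f"\t{r.score}\t{r.strand}\t{mm}\t{seq}\n"
            )


def read_sites(path: str | Path, name: str | None = None) -> SiteSet:
    """Read a BED6+2 site file written by :func:`write_sites` (inverse of it)."""
    records: list[SiteRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise SiteParseError(f"{path}:{lineno}: expected >=6 BED columns, got {len(fields)}")
            try:
                start = int(fields[1])
                end = int(fields[2])
                score = int(round(float(fields[4])))
            except ValueError as exc:
                raise SiteParseError(f"{path}:{lineno}: malformed coordinates/score: {exc}") from exc
            if end != start + 1:
                raise SiteParseError(
                    f"{path}:{lineno}: a cleavage site is a single breakpoint; "
                    f"expected end == start+1, got [{start}, {end})"
                )
            if start < 0:
                raise SiteParseError(f"{path}:{lineno}: negative coordinate {start}")
            mm_field = fields[6] if len(fields) > 6 else "."
            mismatches = None if mm_field in (".", "") else int(mm_field)
            seq_field = fields[7] if len(fields) > 7 else "."
            records.append(
                SiteRecord(
                    chrom=fields[0],
                    cut_position=start,
                    strand=fields[5],
                    score=score,
                    mismatches=mismatches,
                    matched_sequence=None if seq_field in (".", "") else seq_field,
                    label="" if fields[3] == "." else fields[3],
                )
            )
    return SiteSet(name or Path(path).stem, records)
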