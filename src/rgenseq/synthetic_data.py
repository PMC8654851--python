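"""Ground-truthed simulation of an amplification-free cut-site sequencing library.

The generator reproduces, step by step, the physics the method relies on:

* **Guide targets.** A 20-nt protospacer followed by an NGG PAM is planted at
  chosen positions with an exact number of mismatches; the blunt Cas9 cut
  sits 3 bp upstream of the PAM.
* **Single-turnover cleavage.** Cas9 stays bound after cutting, so each
  template copy is cleaved at each site at most once, with probability
  ``p = C^h / (C^h + K^h)`` — Hill saturation in the RGEN concentration C
  with per-site affinity K (concentration of half-maximal cleavage).
* **Productive-molecule selection.** Only fragments carrying one cut end
  (first-adapter ligation) and one fragmented end cluster on the flowcell,
  so each cleaved molecule yields at most two sequenceable reads, one per
  flank, each surviving ligation with probability
  ``p7L_ligation_efficiency``.
* **End heterogeneity.** Cas9 cleavage products degrade from the PAM-distal
  side.  With end repair on, all read 5' ends sit exactly at the breakpoint.
  With end repair off, the distal flank's 5' end recedes by a geometric
  offset (mean ``resection_mean``) and non-blunt ends ligate with reduced
  efficiency, depleting the distal flank.
* **Background.** Pre-existing or handling-induced breaks ligate residual
  first adapter at a uniform low rate and contribute scattered read ends.

Coordinate convention (0-based, half-open): for a + strand protospacer on
[s, s+20) with PAM on [s+20, s+23), the blunt-cut breakpoint coordinate is
s+17.  A productive read from the right flank is a forward-strand read with
5' end at the breakpoint; from the left flank, a reverse-strand read with 5'
end at breakpoint-1 — this reproduces the characteristic bidirectional
pileup that flanks true cut sites in a genome browser.  Minus-strand sites
are mirrored: protospacer on [s, s+20) read on the reverse strand, PAM on
[s-3, s), breakpoint s+3.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .align_io import ReadEndTrack
from .sequences import BASES, revcomp

log = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
PAM_LEN = 3
CUT_OFFSET = 3  # blunt cut this many bp upstream of the PAM

# rng stream tags so stages draw from independent, individually reproducible streams
_STREAM_GENOME = 1
_STREAM_PLANT = 2
_STREAM_CLEAVE = 3
_STREAM_READS = 4
_STREAM_BACKGROUND = 5


class PlantingError(RuntimeError):
    """Genome cannot accommodate the requested sites without collisions."""


@dataclass(frozen=True)
class GuideRNA:
    """A guide RNA: 20-nt protospacer plus a 3-letter IUPAC PAM pattern."""

    name: str
    protospacer: str
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if len(proto) != PROTOSPACER_LEN:
            raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt, got {len(proto)}")
        if set(proto) - set(BASES):
            raise ValueError(f"protospacer must be over ACGT, got {proto!r}")
        if len(self.pam_pattern) != PAM_LEN:
            raise ValueError(f"PAM pattern must be {PAM_LEN} letters, got {self.pam_pattern!r}")


@dataclass
class PlantedSite:
    """Ground-truth genomic target: placement, mismatch load, and affinity.

    ``affinity_K`` is the RGEN concentration (nM) at which the per-copy
    cleavage probability is 0.5.  ``cut_position`` is the breakpoint
    coordinate under the package-wide convention (s+17 on +, s+3 on -).
    """

    chrom: str
    protospacer_start: int
    strand: str
    mismatches: int
    affinity_K: float
    cut_position: int
    name: str = ""
    cleaved_molecules: int = 0

    @property
    def pam_edge(self) -> int:
        """Boundary coordinate of the protospacer/PAM junction (the PAM 5' edge)."""
        if self.strand == "+":
            return self.protospacer_start + PROTOSPACER_LEN
        return self.protospacer_start

    def pam_offset(self) -> int:
        """Distance from the cut breakpoint to the PAM 5' edge, measured in
        protospacer orientation (3 for a canonical blunt cut)."""
        if self.strand == "+":
            return self.pam_edge - self.cut_position
        return self.cut_position - self.pam_edge


@dataclass
class SimConfig:
    """All knobs of the library simulation (one seed drives every stage)."""

    genome_length: int = 1_000_000
    gc_content: float = 0.42
    genome_copies: int = 20_000
    rgen_concentration_nM: float = 64.0
    hill_coefficient: float = 1.0
    end_repair: bool = True
    resection_mean: float = 5.0
    nonblunt_ligation_efficiency: float = 0.5
    background_break_rate: float = 1e-5  # expected background cut ends /kb /copy
    p7L_ligation_efficiency: float = 0.8
    read_length: int = 151
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.genome_copies < 1:
            raise ValueError("genome_copies must be >= 1")
        if self.rgen_concentration_nM < 0:
            raise ValueError("rgen_concentration_nM must be >= 0")
        for name in ("gc_content", "nonblunt_ligation_efficiency", "p7L_ligation_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_break_rate < 0:
            raise ValueError("background_break_rate must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class SimResult:
    """Everything one simulation produced, with full ground truth attached."""

    sam_path: Path | None
    sites: list[PlantedSite]
    background_positions: list[tuple[str, int]]
    track: ReadEndTrack
    n_reads: int
    n_dropped: int = 0


def generate_genome(length: int, gc_content: float, seed: int) -> str:
    """Random i.i.d. genome with P(G)+P(C) = ``gc_content``."""
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError(f"gc_content must be in [0, 1], got {gc_content}")
    rng = np.random.default_rng([seed, _STREAM_GENOME])
    p = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(list("ACGT"))[idx])


def cut_position_for(protospacer_start: int, strand: str) -> int:
    """Breakpoint coordinate implied by a protospacer placement."""
    if strand == "+":
        return protospacer_start + PROTOSPACER_LEN - CUT_OFFSET
    return protospacer_start + CUT_OFFSET


def _mutate(protospacer: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Protospacer variant at exact Hamming distance ``n_mismatches``."""
    seq = list(protospacer)
    for i in rng.choice(PROTOSPACER_LEN, size=n_mismatches, replace=False):
        alternatives = [b for b in BASES if b != seq[i]]
        seq[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def _random_pam(pattern: str, rng: np.random.Generator) -> str:
    from .sequences import IUPAC

    return "".join(IUPAC[sym][rng.integers(len(IUPAC[sym]))] for sym in pattern)


def plant_sites(
    genome: dict[str, str],
    guide: GuideRNA,
    spec: Sequence[tuple[int, str, float]],
    seed: int,
    min_separation: int = 200,
    edge_margin: int = 100,
    verify_max_mismatches: int | None = None,
    max_attempts: int = 10,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Write protospacer+PAM instances into a genome and return the ground truth.

    ``spec`` is a list of (mismatches, strand, affinity_K).  Positions are
    drawn at least ``min_separation`` bp apart and ``edge_margin`` bp from
    contig ends.  After planting, an exhaustive Hamming scan confirms no
    unintended placement at ``verify_max_mismatches`` or fewer mismatches
    exists anywhere; positions and mismatch placements are redrawn on
    collision, and :class:`PlantingError` is raised if the genome itself
    harbours irreducible near-matches.
    """
    from .cutsite_caller import enumerate_genome_matches  # deferred: avoids cycle

    rng = np.random.default_rng([seed, _STREAM_PLANT])
    chroms = sorted(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    usable = {c: lengths[c] - 2 * edge_margin - PROTOSPACER_LEN - PAM_LEN for c in chroms}
    if sum(max(u, 0) for u in usable.values()) < len(spec) * min_separation:
        raise PlantingError(
            f"genome too short to hold {len(spec)} sites {min_separation} bp apart"
        )
    if verify_max_mismatches is None:
        verify_max_mismatches = max((mm for mm, _, _ in spec), default=0)

    weights = np.array([max(usable[c], 0) for c in chroms], dtype=float)
    weights /= weights.sum()

    for _ in range(max_attempts):
        placed: dict[str, list[int]] = {c: [] for c in chroms}
        positions: list[tuple[str, int]] = []
        ok = True
        for _site in spec:
            for _try in range(200):
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                pos = int(rng.integers(edge_margin + PAM_LEN, lengths[chrom] - edge_margin - PROTOSPACER_LEN - PAM_LEN))
                if all(abs(pos - q) >= min_separation for q in placed[chrom]):
                    placed[chrom].append(pos)
                    positions.append((chrom, pos))
                    break
            else:
                ok = False
                break
        if not ok:
            continue

        mutable = {c: list(genome[c]) for c in chroms}
        sites: list[PlantedSite] = []
        for i, ((mm, strand, affinity), (chrom, pos)) in enumerate(zip(spec, positions)):
            proto = _mutate(guide.protospacer, mm, rng)
            pam = _random_pam(guide.pam_pattern, rng)
            if strand == "+":
                insert = proto + pam
                start = pos
            elif strand == "-":
                insert = revcomp(proto + pam)
                start = pos - PAM_LEN  # PAM occupies [pos-3, pos) in forward coords
            else:
                raise ValueError(f"strand must be '+' or '-', got {strand!r}")
            mutable[chrom][start : start + len(insert)] = insert
            sites.append(
                PlantedSite(
                    chrom=chrom,
                    protospacer_start=pos,
                    strand=strand,
                    mismatches=mm,
                    affinity_K=float(affinity),
                    cut_position=cut_position_for(pos, strand),
                    name=f"site_{i:03d}_mm{mm}",
                )
            )
        planted_genome = {c: "".join(mutable[c]) for c in chroms}

        found = enumerate_genome_matches(planted_genome, guide, verify_max_mismatches)
        expected = {
            (s.chrom, s.protospacer_start, s.strand)
            for s in sites
            if s.mismatches <= verify_max_mismatches
        }
        got = {(chrom, start, strand) for chrom, start, strand, _ in found}
        if got == expected:
            return planted_genome, sites
        log.info("planting collision (%d unintended matches); redrawing", len(got - expected))

    raise PlantingError(
        f"could not plant {len(spec)} collision-free sites after {max_attempts} attempts "
        f"(verification at <={verify_max_mismatches} mismatches)"
    )


def cleavage_probability(concentration_nM: float, affinity_K: float, hill: float = 1.0) -> float:
    """Hill-saturation per-copy cleavage probability C^h / (C^h + K^h)."""
    if concentration_nM < 0:
        raise ValueError("concentration must be >= 0")
    if concentration_nM == 0:
        return 0.0
    ch = concentration_nM**hill
    return float(ch / (ch + affinity_K**hill))


def simulate_cleavage(sites: Sequence[PlantedSite], config: SimConfig) -> list[int]:
    """Number of template copies cleaved at each site (single turnover).

    Each of ``genome_copies`` template molecules is cut at each site
    independently at most once.  Per-site uniforms are drawn from a stream
    keyed by (seed, site index), so with a fixed seed the realised counts are
    coupled across concentrations: the set of copies cleaved at a lower
    concentration is a subset of that at a higher one, matching the
    single-turnover occupancy picture.
    """
    counts: list[int] = []
    for i, site in enumerate(sites):
        p = cleavage_probability(
            config.rgen_concentration_nM, site.affinity_K, config.hill_coefficient
        )
        rng = np.random.default_rng([config.seed, _STREAM_CLEAVE, i])
        u = rng.random(config.genome_copies)
        counts.append(int((u < p).sum()))
    return counts


def draw_background_breaks(genome: dict[str, str], config: SimConfig) -> list[tuple[str, int]]:
    """Uniformly scattered background cut ends (residual-adapter ligations)."""
    rng = np.random.default_rng([config.seed, _STREAM_BACKGROUND])
    breaks: list[tuple[str, int]] = []
    for chrom in sorted(genome):
        lam = config.background_break_rate * (len(genome[chrom]) / 1000.0) * config.genome_copies
        n = int(rng.poisson(lam))
        for pos in sorted(rng.integers(0, len(genome[chrom]), size=n)):
            breaks.append((chrom, int(pos)))
    return breaks


def _distal_is_left(strand: str) -> bool:
    # proximal flank = PAM side: right of the cut for + sites, left for - sites
    return strand == "+"


def simulate_reads(
    genome: dict[str, str],
    sites: Sequence[PlantedSite],
    cleaved_counts: Sequence[int],
    background_positions: Sequence[tuple[str, int]],
    config: SimConfig,
    sam_path: str | Path | None = None,
) -> SimResult:
    """Turn cleaved molecules and background breaks into aligned reads.

    Each cleaved molecule can yield two productive reads: a forward read with
    5' end at the breakpoint (right flank) and a reverse read with 5' end at
    breakpoint-1 (left flank); each survives first-adapter ligation with
    probability ``p7L_ligation_efficiency``.  Without end repair the
    PAM-distal flank is degraded: its 5' end recedes from the cut by a
    geometric offset and receded (non-blunt) ends ligate with probability
    ``nonblunt_ligation_efficiency``.  Reads overrunning a contig end are
    truncated; reads whose 5' end falls off the contig are dropped and
    counted, never emitted malformed.
    """
    if len(sites) != len(cleaved_counts):
        raise ValueError("one cleaved count per site required")
    rng = np.random.default_rng([config.seed, _STREAM_READS])
    eff = config.p7L_ligation_efficiency
    # (chrom, strand, five_prime_end) per retained read
    ends: list[tuple[str, str, int]] = []

    # input sites stay untouched; realised counts live on copies in the result
    realized = [replace(s, cleaved_molecules=int(n)) for s, n in zip(sites, cleaved_counts)]
    for site, n_cut in zip(realized, cleaved_counts):
        if n_cut == 0:
            continue
        b = site.cut_position
        for flank in ("right", "left"):
            keep = rng.random(n_cut) < eff
            offsets = np.zeros(n_cut, dtype=np.int64)
            is_distal = _distal_is_left(site.strand) == (flank == "left")
            if not config.end_repair and is_distal:
                # geometric recession (support 0,1,2,... with mean resection_mean)
                if config.resection_mean > 0:
                    offsets = rng.geometric(1.0 / (1.0 + config.resection_mean), size=n_cut) - 1
                receded = offsets > 0
                keep &= ~receded | (rng.random(n_cut) < config.nonblunt_ligation_efficiency)
            for off in offsets[keep]:
                if flank == "right":
                    ends.append((site.chrom, "+", b + int(off)))
                else:
                    ends.append((site.chrom, "-", b - 1 - int(off)))

    bg_strand_draw = rng.random(len(background_positions)) < 0.5
    for (chrom, pos), fwd in zip(background_positions, bg_strand_draw):
        ends.append((chrom, "+", pos) if fwd else (chrom, "-", pos - 1))

    # materialise alignments, clipping at contig bounds
    L = config.read_length
    reads: list[tuple[str, int, int, bool]] = []  # chrom, start, length, is_reverse
    track = ReadEndTrack()
    n_dropped = 0
    for chrom, strand, e in ends:
        clen = len(genome[chrom])
        if strand == "+":
            if e < 0 or e >= clen:
                n_dropped += 1
                continue
            start, length = e, min(L, clen - e)
        else:
            if e < 0 or e >= clen:
                n_dropped += 1
                continue
            start = max(0, e - L + 1)
            length = e - start + 1
        reads.append((chrom, start, length, strand == "-"))
        track.add_end(chrom, strand, e)
    if n_dropped:
        log.info("dropped %d reads whose 5' end fell outside a contig", n_dropped)

    out_path: Path | None = None
    if sam_path is not None:
        out_path = Path(sam_path)
        _write_sam(out_path, genome, reads)

    return SimResult(
        sam_path=out_path,
        sites=realized,
        background_positions=list(background_positions),
        track=track,
        n_reads=len(reads),
        n_dropped=n_dropped,
    )


def _write_sam(path: Path, genome: dict[str, str], reads: list[tuple[str, int, int, bool]]) -> None:
    chroms = sorted(genome)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(genome[c])} for c in chroms],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}
    order = sorted(range(len(reads)), key=lambda i: (tid[reads[i][0]], reads[i][1]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for serial, i in enumerate(order):
            chrom, start, length, is_reverse = reads[i]
            a = pysam.AlignedSegment(header)
            a.query_name = f"sim.{serial}"
            a.flag = 16 if is_reverse else 0
            a.reference_id = tid[chrom]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, length)]
            a.query_sequence = genome[chrom][start : start + length]
            out.write(a)


def simulate_library(
    genome: dict[str, str],
    sites: Sequence[PlantedSite],
    config: SimConfig,
    sam_path: str | Path | None = None,
) -> SimResult:
    """Convenience pipeline: cleavage -> background -> reads."""
    counts = simulate_cleavage(sites, config)
    background = draw_background_breaks(genome, config)
    return simulate_reads(genome, sites, counts, background, config, sam_path=sam_path)


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write a genome dict as wrapped FASTA."""
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a plain {name: sequence} dict."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_truth_bed(sites: Sequence[PlantedSite], path: str | Path) -> None:
    """Ground-truth sites as BED6 (start=cut breakpoint, score=mismatches)."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.cut_position)):
            fh.write(
                f"{s.chrom}\t{s.cut_position}\t{s.cut_position + 1}\t{s.name}"
                f"\t{s.mismatches}\t{s.strand}\n"
            )
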