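"""Per-site and per-experiment quality statistics.

Implements the diagnostics used to characterise an amplification-free
cut-site library: flank-coverage skewness (sensitive to end degradation),
the fraction of reads that are productive (aligned to enzyme-generated
ends), site-recovery saturation versus sequencing depth, the response of
site counts and scores to RGEN concentration, and score distributions
grouped by mismatch load.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align_io import ReadEndTrack, SiteRecord, SiteSet, nested_subsample_tracks, subsample_track
from .cutsite_caller import CallerParams, call_cut_sites
from .synthetic_data import GuideRNA, PlantedSite, SimConfig, draw_background_breaks, simulate_cleavage, simulate_reads

log = logging.getLogger(__name__)

#: mismatch groups used for score statistics; the lowest group pools 0-3
MISMATCH_GROUPS = ("0-3", "4", "5", "6", "7")


@dataclass
class SkewnessRecord:
    """Coverage imbalance between the two flanks of one cut site.

    ``L_cov`` is the PAM-proximal flank's read-end count, ``R_cov`` the
    PAM-distal one.  ``skewness_percent`` is 100*|L-R|/(L+R); None when both
    flanks are empty (undefined).
    """

    site: str
    L_cov: int
    R_cov: int
    skewness_percent: float | None

    @property
    def undefined(self) -> bool:
        return self.skewness_percent is None


@dataclass
class SaturationPoint:
    """One point of a recovery-vs-depth curve."""

    retained_reads: int
    recovered_sites: int
    recovered_sites_max3_mismatches: int


def skewness(L_cov: int, R_cov: int) -> float:
    """%skewness = |L - R| / (L + R) * 100 — symmetric, scale-invariant, in [0, 100]."""
    if L_cov < 0 or R_cov < 0:
        raise ValueError("coverages must be >= 0")
    total = L_cov + R_cov
    if total == 0:
        raise ValueError("skewness is undefined when both flanks have zero coverage")
    return abs(L_cov - R_cov) / total * 100.0


def site_skewness(
    track: ReadEndTrack,
    call: SiteRecord | PlantedSite,
    flank: int = 200,
    chrom_lengths: Mapping[str, int] | None = None,
) -> SkewnessRecord:
    """Flank skewness of one site, proximal/distal labelled by matched strand.

    Counts read ends in [cut-flank, cut) and [cut, cut+flank); the PAM side
    (right of the cut for + sites, left for - sites, right by convention for
    unmatched sites) is reported as proximal (L_cov).  Near a contig edge the
    flank is truncated to the available span, with a warning.
    """
    chrom = call.chrom
    cut = call.cut_position
    strand = getattr(call, "strand", "+")
    lo, hi = cut - flank, cut + flank
    if chrom_lengths and chrom in chrom_lengths:
        clen = chrom_lengths[chrom]
        if lo < 0 or hi > clen:
            warnings.warn(
                f"site {chrom}:{cut} nearer than {flank} bp to a contig edge; "
                "skewness computed on the truncated span",
                stacklevel=2,
            )
            lo, hi = max(lo, 0), min(hi, clen)
    left = track.range_sum(chrom, lo, cut)
    right = track.range_sum(chrom, cut, hi)
    proximal, distal = (right, left) if strand == "+" else (left, right)
    label = getattr(call, "label", "") or getattr(call, "name", "") or f"{chrom}:{cut}"
    if proximal + distal == 0:
        return SkewnessRecord(label, proximal, distal, None)
    return SkewnessRecord(label, proximal, distal, skewness(proximal, distal))


def skewness_table(
    track: ReadEndTrack,
    sites: Sequence[SiteRecord | PlantedSite],
    flank: int = 200,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Skewness of every site as a tidy table (one row per site)."""
    rows = [site_skewness(track, s, flank, chrom_lengths) for s in sites]
    return pd.DataFrame(
        {
            "site": [r.site for r in rows],
            "L_cov": [r.L_cov for r in rows],
            "R_cov": [r.R_cov for r in rows],
            "skewness_percent": [r.skewness_percent for r in rows],
        }
    )


def productive_read_fraction(
    track: ReadEndTrack,
    sites: Sequence[SiteRecord | PlantedSite] | SiteSet,
    window: int = 5,
) -> float:
    """Percent of mapped read ends within +-``window`` bp of any known cut."""
    if track.total_mapped == 0:
        raise ValueError("empty track: no mapped reads")
    site_list = list(sites)
    if not site_list:
        return 0.0
    cuts_by_chrom: dict[str, np.ndarray] = {}
    for s in site_list:
        cuts_by_chrom.setdefault(s.chrom, [])  # type: ignore[arg-type]
    for s in site_list:
        cuts_by_chrom[s.chrom].append(s.cut_position)  # type: ignore[attr-defined]
    cuts_by_chrom = {c: np.unique(np.asarray(v)) for c, v in cuts_by_chrom.items()}
    productive = 0
    for chrom in track.chroms():
        cuts = cuts_by_chrom.get(chrom)
        pos, fwd, rev = track.positions_and_counts(chrom)
        if cuts is None or len(pos) == 0:
            continue
        idx = np.searchsorted(cuts, pos)
        dist_right = np.where(idx < len(cuts), np.abs(cuts[np.minimum(idx, len(cuts) - 1)] - pos), np.iinfo(np.int64).max)
        dist_left = np.where(idx > 0, np.abs(pos - cuts[np.maximum(idx - 1, 0)]), np.iinfo(np.int64).max)
        near = np.minimum(dist_left, dist_right) <= window
        productive += int((fwd[near] + rev[near]).sum())
    return productive / track.total_mapped * 100.0


def saturation_curve(
    track: ReadEndTrack,
    genome: Mapping[str, str],
    guide: GuideRNA,
    params: CallerParams | None = None,
    fractions: Sequence[float] = (0.05, 0.1, 0.25, 0.5, 1.0),
    seed: int = 0,
) -> list[SaturationPoint]:
    """Recovered-site counts under nested subsampling of the read track.

    Fractions must be ascending in (0, 1].  Subsamples are nested (each
    smaller sample is a subset of the next), so window scores — and with a
    clean fixture, recovered-site counts — are monotone by construction.
    The fraction-1.0 point is exactly the full call.
    """
    fracs = list(fractions)
    if fracs != sorted(fracs) or any(not 0.0 < f <= 1.0 for f in fracs):
        raise ValueError("fractions must be ascending and in (0, 1]")
    params = params or CallerParams()
    tracks = nested_subsample_tracks(track, fracs, seed)
    points: list[SaturationPoint] = []
    for f in fracs:
        sub = tracks[f]
        calls = call_cut_sites(sub, genome, guide, params)
        matched = [r for r in calls if r.mismatches is not None]
        points.append(
            SaturationPoint(
                retained_reads=sub.total_mapped,
                recovered_sites=len(matched),
                recovered_sites_max3_mismatches=sum(1 for r in matched if r.mismatches <= 3),
            )
        )
    return points


def concentration_response(
    genome: Mapping[str, str],
    guide: GuideRNA,
    truth: Sequence[PlantedSite],
    concentrations: Sequence[float],
    params: CallerParams | None = None,
    sim_config: SimConfig | None = None,
    read_budget: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Full simulate->call sweep over an RGEN concentration grid.

    The truth set and the simulation seed are shared across concentrations,
    so realised cleavage counts are coupled (monotone non-decreasing in C
    site by site).  ``read_budget`` caps the sequenced reads per library,
    emulating a fixed sequencing depth: past saturation, more cleaved sites
    dilute the per-site coverage, which is what drives the median score back
    down at high concentration.  Returns one row per concentration with the
    number of recovered (guide-matched) sites and their median score.
    """
    concs = list(concentrations)
    if concs != sorted(concs):
        raise ValueError("concentrations must be ascending")
    params = params or CallerParams()
    base = sim_config or SimConfig()
    rows = []
    for i, conc in enumerate(concs):
        cfg = replace(base, rgen_concentration_nM=float(conc))
        counts = simulate_cleavage(truth, cfg)
        background = draw_background_breaks(genome, cfg)
        sim = simulate_reads(genome, truth, counts, background, cfg, sam_path=None)
        track = sim.track
        if read_budget is not None and track.total_mapped > read_budget:
            track = subsample_track(track, read_budget / track.total_mapped, seed=seed * 1000 + i)
        calls = call_cut_sites(track, genome, guide, params)
        matched = [r for r in calls if r.mismatches is not None]
        scores = np.array([r.score for r in matched], dtype=float)
        rows.append(
            {
                "concentration_nM": float(conc),
                "total_reads": track.total_mapped,
                "cleaved_molecules": int(sum(counts)),
                "recovered_sites": len(matched),
                "median_score": float(np.median(scores)) if len(scores) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _mismatch_group(mm: int) -> str | None:
    if mm <= 3:
        return "0-3"
    if mm <= 7:
        return str(mm)
    return None


def score_stats_by_mismatch(sites: SiteSet, log_scale: bool = False) -> pd.DataFrame:
    """Count, median and variance of scores per mismatch group.

    Groups follow the reporting convention {0-3, 4, 5, 6, 7}: the lowest
    group pools everything up to three mismatches.  Unmatched sites (no
    mismatch annotation) and sites beyond 7 mismatches are excluded.
    Variance is the unbiased sample variance (NaN for groups with < 2
    sites); with ``log_scale`` a log10-variance column is added for
    log-axis presentation.
    """
    rows = [
        (g, r.score)
        for r in sites
        if r.mismatches is not None and (g := _mismatch_group(r.mismatches)) is not None
    ]
    df = pd.DataFrame(rows, columns=["mismatch_group", "score"])
    stats = (
        df.groupby("mismatch_group")["score"]
        .agg(count="count", median_score="median", var_score=lambda s: s.var(ddof=1))
        .reindex(MISMATCH_GROUPS)
    )
    stats["count"] = stats["count"].fillna(0).astype(int)
    if log_scale:
        with np.errstate(divide="ignore"):
            stats["log10_var_score"] = np.log10(stats["var_score"].astype(float))
    return stats.reset_index()
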