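"""Self-contained benchmark scenarios built entirely from the simulator.

These functions wire the synthetic-data generator, the caller and the
diagnostics into reproducible end-to-end scenarios used by the test suite
and the ``benchmark`` CLI subcommand.  Every scenario is deterministic
given its seed; problem sizes are chosen to finish in seconds-to-minutes
on one CPU while keeping per-site coverage in the regimes the method's
claims concern.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .align_io import ReadEndTrack
from .cutsite_caller import CallerParams, call_cut_sites
from .synthetic_data import (
    CUT_OFFSET,
    GuideRNA,
    PlantedSite,
    PlantingError,
    SimConfig,
    SimResult,
    generate_genome,
    plant_sites,
    simulate_library,
)

log = logging.getLogger(__name__)


@dataclass
class Scenario:
    """A fully realised simulation scenario with its ground truth."""

    genome: dict[str, str]
    guide: GuideRNA
    sites: list[PlantedSite]
    config: SimConfig
    sim: SimResult

    @property
    def track(self) -> ReadEndTrack:
        return self.sim.track

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _random_guide(seed: int, name: str = "sgSim") -> GuideRNA:
    rng = np.random.default_rng([seed, 17])
    proto = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))
    return GuideRNA(name, proto)


def _build(
    seed: int,
    genome_length: int,
    site_plan: list[tuple[int, str, float]],
    config: SimConfig,
    verify_max_mismatches: int,
    gc_content: float = 0.42,
) -> Scenario:
    """Generate genome + sites, retrying with a fresh genome when the random
    background happens to contain an irreducible near-match to the guide."""
    guide = _random_guide(seed)
    for attempt in range(6):
        genome_seed = seed + 7919 * attempt
        genome = {"chr_sim": generate_genome(genome_length, gc_content, genome_seed)}
        try:
            planted, sites = plant_sites(
                genome,
                guide,
                site_plan,
                seed=genome_seed,
                verify_max_mismatches=verify_max_mismatches,
            )
        except PlantingError:
            log.info("fixture genome %d rejected, regenerating", attempt)
            continue
        sim = simulate_library(planted, sites, config)
        return Scenario(planted, guide, sites, config, sim)
    raise PlantingError("could not build a collision-free scenario in 6 attempts")


def standard_scenario(seed: int = 11) -> Scenario:
    """The workhorse recovery benchmark.

    1-Mb genome, 12 planted sites with 0-6 mismatches, affinities log-spaced
    over two decades (4-400 nM), 64 nM RGEN, 20k template copies, end repair
    on, low uniform background — about 200k productive reads, with every
    low-mismatch site covered thousands of times.
    """
    mismatches = [0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6]
    strands = ["+", "-"] * 6
    affinities = np.logspace(np.log10(4.0), np.log10(400.0), len(mismatches))
    plan = list(zip(mismatches, strands, affinities))
    config = SimConfig(
        genome_length=1_000_000,
        genome_copies=20_000,
        rgen_concentration_nM=64.0,
        end_repair=True,
        background_break_rate=1e-5,
        p7L_ligation_efficiency=0.8,
        seed=seed,
    )
    return _build(seed, config.genome_length, plan, config, verify_max_mismatches=4)


def replicate_scenarios(seed: int = 23) -> tuple[Scenario, Scenario]:
    """Two independently seeded libraries from one truth set.

    36 sites spanning 0-6 mismatches with affinities log-spaced over two
    decades, 2k copies each — every site expects well over 100 reads, the
    regime where replicate score scatter is dominated by true affinity
    differences rather than counting noise.
    """
    mismatches = [0] + [1] * 2 + [2] * 3 + [3] * 6 + [4] * 8 + [5] * 8 + [6] * 8
    strands = (["+", "-"] * 18)[: len(mismatches)]
    affinities = np.logspace(np.log10(6.4), np.log10(640.0), len(mismatches))
    plan = list(zip(mismatches, strands, affinities))
    config = SimConfig(
        genome_length=400_000,
        genome_copies=2_000,
        rgen_concentration_nM=64.0,
        background_break_rate=1e-5,
        seed=seed,
    )
    first = _build(seed, config.genome_length, plan, config, verify_max_mismatches=4)
    # same genome and truth, independent library realisation
    sim2 = simulate_library(first.genome, first.sites, replace(config, seed=seed + 1))
    second = Scenario(first.genome, first.guide, first.sites, replace(config, seed=seed + 1), sim2)
    return first, second


def end_repair_pair(seed: int = 31) -> tuple[Scenario, Scenario]:
    """Paired libraries differing only in the end-repair step.

    Same genome, truth set and seed; the second library skips end repair
    (geometric end recession, mean 5 bp, on the PAM-distal flank), which is
    the treatment contrast behind the flank-skewness diagnostic.
    """
    mismatches = [0, 1, 1, 2, 2, 3, 0, 1, 2, 3, 2, 3]
    strands = ["+", "-"] * 6
    affinities = np.logspace(np.log10(4.0), np.log10(40.0), len(mismatches))
    plan = list(zip(mismatches, strands, affinities))
    config_on = SimConfig(
        genome_length=200_000,
        genome_copies=2_000,
        rgen_concentration_nM=64.0,
        end_repair=True,
        background_break_rate=1e-5,
        seed=seed,
    )
    on = _build(seed, config_on.genome_length, plan, config_on, verify_max_mismatches=3)
    config_off = replace(config_on, end_repair=False, resection_mean=5.0)
    sim_off = simulate_library(on.genome, on.sites, config_off)
    off = Scenario(on.genome, on.guide, on.sites, config_off, sim_off)
    return on, off


def concentration_scenario(seed: int = 47) -> tuple[Scenario, list[float], int]:
    """Truth set and grid for the concentration-response sweep.

    Affinities span two decades (30-3000 nM) with site multiplicity growing
    toward weak affinity (2 strong, 8 intermediate, 40 weak sites) — genomes
    hold far more high-mismatch, low-affinity near-targets than true targets.
    A fixed read budget of 1500 reads per library and a sizeable uniform
    background emulate constant sequencing depth; the returned scenario's
    ``sim`` is a placeholder at the lowest concentration (the sweep re-runs
    the library per concentration).
    """
    plan: list[tuple[int, str, float]] = []
    rng = np.random.default_rng([seed, 5])
    for mm, K, n in ((0, 30.0, 1), (1, 30.0, 1), (2, 300.0, 4), (3, 300.0, 4), (4, 3000.0, 14), (5, 3000.0, 13), (6, 3000.0, 13)):
        for _ in range(n):
            plan.append((mm, "+" if rng.random() < 0.5 else "-", K))
    config = SimConfig(
        genome_length=300_000,
        genome_copies=400,
        rgen_concentration_nM=16.0,
        background_break_rate=0.05,
        p7L_ligation_efficiency=0.8,
        seed=seed,
    )
    scenario = _build(seed, config.genome_length, plan, config, verify_max_mismatches=3)
    grid = [16.0, 32.0, 64.0, 128.0, 256.0, 512.0, 1024.0]
    read_budget = 1500
    return scenario, grid, read_budget


def modal_pam_offset(calls, truth_sites, tolerance: int = 1) -> float:
    """Modal distance (bp) from the observed pileup position to the matched
    PAM's 5' edge, in protospacer orientation, over called sites recovered
    within ``tolerance`` of a ground-truth breakpoint.

    The pileup position is the caller's raw candidate (plateau center of the
    read-end signature), so the distance is measured from the data, not from
    the placement arithmetic; a canonical blunt cut gives 3.
    """
    offsets: list[int] = []
    for s in truth_sites:
        near = [
            r
            for r in calls
            if r.chrom == s.chrom and abs(r.cut_position - s.cut_position) <= tolerance
        ]
        for r in near:
            observed = r.candidate_position if r.candidate_position is not None else r.cut_position
            if r.strand == "+":
                pam_edge = r.cut_position + CUT_OFFSET
                offsets.append(pam_edge - observed)
            elif r.strand == "-":
                pam_edge = r.cut_position - CUT_OFFSET
                offsets.append(observed - pam_edge)
    if not offsets:
        return float("nan")
    vals, counts = np.unique(offsets, return_counts=True)
    return float(vals[counts.argmax()])


def run_benchmark(seed: int = 11) -> dict[str, float]:
    """End-to-end benchmark: recovery, offset law, replicate correlation.

    Returns a flat metric dict (also printed by ``rgenseq benchmark``).
    """
    from . import diagnostics, site_compare

    sc = standard_scenario(seed)
    calls = call_cut_sites(sc.track, sc.genome, sc.guide, CallerParams())
    matched = [r for r in calls if r.mismatches is not None]

    truth_low = [s for s in sc.sites if s.mismatches <= 3]
    recovered = sum(
        1
        for s in truth_low
        if any(r.chrom == s.chrom and abs(r.cut_position - s.cut_position) <= 1 for r in matched)
    )
    modal_offset = modal_pam_offset(matched, truth_low)

    rep_a, rep_b = replicate_scenarios(seed + 101)
    calls_a = call_cut_sites(rep_a.track, rep_a.genome, rep_a.guide, name="repA")
    calls_b = call_cut_sites(rep_b.track, rep_b.genome, rep_b.guide, name="repB")
    _, r2 = site_compare.score_correlation(calls_a, calls_b)

    on, off = end_repair_pair(seed + 211)
    skew_on = diagnostics.skewness_table(on.track, on.sites)["skewness_percent"].median()
    skew_off = diagnostics.skewness_table(off.track, off.sites)["skewness_percent"].median()

    return {
        "n_reads_standard": float(sc.sim.n_reads),
        "recall_low_mismatch": recovered / len(truth_low) * 100.0,
        "modal_pam_offset_bp": modal_offset,
        "replicate_score_r2": r2,
        "median_skew_end_repair_on": float(skew_on),
        "median_skew_end_repair_off": float(skew_off),
    }
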