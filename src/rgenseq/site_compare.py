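"""Comparison of cleavage-site sets across replicates or methods.

Sites from different inputs are merged by single-linkage clustering of
positions on the same chromosome (strand is ignored when merging: a
cleavage site is a genomic breakpoint; the matched protospacer strand is
annotation).  The resulting membership matrix supports UpSet-style
"distinct" (exactly this combination) and "intersect" (at least this
combination) counting, and score correlation over shared sites.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align_io import SiteSet

log = logging.getLogger(__name__)


class InsufficientSitesError(ValueError):
    """Fewer shared sites than a correlation needs."""


@dataclass
class MembershipMatrix:
    """Merged site list: one row per merged site, presence/score per input.

    ``table`` columns: chrom, position (representative: the highest-scoring
    member's coordinate, tie -> leftmost), then ``in_<name>`` booleans and
    ``score_<name>`` floats (NaN when absent) for every input.
    """

    table: pd.DataFrame
    inputs: list[str]

    def __len__(self) -> int:
        return len(self.table)

    def presence(self) -> pd.DataFrame:
        return self.table[[f"in_{n}" for n in self.inputs]].rename(
            columns={f"in_{n}": n for n in self.inputs}
        )


def merge_site_sets(sets: list[SiteSet], tolerance: int = 5) -> MembershipMatrix:
    """Single-linkage merge of site sets with a positional tolerance (bp).

    Two sites on the same chromosome link when their positions differ by at
    most ``tolerance``; clusters are the connected components, so every
    input site lands in exactly one merged row.  Raises on duplicate input
    names or when two non-empty inputs share no chromosome names (which
    signals mismatched assemblies).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"input site sets must have unique names, got {names}")
    nonempty = [s for s in sets if len(s)]
    for a, b in itertools.combinations(nonempty, 2):
        if not a.chroms() & b.chroms():
            raise ValueError(
                f"site sets {a.name!r} and {b.name!r} share no chromosome names; "
                "are they on the same assembly?"
            )

    entries = []  # (chrom, position, score, input_name)
    for s in sets:
        for r in s:
            entries.append((r.chrom, r.cut_position, float(r.score), s.name))
    entries.sort(key=lambda e: (e[0], e[1]))

    rows = []
    cluster: list[tuple[str, int, float, str]] = []

    def flush() -> None:
        if not cluster:
            return
        rep = max(cluster, key=lambda e: (e[2], -e[1]))  # max score, tie -> leftmost
        row: dict[str, object] = {"chrom": rep[0], "position": rep[1]}
        for n in names:
            member_scores = [e[2] for e in cluster if e[3] == n]
            row[f"in_{n}"] = bool(member_scores)
            row[f"score_{n}"] = max(member_scores) if member_scores else np.nan
        rows.append(row)

    for e in entries:
        if cluster and (e[0] != cluster[-1][0] or e[1] - cluster[-1][1] > tolerance):
            flush()
            cluster = []
        cluster.append(e)
    flush()

    cols = ["chrom", "position"]
    for n in names:
        cols += [f"in_{n}", f"score_{n}"]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values(["chrom", "position"], ignore_index=True)
    return MembershipMatrix(table=table, inputs=list(names))


def combination_counts(
    matrix: MembershipMatrix, mode: str = "distinct"
) -> dict[tuple[str, ...], int]:
    """Counts of merged sites per input combination (UpSet semantics).

    ``distinct``: rows present in exactly the named inputs and no other
    (counts over all combinations partition the merged rows).
    ``intersect``: rows present in at least the named inputs.
    """
    if mode not in ("distinct", "intersect"):
        raise ValueError(f"mode must be 'distinct' or 'intersect', got {mode!r}")
    if len(matrix.inputs) < 2:
        raise ValueError("need at least two input sets to compare")
    presence = matrix.presence()
    counts: dict[tuple[str, ...], int] = {}
    for k in range(1, len(matrix.inputs) + 1):
        for combo in itertools.combinations(matrix.inputs, k):
            in_combo = presence[list(combo)].all(axis=1)
            if mode == "distinct":
                others = [n for n in matrix.inputs if n not in combo]
                out_others = ~presence[others].any(axis=1) if others else True
                counts[combo] = int((in_combo & out_others).sum())
            else:
                counts[combo] = int(in_combo.sum())
    return counts


def score_correlation(
    a: SiteSet | MembershipMatrix,
    b: SiteSet | None = None,
    tolerance: int = 5,
    shared_only: bool = True,
) -> tuple[float, float]:
    """Pearson correlation of scores over shared sites: returns (r, R^2).

    Accepts either two site sets (merged here with ``tolerance``) or a
    prebuilt two-input membership matrix.  Requires at least three shared
    sites.
    """
    if isinstance(a, MembershipMatrix):
        matrix = a
        if len(matrix.inputs) != 2:
            raise ValueError("score correlation needs exactly two inputs")
    else:
        if b is None:
            raise ValueError("two site sets (or a membership matrix) required")
        matrix = merge_site_sets([a, b], tolerance=tolerance)
    n1, n2 = matrix.inputs
    t = matrix.table
    if shared_only:
        t = t[t[f"in_{n1}"] & t[f"in_{n2}"]]
    x = t[f"score_{n1}"].to_numpy(dtype=float)
    y = t[f"score_{n2}"].to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientSitesError(
            f"score correlation needs >= 3 shared sites, got {len(x)}"
        )
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r


def combination_counts_table(counts: dict[tuple[str, ...], int]) -> pd.DataFrame:
    """Tidy one-row-per-combination view of :func:`combination_counts`."""
    rows = [
        {"combination": "&".join(combo), "degree": len(combo), "count": n}
        for combo, n in sorted(counts.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["combination", "degree", "count"])
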