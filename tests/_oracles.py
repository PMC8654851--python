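"""Independent brute-force reference implementations used only by tests.

Everything here is written position-by-position in plain Python, sharing no
code path with the package's vectorised implementations.
"""
from __future__ import annotations

import itertools

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def brute_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_genome_scan(genome: dict[str, str], protospacer: str, pam: str,
                      max_mismatches: int) -> list[tuple[str, int, str, int]]:
    """Position-by-position scan of both strands for protospacer+PAM placements."""
    hits = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for s in range(len(seq) - len(protospacer) - len(pam) + 1):
            window = seq[s : s + len(protospacer)]
            pam_seq = seq[s + len(protospacer) : s + len(protospacer) + len(pam)]
            if all(b in _IUPAC[p] for b, p in zip(pam_seq, pam)):
                mm = sum(a != b for a, b in zip(window, protospacer))
                if mm <= max_mismatches:
                    hits.append((chrom, s, "+", mm))
        for s in range(len(pam), len(seq) - len(protospacer) + 1):
            window = brute_revcomp(seq[s : s + len(protospacer)])
            pam_seq = brute_revcomp(seq[s - len(pam) : s])
            if all(b in _IUPAC[p] for b, p in zip(pam_seq, pam)):
                mm = sum(a != b for a, b in zip(window, protospacer))
                if mm <= max_mismatches:
                    hits.append((chrom, s, "-", mm))
    return sorted(hits)


def brute_window_sum(ends: dict[tuple[str, int], int], chrom: str, position: int,
                     width: int = 10) -> int:
    """Direct enumeration of the half-open window [pos - w/2, pos + w/2)."""
    return sum(
        ends.get((chrom, p), 0)
        for p in range(position - width // 2, position + width // 2)
    )


def brute_single_linkage(points: list[tuple[str, int]], tolerance: int) -> list[set[int]]:
    """Connected components under |dpos| <= tolerance on the same chromosome,
    found by exhaustive pairwise union-find."""
    parent = list(range(len(points)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(points)), 2):
        if points[i][0] == points[j][0] and abs(points[i][1] - points[j][1]) <= tolerance:
            parent[find(i)] = find(j)
    clusters: dict[int, set[int]] = {}
    for i in range(len(points)):
        clusters.setdefault(find(i), set()).add(i)
    return sorted(clusters.values(), key=lambda s: min(s))
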