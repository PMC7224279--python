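"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (exhaustive scans, triple loops,
closed-form matrix algebra, enumeration) and shares no code with the
implementation paths it verifies.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------- k-mer scan


def brute_force_kmer_hits(contigs: dict[str, str], kmer: str) -> set[tuple[str, int, str]]:
    """All genomic occurrences of a k-mer on both strands by direct string scan."""
    hits = set()
    k = len(kmer)
    for contig, seq in contigs.items():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if w == kmer:
                hits.add((contig, i, "+"))
            if w == rc(kmer):
                hits.add((contig, i, "-"))
    return hits


# ------------------------------------------------------- splice-scan oracle


def _mismatch_profile(genome: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """mm[i] = mismatches of pattern aligned at genome position i (all i)."""
    n, m = genome.size, pattern.size
    if n < m:
        return np.zeros(0, dtype=int)
    mm = np.zeros(n - m + 1, dtype=int)
    for t in range(m):
        mm += genome[t : n - m + 1 + t] != pattern[t]
    return mm


def splice_scan_oracle(
    read: str,
    contigs: dict[str, str],
    anchor_length: int = 20,
    max_mismatches: int = 1,
    require_canonical: bool = True,
) -> tuple[str, str, int, int] | None:
    """Exhaustive back-splice scan of one read against small contigs.

    Tries every breakpoint of the read (both orientations) against every
    admissible placement pair (terminal anchors exact, right part strictly
    upstream of and non-overlapping the left part), keeps the placements with
    the fewest mismatches, applies the canonical-splice requirement, and
    reports the junction only if it is unique.  Returns
    (contig, strand, start, end) or None.
    """
    k = anchor_length
    signals = {("AG", "GT"): "+", ("AC", "CT"): "-"}
    candidates: list[tuple[int, str, str, int, int]] = []  # (mm, contig, strand, start, end)
    for orient in (read.upper(), rc(read.upper())):
        L = len(orient)
        s_codes = np.frombuffer(orient.encode(), dtype=np.uint8)
        for contig, seq in contigs.items():
            g = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            for j in range(k, L - k + 1):
                left, right = s_codes[:j], s_codes[j:]
                mm_left = _mismatch_profile(g, left)
                anchor_left = _mismatch_profile(g, left[:k]) if j > k else mm_left
                i1_all = np.nonzero((mm_left <= max_mismatches) & (anchor_left[: mm_left.size] == 0))[0]
                mm_right = _mismatch_profile(g, right)
                anchor_right = _mismatch_profile(g, right[-k:])
                off = right.size - k
                i2_all = np.nonzero(
                    (mm_right <= max_mismatches) & (anchor_right[off : off + mm_right.size] == 0)
                )[0]
                for i1 in i1_all:
                    for i2 in i2_all:
                        if i2 + k > i1:  # head-to-tail: right anchor strictly upstream
                            continue
                        mm = int(mm_left[i1] + mm_right[i2])
                        if mm > max_mismatches:
                            continue
                        start, end = int(i2), int(i1 + j)
                        if start >= end:
                            continue
                        strand = signals.get((seq[start - 2 : start], seq[end : end + 2]))
                        if require_canonical and strand is None:
                            continue
                        candidates.append((mm, contig, strand or "+", start, end))
    if not candidates:
        return None
    best = min(c[0] for c in candidates)
    keep = {(c, s, a, b) for mm, c, s, a, b in candidates if mm == best}
    if len(keep) != 1:
        return None
    return next(iter(keep))


# -------------------------------------------------------------- PCIT oracle


def naive_pcit(R: np.ndarray) -> np.ndarray:
    """Direct O(n^3) PCIT with explicit trio loops (reference semantics)."""
    R = np.clip(np.asarray(R, dtype=float), -(1 - 1e-12), 1 - 1e-12)
    n = R.shape[0]
    keep = ~np.eye(n, dtype=bool)
    if n < 3:
        return keep

    def partial(a, b, c):
        return (R[a, b] - R[a, c] * R[b, c]) / math.sqrt(
            (1 - R[a, c] ** 2) * (1 - R[b, c] ** 2)
        )

    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            for z in range(n):
                if z == x or z == y:
                    continue
                trio = [
                    (partial(x, y, z), R[x, y]),
                    (partial(x, z, y), R[x, z]),
                    (partial(y, z, x), R[y, z]),
                ]
                ratios = [p / r for p, r in trio if abs(r) >= 1e-12]
                if not ratios:
                    continue
                eps = sum(ratios) / len(ratios)
                if abs(R[x, y]) <= abs(eps * R[x, z]) and abs(R[x, y]) <= abs(eps * R[y, z]):
                    keep[x, y] = False
                    break
    return keep


# --------------------------------------------------------------- OLS / stats


def hat_matrix_residuals(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(I - X (X'X)^-1 X') y computed directly."""
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    return (np.eye(len(y)) - H) @ y


def pearson_by_formula(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd, yd = x - x.mean(), y - y.mean()
    return float((xd * yd).sum() / math.sqrt((xd**2).sum() * (yd**2).sum()))


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration (no ties)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    obs_u = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = [
        sum(c) - n1 * (n1 + 1) / 2
        for c in itertools.combinations(range(1, len(pooled) + 1), n1)
    ]
    us = np.array(us)
    p_low = np.mean(us <= obs_u)
    p_high = np.mean(us >= obs_u)
    return float(min(1.0, 2 * min(p_low, p_high)))
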