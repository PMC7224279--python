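"""Back-splice junction (BSJ) detection from RNA-seq reads.

The caller follows the anchor-splitting strategy of circRNA discovery
pipelines: the two terminal anchors of a read are placed on the genome by
exact k-mer lookup; a hit pair in head-to-tail order (right anchor upstream
of the left anchor) indicates a candidate back-splice.  Both anchors are
then extended toward the read interior, the breakpoint is the split
maximizing matches, and the candidate is reported only when a single best
breakpoint exists and the genomic splice signal is canonical (GT at the
donor, AG at the acceptor, read on the annotated strand; the signal reads
AC...CT on the + strand for a - strand junction).

Candidates are aggregated per junction within a sample, filtered by the
stringency rules (>=2 unique supporting reads, junction-window Phred >= 35),
and merged across samples keeping junctions seen in a minimum number of
samples (default three quarters of the cohort).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomePackage, revcomp, format_coord


@dataclass
class DetectionParams:
    anchor_length: int = 20
    max_extension_mismatches: int = 1
    require_canonical_splice: bool = True
    max_anchor_hits: int = 1
    min_unique_support: int = 2
    min_junction_phred: float = 35.0
    max_circle_span: int = 1_000_000
    junction_window: int = 10  # +/- nt around the breakpoint for the quality score

    def __post_init__(self) -> None:
        if self.anchor_length < 12:
            raise ValueError("anchor_length must be >= 12")
        if min(self.max_extension_mismatches, self.max_anchor_hits,
               self.min_unique_support, self.min_junction_phred, self.max_circle_span) < 0:
            raise ValueError("thresholds must be non-negative")


class GenomeIndex:
    """Exact k-mer lookup over the + strand of every contig.

    Minus-strand occurrences of a k-mer are, by definition, + strand
    occurrences of its reverse complement, so both strands are queryable.
    """

    def __init__(self, contigs: dict[str, str], k: int):
        shortest = min((len(s) for s in contigs.values()), default=0)
        if not contigs:
            raise ValueError("no contigs")
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest contig length {shortest}")
        self.contigs = {c: s.upper() for c, s in contigs.items()}
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((contig, i))
        self._index = index

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """+ strand occurrences (contig, start) of ``kmer``."""
        return self._index.get(kmer, [])

    def query(self, kmer: str) -> list[tuple[str, int, str]]:
        """Occurrences of ``kmer`` on both strands as (contig, +strand start, strand)."""
        hits = [(c, p, "+") for c, p in self.lookup(kmer)]
        hits += [(c, p, "-") for c, p in self.lookup(revcomp(kmer))]
        return hits

    def n_genomic_hits(self, kmer: str) -> int:
        return len(self.lookup(kmer)) + len(self.lookup(revcomp(kmer)))


def build_index(genome: GenomePackage | dict[str, str], anchor_length: int = 20) -> GenomeIndex:
    contigs = genome.contigs if isinstance(genome, GenomePackage) else genome
    return GenomeIndex(contigs, anchor_length)


@dataclass
class BsjEvidence:
    """One read's evidence for a back-splice junction."""

    contig: str
    strand: str
    start: int  # genomic span [start, end); acceptor on '+', donor on '-'
    end: int
    splice_signal: str
    anchors_unique: bool
    junction_phred: float

    @property
    def donor_pos(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def acceptor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class BsjCandidate:
    """A putative junction aggregated over the supporting reads of one sample."""

    contig: str
    strand: str
    start: int
    end: int
    splice_signal: str = ""
    supporting_read_ids: set[str] = field(default_factory=set)
    _unique_frags: dict[str, bool] = field(default_factory=dict)
    min_junction_phred: float = math.inf
    breakpoint_ambiguous: bool = False

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.contig, self.strand, self.start, self.end)

    @property
    def donor_pos(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def acceptor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def n_support(self) -> int:
        return len(self.supporting_read_ids)

    @property
    def n_unique_support(self) -> int:
        return sum(self._unique_frags.values())

    @property
    def span(self) -> int:
        return self.end - self.start

    def add(self, fragment_id: str, ev: BsjEvidence) -> None:
        if fragment_id not in self.supporting_read_ids:
            self.supporting_read_ids.add(fragment_id)
            self._unique_frags[fragment_id] = ev.anchors_unique
        else:  # a mate of an already-counted fragment: uniqueness is OR'd
            self._unique_frags[fragment_id] |= ev.anchors_unique
        self.min_junction_phred = min(self.min_junction_phred, ev.junction_phred)
        self.splice_signal = ev.splice_signal


_SIGNALS = {("AG", "GT"): "+", ("AC", "CT"): "-"}  # (before start, after end) on + strand


def _signal_at(contig_seq: str, start: int, end: int) -> str | None:
    """Strand implied by the splice dinucleotides flanking [start, end), or None."""
    if start < 2 or end + 2 > len(contig_seq):
        return None
    return _SIGNALS.get((contig_seq[start - 2 : start], contig_seq[end : end + 2]))


def _scan_orientation(
    seq: str, index: GenomeIndex, params: DetectionParams
) -> list[tuple[str, str, int, int, int]]:
    """All acceptable (contig, strand, start, end, breakpoint j) for one read orientation."""
    k = params.anchor_length
    L = len(seq)
    left_hits = index.lookup(seq[:k])
    if not left_hits:
        return []
    right_hits = index.lookup(seq[L - k :])
    if not right_hits:
        return []
    out = []
    for cL, pL in left_hits:
        contig_seq = index.contigs[cL]
        for cR, pR in right_hits:
            # head-to-tail: the right anchor must map strictly upstream
            if cR != cL or pR + k > pL:
                continue
            # prefix/suffix mismatch accumulators over breakpoints j in [k, L-k]
            left_mm = [0] * (L + 1)
            for j in range(1, L - k + 1):
                left_mm[j] = left_mm[j - 1] + (
                    1 if pL + j - 1 >= len(contig_seq) or seq[j - 1] != contig_seq[pL + j - 1] else 0
                )
            right_mm = [0] * (L + 1)
            for j in range(L - 1, k - 1, -1):
                g = pR + k - (L - j)
                right_mm[j] = right_mm[j + 1] + (1 if g < 0 or seq[j] != contig_seq[g] else 0)
            best_mm, best_js = None, []
            for j in range(k, L - k + 1):
                mm = left_mm[j] + right_mm[j]
                if mm > params.max_extension_mismatches:
                    continue
                if best_mm is None or mm < best_mm:
                    best_mm, best_js = mm, [j]
                elif mm == best_mm:
                    best_js.append(j)
            for j in best_js:
                start = pR + k - (L - j)
                end = pL + j
                if start >= end:
                    continue
                sig = _signal_at(contig_seq, start, end)
                if params.require_canonical_splice and sig is None:
                    continue
                out.append((cL, sig or "+", start, end, j))
    return out


def detect_bsj_in_read(
    seq: str,
    qualities: str | np.ndarray,
    index: GenomeIndex,
    params: DetectionParams | None = None,
) -> BsjEvidence | None:
    """Detect a back-splice junction in one read, or return None.

    Both the read and its reverse complement are probed (minus-strand
    junctions surface through the splice-signal pattern).  A read with more
    than one admissible breakpoint/junction is discarded as ambiguous.
    """
    params = params or DetectionParams()
    seq = seq.upper()
    L = len(seq)
    k = params.anchor_length
    if L < 2 * k + 1:
        return None
    if isinstance(qualities, str):
        quals = np.frombuffer(qualities.encode(), dtype=np.uint8).astype(float) - 33.0
    else:
        quals = np.asarray(qualities, dtype=float)

    found: list[tuple] = []  # (contig, strand, start, end, j, oriented_seq_is_rc)
    for rc in (False, True):
        oseq = revcomp(seq) if rc else seq
        for contig, strand, start, end, j in _scan_orientation(oseq, index, params):
            found.append((contig, strand, start, end, j, rc))
    distinct = {(c, s, a, b) for c, s, a, b, _, _ in found}
    if len(distinct) != 1:
        return None  # no junction, or ambiguous breakpoint/placement
    contig, strand, start, end, j, rc = found[0]

    oseq = revcomp(seq) if rc else seq
    oquals = quals[::-1] if rc else quals
    w = params.junction_window
    window = oquals[max(0, j - w) : min(L, j + w)]
    junction_phred = float(window.mean())

    n_left = index.n_genomic_hits(oseq[:k])
    n_right = index.n_genomic_hits(oseq[L - k :])
    unique = n_left <= params.max_anchor_hits and n_right <= params.max_anchor_hits
    contig_seq = index.contigs[contig]
    signal = contig_seq[start - 2 : start] + "/" + contig_seq[end : end + 2]
    return BsjEvidence(
        contig=contig,
        strand=strand,
        start=start,
        end=end,
        splice_signal=signal,
        anchors_unique=unique,
        junction_phred=junction_phred,
    )


_MATE_SUFFIX = re.compile(r"/[12]$")


def call_sample(
    fastq_paths: str | Path | list[str | Path],
    index: GenomeIndex,
    params: DetectionParams | None = None,
) -> list[BsjCandidate]:
    """Scan one sample's FASTQ file(s) and aggregate junction candidates.

    Paired-end mates (read names differing only by a ``/1``/``/2`` suffix)
    probe the junction independently but count once per fragment toward
    support.
    """
    import pysam

    params = params or DetectionParams()
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    candidates: dict[tuple, BsjCandidate] = {}
    for path in fastq_paths:
        record_idx = 0
        try:
            with pysam.FastxFile(str(path)) as fh:
                for entry in fh:
                    record_idx += 1
                    if entry.sequence is None or entry.quality is None:
                        raise ValueError("record missing sequence or quality")
                    if len(entry.sequence) < 2 * params.anchor_length + 1:
                        continue
                    ev = detect_bsj_in_read(entry.sequence, entry.quality, index, params)
                    if ev is None:
                        continue
                    frag_id = _MATE_SUFFIX.sub("", entry.name)
                    key = (ev.contig, ev.strand, ev.start, ev.end)
                    cand = candidates.get(key)
                    if cand is None:
                        cand = candidates[key] = BsjCandidate(
                            contig=ev.contig, strand=ev.strand, start=ev.start, end=ev.end
                        )
                    cand.add(frag_id, ev)
        except (ValueError, OSError) as exc:
            raise ValueError(f"malformed FASTQ {path!s} at record {record_idx + 1}: {exc}") from exc
    return sorted(candidates.values(), key=lambda c: c.key)


def filter_candidates(
    candidates: list[BsjCandidate], params: DetectionParams | None = None
) -> list[BsjCandidate]:
    """Apply the stringency filters: unique support, junction quality, span."""
    params = params or DetectionParams()
    return [
        c
        for c in candidates
        if c.n_unique_support >= params.min_unique_support
        and c.min_junction_phred >= params.min_junction_phred
        and not c.breakpoint_ambiguous
        and c.span <= params.max_circle_span
    ]


def merge_across_samples(
    per_sample: dict[str, list[BsjCandidate]] | list[tuple[str, list[BsjCandidate]]],
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Merge filtered per-sample candidates into a junction x sample count matrix.

    Junctions are matched by exact (contig, strand, donor, acceptor) and kept
    when detected in at least ``min_samples`` samples (default
    ceil(0.75 x n_samples)).  Cell values are BSJ-supporting fragment counts
    (0 where the junction was not detected).  Row index:
    ``contig:start..end:strand`` (1-based inclusive display coordinates).
    """
    if isinstance(per_sample, dict):
        items = list(per_sample.items())
    else:
        items = list(per_sample)
        ids = [s for s, _ in items]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids: {sorted(ids)}")
    n_samples = len(items)
    if n_samples == 0:
        raise ValueError("no samples to merge")
    if min_samples is None:
        min_samples = math.ceil(0.75 * n_samples)

    sample_ids = [s for s, _ in items]
    counts: dict[tuple, dict[str, int]] = {}
    for sample, cands in items:
        for c in cands:
            counts.setdefault(c.key, {})[sample] = c.n_support
    kept = [key for key, per in counts.items() if len(per) >= min_samples]
    kept.sort()
    rows = [
        f"{format_coord(contig, start, end)}:{strand}"
        for contig, strand, start, end in kept
    ]
    mat = pd.DataFrame(0, index=rows, columns=sample_ids, dtype=int)
    for key, row in zip(kept, rows):
        for sample, n in counts[key].items():
            mat.loc[row, sample] = n
    mat.index.name = "junction"
    return mat


def junction_key_to_coords(key: str) -> tuple[str, str, int, int]:
    """Parse ``contig:start..end:strand`` back to 0-based half-open coordinates."""
    m = re.fullmatch(r"(.+):(\d+)\.\.(\d+):([+-])", key)
    if not m:
        raise ValueError(f"bad junction key {key!r}")
    contig, s, e, strand = m.groups()
    return contig, strand, int(s) - 1, int(e)


def write_candidates_bed(candidates: list[BsjCandidate], path: str | Path) -> None:
    """Per-sample candidate BED6+ (score = support; extra columns as documented)."""
    with open(path, "w") as fh:
        fh.write(
            "#contig\tstart\tend\tname\tscore\tstrand\tunique_support\tjunction_phred\tsplice_signal\n"
        )
        for i, c in enumerate(candidates):
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\tbsj{i + 1:05d}\t{c.n_support}\t{c.strand}\t"
                f"{c.n_unique_support}\t{c.min_junction_phred:.2f}\t{c.splice_signal}\n"
            )


def read_candidates_bed(path: str | Path) -> list[BsjCandidate]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            c = BsjCandidate(contig=f[0], strand=f[5], start=int(f[1]), end=int(f[2]))
            n_support, n_unique = int(f[4]), int(f[6])
            for i in range(n_support):
                c.supporting_read_ids.add(f"frag{i}")
                c._unique_frags[f"frag{i}"] = i < n_unique
            c.min_junction_phred = float(f[7])
            c.splice_signal = f[8] if len(f) > 8 else ""
            out.append(c)
    return out
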