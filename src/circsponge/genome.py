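"""Reference genome and gene-annotation containers.

Coordinates are 0-based half-open internally.  The display format used in
reports is ``contig:start..end`` with a 1-based inclusive start, which is the
convention circRNA catalogues print.

A :class:`GenomePackage` bundles contig sequences with exon-level gene models
(strand, ordered exons, and CDS/UTR sub-intervals).  It round-trips through
plain FASTA + GTF so every downstream stage can also be driven from files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def format_coord(contig: str, start: int, end: int) -> str:
    """Render a 0-based half-open interval as ``contig:start..end`` (1-based inclusive)."""
    return f"{contig}:{start + 1}..{end}"


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) on one contig."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class GeneModel:
    """One gene: ordered exons plus CDS/UTR sub-intervals.

    ``exons`` are stored in genomic (left-to-right) order regardless of
    strand; transcript order is genomic order on ``+`` and reversed on ``-``.
    Feature sub-intervals (``cds``, ``utr5``, ``utr3``) must each be contained
    in an exon.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    def introns(self) -> list[Interval]:
        return [
            Interval(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]

    def validate(self, contig_length: int | None = None) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.gene_id}: exons overlap or unordered")
        if contig_length is not None:
            if self.exons[0].start < 0 or self.exons[-1].end > contig_length:
                raise ValueError(f"{self.gene_id}: exon outside contig bounds")
        for kind, feats in (("CDS", self.cds), ("5UTR", self.utr5), ("3UTR", self.utr3)):
            for f in feats:
                if not any(e.contains(f) for e in self.exons):
                    raise ValueError(f"{self.gene_id}: {kind} interval not inside an exon")


@dataclass
class GenomePackage:
    """Contig sequences plus gene annotation."""

    contigs: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"{g.gene_id}: unknown contig {g.contig}")
            g.validate(len(self.contigs[g.contig]))

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def spliced_sequence(self, contig: str, strand: str, exons: Iterable[Interval]) -> str:
        """Exon-concatenated sequence in transcript (5'->3') orientation."""
        seq = "".join(self.contigs[contig][e.start:e.end] for e in exons)
        return revcomp(seq) if strand == "-" else seq

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gtf(self, path: str | os.PathLike) -> None:
        feature_names = {"cds": "CDS", "utr5": "five_prime_utr", "utr3": "three_prime_utr"}
        with open(path, "w") as fh:
            for g in self.genes:
                tx_id = f"{g.gene_id}.t1"
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{tx_id}";'
                span = g.span
                for feat, iv_list in [("gene", [span]), ("transcript", [span])]:
                    for iv in iv_list:
                        fh.write(
                            f"{g.contig}\tcircsponge\t{feat}\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                        )
                for iv in g.exons:
                    fh.write(
                        f"{g.contig}\tcircsponge\texon\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
                for key, name in feature_names.items():
                    for iv in getattr(g, key):
                        fh.write(
                            f"{g.contig}\tcircsponge\t{name}\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                        )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load all contigs of a FASTA file into memory (pyfaidx-backed)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models from a GTF file via gffutils.

    Recognizes exon, CDS, five_prime_utr and three_prime_utr features grouped
    by ``gene_id``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_gene: dict[str, GeneModel] = {}
    kind_map = {"exon": "exons", "CDS": "cds", "five_prime_utr": "utr5", "three_prime_utr": "utr3"}
    for feat in db.all_features():
        attr = kind_map.get(feat.featuretype)
        if attr is None:
            continue
        gid = feat.attributes["gene_id"][0]
        gm = by_gene.get(gid)
        if gm is None:
            gm = by_gene[gid] = GeneModel(
                gene_id=gid, contig=feat.seqid, strand=feat.strand, exons=[]
            )
        getattr(gm, attr).append(Interval(feat.start - 1, feat.end))
    genes = []
    for gm in by_gene.values():
        gm.exons.sort(key=lambda iv: iv.start)
        for key in ("cds", "utr5", "utr3"):
            getattr(gm, key).sort(key=lambda iv: iv.start)
        genes.append(gm)
    genes.sort(key=lambda g: (g.contig, g.span.start, g.gene_id))
    return genes


def load_genome(fasta_path: str | os.PathLike, gtf_path: str | os.PathLike | None = None) -> GenomePackage:
    contigs = read_fasta(fasta_path)
    genes = read_gtf(gtf_path) if gtf_path is not None else []
    pkg = GenomePackage(contigs=contigs, genes=genes)
    pkg.validate()
    return pkg
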