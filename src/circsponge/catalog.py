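"""circRNA cataloguing: CPM quantification, genomic classification, summaries.

Abundance is normalized as BSJ-spanning reads per million raw sequenced
reads (CPM).  Each junction is classified by co-location with annotation:
no overlapping gene -> intergenic; gene but no exon -> intronic; otherwise
exonic with sub-class (CDS / 5UTR / 3UTR) decided by the feature type
covering the largest share of the circle's exonic overlap (ties broken
CDS > 3UTR > 5UTR).  Host gene is the gene with the largest overlap
(ties alphabetical).  Hotspot genes host >= 5 distinct exonic isoforms.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomePackage, GeneModel, Interval, format_coord

CLASSES = ("CDS", "5UTR", "3UTR", "intronic", "intergenic")
_CLASS_PRIORITY = {"CDS": 0, "3UTR": 1, "5UTR": 2}  # tie-break order


def normalize_cpm(count_matrix: pd.DataFrame, raw_read_totals: pd.Series | dict) -> pd.DataFrame:
    """Counts-per-million: count / raw_total x 1e6, per sample (column)."""
    totals = pd.Series(raw_read_totals, dtype=float)
    for sample in count_matrix.columns:
        if sample not in totals.index or not np.isfinite(totals[sample]) or totals[sample] <= 0:
            raise ValueError(f"missing or non-positive raw read total for sample {sample!r}")
    return count_matrix.astype(float) / totals[count_matrix.columns] * 1e6


class AnnotationIndex:
    """Interval trees over gene spans, per contig, for fast overlap queries."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = genes
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            span = g.span
            self._trees.setdefault(g.contig, IntervalTree()).addi(span.start, span.end, g)

    def overlapping_genes(self, contig: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)), key=lambda g: g.gene_id)


def _overlap(a_start: int, a_end: int, b: Interval) -> int:
    return max(0, min(a_end, b.end) - max(a_start, b.start))


def classify_circrna(
    contig: str,
    start: int,
    end: int,
    annotation: AnnotationIndex | list[GeneModel] | GenomePackage,
) -> tuple[str, str | None, int, int, list[Interval]]:
    """Classify one junction span against the annotation.

    Returns (class, host_gene_id, n_exons, spliced_length, exon_blocks).
    ``exon_blocks`` are the host-gene exons within the span (the inferred
    circle structure); for non-exonic circles it is the genomic span itself.
    """
    if isinstance(annotation, GenomePackage):
        annotation = AnnotationIndex(annotation.genes)
    elif isinstance(annotation, list):
        annotation = AnnotationIndex(annotation)
    genes = annotation.overlapping_genes(contig, start, end)
    span_block = [Interval(start, end)]
    if not genes:
        return "intergenic", None, 0, end - start, span_block
    # genes are sorted by id, so keeping the first maximum breaks ties alphabetically
    host, best_ov = genes[0], _overlap(start, end, genes[0].span)
    for g in genes[1:]:
        ov = _overlap(start, end, g.span)
        if ov > best_ov:
            host, best_ov = g, ov

    exon_ov = {g.gene_id: sum(_overlap(start, end, e) for e in g.exons) for g in genes}
    if all(v == 0 for v in exon_ov.values()):
        return "intronic", host.gene_id, 0, end - start, span_block
    # prefer a host whose exons are actually touched
    if exon_ov[host.gene_id] == 0:
        host = max(genes, key=lambda g: exon_ov[g.gene_id])

    shares = {}
    for cls, feats in (("CDS", host.cds), ("5UTR", host.utr5), ("3UTR", host.utr3)):
        shares[cls] = sum(_overlap(start, end, f) for f in feats)
    if sum(shares.values()) == 0:
        cls = "CDS"  # exonic overlap but no typed feature annotated; default coding
    else:
        cls = min(shares, key=lambda c: (-shares[c], _CLASS_PRIORITY[c]))

    contained = [e for e in host.exons if start <= e.start and e.end <= end]
    if contained:
        n_exons = len(contained)
        spliced = sum(len(e) for e in contained)
        blocks = contained
    else:  # partial exon overlap only: count touched exons, clipped to the span
        touched = [e for e in host.exons if _overlap(start, end, e) > 0]
        blocks = [Interval(max(start, e.start), min(end, e.end)) for e in touched]
        n_exons = len(blocks)
        spliced = sum(len(b) for b in blocks)
    return cls, host.gene_id, n_exons, spliced, blocks


@dataclass
class CatalogEntry:
    circ_id: str
    contig: str
    strand: str
    start: int
    end: int
    circ_class: str
    host_gene: str | None
    n_exons: int
    spliced_length: int
    exon_blocks: list[Interval] = field(default_factory=list)

    @property
    def display_coord(self) -> str:
        return format_coord(self.contig, self.start, self.end)

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.contig, self.strand, self.start, self.end)

    @property
    def donor_pos(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def acceptor_pos(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class CircCatalog:
    """Merged multi-sample circRNA set with counts, CPM and classification."""

    entries: list[CatalogEntry]
    counts: pd.DataFrame  # circ_id x sample BSJ fragment counts
    cpm: pd.DataFrame  # circ_id x sample CPM
    raw_read_totals: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def mean_cpm(self) -> pd.Series:
        return self.cpm.mean(axis=1)

    @property
    def sd_cpm(self) -> pd.Series:
        return self.cpm.std(axis=1, ddof=1)

    def entry(self, circ_id: str) -> CatalogEntry:
        return next(e for e in self.entries if e.circ_id == circ_id)

    def spliced_sequences(self, genome: GenomePackage) -> dict[str, str]:
        """Spliced circle sequence per entry, 5'->3' in transcript orientation."""
        return {
            e.circ_id: genome.spliced_sequence(e.contig, e.strand, e.exon_blocks or [Interval(e.start, e.end)])
            for e in self.entries
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "circ_id": e.circ_id,
                    "coord": e.display_coord,
                    "contig": e.contig,
                    "start": e.start,
                    "end": e.end,
                    "strand": e.strand,
                    "class": e.circ_class,
                    "host_gene": e.host_gene or ".",
                    "n_exons": e.n_exons,
                    "spliced_length": e.spliced_length,
                    "mean_cpm": self.mean_cpm[e.circ_id],
                    "sd_cpm": self.sd_cpm[e.circ_id],
                }
            )
        df = pd.DataFrame(rows).set_index("circ_id")
        return df.join(self.cpm.add_prefix("cpm_"))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_bed12(self, path: str | Path) -> None:
        """BED12 with exon blocks for exonic circles."""
        with open(path, "w") as fh:
            for e in self.entries:
                blocks = e.exon_blocks or [Interval(e.start, e.end)]
                sizes = ",".join(str(len(b)) for b in blocks)
                starts = ",".join(str(b.start - e.start) for b in blocks)
                fh.write(
                    f"{e.contig}\t{e.start}\t{e.end}\t{e.circ_id}\t0\t{e.strand}\t"
                    f"{e.start}\t{e.end}\t0,0,0\t{len(blocks)}\t{sizes}\t{starts}\n"
                )


def build_catalog(
    merged_counts: pd.DataFrame,
    raw_read_totals: pd.Series | dict,
    annotation: AnnotationIndex | list[GeneModel] | GenomePackage,
    id_prefix: str = "ssc_circ",
) -> CircCatalog:
    """Assemble the catalogue from a merged junction count matrix.

    ``merged_counts`` rows are ``contig:start..end:strand`` junction keys
    (as produced by the multi-sample merge); columns are samples.
    """
    from .detect import junction_key_to_coords

    if isinstance(annotation, GenomePackage):
        annotation = AnnotationIndex(annotation.genes)
    elif isinstance(annotation, list):
        annotation = AnnotationIndex(annotation)
    totals = pd.Series(raw_read_totals, dtype=float)
    entries = []
    for i, key in enumerate(merged_counts.index):
        contig, strand, start, end = junction_key_to_coords(key)
        cls, host, n_exons, spliced, blocks = classify_circrna(contig, start, end, annotation)
        entries.append(
            CatalogEntry(
                circ_id=f"{id_prefix}_{i + 1:04d}",
                contig=contig,
                strand=strand,
                start=start,
                end=end,
                circ_class=cls,
                host_gene=host,
                n_exons=n_exons,
                spliced_length=spliced,
                exon_blocks=blocks,
            )
        )
    counts = merged_counts.copy()
    counts.index = [e.circ_id for e in entries]
    counts.index.name = "circ_id"
    cpm = normalize_cpm(counts, totals)
    return CircCatalog(entries=entries, counts=counts, cpm=cpm, raw_read_totals=totals)


def detect_hotspots(catalog: CircCatalog, min_isoforms: int = 5) -> pd.DataFrame:
    """Count distinct exonic circRNA isoforms per host gene; flag hotspots."""
    per_gene: dict[str, set] = {}
    for e in catalog.entries:
        if e.circ_class in ("CDS", "5UTR", "3UTR") and e.host_gene:
            per_gene.setdefault(e.host_gene, set()).add(e.key)
    rows = [
        {"gene_id": g, "n_isoforms": len(keys), "hotspot": len(keys) >= min_isoforms}
        for g, keys in sorted(per_gene.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_isoforms", "hotspot"])


def summarize_catalog(
    catalog: CircCatalog, top_n: int = 15, length_threshold: int = 400
) -> dict:
    """Class fractions, exon-count and length histograms, top-N by mean CPM."""
    n = len(catalog.entries)
    fractions = {c: 0.0 for c in CLASSES}
    for e in catalog.entries:
        fractions[e.circ_class] += 1
    if n:
        fractions = {c: v / n for c, v in fractions.items()}
    exonic = [e for e in catalog.entries if e.circ_class in ("CDS", "5UTR", "3UTR")]
    exon_hist: dict[int, int] = {}
    for e in exonic:
        exon_hist[e.n_exons] = exon_hist.get(e.n_exons, 0) + 1
    lengths = [e.spliced_length for e in exonic]
    short_share = (
        sum(1 for x in lengths if x < length_threshold) / len(lengths) if lengths else math.nan
    )
    order = sorted(
        catalog.entries,
        key=lambda e: (-catalog.mean_cpm[e.circ_id], e.contig, e.start, e.end),
    )
    top = [
        {
            "circ_id": e.circ_id,
            "coord": e.display_coord,
            "class": e.circ_class,
            "host_gene": e.host_gene or ".",
            "mean_cpm": float(catalog.mean_cpm[e.circ_id]),
            "sd_cpm": float(catalog.sd_cpm[e.circ_id]),
        }
        for e in order[:top_n]
    ]
    return {
        "n_circrnas": n,
        "class_fractions": fractions,
        "exonic_fraction": sum(fractions[c] for c in ("CDS", "5UTR", "3UTR")),
        "exon_count_histogram": {str(k): v for k, v in sorted(exon_hist.items())},
        "short_length_share": short_share,
        "length_threshold": length_threshold,
        "top_by_mean_cpm": top,
    }


def compare_catalogs(
    catalog_a: CircCatalog | list[CatalogEntry],
    catalog_b: CircCatalog | list[CatalogEntry],
    boundary_tolerance_nt: int = 0,
) -> tuple[float, float]:
    """Bidirectional junction overlap between two same-assembly catalogues.

    A junction matches when donor and acceptor each agree within
    ``boundary_tolerance_nt``.  Returns (|A&B|/|A|, |A&B|/|B|).  Catalogues
    on different assemblies cannot be detected and will silently disagree.
    """
    ea = catalog_a.entries if isinstance(catalog_a, CircCatalog) else catalog_a
    eb = catalog_b.entries if isinstance(catalog_b, CircCatalog) else catalog_b

    def matched(x, pool) -> bool:
        return any(
            x.contig == y.contig
            and x.strand == y.strand
            and abs(x.start - y.start) <= boundary_tolerance_nt
            and abs(x.end - y.end) <= boundary_tolerance_nt
            for y in pool
        )

    if not ea or not eb:
        return 0.0, 0.0
    a_in_b = sum(matched(x, eb) for x in ea) / len(ea)
    b_in_a = sum(matched(y, ea) for y in eb) / len(eb)
    return a_in_b, b_in_a


def read_catalog_tsv(path: str | Path) -> list[CatalogEntry]:
    """Load catalogue entries (for `compare`) from a catalogue TSV."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for _, r in df.iterrows():
        entries.append(
            CatalogEntry(
                circ_id=str(r["circ_id"]),
                contig=str(r["contig"]),
                strand=str(r["strand"]),
                start=int(r["start"]),
                end=int(r["end"]),
                circ_class=str(r["class"]),
                host_gene=None if r["host_gene"] == "." else str(r["host_gene"]),
                n_exons=int(r["n_exons"]),
                spliced_length=int(r["spliced_length"]),
            )
        )
    return entries


def write_summary_json(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
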