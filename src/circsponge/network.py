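"""circRNA-miRNA sponge network inference.

Two independent lines of evidence are intersected:

1. Co-abundance: all-pairs Pearson correlation of log2-stabilized
   abundances, pruned by Partial Correlation with Information Theory (PCIT).
   For every trio (x, y, z) the three first-order partial correlations are
   computed; the trio tolerance is the mean ratio of partial to direct
   correlation, and the x-y association is eliminated when its magnitude
   falls below the tolerance-scaled product with both of the other two edges.
   Only surviving edges with negative correlation are kept.

2. Sequence: a position-weighted complementarity scan of each miRNA against
   each circle's spliced sequence (extended across the back-splice seam so
   junction-spanning sites are visible), requiring a perfect Watson-Crick
   seed match (miRNA positions 2-7) plus an alignment score threshold.

An edge enters the final network only if supported by both approaches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-12


def log2_stabilize(values: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) abundance stabilization (pseudocount 1)."""
    if (values.values < 0).any():
        raise ValueError("abundances must be non-negative")
    return np.log2(values.astype(float) + 1.0)


def combine_abundances(
    circ: pd.DataFrame, mirna: pd.DataFrame, stabilize: bool = True
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Join samples x circRNA and samples x miRNA tables on their samples.

    Returns the combined (optionally log2-stabilized) matrix and a feature ->
    kind map ('circRNA' | 'miRNA').  Zero-variance features are dropped
    (they carry no correlation information) with a note in the kinds map.
    """
    common = circ.index.intersection(mirna.index)
    if len(common) < 3:
        raise ValueError("need >=3 shared samples")
    mat = pd.concat([circ.loc[common], mirna.loc[common]], axis=1)
    if stabilize:
        mat = log2_stabilize(mat)
    kinds = {f: "circRNA" for f in circ.columns}
    kinds.update({f: "miRNA" for f in mirna.columns})
    keep = mat.columns[mat.std(axis=0).values > 0]
    return mat[keep], {f: kinds[f] for f in keep}


def pearson_all_pairs(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlation of the columns of a samples x features table."""
    sd = matrix.std(axis=0, ddof=0)
    bad = list(sd.index[sd.values == 0])
    if bad:
        raise ValueError(f"zero-variance features: {bad}")
    r = np.corrcoef(matrix.values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=matrix.columns, columns=matrix.columns)


def pcit(correlations: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """PCIT edge selection on a correlation matrix.

    For each trio, first-order partials r_xy.z = (r_xy - r_xz r_yz) /
    sqrt((1-r_xz^2)(1-r_yz^2)); the trio tolerance is the mean of the three
    partial/direct ratios (terms with |direct r| < 1e-12 are skipped, and
    |r| is clamped below 1 to avoid division blow-ups).  Edge x-y is
    eliminated if for some z both |r_xy| <= |eps r_xz| and
    |r_xy| <= |eps r_yz|.  Returns a boolean adjacency matrix of surviving
    ("significant") associations; with fewer than 3 features no trio exists
    and every edge survives.
    """
    is_df = isinstance(correlations, pd.DataFrame)
    R = np.asarray(correlations, dtype=float)
    n = R.shape[0]
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    R = np.clip(R, -(1 - _EPS), 1 - _EPS)
    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)
    if n >= 3:
        absR = np.abs(R)
        for z in range(n):
            rxz = R[:, z][:, None]  # column vector over x
            ryz = R[z, :][None, :]  # row vector over y
            denom = np.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))
            p_xy = (R - rxz * ryz) / denom
            # r_xz.y: partial of (x,z) controlling y, as a function of (x, y)
            d_xz = np.sqrt((1.0 - R**2) * (1.0 - ryz**2))
            p_xz = (rxz - R * ryz) / d_xz
            # r_yz.x: partial of (y,z) controlling x
            d_yz = np.sqrt((1.0 - R**2) * (1.0 - rxz**2))
            p_yz = (ryz - R * rxz) / d_yz
            ratios = []
            for p, r in ((p_xy, R), (p_xz, np.broadcast_to(rxz, R.shape)), (p_yz, np.broadcast_to(ryz, R.shape))):
                ok = np.abs(r) >= _EPS
                ratios.append(np.where(ok, p / np.where(ok, r, 1.0), np.nan))
            with np.errstate(invalid="ignore"):
                eps = np.nanmean(np.stack(ratios), axis=0)
            aeps = np.abs(eps)
            elim = (absR <= aeps * np.abs(rxz)) & (absR <= aeps * np.abs(ryz))
            elim[:, z] = False
            elim[z, :] = False
            elim &= ~np.isnan(eps)
            keep &= ~elim
    if is_df:
        return pd.DataFrame(keep, index=correlations.index, columns=correlations.columns)
    return keep


# ------------------------------------------------------------ target scanning


@dataclass
class TargetScanParams:
    """Scoring scheme of the complementarity scan (miRanda-like, ungapped)."""

    seed_span: tuple[int, int] = (2, 8)  # miRNA positions scaled up (1-based, inclusive)
    strict_seed_span: tuple[int, int] = (2, 7)  # must be perfect Watson-Crick
    allow_GU_wobble: bool = True
    match_score: float = 5.0
    mismatch_score: float = -4.0
    wobble_score: float = 1.0
    seed_scale: float = 2.0
    min_alignment_score: float = 50.0

    def __post_init__(self) -> None:
        if self.min_alignment_score <= 0:
            raise ValueError("min_alignment_score must be > 0")
        for s in (self.match_score, self.mismatch_score, self.wobble_score, self.seed_scale):
            if not np.isfinite(s):
                raise ValueError("scores must be finite")


@dataclass
class TargetHit:
    circ_id: str
    mirna_id: str
    position: int  # site start in circle coordinates (modulo circle length)
    score: float
    seed_match: str  # '7mer' (positions 2-8 WC) or '6mer' (2-7 only)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide symbol {exc.args[0]!r} in sequence") from exc


def max_site_score(mirna_seq: str, params: TargetScanParams | None = None) -> float:
    """Score of a perfectly complementary site for this miRNA (closed form)."""
    params = params or TargetScanParams()
    lo, hi = params.seed_span
    n = len(mirna_seq)
    n_seed = max(0, min(hi, n) - lo + 1)
    return params.match_score * (params.seed_scale * n_seed + (n - n_seed))


def scan_targets(
    mirna_seqs: dict[str, str],
    circ_seqs: dict[str, str],
    params: TargetScanParams | None = None,
) -> list[TargetHit]:
    """Scan every miRNA against every circle sequence.

    Circle sequences are extended by (miRNA length - 1) nt of their own
    start so sites spanning the back-splice seam are scored; positions are
    reported modulo the circle length.  A window is a hit when the miRNA
    seed (positions 2-7, 1-based from the 5' end) is perfectly Watson-Crick
    paired and the position-weighted alignment score reaches the threshold.
    """
    params = params or TargetScanParams()
    hits: list[TargetHit] = []
    enc_mirnas = []
    for mid, mseq in mirna_seqs.items():
        m = _encode(mseq)
        lm = len(m)
        # reverse-complement in code space: complement is 3 - code
        rc = (3 - m)[::-1]
        # weight/slice bookkeeping: window position t pairs miRNA position lm - t
        mpos = lm - np.arange(lm)  # 1-based miRNA position per window column
        weights = np.where(
            (mpos >= params.seed_span[0]) & (mpos <= params.seed_span[1]),
            params.seed_scale,
            1.0,
        )
        strict_cols = np.where(
            (mpos >= params.strict_seed_span[0]) & (mpos <= params.strict_seed_span[1])
        )[0]
        enc_mirnas.append((mid, m, rc, weights, strict_cols))

    for cid, cseq in circ_seqs.items():
        clen = len(cseq)
        if clen == 0:
            continue
        max_lm = max((len(m) for _, m, _, _, _ in enc_mirnas), default=1)
        ext = _encode(cseq + cseq[: max_lm - 1])
        for mid, m, rc, weights, strict_cols in enc_mirnas:
            lm = len(m)
            if len(ext) < lm:
                continue
            win = np.lib.stride_tricks.sliding_window_view(ext, lm)
            win = win[: clen]  # one window per circle position
            wc = win == rc  # Watson-Crick pair per column
            # G:U wobble: miRNA G with target T, or miRNA U with target G
            mir_col = m[::-1]  # miRNA base per window column (code space)
            wob = ((mir_col == 2) & (win == 3)) | ((mir_col == 3) & (win == 2))
            per_col = np.where(
                wc,
                params.match_score,
                np.where(
                    wob & params.allow_GU_wobble, params.wobble_score, params.mismatch_score
                ),
            )
            scores = per_col @ weights
            seed_ok = wc[:, strict_cols].all(axis=1)
            for pos in np.nonzero(seed_ok & (scores >= params.min_alignment_score))[0]:
                wc_row = wc[pos]
                mpos8 = lm - np.arange(lm)
                seed8 = wc_row[(mpos8 >= 2) & (mpos8 <= 8)].all()
                hits.append(
                    TargetHit(
                        circ_id=cid,
                        mirna_id=mid,
                        position=int(pos % clen),
                        score=float(scores[pos]),
                        seed_match="7mer" if seed8 else "6mer",
                    )
                )
    return hits


# ------------------------------------------------------------- intersection


@dataclass
class SpongeEdge:
    circ_id: str
    mirna_id: str
    pearson_r: float
    kept_by_pcit: bool
    target_hits: list[TargetHit] = field(default_factory=list)
    in_final_network: bool = False

    @property
    def n_sites(self) -> int:
        return len(self.target_hits)

    @property
    def best_score(self) -> float:
        return max((h.score for h in self.target_hits), default=float("nan"))


def build_network(
    pcit_edges: pd.DataFrame,
    correlations: pd.DataFrame,
    target_hits: list[TargetHit],
    kinds: dict[str, str],
) -> tuple[list[SpongeEdge], pd.DataFrame]:
    """Intersect PCIT-negative edges with target hits over circ-miR pairs.

    Returns every circ-miR edge (with its evidence) plus a node-degree table
    counting final-network edges per node.
    """
    circ_ids = [f for f, k in kinds.items() if k == "circRNA"]
    mir_ids = [f for f, k in kinds.items() if k == "miRNA"]
    hits_by_pair: dict[tuple[str, str], list[TargetHit]] = {}
    for h in target_hits:
        hits_by_pair.setdefault((h.circ_id, h.mirna_id), []).append(h)
    edges = []
    for c in circ_ids:
        for m in mir_ids:
            r = float(correlations.loc[c, m])
            kept = bool(pcit_edges.loc[c, m])
            th = hits_by_pair.get((c, m), [])
            edge = SpongeEdge(
                circ_id=c,
                mirna_id=m,
                pearson_r=r,
                kept_by_pcit=kept,
                target_hits=th,
                in_final_network=kept and r < 0 and len(th) > 0,
            )
            edges.append(edge)
    degree: dict[str, int] = {f: 0 for f in list(circ_ids) + list(mir_ids)}
    for e in edges:
        if e.in_final_network:
            degree[e.circ_id] += 1
            degree[e.mirna_id] += 1
    deg = pd.DataFrame(
        {
            "node": list(degree),
            "kind": [kinds[f] for f in degree],
            "degree": list(degree.values()),
        }
    )
    return edges, deg


def edges_to_frame(edges: list[SpongeEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [e.circ_id for e in edges],
            "mirna_id": [e.mirna_id for e in edges],
            "pearson_r": [e.pearson_r for e in edges],
            "pcit_kept": [e.kept_by_pcit for e in edges],
            "best_target_score": [e.best_score for e in edges],
            "n_sites": [e.n_sites for e in edges],
            "in_final_network": [e.in_final_network for e in edges],
        }
    )


def network_to_graphml(edges: list[SpongeEdge], degrees: pd.DataFrame, path) -> None:
    """Export the final network (Cytoscape-importable GraphML via networkx)."""
    import networkx as nx

    g = nx.Graph()
    deg = degrees.set_index("node")
    for e in edges:
        if not e.in_final_network:
            continue
        for node in (e.circ_id, e.mirna_id):
            if node not in g:
                g.add_node(node, kind=str(deg.loc[node, "kind"]), degree=int(deg.loc[node, "degree"]))
        g.add_edge(e.circ_id, e.mirna_id, pearson_r=e.pearson_r, n_sites=e.n_sites)
    nx.write_graphml(g, str(path))


def infer_sponge_network(
    circ_abundance: pd.DataFrame,
    mirna_abundance: pd.DataFrame,
    circ_seqs: dict[str, str],
    mirna_seqs: dict[str, str],
    scan_params: TargetScanParams | None = None,
) -> dict:
    """End-to-end sponge inference from abundance tables + sequences.

    Both abundance tables are samples x features on a shared sample index.
    Returns dict with correlations, pcit adjacency, hits, edges, degrees.
    """
    mat, kinds = combine_abundances(circ_abundance, mirna_abundance, stabilize=True)
    corr = pearson_all_pairs(mat)
    adj = pcit(corr)
    hits = scan_targets(mirna_seqs, {c: s for c, s in circ_seqs.items() if c in kinds}, scan_params)
    edges, degrees = build_network(adj, corr, hits, kinds)
    return {
        "matrix": mat,
        "kinds": kinds,
        "correlations": corr,
        "pcit": adj,
        "target_hits": hits,
        "edges": edges,
        "degrees": degrees,
    }
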