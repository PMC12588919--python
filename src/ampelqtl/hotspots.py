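"""QTL hotspots and gene-window pathway enrichment.

A hotspot is a marker where at least ``min_qtl`` trait QTL collocate:
identical peak marker and pairwise-overlapping credible intervals.
Genes within a +-700 kb physical window of the hotspot peak (1.4 Mb
total) feed a one-sided Fisher exact test per annotated pathway, with
Benjamini-Hochberg adjusted p-values reported alongside the raw-p
significance rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetics import parse_marker_name
from .exceptions import FormatError

__all__ = [
    "Hotspot",
    "EnrichmentResult",
    "detect_hotspots",
    "gene_window",
    "fisher_enrichment",
    "DEFAULT_WINDOW_BP",
]

DEFAULT_WINDOW_BP = 700_000  # half-width either side of the peak


@dataclass(frozen=True)
class Hotspot:
    """Collocated QTL sharing one peak marker."""

    marker: str
    chromosome: int | None
    bp: int | None
    traits: tuple[str, ...]
    lods: tuple[float, ...]
    intervals: tuple[tuple[float, float], ...]

    @property
    def n_qtl(self) -> int:
        return len(self.traits)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    n_window: int
    n_overlap: int
    n_universe: int
    n_pathway: int
    p_value: float
    p_adjusted: float
    significant: bool


def _max_pairwise_overlapping(intervals: list[tuple[float, float]]) -> list[int]:
    """Indices of the largest interval subset sharing a common point.

    For 1-D intervals pairwise overlap is equivalent to a common
    intersection point, so a sweep over candidate stab points (the
    interval endpoints) finds the maximum subset.
    """
    best: list[int] = []
    points = sorted({lo for lo, _ in intervals} | {hi for _, hi in intervals})
    for p in points:
        members = [k for k, (lo, hi) in enumerate(intervals) if lo <= p <= hi]
        if len(members) > len(best):
            best = members
    return best


def detect_hotspots(peaks: pd.DataFrame, min_qtl: int = 3) -> list[Hotspot]:
    """Group QTL peaks into hotspots.

    ``peaks`` needs columns trait, marker, ci_low_cm, ci_high_cm (the
    peak-table layout of the scan results).  QTL grouped by identical
    peak marker are kept when at least ``min_qtl`` members have
    pairwise-overlapping credible intervals; hotspots are ordered by
    chromosome then bp (parsed from the marker name when possible).
    """
    required = {"trait", "marker", "ci_low_cm", "ci_high_cm"}
    if not required.issubset(peaks.columns):
        raise FormatError(f"peak table needs columns {sorted(required)}")
    hotspots = []
    for marker, grp in peaks.groupby("marker"):
        if len(grp) < min_qtl:
            continue
        intervals = list(zip(grp["ci_low_cm"], grp["ci_high_cm"]))
        members = _max_pairwise_overlapping(intervals)
        if len(members) < min_qtl:
            continue
        sub = grp.iloc[members]
        try:
            chrom, bp = parse_marker_name(marker)
        except FormatError:
            chrom, bp = None, None
        hotspots.append(
            Hotspot(
                marker=str(marker),
                chromosome=chrom,
                bp=bp,
                traits=tuple(sub["trait"]),
                lods=tuple(float(v) for v in sub.get("lod", pd.Series([np.nan] * len(sub)))),
                intervals=tuple((float(lo), float(hi)) for lo, hi in zip(sub["ci_low_cm"], sub["ci_high_cm"])),
            )
        )
    hotspots.sort(key=lambda h: (h.chromosome is None, h.chromosome, h.bp, h.marker))
    return hotspots


def gene_window(
    hotspot: Hotspot,
    genes: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[str]:
    """Gene ids within ``window_bp`` either side of the hotspot peak.

    ``genes`` needs columns gene_id, chromosome, bp_start; a gene is in
    the window when it lies on the peak chromosome and its (1-based)
    start position satisfies |bp_start - peak_bp| <= window_bp (closed
    interval; the gene is represented by its start point).
    """
    required = {"gene_id", "chromosome", "bp_start"}
    if not required.issubset(genes.columns):
        raise FormatError(f"gene table needs columns {sorted(required)}")
    if hotspot.chromosome is None or hotspot.bp is None:
        raise FormatError(f"hotspot {hotspot.marker!r} has no parsed physical position")
    on_chrom = genes[genes["chromosome"] == hotspot.chromosome]
    if on_chrom.empty:
        warnings.warn(f"no genes annotated on chromosome {hotspot.chromosome}")
        return []
    hit = on_chrom[(on_chrom["bp_start"] - hotspot.bp).abs() <= window_bp]
    return hit["gene_id"].astype(str).tolist()


def fisher_pvalue(n_overlap: int, n_window: int, n_pathway: int, n_universe: int) -> float:
    """One-sided (enrichment) Fisher exact p for one pathway's 2x2 table."""
    table = [
        [n_overlap, n_window - n_overlap],
        [n_pathway - n_overlap, n_universe - n_window - n_pathway + n_overlap],
    ]
    return float(stats.fisher_exact(table, alternative="greater").pvalue)


def fisher_enrichment(
    window_genes,
    annotation: pd.DataFrame,
    universe=None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-pathway one-sided Fisher exact enrichment of the window genes.

    The 2x2 table per pathway counts window/non-window against
    pathway/non-pathway genes over the universe (default: every gene in
    the annotation).  ``significant`` follows the raw p < alpha rule;
    Benjamini-Hochberg adjusted p-values are reported alongside.
    """
    required = {"gene_id", "pathway_id"}
    if not required.issubset(annotation.columns):
        raise FormatError(f"annotation table needs columns {sorted(required)}")
    if annotation.empty:
        raise FormatError("annotation table is empty")
    if universe is None:
        universe = annotation["gene_id"].astype(str).unique()
    universe = pd.Index(pd.unique(pd.Series(universe).astype(str)))
    window = pd.Index(pd.unique(pd.Series(list(window_genes)).astype(str)))
    if not window.isin(universe).all():
        raise FormatError("window genes must be a subset of the universe")

    ann = annotation.assign(gene_id=annotation["gene_id"].astype(str))
    ann = ann[ann["gene_id"].isin(universe)]
    n_universe = len(universe)
    n_window = len(window)
    results = []
    skipped = []
    for pathway, grp in ann.groupby("pathway_id"):
        members = pd.Index(grp["gene_id"].unique())
        if members.empty:
            skipped.append(pathway)
            continue
        n_pathway = len(members)
        n_overlap = int(window.isin(members).sum())
        p = fisher_pvalue(n_overlap, n_window, n_pathway, n_universe)
        results.append((str(pathway), n_window, n_overlap, n_universe, n_pathway, p))
    if skipped:
        warnings.warn(f"pathways absent from universe skipped: {skipped[:5]}")
    if not results:
        return []
    raw_p = [r[5] for r in results]
    adj = multipletests(raw_p, method="fdr_bh")[1]
    return [
        EnrichmentResult(
            pathway=r[0],
            n_window=r[1],
            n_overlap=r[2],
            n_universe=r[3],
            n_pathway=r[4],
            p_value=r[5],
            p_adjusted=float(a),
            significant=r[5] < alpha,
        )
        for r, a in zip(results, adj)
    ]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = [
        "pathway", "n_window", "n_overlap", "n_universe", "n_pathway",
        "p_value", "p_adjusted", "significant",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


def hotspot_table(hotspots: list[Hotspot]) -> pd.DataFrame:
    rows = []
    for h in hotspots:
        rows.append(
            {
                "marker": h.marker,
                "chromosome": h.chromosome,
                "bp": h.bp,
                "n_qtl": h.n_qtl,
                "traits": ";".join(h.traits),
                "max_lod": max(h.lods) if h.lods else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["marker", "chromosome", "bp", "n_qtl", "traits", "max_lod"]
    )
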