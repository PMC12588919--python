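"""Genetic maps and ABH-coded F1 genotype matrices.

Markers live on up to 19 linkage groups with centimorgan positions;
physical positions are parsed from marker names of the form
``rh<chromosome>_<bp>`` (a sidecar physical-position table can override
the convention).  Genotype calls use the intercross ABH alphabet: A and
B for the major and minor homozygote, H for the heterozygote, ``-`` for
missing.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FormatError, ReconciliationError

__all__ = [
    "GeneticMap",
    "MapSummary",
    "parse_marker_name",
    "read_abh",
    "write_abh",
    "read_map",
    "map_summary",
    "collinearity",
    "recombination_fraction",
    "CALL_ALPHABET",
]

MAX_LINKAGE_GROUPS = 19
CALL_ALPHABET = ("A", "H", "B")
_MISSING_TOKENS = {"-", "", "NA", "U", "nan"}

_MARKER_RE = re.compile(r"^rh(\d+)_(\d+)$")


def parse_marker_name(name: str) -> tuple[int, int]:
    """Chromosome and bp position from an ``rh<chr>_<bp>`` marker name."""
    m = _MARKER_RE.match(str(name))
    if not m:
        raise FormatError(f"cannot parse chromosome/bp from marker name {name!r}")
    chrom, bp = int(m.group(1)), int(m.group(2))
    if bp < 1:
        raise FormatError(f"marker {name!r}: bp must be >= 1, got {bp}")
    return chrom, bp


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker records: name, linkage group, cM, chromosome, bp.

    ``table`` columns: marker, linkage_group, cm, chromosome, bp (the
    last two may be NA when the physical position is unknown).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "linkage_group", "cm"}
        if not required.issubset(t.columns):
            raise FormatError(f"genetic map needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise FormatError(f"duplicate marker names in map: {dups[:5]}")
        if t["linkage_group"].nunique() > MAX_LINKAGE_GROUPS:
            raise FormatError(
                f"more than {MAX_LINKAGE_GROUPS} linkage groups: "
                f"{t['linkage_group'].nunique()}"
            )
        for lg, grp in t.groupby("linkage_group"):
            if not grp["cm"].is_monotonic_increasing:
                raise FormatError(f"cM positions not non-decreasing on LG {lg}")
        t = t.reset_index(drop=True)
        if "chromosome" not in t.columns or "bp" not in t.columns:
            chroms, bps = [], []
            for name in t["marker"]:
                try:
                    c, b = parse_marker_name(name)
                except FormatError:
                    c, b = np.nan, np.nan
                chroms.append(c)
                bps.append(b)
            t = t.assign(chromosome=chroms, bp=bps)
        object.__setattr__(self, "table", t)

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def linkage_groups(self) -> list:
        return list(dict.fromkeys(self.table["linkage_group"]))

    def lg_slice(self, lg) -> pd.DataFrame:
        return self.table[self.table["linkage_group"] == lg]


@dataclass(frozen=True)
class MapSummary:
    per_lg: pd.DataFrame  # linkage_group, n_markers, length_cm, max_gap_cm
    n_markers: int
    n_lgs: int
    total_length_cm: float
    mean_spacing_cm: float
    max_gap_cm: float
    recomb_rate_cm_per_mbp: float | None  # approximate: total cM / spanned Mbp


def map_summary(gmap: GeneticMap) -> MapSummary:
    """Per-LG and genome-wide map statistics.

    mean spacing = total length / (marker count - LG count); the
    genome-wide recombination rate divides total cM by the physical
    span of parsed bp positions (an approximation, flagged None when no
    bp could be parsed).  LGs with <2 markers are excluded from spacing
    and gap statistics with a warning.
    """
    rows = []
    n_used_markers = 0
    spanned_bp = 0.0
    for lg in gmap.linkage_groups:
        grp = gmap.lg_slice(lg)
        if len(grp) < 2:
            warnings.warn(f"LG {lg} has <2 markers; excluded from spacing statistics")
            continue
        cm = grp["cm"].to_numpy(dtype=float)
        length = float(cm.max() - cm.min())
        gaps = np.diff(np.sort(cm))
        rows.append(
            {
                "linkage_group": lg,
                "n_markers": len(grp),
                "length_cm": length,
                "max_gap_cm": float(gaps.max()),
            }
        )
        n_used_markers += len(grp)
        bp = grp["bp"].dropna()
        if len(bp) >= 2:
            spanned_bp += float(bp.max() - bp.min())
    per_lg = pd.DataFrame(rows)
    if per_lg.empty:
        raise FormatError("no linkage group has >=2 markers")
    n_lgs = len(per_lg)
    total = float(per_lg["length_cm"].sum())
    spacing = total / (n_used_markers - n_lgs)
    rate = total / (spanned_bp / 1e6) if spanned_bp > 0 else None
    return MapSummary(
        per_lg=per_lg,
        n_markers=n_used_markers,
        n_lgs=n_lgs,
        total_length_cm=total,
        mean_spacing_cm=spacing,
        max_gap_cm=float(per_lg["max_gap_cm"].max()),
        recomb_rate_cm_per_mbp=rate,
    )


def collinearity(gmap: GeneticMap) -> pd.Series:
    """Per-LG Spearman rank correlation between cM order and bp order.

    Ties are handled by average ranks; LGs with <3 markers carrying a
    physical position are reported as NaN.
    """
    out = {}
    for lg in gmap.linkage_groups:
        grp = gmap.lg_slice(lg).dropna(subset=["bp"])
        if len(grp) < 3:
            out[lg] = np.nan
            continue
        rho = stats.spearmanr(grp["cm"], grp["bp"]).statistic
        out[lg] = float(rho)
    return pd.Series(out, name="spearman_rho")


# ---------------------------------------------------------------------------
# R/qtl "csv" dialect: row 1 = id + marker names, row 2 = linkage groups,
# row 3 = cM positions, then one row per individual.


def read_abh(genotype_csv, map_csv=None) -> tuple[GeneticMap, pd.DataFrame]:
    """Read an R/qtl-style ABH genotype CSV (and optional map-only CSV).

    Returns the genetic map and an individuals x markers DataFrame of
    calls in {A, H, B} with NaN for missing.  When ``map_csv`` is given
    its marker set must reconcile with the genotype file.
    """
    raw = pd.read_csv(genotype_csv, header=None, dtype=str, comment="#")
    if len(raw) < 4:
        raise FormatError("ABH CSV needs 3 header rows plus >=1 individual row")
    markers = raw.iloc[0, 1:].tolist()
    lgs = raw.iloc[1, 1:].tolist()
    cms = raw.iloc[2, 1:].astype(float).tolist()
    body = raw.iloc[3:]
    individuals = body.iloc[:, 0].tolist()
    calls = body.iloc[:, 1:].copy()
    calls.index = individuals
    calls.columns = markers

    cleaned = calls.apply(lambda col: col.str.strip())
    bad = ~(cleaned.isin(CALL_ALPHABET) | cleaned.isin(_MISSING_TOKENS) | cleaned.isna())
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"invalid genotype call {cleaned.iloc[i, j]!r} for individual "
            f"{individuals[i]!r} at marker {markers[j]!r} "
            f"(alphabet: A/H/B/-)"
        )
    geno = cleaned.where(cleaned.isin(CALL_ALPHABET))

    lg_values = [int(v) if str(v).strip().isdigit() else v for v in lgs]
    gmap = GeneticMap(
        pd.DataFrame({"marker": markers, "linkage_group": lg_values, "cm": cms})
    )
    if map_csv is not None:
        side = read_map(map_csv)
        if set(side.markers) != set(markers):
            orphans = sorted(set(markers) ^ set(side.markers))
            raise ReconciliationError(
                f"marker sets differ between genotype and map files: {orphans[:10]}"
            )
        gmap = side
    return gmap, geno


def write_abh(gmap: GeneticMap, geno: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write genotypes back to the R/qtl csv dialect (lossless round-trip)."""
    t = gmap.table.set_index("marker").loc[geno.columns]
    lines = [
        "id," + ",".join(str(m) for m in geno.columns),
        "," + ",".join(str(v) for v in t["linkage_group"]),
        "," + ",".join(repr(float(v)) for v in t["cm"]),
    ]
    filled = geno.fillna("-")
    for ind, row in filled.iterrows():
        lines.append(f"{ind}," + ",".join(row.tolist()))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\n".join(lines) + "\n")


def read_map(path) -> GeneticMap:
    """Read a map-only CSV: marker, linkage_group, cm (+ optional chromosome, bp)."""
    df = pd.read_csv(path, comment="#")
    required = {"marker", "linkage_group", "cm"}
    if not required.issubset(df.columns):
        raise FormatError(f"map CSV needs columns {sorted(required)}, got {list(df.columns)}")
    return GeneticMap(df)


def write_map(gmap: GeneticMap, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        gmap.table.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Two-locus recombination fraction (intercross EM)


def _abh_to_int(col: pd.Series) -> np.ndarray:
    mapping = {"A": 0, "H": 1, "B": 2}
    return col.map(mapping).to_numpy(dtype=float)


def recombination_fraction(
    geno: pd.DataFrame,
    m1: str,
    m2: str,
    min_n: int = 20,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> float:
    """Maximum-likelihood recombination fraction between two markers.

    Treats ABH calls as phase-known intercross (F2-like) genotypes and
    runs EM over the 3x3 two-locus table: each individual carries two
    informative meioses whose recombinant status is determined by the
    genotype pair except in the double-heterozygote cell, where 0 or 2
    recombinant gametes are mixed and weighted by their posterior
    probability.  Returns a value in [0, 0.5], or NaN when fewer than
    ``min_n`` individuals are typed at both markers.
    """
    g1 = _abh_to_int(geno[m1])
    g2 = _abh_to_int(geno[m2])
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    n = len(g1)
    if n < min_n:
        warnings.warn(f"only {n} individuals typed at both {m1} and {m2}; rf undefined")
        return float("nan")

    counts = np.zeros((3, 3))
    np.add.at(counts, (g1, g2), 1.0)

    # recombinant gametes contributed by each genotype-pair cell
    # (rows/cols: 0=A,1=H,2=B); HH is ambiguous between 0 and 2.
    R = np.array([[0, 1, 2], [1, np.nan, 1], [2, 1, 0]], dtype=float)

    r = 0.25
    n_hh = counts[1, 1]
    fixed_rec = np.nansum(R * counts)
    for _ in range(max_iter):
        # P(2 recombinant gametes | HH) = r^2 / (r^2 + (1-r)^2)
        w2 = r**2 / (r**2 + (1 - r) ** 2)
        exp_rec = fixed_rec + n_hh * 2 * w2
        r_new = min(max(exp_rec / (2 * n), 1e-12), 0.5)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(r)
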