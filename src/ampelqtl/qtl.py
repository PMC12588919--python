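"""Single-locus QTL genome scans for an ABH-coded F1 population.

The central objects follow the model/results convention: a
:class:`QTLScan` is built from one phenotype vector plus the genotype
matrix and genetic map; ``fit()`` runs the normality gate, the marker
scan, the genome-wide permutation threshold, and returns a
:class:`QTLScanResults` holding the LOD curve, the detected peaks with
percent variance explained and 95% Bayes credible intervals, and a
``summary()`` table.  :func:`run_all` fans the same procedure out over
every attribute of a trait matrix.

Model
-----
At each marker the phenotype is regressed on an additive code
(A=-1, H=0, B=+1) and a dominance indicator (H=1, else 0):

    LOD = (n/2) * log10(RSS_0 / RSS_1)

comparing the intercept-only model with the genotype model on the
individuals typed at that marker.  Skewed traits that resist the
normalisation ladder fall back to a rank-based scan: per-marker
Kruskal-Wallis H converted to a LOD analog H / (2 ln 10).  The
genome-wide threshold is the empirical (1-alpha) quantile of the
maximum LOD over phenotype permutations; PVE uses the standard
identity PVE = 100 (1 - 10^(-2 LOD / n)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ReconciliationError
from .genetics import GeneticMap
from .trait_matrix import parse_attribute_key

__all__ = [
    "QTLScan",
    "QTLScanResults",
    "QtlPeak",
    "shapiro_wilk",
    "normalize_trait",
    "scan_parametric",
    "scan_nonparametric",
    "permutation_threshold",
    "pve",
    "bayes_interval",
    "run_all",
]

LOG10 = np.log(10.0)


def shapiro_wilk(x) -> dict[str, float]:
    """Shapiro-Wilk normality test; requires 3 <= n <= 5000, non-constant."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.shapiro(x)
    return {"W": float(res.statistic), "p": float(res.pvalue)}


_BOXCOX_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


def normalize_trait(x, alpha: float = 0.05, min_n: int = 20) -> tuple[np.ndarray, str]:
    """Transform a trait toward normality; tag the method used.

    Ladder: identity when Shapiro-Wilk p >= alpha; else natural log
    (positive traits only); else Box-Cox with the profile-likelihood
    lambda on a fixed grid -2..2 step 0.1.  The first transform whose
    Shapiro-Wilk p reaches alpha wins; when none does the trait is
    tagged ``nonparametric`` and returned untransformed.
    """
    x = np.asarray(x, dtype=float)
    obs = x[np.isfinite(x)]
    if len(obs) < min_n:
        raise ValueError(f"normalize_trait needs >= {min_n} non-missing values, got {len(obs)}")

    if shapiro_wilk(obs)["p"] >= alpha:
        return x, "identity"

    positive = np.all(obs > 0)
    if positive:
        logged = np.where(np.isfinite(x), np.log(np.where(np.isfinite(x) & (x > 0), x, 1.0)), np.nan)
        if shapiro_wilk(logged[np.isfinite(logged)])["p"] >= alpha:
            return logged, "log"
        llf = [stats.boxcox_llf(lmb, obs) for lmb in _BOXCOX_GRID]
        lmb = float(_BOXCOX_GRID[int(np.argmax(llf))])
        transformed = np.full_like(x, np.nan)
        mask = np.isfinite(x)
        if lmb == 0.0:
            transformed[mask] = np.log(x[mask])
        else:
            transformed[mask] = (x[mask] ** lmb - 1.0) / lmb
        if shapiro_wilk(transformed[mask])["p"] >= alpha:
            return transformed, f"boxcox(lambda={lmb:g})"
    return x, "nonparametric"


def _code_genotypes(geno: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Additive (-1/0/+1) and dominance (H=1) codes; NaN for missing."""
    arr = geno.to_numpy(dtype=object)
    add = np.full(arr.shape, np.nan)
    add[arr == "A"] = -1.0
    add[arr == "H"] = 0.0
    add[arr == "B"] = 1.0
    dom = np.where(np.isnan(add), np.nan, (add == 0.0).astype(float))
    return add, dom


class _ScanEngine:
    """Per-marker regression/rank machinery, vectorised over phenotype columns.

    Precomputes, per marker, the complete-case row mask and an
    orthonormal basis of the genotype design [1, additive, dominance]
    so that permutation scans reduce to small matrix products.
    """

    def __init__(self, geno: pd.DataFrame):
        self.markers = list(geno.columns)
        self.add, self.dom = _code_genotypes(geno)
        self.n_individuals = len(geno)
        self._bases: list[tuple[np.ndarray, np.ndarray, bool] | None] = []
        for j in range(self.add.shape[1]):
            a = self.add[:, j]
            mask = np.isfinite(a)
            a_obs = a[mask]
            classes = np.unique(a_obs)
            if mask.sum() < 3 or len(classes) < 2:
                self._bases.append(None)
                continue
            d_obs = self.dom[mask, j]
            X = np.column_stack([np.ones(mask.sum()), a_obs, d_obs])
            # orthonormal basis of the column space (rank-robust)
            u, s, _ = np.linalg.svd(X, full_matrices=False)
            q = u[:, s > s[0] * 1e-10]
            self._bases.append((mask, q, len(classes) == 3))

    def parametric_lod(self, Y: np.ndarray) -> np.ndarray:
        """LOD for each marker (rows) and each phenotype column of Y."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != self.n_individuals:
            Y = Y.T
        m = len(self.markers)
        out = np.zeros((m, Y.shape[1]))
        for j, basis in enumerate(self._bases):
            if basis is None:
                continue
            mask, q, _ = basis
            Ys = Y[mask]
            nk = mask.sum()
            ss = np.einsum("ij,ij->j", Ys, Ys)
            rss0 = ss - Ys.sum(axis=0) ** 2 / nk
            qty = q.T @ Ys
            rss1 = ss - np.einsum("ij,ij->j", qty, qty)
            rss1 = np.maximum(rss1, np.finfo(float).tiny)
            with np.errstate(divide="ignore", invalid="ignore"):
                lod = np.where(
                    rss0 > 0, (nk / 2.0) * (np.log10(rss0) - np.log10(rss1)), 0.0
                )
            out[j] = np.maximum(lod, 0.0)
        return out

    def nonparametric_lod(self, Y: np.ndarray) -> np.ndarray:
        """Kruskal-Wallis LOD analog H / (2 ln 10) per marker and column."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != self.n_individuals:
            Y = Y.T
        m = len(self.markers)
        out = np.zeros((m, Y.shape[1]))
        for j, basis in enumerate(self._bases):
            if basis is None:
                continue
            mask, _, _ = basis
            a_obs = self.add[mask, j]
            Ys = Y[mask]
            nk = mask.sum()
            ranks = stats.rankdata(Ys, axis=0)
            # tie correction per column
            tie_term = np.ones(Ys.shape[1])
            for c in range(Ys.shape[1]):
                _, counts = np.unique(Ys[:, c], return_counts=True)
                tie_term[c] = 1.0 - ((counts**3 - counts).sum()) / (nk**3 - nk)
            H = np.zeros(Ys.shape[1])
            for cls in np.unique(a_obs):
                sel = a_obs == cls
                nc = sel.sum()
                H += ranks[sel].sum(axis=0) ** 2 / nc
            H = 12.0 / (nk * (nk + 1)) * H - 3.0 * (nk + 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                H = np.where(tie_term > 0, H / tie_term, 0.0)
            out[j] = np.maximum(H, 0.0) / (2.0 * LOG10)
        return out

    def flags(self) -> list[str]:
        return [
            self.markers[j] for j, b in enumerate(self._bases) if b is None
        ]


def _align(geno: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, np.ndarray]:
    shared = geno.index.intersection(y.index)
    if len(shared) == 0:
        orphans = list(y.index.difference(geno.index))[:10]
        raise ReconciliationError(f"no shared genotype ids; phenotype orphans: {orphans}")
    y_al = y.loc[shared].to_numpy(dtype=float)
    keep = np.isfinite(y_al)
    return geno.loc[shared].loc[keep], y_al[keep]


def scan_parametric(geno: pd.DataFrame, y: pd.Series, min_n: int = 30) -> pd.Series:
    """Per-marker regression LOD for one phenotype (complete cases)."""
    g, yv = _align(geno, y)
    if len(yv) < min_n:
        raise ValueError(f"scan needs >= {min_n} phenotyped individuals, got {len(yv)}")
    engine = _ScanEngine(g)
    lod = engine.parametric_lod(yv[:, None])[:, 0]
    return pd.Series(lod, index=engine.markers, name="lod")


def scan_nonparametric(geno: pd.DataFrame, y: pd.Series, min_n: int = 30) -> pd.Series:
    """Per-marker Kruskal-Wallis LOD analog for one phenotype."""
    g, yv = _align(geno, y)
    if len(yv) < min_n:
        raise ValueError(f"scan needs >= {min_n} phenotyped individuals, got {len(yv)}")
    engine = _ScanEngine(g)
    lod = engine.nonparametric_lod(yv[:, None])[:, 0]
    return pd.Series(lod, index=engine.markers, name="lod")


def permutation_threshold(
    geno: pd.DataFrame,
    y: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    method: str = "parametric",
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Empirical (1 - alpha) quantile (type 7) of the maximum LOD across
    markers over ``n_perm`` random permutations of the phenotype.
    """
    g, yv = _align(geno, y)
    engine = _ScanEngine(g)
    return _threshold_from_engine(engine, yv, n_perm, alpha, seed, method)


def _threshold_from_engine(engine, yv, n_perm, alpha, seed, method) -> float:
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives an unstable threshold tail")
    rng = np.random.default_rng(seed)
    # permute the sorted values: the threshold then depends on the
    # phenotype only through its multiset, making it exactly invariant
    # to relabelling individuals
    ys = np.sort(np.asarray(yv, dtype=float))
    Y = rng.permuted(np.tile(ys, (n_perm, 1)), axis=1).T
    scan = engine.parametric_lod if method == "parametric" else engine.nonparametric_lod
    max_lod = scan(Y).max(axis=0)
    return float(np.quantile(max_lod, 1.0 - alpha, method="linear"))


def pve(lod: float, n: int) -> float:
    """Percent variance explained: 100 (1 - 10^(-2 LOD / n))."""
    if lod < 0:
        raise ValueError("lod must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(100.0 * (1.0 - 10.0 ** (-2.0 * lod / n)))


def bayes_interval(
    lod: pd.Series,
    cm: pd.Series,
    coverage: float = 0.95,
) -> tuple[float, float, bool]:
    """Bayes credible interval for a QTL on one linkage group.

    The posterior mass at each marker is proportional to 10^LOD;
    the interval is the smallest contiguous cM span that contains the
    peak marker and at least ``coverage`` of the normalised mass.
    Returns (low cM, high cM, flat_flag); a flat LOD curve yields the
    whole linkage group with the flag set.
    """
    lod_v = np.asarray(lod, dtype=float)
    cm_v = np.asarray(cm, dtype=float)
    if len(lod_v) < 3:
        raise ValueError("bayes_interval needs >=3 markers on the linkage group")
    order = np.argsort(cm_v, kind="stable")
    lod_v, cm_v = lod_v[order], cm_v[order]
    if np.ptp(lod_v) < 1e-12:
        return float(cm_v.min()), float(cm_v.max()), True
    w = 10.0 ** (lod_v - lod_v.max())
    w /= w.sum()
    peak = int(np.argmax(lod_v))
    best = None
    for i in range(peak + 1):
        for j in range(peak, len(w)):
            if w[i : j + 1].sum() >= coverage - 1e-12:
                span = cm_v[j] - cm_v[i]
                key = (span, j - i)
                if best is None or key < best[0]:
                    best = (key, (float(cm_v[i]), float(cm_v[j])))
                break
    if best is None:
        return float(cm_v.min()), float(cm_v.max()), True
    return best[1][0], best[1][1], False


@dataclass(frozen=True)
class QtlPeak:
    """One detected QTL: the maximal above-threshold marker on an LG."""

    trait: str
    linkage_group: object
    marker: str
    position_cm: float
    lod: float
    pve: float
    ci_low_cm: float
    ci_high_cm: float
    method: str
    threshold: float


@dataclass
class QTLScanResults:
    """Fitted genome scan for one trait."""

    trait: str
    method: str
    transform: str
    lod: pd.Series
    threshold: float
    alpha: float
    n_perm: int
    seed: object
    n: int
    peaks: list[QtlPeak] = field(default_factory=list)

    def peak_table(self) -> pd.DataFrame:
        cols = [
            "trait", "linkage_group", "marker", "position_cm", "lod",
            "pve", "ci_low_cm", "ci_high_cm", "method", "threshold",
        ]
        rows = [{c: getattr(p, c) for c in cols} for p in self.peaks]
        return pd.DataFrame(rows, columns=cols)

    def summary(self) -> str:
        lines = [
            f"QTL genome scan: {self.trait}",
            f"  method: {self.method} (transform: {self.transform})",
            f"  individuals: {self.n}",
            f"  genome-wide threshold (alpha={self.alpha}, "
            f"{self.n_perm} permutations): {self.threshold:.3f}",
            f"  markers scanned: {len(self.lod)}",
            f"  max LOD: {self.lod.max():.3f} at {self.lod.idxmax()}",
            f"  peaks above threshold: {len(self.peaks)}",
        ]
        for p in self.peaks:
            lines.append(
                f"    LG {p.linkage_group} {p.marker} @ {p.position_cm:.1f} cM  "
                f"LOD {p.lod:.2f}  PVE {p.pve:.1f}%  "
                f"CI [{p.ci_low_cm:.1f}, {p.ci_high_cm:.1f}] cM"
            )
        return "\n".join(lines)


class QTLScan:
    """Genome scan model for one phenotype over an ABH genotype matrix.

    Parameters
    ----------
    y : pd.Series
        Phenotype indexed by genotype id.
    geno : pd.DataFrame
        Individuals x markers ABH calls.
    gmap : GeneticMap
        Map carrying the marker order, linkage groups and cM positions.
    method : {"auto", "parametric", "nonparametric"}
        ``auto`` applies the normality gate: traits passing (possibly
        after the transform ladder) are scanned parametrically, the
        rest by rank scan.
    """

    def __init__(
        self,
        y: pd.Series,
        geno: pd.DataFrame,
        gmap: GeneticMap,
        method: str = "auto",
        trait: str | None = None,
        min_n: int = 30,
        normal_alpha: float = 0.05,
    ):
        missing = [m for m in geno.columns if m not in set(gmap.markers)]
        if missing:
            raise ReconciliationError(f"markers absent from map: {missing[:10]}")
        self.trait = trait or (y.name or "trait")
        self.gmap = gmap
        self.min_n = min_n
        self.method = method
        self.normal_alpha = normal_alpha
        self._geno, self._y = _align(geno, y)
        if len(self._y) < min_n:
            raise ValueError(
                f"trait {self.trait!r}: {len(self._y)} phenotyped individuals "
                f"< min_n={min_n}"
            )

    def fit(
        self,
        n_perm: int = 1000,
        alpha: float = 0.05,
        seed: int | np.random.SeedSequence = 0,
        coverage: float = 0.95,
    ) -> QTLScanResults:
        yv = self._y
        if self.method == "auto":
            transformed, tag = normalize_trait(yv, alpha=self.normal_alpha)
            if tag == "nonparametric":
                method = "nonparametric"
            else:
                method, yv = "parametric", transformed
        else:
            method, tag = self.method, "as-given"

        engine = _ScanEngine(self._geno)
        scan = engine.parametric_lod if method == "parametric" else engine.nonparametric_lod
        lod = pd.Series(scan(yv[:, None])[:, 0], index=engine.markers, name="lod")
        threshold = _threshold_from_engine(engine, yv, n_perm, alpha, seed, method)

        mt = self.gmap.table.set_index("marker")
        peaks: list[QtlPeak] = []
        n = len(yv)
        for lg in self.gmap.linkage_groups:
            lg_markers = [m for m in engine.markers if mt.loc[m, "linkage_group"] == lg]
            if not lg_markers:
                continue
            lg_lod = lod.loc[lg_markers]
            best = lg_lod.idxmax()
            if lg_lod.loc[best] < threshold:
                continue
            cm = mt.loc[lg_markers, "cm"]
            if len(lg_markers) >= 3:
                lo, hi, _flat = bayes_interval(lg_lod, cm, coverage)
            else:
                lo, hi = float(cm.min()), float(cm.max())
            peaks.append(
                QtlPeak(
                    trait=self.trait,
                    linkage_group=lg,
                    marker=best,
                    position_cm=float(mt.loc[best, "cm"]),
                    lod=float(lg_lod.loc[best]),
                    pve=pve(float(lg_lod.loc[best]), n),
                    ci_low_cm=lo,
                    ci_high_cm=hi,
                    method=method,
                    threshold=threshold,
                )
            )
        return QTLScanResults(
            trait=self.trait,
            method=method,
            transform=tag,
            lod=lod,
            threshold=threshold,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed,
            n=n,
            peaks=peaks,
        )


def run_all(
    matrix: pd.DataFrame,
    geno: pd.DataFrame,
    gmap: GeneticMap,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_n: int = 30,
    coverage: float = 0.95,
) -> pd.DataFrame:
    """Scan every attribute of a trait matrix; return the peak table.

    Attributes with fewer than ``min_n`` phenotyped individuals are
    skipped (logged via warnings).  Each attribute uses a child seed
    derived deterministically from ``seed`` and its column position, so
    the full output is reproducible bit-for-bit for a fixed seed.
    """
    shared = matrix.index.intersection(geno.index)
    if len(shared) == 0:
        raise ReconciliationError(
            f"no shared genotype ids between trait matrix and genotypes; "
            f"matrix orphans: {list(matrix.index[:5])}"
        )
    rows = []
    skipped = []
    for k, col in enumerate(matrix.columns):
        y = matrix[col].dropna()
        if len(y.index.intersection(geno.index)) < min_n:
            skipped.append(col)
            continue
        child_seed = np.random.SeedSequence(entropy=int(seed), spawn_key=(k,))
        model = QTLScan(y, geno, gmap, method="auto", trait=col, min_n=min_n)
        res = model.fit(n_perm=n_perm, alpha=alpha, seed=child_seed, coverage=coverage)
        table = res.peak_table()
        if not table.empty:
            phenotype, position, dl, year = parse_attribute_key(col)
            table.insert(1, "phenotype", phenotype)
            table.insert(2, "position", position)
            table.insert(3, "daylength_h", dl)
            table.insert(4, "year", year)
            rows.append(table)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} attributes with < {min_n} phenotyped ids")
    if rows:
        return pd.concat(rows, ignore_index=True)
    return pd.DataFrame(
        columns=[
            "trait", "phenotype", "position", "daylength_h", "year",
            "linkage_group", "marker", "position_cm", "lod", "pve",
            "ci_low_cm", "ci_high_cm", "method", "threshold",
        ]
    )
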