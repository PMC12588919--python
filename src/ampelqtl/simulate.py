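"""Synthetic leaves, genotypes and planted-QTL phenotypes.

The generators emulate the structure the analysis assumes so every
pipeline stage can be exercised without experimental data:

* an F1 intercross genotype matrix over up to 19 linkage groups, with
  gametes drawn from two heterozygous parents and crossovers placed by
  the Haldane map function (recombination probability
  (1 - exp(-2 d / 100)) / 2 for a distance of d cM), giving the
  expected 1:2:1 A:H:B frequencies;
* quantitative phenotypes with planted QTL of controlled percent
  variance explained (additive + dominance effects plus Gaussian
  noise);
* position-structured 21-landmark leaves: apical / middle / basal
  templates, genotype size effects driven by planted QTL, daylength
  and year multipliers, and per-landmark digitising jitter.

Every generator is seed-deterministic and the CSV writers emit a
provenance manifest (seed + config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .genetics import GeneticMap
from .morphometrics import LandmarkSet, N_LANDMARKS

__all__ = [
    "SimulationConfig",
    "PlantedQtl",
    "leaf_template",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_leaves",
    "simulate_gene_table",
    "write_bundle",
]

#: per-position (uniform scale, relative vein width); apical leaves are
#: smaller with relatively thicker veins, basal the opposite
POSITION_PARAMS = {
    "apical": (0.62, 1.35),
    "middle": (1.00, 1.00),
    "basal": (1.15, 0.85),
}


def leaf_template(position: str = "middle", scale: float | None = None, vein_width: float | None = None) -> np.ndarray:
    """Idealised 21-landmark leaf for one shoot position (cm).

    A stylised non-lobed outline consistent with the landmark scheme:
    margin landmarks 14-21 sweep the digitised half of the blade, the
    three vein polygons are thin branched quadrilaterals inside it.
    ``scale`` multiplies all coordinates; ``vein_width`` multiplies the
    perpendicular width components only (template coordinates are
    synthetic fixtures, not measured leaves).
    """
    if position not in POSITION_PARAMS:
        raise ConfigError(f"unknown leaf position {position!r}")
    s0, w0 = POSITION_PARAMS[position]
    s = s0 if scale is None else scale
    w = w0 if vein_width is None else vein_width

    pts = np.zeros((N_LANDMARKS, 2))

    def put(i, x, y):
        pts[i - 1] = (x, y)

    # vein-base width points across the petiole insertion
    put(1, -0.1 - 0.4 * w, 0.0)
    put(2, -0.1 - 0.2 * w, 0.0)
    put(3, -0.1, 0.0)
    put(4, -0.1 + 0.2 * w, 0.0)

    # margin landmarks (width-independent skeleton)
    put(14, 0.6, -2.2)
    put(15, -5.2, 1.4)
    put(16, -3.2, 1.6)
    put(17, -4.3, 3.0)
    put(18, -3.2, 4.0)
    put(19, -1.5, 4.0)
    put(20, -0.6, 7.0)
    put(21, 0.0, 8.0)

    # midvein branch junction (vein runs x ~ -0.1..+0.1 at w=1)
    put(11, -0.1, 6.2)
    put(12, -0.1, 5.8)
    put(13, -0.1 + 0.2 * w, 5.8)

    # distal-vein branch junction near J=(-1.85, 2.2), vein direction
    # u=(-0.6, 0.8), proximal-side normal (-0.8, -0.6)
    J = np.array([-1.85, 2.2])
    u = np.array([-0.6, 0.8])
    npx = np.array([-0.8, -0.6])
    put(8, *(J + 0.15 * u + 0.06 * w * npx))
    put(9, *(J - 0.15 * u + 0.06 * w * npx))
    put(10, *(J + 0.06 * w * np.array([0.8, 0.6])))

    # petiolar-vein junction on the proximal vein near J2=(-1.552, 0.336)
    J2 = np.array([-1.552, 0.336])
    u2 = np.array([-0.96, 0.28])
    n2 = np.array([-0.28, -0.96])
    put(5, *(J2 + 0.12 * u2 + 0.05 * w * n2))
    put(6, *(J2 - 0.12 * u2 + 0.05 * w * n2))
    put(7, *(J2 + 0.05 * w * np.array([0.28, 0.96])))

    return pts * s


@dataclass(frozen=True)
class PlantedQtl:
    """A QTL planted at one marker with a target percent variance explained."""

    marker: str
    pve: float
    dominance_ratio: float = 0.0  # d / a
    affected: tuple[str, ...] = ("size",)  # "size" and/or "shape"

    def __post_init__(self) -> None:
        if not 0.0 < self.pve < 0.95:
            raise ConfigError(f"target PVE must be in (0, 0.95), got {self.pve}")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic bundle.

    Defaults mirror the experimental design the pipeline targets: 135
    genotypes, 19 linkage groups, three leaf positions, two daylengths
    (14 h and 13 h) and two years.
    """

    n_genotypes: int = 135
    n_lgs: int = 19
    markers_per_lg: int = 10
    lg_length_cm: float = 90.0
    seed: int = 0
    qtl: list[PlantedQtl] = field(default_factory=list)
    daylengths: tuple[int, ...] = (14, 13)
    years: tuple[int, ...] = (2021, 2022)
    positions: tuple[str, ...] = ("apical", "middle", "basal")
    presentation: str = "own_rooted"
    daylength_effect: float = 0.04   # log-scale size multiplier for 14 h vs 13 h
    year_effect: float = 0.03        # log-scale size multiplier for the second year
    genotype_sd: float = 0.08        # non-QTL genotype size variation (log scale)
    landmark_noise_sd: float = 0.02  # digitising jitter per coordinate (cm)
    bp_per_cm: float = 1e5

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ConfigError("n_genotypes must be >= 2 (a scan is infeasible otherwise)")
        if self.markers_per_lg < 1 or self.n_lgs < 1:
            raise ConfigError("markers_per_lg and n_lgs must be positive")
        if self.n_lgs > 19:
            raise ConfigError("at most 19 linkage groups")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["qtl"] = [asdict(q) for q in self.qtl]
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)))


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GeneticMap, pd.DataFrame]:
    """F1 intercross ABH genotypes over the configured map.

    Markers are evenly spaced along each linkage group; each individual
    receives two independent gametes per LG with crossovers from the
    Haldane map function, so adjacent-marker recombination fractions
    and the 1:2:1 genotype frequencies follow the map distances.
    Marker names encode physical positions as rh<lg>_<bp> with
    bp = cM * bp_per_cm.
    """
    rng = _rng(cfg.seed, 0)
    n = cfg.n_genotypes
    rows = []
    all_calls = []
    for lg in range(1, cfg.n_lgs + 1):
        m = cfg.markers_per_lg
        if m == 1:
            cms = np.array([0.0])
        else:
            cms = np.linspace(0.0, cfg.lg_length_cm, m)
        bps = np.maximum((cms * cfg.bp_per_cm).round().astype(int), 1)
        names = [f"rh{lg}_{bp}" for bp in bps]
        rows.extend(
            {"marker": nm, "linkage_group": lg, "cm": float(cm)}
            for nm, cm in zip(names, cms)
        )
        d = np.diff(cms)
        r = (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0
        gametes = np.empty((2, n, m), dtype=int)
        for g in range(2):
            alleles = np.empty((n, m), dtype=int)
            alleles[:, 0] = rng.integers(0, 2, size=n)
            for j in range(1, m):
                crossover = rng.random(n) < r[j - 1]
                alleles[:, j] = np.where(crossover, 1 - alleles[:, j - 1], alleles[:, j - 1])
            gametes[g] = alleles
        dosage = gametes.sum(axis=0)  # 0, 1, 2 copies of the "B" allele
        calls = np.array(["A", "H", "B"])[dosage]
        all_calls.append(pd.DataFrame(calls, columns=names))
    geno = pd.concat(all_calls, axis=1)
    geno.index = pd.Index([f"G{i + 1:03d}" for i in range(n)], name="id")
    gmap = GeneticMap(pd.DataFrame(rows))
    return gmap, geno


def _qtl_effects(geno: pd.DataFrame, q: PlantedQtl, residual_sd: float = 1.0) -> tuple[np.ndarray, float, float]:
    """Additive/dominance codes and effect sizes hitting the target PVE.

    With 1:2:1 genotype frequencies, Var(s) = 1/2 for the additive code
    and Var(h) = 1/4 for the dominance indicator (uncorrelated), so the
    genetic variance is a^2/2 + d^2/4 and the additive effect solves
    pve = var_g / (var_g + residual_sd^2).
    """
    if q.marker not in geno.columns:
        raise ConfigError(f"planted QTL marker {q.marker!r} not in genotype matrix")
    var_g = q.pve / (1.0 - q.pve) * residual_sd**2
    a = np.sqrt(var_g / (0.5 + 0.25 * q.dominance_ratio**2))
    d = q.dominance_ratio * a
    s = geno[q.marker].map({"A": -1.0, "H": 0.0, "B": 1.0}).to_numpy(dtype=float)
    h = (s == 0.0).astype(float)
    return a * s + d * h, a, d


def simulate_phenotype(
    geno: pd.DataFrame,
    qtl: PlantedQtl | list[PlantedQtl],
    seed: int = 0,
    mean: float = 0.0,
    residual_sd: float = 1.0,
) -> pd.Series:
    """Phenotype y = mu + sum(a s + d h) + N(0, residual_sd^2).

    The residual SD is fixed and the genetic effects are solved so the
    expected PVE of each planted QTL equals its target.
    """
    qtl_list = [qtl] if isinstance(qtl, PlantedQtl) else list(qtl)
    total_pve = sum(q.pve for q in qtl_list)
    if total_pve >= 0.95:
        raise ConfigError(f"summed target PVE {total_pve} is unattainable")
    rng = _rng(seed, 1)
    y = np.full(len(geno), mean, dtype=float)
    for q in qtl_list:
        genetic, _, _ = _qtl_effects(geno, q, residual_sd)
        y = y + genetic
    y = y + rng.normal(0.0, residual_sd, size=len(geno))
    return pd.Series(y, index=geno.index, name="phenotype")


def simulate_leaves(
    cfg: SimulationConfig,
    geno: pd.DataFrame,
) -> list[LandmarkSet]:
    """Position-structured landmark leaves for every genotype.

    Each leaf is the position template scaled by
    exp(genotype size effect + daylength effect + year effect + noise),
    with an anisotropic x-stretch for planted shape QTL and independent
    Gaussian landmark jitter.  The full factorial over positions x
    daylengths x years is emitted per genotype.
    """
    rng = _rng(cfg.seed, 2)
    n = len(geno)

    size_qtl = [q for q in cfg.qtl if "size" in q.affected]
    shape_qtl = [q for q in cfg.qtl if "shape" in q.affected]

    # log-scale genotype size signal: planted QTL + polygenic background
    log_size = np.zeros(n)
    genetic_var = 0.0
    for q in size_qtl:
        genetic, a, d = _qtl_effects(geno, q, residual_sd=1.0)
        genetic_var += a**2 / 2.0 + d**2 / 4.0
        log_size = log_size + genetic
    total_sd_target = cfg.genotype_sd
    if genetic_var > 0:
        # rescale so planted PVE is preserved within the genotype signal
        resid_var = genetic_var * (1.0 - sum(q.pve for q in size_qtl)) / max(
            sum(q.pve for q in size_qtl), 1e-12
        )
        scale = total_sd_target / np.sqrt(genetic_var + resid_var)
        log_size = log_size * scale
        resid_sd = np.sqrt(resid_var) * scale
    else:
        resid_sd = total_sd_target
    log_size = log_size + rng.normal(0.0, resid_sd, size=n)

    log_shape = np.zeros(n)
    for q in shape_qtl:
        genetic, _, _ = _qtl_effects(geno, q, residual_sd=1.0)
        log_shape = log_shape + 0.1 * genetic

    templates = {p: leaf_template(p) for p in cfg.positions}
    leaves = []
    for i, gid in enumerate(geno.index):
        for position in cfg.positions:
            for dl in cfg.daylengths:
                for year_idx, year in enumerate(cfg.years):
                    log_scale = (
                        log_size[i]
                        + (cfg.daylength_effect if dl == max(cfg.daylengths) else 0.0)
                        + (cfg.year_effect * year_idx)
                    )
                    pts = templates[position] * np.exp(log_scale)
                    if log_shape[i] != 0.0:
                        stretch = np.exp(log_shape[i])
                        pts = pts * np.array([stretch, 1.0 / stretch])
                    pts = pts + rng.normal(0.0, cfg.landmark_noise_sd, size=pts.shape)
                    leaves.append(
                        LandmarkSet(
                            leaf_id=f"{gid}_{position}_{dl}h_{year}",
                            genotype_id=str(gid),
                            presentation=cfg.presentation,
                            position=position,
                            daylength_h=dl,
                            year=year,
                            points=pts,
                        )
                    )
    return leaves


def simulate_gene_table(
    cfg: SimulationConfig,
    genes_per_chromosome: int = 120,
    n_pathways: int = 12,
    seed_offset: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random gene positions and pathway annotation over the map's genome.

    Genes are uniform on each chromosome's physical span; every gene is
    assigned to one of ``n_pathways`` pathways uniformly at random.
    """
    rng = _rng(cfg.seed, seed_offset)
    span = int(cfg.lg_length_cm * cfg.bp_per_cm)
    rows = []
    for chrom in range(1, cfg.n_lgs + 1):
        bps = np.sort(rng.integers(1, span + 1, size=genes_per_chromosome))
        for k, bp in enumerate(bps):
            rows.append(
                {"gene_id": f"gene{chrom}_{k + 1:04d}", "chromosome": chrom, "bp_start": int(bp)}
            )
    genes = pd.DataFrame(rows)
    annotation = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "pathway_id": [f"vv{rng.integers(1, n_pathways + 1):03d}" for _ in range(len(genes))],
        }
    )
    annotation["pathway_name"] = annotation["pathway_id"].map(lambda p: f"pathway {p}")
    return genes, annotation


def write_bundle(cfg: SimulationConfig, outdir) -> dict[str, str]:
    """Simulate and write the full synthetic CSV bundle + manifest.

    Emits landmark, genotype (R/qtl ABH), map, gene and annotation
    CSVs in the same dialects the readers consume, plus a JSON manifest
    carrying the seed and config hash.
    """
    from .genetics import write_abh, write_map
    from .morphometrics import write_landmarks

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gmap, geno = simulate_genotypes(cfg)
    leaves = simulate_leaves(cfg, geno)
    genes, annotation = simulate_gene_table(cfg)

    stamp = f"ampelqtl simulation seed={cfg.seed} config={cfg.config_hash()}"
    paths = {
        "landmarks": outdir / "landmarks.csv",
        "genotypes": outdir / "genotypes_abh.csv",
        "map": outdir / "map.csv",
        "genes": outdir / "genes.csv",
        "annotation": outdir / "annotation.csv",
        "manifest": outdir / "manifest.json",
    }
    write_landmarks(leaves, paths["landmarks"], header_comment=stamp)
    write_abh(gmap, geno, paths["genotypes"], header_comment=stamp)
    write_map(gmap, paths["map"], header_comment=stamp)
    with open(paths["genes"], "w") as fh:
        fh.write(f"# {stamp}\n")
        genes.to_csv(fh, index=False)
    with open(paths["annotation"], "w") as fh:
        fh.write(f"# {stamp}\n")
        annotation.to_csv(fh, index=False)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_genotypes": cfg.n_genotypes,
        "n_leaves": len(leaves),
        "n_markers": gmap.n_markers,
        "files": {k: str(v.name) for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
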