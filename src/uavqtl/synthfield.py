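"""Synthetic field trial generator with known ground truth.

Emulates a UAV phenotyping study of a maize inbred-line panel: a flat field
of 3-row plots (2 m rows, 65 cm row spacing, 8 plants per row), four flights
at the V5/V12/V15/R growth stages, a temperate (TEM) and a tropical (TST)
subpopulation whose logistic growth curves cross — temperate lines are
taller at the first three stages, tropical lines overtake at the fourth —
plus biallelic genotypes with Balding-Nichols population structure and
planted stage-specific QTL effects.

Every generator is a pure function of its parameters and seed, so each
downstream stage (kriged DEM -> CSM -> segmentation -> zonal extraction ->
traits -> association) can be tested against exact ground truth without any
external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box

from .assoc import MISSING, GenotypeMatrix
from .extract import PlotMap
from .raster import Affine, Raster

logger = logging.getLogger(__name__)

__all__ = [
    "FieldDesign",
    "GrowthParams",
    "QTLSpec",
    "generate_terrain",
    "generate_true_heights",
    "render_flight",
    "sample_bare_points",
    "simulate_genotypes",
    "apply_qtl_effects",
]

PH_COLUMNS = ("PH_1", "PH_2", "PH_3", "PH_4")
STAGE_NAMES = ("V5", "V12", "V15", "R")


def _default_groups() -> tuple[str, ...]:
    return tuple(["TEM"] * 117 + ["TST"] * 135)


@dataclass(frozen=True)
class FieldDesign:
    """Geometry of the trial: plots, rows, plants, raster resolution.

    All distances are centimetres.  Plots are laid out on a regular grid of
    ``n_cols`` plots per field row, separated by alleys; the plot polygon
    spans the row length in x and the three rows plus half a row spacing of
    margin in y, so adjacent plot polygons are disjoint.
    """

    groups: tuple[str, ...] = field(default_factory=_default_groups)
    plot_rows: int = 3
    row_length: float = 200.0
    row_spacing: float = 65.0
    plants_per_row: int = 8
    pixel_size: float = 4.0
    field_origin: tuple[float, float] = (10_000.0, 50_000.0)
    n_cols: int = 18
    alley_x: float = 80.0
    alley_y: float = 65.0
    margin: float = 200.0
    base_elevation: float = 5_000.0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        labels = set(self.groups)
        if not {"TEM", "TST"} <= labels:
            raise ValueError("both TEM and TST labels must be present")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_lines(self) -> int:
        return len(self.groups)

    @property
    def line_ids(self) -> list[str]:
        return [f"L{i + 1:03d}" for i in range(self.n_lines)]

    @property
    def plot_size(self) -> tuple[float, float]:
        return self.row_length, self.plot_rows * self.row_spacing

    def plot_anchor(self, i: int) -> tuple[float, float]:
        """Top-left corner (world x, y) of plot i's polygon."""
        w, h = self.plot_size
        col, row = i % self.n_cols, i // self.n_cols
        x0 = self.field_origin[0] + self.margin + col * (w + self.alley_x)
        y0 = self.field_origin[1] - self.margin - row * (h + self.alley_y)
        return x0, y0

    def plot_polygon(self, i: int):
        x0, y0 = self.plot_anchor(i)
        w, h = self.plot_size
        return box(x0, y0 - h, x0 + w, y0)

    def plant_positions(self, i: int) -> np.ndarray:
        """(n_plants, 2) world coordinates of plot i's plant apices."""
        x0, y0 = self.plot_anchor(i)
        dx = self.row_length / self.plants_per_row
        xs = x0 + dx / 2 + dx * np.arange(self.plants_per_row)
        ys = y0 - self.row_spacing / 2 - self.row_spacing * np.arange(self.plot_rows)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    @property
    def canopy_radius_full(self) -> float:
        """Plant influence radius at closed canopy: covers the plot polygon."""
        dx = self.row_length / self.plants_per_row
        return float(np.hypot(dx / 2, self.row_spacing / 2)) + self.pixel_size

    def extent(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the full field incl. margins."""
        w, h = self.plot_size
        n_rows = -(-self.n_lines // self.n_cols)
        maxx = (self.field_origin[0] + 2 * self.margin
                + self.n_cols * w + (self.n_cols - 1) * self.alley_x)
        miny = (self.field_origin[1] - 2 * self.margin
                - n_rows * h - (n_rows - 1) * self.alley_y)
        return self.field_origin[0], miny, maxx, self.field_origin[1]

    def grid_template(self) -> Raster:
        minx, miny, maxx, maxy = self.extent()
        ncol = int(np.ceil((maxx - minx) / self.pixel_size))
        nrow = int(np.ceil((maxy - miny) / self.pixel_size))
        if ncol <= 0 or nrow <= 0:
            raise ValueError("non-positive raster extent")
        return Raster(np.zeros((nrow, ncol)), Affine.north_up(minx, maxy, self.pixel_size))

    def plot_map(self) -> PlotMap:
        table = pd.DataFrame({
            "plot_id": [f"P{i + 1:03d}" for i in range(self.n_lines)],
            "line_id": self.line_ids,
            "group": list(self.groups),
            "geometry": [self.plot_polygon(i) for i in range(self.n_lines)],
        })
        return PlotMap(table)


@dataclass(frozen=True)
class GrowthParams:
    """Per-group logistic height curves H(t) = K / (1 + exp(-r (t - t0))).

    Defaults reproduce the study pattern at sampling days 24/45/57/80:
    the temperate group (earlier inflection) leads at stages 1-3 while the
    tropical group (taller asymptote, later inflection) overtakes at stage 4,
    and the tropical growth-rate ratios are larger over the 1->2 and 3->4
    intervals.  Per-line deviations are multiplicative on K and r and
    additive on t0; an extra "seedling vigor" line effect with
    stage-decaying weights models the large independent spread of
    early-stage heights (emergence and establishment variation), so
    adjacent mid-season stages end up the most strongly correlated pair.
    """

    asymptote: dict = field(default_factory=lambda: {"TEM": 205.0, "TST": 235.0})
    rate: dict = field(default_factory=lambda: {"TEM": 0.115, "TST": 0.115})
    inflection: dict = field(default_factory=lambda: {"TEM": 48.0, "TST": 53.0})
    stage_days: tuple[float, ...] = (24.0, 45.0, 57.0, 80.0)
    asymptote_cv: float = 0.07
    rate_cv: float = 0.05
    inflection_sd: float = 1.0
    vigor_sd: float = 0.35
    vigor_weights: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.asymptote.values()):
            raise ValueError("asymptotes must be positive")
        if np.any(np.diff(self.stage_days) <= 0):
            raise ValueError("stage_days must be strictly increasing")

    def curve(self, group: str, t: np.ndarray, k_mult: float = 1.0,
              r_mult: float = 1.0, t0_shift: float = 0.0) -> np.ndarray:
        k = self.asymptote[group] * k_mult
        r = self.rate[group] * r_mult
        t0 = self.inflection[group] + t0_shift
        return k / (1.0 + np.exp(-r * (np.asarray(t, dtype=float) - t0)))


@dataclass(frozen=True)
class QTLSpec:
    """Planted QTL effects: (chrom, pos, trait, effect) plus h2 per trait.

    ``effect`` is the per-dosage additive effect in the trait's units (cm for
    PH traits, ratio units for growth rates); ``h2`` gives the target fraction
    of the added variance (QTL + environmental noise) that is genetic.
    """

    effects: tuple[tuple[int, int, str, float], ...] = ()
    h2: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait, h in self.h2.items():
            if not 0 < h < 1:
                raise ValueError(f"h2 for {trait} must lie in (0, 1)")


def generate_terrain(design: FieldDesign, relief_amplitude: float,
                     seed: int) -> Raster:
    """Smooth single-band terrain over the field extent.

    The surface is a sum of long-wavelength random cosines rescaled so the
    maximum absolute deviation from the base elevation is ``relief_amplitude``
    cm (hence max - min <= 2 x amplitude); amplitude 0 gives a flat field.
    Wavelengths are 1.5-4x the field span (>= 30 m), the gentle undulation of
    a levelled trial field, so bare-ground interpolation across plot-sized
    gaps stays accurate.
    """
    if relief_amplitude < 0:
        raise ValueError("relief_amplitude must be >= 0")
    template = design.grid_template()
    if relief_amplitude == 0:
        return template.copy_with(np.full(template.shape, design.base_elevation))
    rng = np.random.default_rng(seed)
    xs, ys = template.cell_centers()
    minx, miny, maxx, maxy = design.extent()
    span = max(maxx - minx, maxy - miny, 3000.0)
    z = np.zeros(template.shape)
    for _ in range(6):
        wavelength = rng.uniform(1.5, 4.0) * span
        theta = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        kx, ky = np.cos(theta), np.sin(theta)
        z += rng.uniform(0.5, 1.0) * np.cos(
            2 * np.pi * (kx * xs + ky * ys) / wavelength + phase)
    z *= relief_amplitude / np.abs(z).max()
    return template.copy_with(design.base_elevation + z)


def generate_true_heights(design: FieldDesign, growth: GrowthParams,
                          seed: int) -> pd.DataFrame:
    """One true height (cm) per line per stage, from the group growth curves.

    Heights are strictly increasing across stages for every line (each line
    follows one monotone logistic curve).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(growth.stage_days)
    w = np.asarray(growth.vigor_weights)
    rows = []
    for line_id, group in zip(design.line_ids, design.groups):
        k_mult = np.exp(rng.normal(0.0, growth.asymptote_cv))
        r_mult = np.exp(rng.normal(0.0, growth.rate_cv))
        t0_shift = rng.normal(0.0, growth.inflection_sd)
        # clipped at 4 sd so the vigor factor can never outgrow the
        # stage-to-stage height increase (keeps per-line monotonicity)
        vigor = float(np.clip(rng.normal(0.0, growth.vigor_sd),
                              -4 * growth.vigor_sd, 4 * growth.vigor_sd))
        heights = growth.curve(group, t, k_mult, r_mult, t0_shift)
        heights = heights * np.exp(vigor * w)
        rows.append({"line_id": line_id, "group": group,
                     **{c: h for c, h in zip(PH_COLUMNS, heights)}})
    return pd.DataFrame(rows)


def _bump_profile(r2: np.ndarray, radius: float) -> np.ndarray:
    """Flat-topped canopy bump: 1 - (r/R)^4 inside the radius, 0 outside."""
    frac = r2 / (radius * radius)
    return np.where(frac < 1.0, 1.0 - frac**2, 0.0)


def render_flight(
    terrain: Raster,
    design: FieldDesign,
    heights: pd.DataFrame,
    stage: int,
    canopy_cover: float = 0.8,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[Raster, Raster]:
    """Synthetic DSM + RGB orthomosaic for one flight.

    Canopy is rendered as one flat-topped smooth bump per plant (8 x 3 per
    plot) whose apex equals the line's true height at that stage, so the
    per-plot DSM-minus-terrain maximum equals the tallest-plant height before
    noise — mirroring ruler measurement of the tallest point.  ``canopy_cover``
    scales the plant influence radius (1 = closed canopy filling the plot
    polygon).  Gaussian noise with sd ``noise_sd`` cm is added to the DSM.
    The RGB image is green-dominant exactly where canopy is present and
    soil-coloured elsewhere, linearly separable under the excess-green index.
    """
    if not 1 <= stage <= 4:
        raise ValueError("stage must be in 1..4")
    if not 0 < canopy_cover <= 1:
        raise ValueError("canopy_cover must lie in (0, 1]")
    col = PH_COLUMNS[stage - 1]
    height_of = dict(zip(heights["line_id"], heights[col]))
    missing = [l for l in design.line_ids if l not in height_of]
    if missing:
        raise ValueError(f"heights missing for lines: {missing[:5]}")

    rng = np.random.default_rng(seed)
    canopy = np.zeros(terrain.shape)
    radius = design.canopy_radius_full * np.sqrt(canopy_cover)
    px = design.pixel_size
    t = terrain.transform
    half = int(np.ceil(radius / px)) + 1
    nrow, ncol = terrain.shape
    for i, line_id in enumerate(design.line_ids):
        h = float(height_of[line_id])
        if h <= 0:
            logger.warning("line %s has non-positive height at stage %d; "
                           "rendered as an empty plot", line_id, stage)
            continue
        for cx, cy in design.plant_positions(i):
            r0, c0 = t.index(cx, cy)
            rlo, rhi = max(0, r0 - half), min(nrow, r0 + half + 1)
            clo, chi = max(0, c0 - half), min(ncol, c0 + half + 1)
            rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi),
                                 indexing="ij")
            xs, ys = t.xy(rr, cc)
            r2 = (xs - cx) ** 2 + (ys - cy) ** 2
            bump = h * _bump_profile(r2, radius)
            np.maximum(canopy[rlo:rhi, clo:chi], bump,
                       out=canopy[rlo:rhi, clo:chi])

    dsm_vals = terrain.values + canopy
    if noise_sd > 0:
        dsm_vals = dsm_vals + rng.normal(0.0, noise_sd, size=dsm_vals.shape)
    dsm = terrain.copy_with(dsm_vals)

    veg = canopy > 0
    soil = np.array([135.0, 110.0, 95.0])
    leaf = np.array([60.0, 160.0, 60.0])
    rgb_vals = np.empty((3,) + terrain.shape)
    for b in range(3):
        rgb_vals[b] = np.where(veg, leaf[b], soil[b])
    rgb_vals += rng.normal(0.0, 5.0, size=rgb_vals.shape)
    rgb_vals = np.clip(rgb_vals, 0.0, 255.0)
    rgb = Raster(rgb_vals, terrain.transform, nodata=terrain.nodata, units="dn")
    return dsm, rgb


def sample_bare_points(terrain: Raster, plots: PlotMap, n_points: int,
                       seed: int, buffer: float = 0.0) -> np.ndarray:
    """Sample (x, y, elevation) records from cells outside all plot polygons.

    Mirrors surveying bare-soil elevations on a flight's DSM where no
    vegetation stands; used to krige the DEM.  ``buffer`` (cm) widens the
    exclusion zone around each plot, e.g. by the canopy radius so leaves
    overhanging the plot boundary are never mistaken for ground.
    """
    if n_points < 3:
        raise ValueError("need at least 3 bare points")
    rng = np.random.default_rng(seed)
    nrow, ncol = terrain.shape
    order = rng.permutation(nrow * ncol)
    union = shapely.union_all(list(plots.table["geometry"]))
    if buffer > 0:
        union = union.buffer(buffer)
    shapely.prepare(union)
    out = np.empty((n_points, 3))
    got = 0
    for lo in range(0, len(order), 4 * n_points):
        idx = order[lo : lo + 4 * n_points]
        rows, cols = idx // ncol, idx % ncol
        xs, ys = terrain.transform.xy(rows, cols)
        bare = ~shapely.contains_xy(union, xs, ys)
        bare &= terrain.values[rows, cols] != terrain.nodata
        take = min(int(bare.sum()), n_points - got)
        sel = np.flatnonzero(bare)[:take]
        out[got : got + take, 0] = xs[sel]
        out[got : got + take, 1] = ys[sel]
        out[got : got + take, 2] = terrain.values[rows[sel], cols[sel]]
        got += take
        if got == n_points:
            return out
    raise ValueError(f"only {got} bare cells available, {n_points} requested")


def simulate_genotypes(
    n_lines: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    fst: float = 0.05,
    groups: tuple[str, ...] | None = None,
    seed: int = 0,
    n_chrom: int = 10,
    chrom_length: int = 50_000_000,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Biallelic dosage matrix with two-subpopulation structure.

    Ancestral allele frequencies are drawn uniformly from ``maf_range``; each
    group's frequency then follows the Balding-Nichols model
    Beta(p (1-F)/F, (1-p) (1-F)/F) with F = ``fst`` (F = 0 keeps the
    ancestral frequency exactly), and dosages are Binomial(2, p_group).
    SNPs are placed uniformly on ``n_chrom`` chromosomes of
    ``chrom_length`` bp, 1-based, sorted within chromosome.
    """
    low, high = maf_range
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0 <= low <= high <= 0.5:
        raise ValueError("maf_range must satisfy 0 <= low <= high <= 0.5")
    if groups is None:
        groups = tuple(["TEM"] * (n_lines // 2) + ["TST"] * (n_lines - n_lines // 2))
    if len(groups) != n_lines:
        raise ValueError("groups length must equal n_lines")
    rng = np.random.default_rng(seed)

    per_chrom = np.full(n_chrom, n_snps // n_chrom)
    per_chrom[: n_snps % n_chrom] += 1
    chrom = np.repeat(np.arange(1, n_chrom + 1), per_chrom)
    pos = np.concatenate([
        np.sort(rng.choice(chrom_length, size=m, replace=False)) + 1
        for m in per_chrom
    ]).astype(np.int64)

    p_anc = rng.uniform(low, high, size=n_snps) if high > low else np.full(n_snps, low)
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels))
    p_group = {}
    for g in uniq:
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_group[g] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        else:
            p_group[g] = p_anc
    dosages = np.empty((n_lines, n_snps), dtype=np.int8)
    for g in uniq:
        rows = labels == g
        dosages[rows] = rng.binomial(
            2, p_group[g][None, :], size=(int(rows.sum()), n_snps))
    if missing_rate > 0:
        miss = rng.random(dosages.shape) < missing_rate
        dosages[miss] = MISSING

    line_ids = np.array([f"L{i + 1:03d}" for i in range(n_lines)])
    snp_ids = np.array([f"chr{c}_{p}" for c, p in zip(chrom, pos)])
    return GenotypeMatrix(line_ids, dosages, snp_ids, chrom, pos)


def apply_qtl_effects(
    genotypes: GenotypeMatrix,
    base_heights: pd.DataFrame,
    spec: QTLSpec,
    seed: int = 0,
    noise_sd: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Overlay planted QTL effects plus environmental noise on trait columns.

    For each trait with planted effects, the genetic increment
    g_i = sum(effect x dosage_i) is added (mean-centred, so group contrasts
    are preserved) together with Gaussian noise scaled to make the genetic
    fraction of the added variance equal the trait's target h2.  Traits
    without planted effects receive N(0, ``noise_sd``) noise only.

    Returns the modified table and a per-trait dict of realized variance
    components {var_g, var_e, h2_realized}.
    """
    rng = np.random.default_rng(seed)
    table = base_heights.copy()
    order = {l: i for i, l in enumerate(genotypes.line_ids)}
    try:
        row_idx = np.array([order[l] for l in table["line_id"]])
    except KeyError as exc:
        raise ValueError(f"line {exc} absent from genotype matrix") from exc

    by_trait: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, pos, trait, effect in spec.effects:
        if trait not in table.columns:
            raise ValueError(f"unknown trait {trait!r} in QTL spec")
        by_trait.setdefault(trait, []).append((chrom, pos, effect))

    info: dict[str, dict] = {}
    trait_cols = [c for c in table.columns if c not in ("line_id", "group")]
    for trait in trait_cols:
        if trait in by_trait:
            g = np.zeros(len(table))
            for chrom, pos, effect in by_trait[trait]:
                hit = np.flatnonzero((genotypes.chrom == chrom) & (genotypes.pos == pos))
                if hit.size == 0:
                    raise ValueError(f"no SNP at chr{chrom}:{pos} in genotypes")
                dose = genotypes.dosages[row_idx, hit[0]].astype(float)
                dose[dose == MISSING] = np.nan
                dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
                g += effect * dose
            var_g = float(np.var(g))
            h2 = spec.h2.get(trait, 0.5)
            sd_e = float(np.sqrt(var_g * (1 - h2) / h2)) if var_g > 0 else noise_sd
            e = rng.normal(0.0, sd_e, size=len(table))
            table[trait] = table[trait] + (g - g.mean()) + e
            info[trait] = {"var_g": var_g, "var_e": float(np.var(e)),
                           "h2_realized": var_g / (var_g + np.var(e))
                           if var_g + np.var(e) > 0 else float("nan")}
        else:
            e = rng.normal(0.0, noise_sd, size=len(table))
            table[trait] = table[trait] + e
            info[trait] = {"var_g": 0.0, "var_e": float(np.var(e)),
                           "h2_realized": 0.0}
    return table, info
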