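"""Synthetic landscapes, climates, sites and genotypes with planted truth.

The generator emulates a mid-latitude mountain-belt sampling design: ~17
demes strung along an east–west landscape, four bioclimatic surfaces
(bio4, bio6, bio15, bio16), hierarchical-island allele frequencies with a
configurable background FST, a minority of elevated-FST loci, and a minority
of loci whose deme frequencies follow a climate gradient logistically.

Every draw comes from a named substream of one master seed, so each stage
(landscape, frequencies, genotypes, missingness, depth, future climate) is
independently reproducible.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix, LOCUS_COLUMNS, write_vcf
from .grids import CLIMATE_VARS, ClimateGrid, write_climate_grid

SITE_COLUMNS = ["pop", "lat", "lon", *CLIMATE_VARS]

#: per-variable surface parameterisation: (mean level, smooth-noise amplitude,
#: (east-west slope, north-south slope) in units per normalised coordinate).
#: bio15 (precipitation seasonality) carries the dominant east-west gradient;
#: bio6 (min temperature of coldest month) declines gently northward.
_SURFACE_PARAMS = {
    "bio4": (600.0, 40.0, (20.0, 10.0)),
    "bio6": (5.0, 1.5, (0.5, -1.5)),
    "bio15": (80.0, 4.0, (25.0, 0.0)),
    "bio16": (550.0, 60.0, (-30.0, 20.0)),
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class LandscapeConfig:
    """Study-design parameters of the synthetic system.

    Defaults mirror the emulated sampling design: 17 demes of 6 diploids,
    background FST 0.056, ~2% missing genotypes, ancestral allele
    frequencies in U(0.1, 0.9), and locus-class counts in the proportions of
    a ~5,354-SNP panel (a small minority of elevated-FST and of
    climate-associated loci). ``clim_effect`` is the logistic slope of a
    planted climate locus per SD of its climate variable.
    """

    grid_nx: int = 48
    grid_ny: int = 20
    lon_min: float = -104.0
    lat_min: float = 18.5
    cell: float = 0.125
    n_pops: int = 17
    n_ind_per_pop: int = 6
    n_neutral: int = 5183
    n_highfst: int = 74
    n_clim: int = 97
    fst_background: float = 0.056
    fst_elevated: float = 0.196
    clim_effect: float = 1.0
    missing_rate: float = 0.02
    mean_depth: float = 21.8
    gradient_amp: float = 1.0
    noise_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 4:
            raise ValueError("n_pops must be >= 4")
        if not (0 < self.fst_background < 1 and 0 < self.fst_elevated < 1):
            raise ValueError("FST parameters must lie in (0, 1)")
        if self.fst_elevated <= self.fst_background:
            raise ValueError("fst_elevated must exceed fst_background")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        for name in ("n_neutral", "n_highfst", "n_clim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_loci(self) -> int:
        return self.n_neutral + self.n_highfst + self.n_clim


class PlacementError(RuntimeError):
    """The grid is too small to place the requested number of sites."""


def _smooth_field(rng: np.random.Generator, nx: int, ny: int, n_waves: int = 6) -> np.ndarray:
    """Sum of low-frequency cosine basis functions with random coefficients,
    normalised to unit standard deviation (zero if degenerate)."""
    x = np.linspace(0.0, 1.0, nx)
    y = np.linspace(0.0, 1.0, ny)
    X, Y = np.meshgrid(x, y)
    field = np.zeros((ny, nx))
    for _ in range(n_waves):
        fx, fy = rng.integers(0, 3, size=2)
        if fx == 0 and fy == 0:
            continue
        amp = rng.normal() / np.hypot(fx, fy)
        phase = rng.uniform(0, 2 * np.pi)
        field += amp * np.cos(2 * np.pi * (fx * X + fy * Y) + phase)
    sd = field.std()
    return field / sd if sd > 0 else field


def simulate_landscape(config: LandscapeConfig) -> tuple[ClimateGrid, pd.DataFrame]:
    """Generate the current-epoch climate grid and the site table.

    Each surface is mean level + planar gradient (scaled by
    ``gradient_amp``) + smooth cosine noise (scaled by ``noise_amp``).
    Sites are distinct cells at least 2 cells apart; their climate values
    are read off the grid.
    """
    rng = substream(config.seed, "landscape")
    nx, ny = config.grid_nx, config.grid_ny
    xs = np.linspace(0.0, 1.0, nx)
    ys = np.linspace(0.0, 1.0, ny)
    X, _Y = np.meshgrid(xs, ys)
    Ynorth = np.meshgrid(xs, ys)[1][::-1]  # row 0 = north

    data = {}
    for var in CLIMATE_VARS:
        mean, amp, (slope_ew, slope_ns) = _SURFACE_PARAMS[var]
        surf = (
            mean
            + config.gradient_amp * (slope_ew * (X - 0.5) + slope_ns * (Ynorth - 0.5))
            + config.noise_amp * amp * _smooth_field(rng, nx, ny)
        )
        data[var] = surf
    grid = ClimateGrid(data, config.lon_min, config.lat_min, config.cell, epoch="current")

    # site placement: rejection sampling with a minimum spacing of 2 cells
    cells: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 200 * config.n_pops
    while len(cells) < config.n_pops:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {config.n_pops} sites >= 2 cells apart on a "
                f"{nx} x {ny} grid"
            )
        r = int(rng.integers(0, ny))
        c = int(rng.integers(0, nx))
        if all(np.hypot(r - r0, c - c0) >= 2 for r0, c0 in cells):
            cells.append((r, c))

    lon = np.array([config.lon_min + (c + 0.5) * config.cell for _, c in cells])
    lat = np.array([config.lat_min + (ny - 1 - r + 0.5) * config.cell for r, _ in cells])
    # label west-to-east so population order follows the main gradient
    order = np.argsort(lon)
    lon, lat = lon[order], lat[order]
    cells = [cells[i] for i in order]
    rows = {
        "pop": [f"P{i + 1:02d}" for i in range(config.n_pops)],
        "lat": lat,
        "lon": lon,
    }
    for var in CLIMATE_VARS:
        rows[var] = np.array([grid.data[var][r, c] for r, c in cells])
    return grid, pd.DataFrame(rows)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def simulate_genotypes(sites: pd.DataFrame, config: LandscapeConfig) -> GenotypeMatrix:
    """Draw genotypes with planted neutral / elevated-FST / climate loci.

    Neutral and elevated-FST loci: ancestral frequency ``p0 ~ U(0.1, 0.9)``
    and deme frequencies ``p_j ~ Beta(p0*theta, (1-p0)*theta)`` with
    ``theta = (1-F)/F`` — the island-model decomposition whose expected FST
    is F. Climate loci instead follow a deterministic logistic cline,
    ``logit(p_j) = logit(p0) + clim_effect * z_j``, in the standardised value
    of one uniformly assigned climate variable. Genotypes are Binomial(2,
    p_j); missingness is uniform; depth is Poisson(mean_depth).
    """
    n_pops = len(sites)
    if n_pops != config.n_pops:
        raise ValueError("site table does not match config.n_pops")
    L = config.n_loci
    freq_rng = substream(config.seed, "freqs")
    geno_rng = substream(config.seed, "genotypes")
    miss_rng = substream(config.seed, "missingness")
    depth_rng = substream(config.seed, "depth")

    classes = np.array(
        ["neutral"] * config.n_neutral
        + ["highfst"] * config.n_highfst
        + ["clim"] * config.n_clim
    )
    p0 = freq_rng.uniform(0.1, 0.9, size=L)
    P = np.empty((n_pops, L))

    z = sites[list(CLIMATE_VARS)].to_numpy(dtype=float)
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)

    fst_of = {"neutral": config.fst_background, "highfst": config.fst_elevated}
    for cls in ("neutral", "highfst"):
        sel = classes == cls
        if not sel.any():
            continue
        F = fst_of[cls]
        theta = (1.0 - F) / F
        P[:, sel] = freq_rng.beta(p0[sel] * theta, (1.0 - p0[sel]) * theta,
                                  size=(n_pops, int(sel.sum())))

    clim_var = np.full(L, "", dtype=object)
    sel = classes == "clim"
    if sel.any():
        which = freq_rng.integers(0, len(CLIMATE_VARS), size=int(sel.sum()))
        clim_var[sel] = [CLIMATE_VARS[w] for w in which]
        P[:, sel] = 1.0 / (
            1.0 + np.exp(-(_logit(p0[sel])[None, :] + config.clim_effect * z[:, which]))
        )
    P = np.clip(P, 1e-9, 1.0 - 1e-9)

    geno = np.empty((n_pops * config.n_ind_per_pop, L), dtype=np.int16)
    pops: list[str] = []
    ids: list[str] = []
    for j, pop in enumerate(sites["pop"]):
        block = geno_rng.binomial(2, P[j], size=(config.n_ind_per_pop, L))
        geno[j * config.n_ind_per_pop:(j + 1) * config.n_ind_per_pop] = block
        pops.extend([pop] * config.n_ind_per_pop)
        ids.extend(f"{pop}_{k + 1}" for k in range(config.n_ind_per_pop))

    miss = miss_rng.random(geno.shape) < config.missing_rate
    geno[miss] = MISSING
    depth = depth_rng.poisson(config.mean_depth, size=geno.shape).astype(float)

    loci = pd.DataFrame(
        {
            "contig": [f"scaffold_{l // 500 + 1}" for l in range(L)],
            "pos": [1000 * (l % 500) + 101 for l in range(L)],
            "ref": ["A"] * L,
            "alt": ["G"] * L,
            "diallelic": [True] * L,
        },
        columns=LOCUS_COLUMNS,
    )
    truth = pd.DataFrame(
        {
            "locus": [f"{c}:{p}" for c, p in zip(loci["contig"], loci["pos"])],
            "cls": classes,
            "clim_var": clim_var,
            "p0": p0,
        }
    )
    return GenotypeMatrix(geno, ids, pops, loci, depth=depth, truth=truth)


def make_future_climate(
    current: ClimateGrid,
    deltas: dict[str, float],
    n_models: int = 3,
    seed: int = 0,
    anomaly_amp: float = 1.0,
) -> ClimateGrid:
    """Ensemble-mean future climate: per-member shift plus smooth anomaly.

    Each of ``n_models`` members adds the per-variable additive ``deltas``
    and a smooth random anomaly (amplitude ``anomaly_amp`` in units of the
    variable's smooth-noise scale); members are averaged cell-wise into one
    ``future-mean`` grid, with the members retained for audit.
    """
    for var, d in deltas.items():
        if var not in current.data:
            raise ValueError(f"delta for unknown variable {var!r}")
        if not np.isfinite(d):
            raise ValueError(f"non-finite delta for {var!r}")
    rng = substream(seed, "future")
    ny, nx = current.shape
    members = []
    for _m in range(n_models):
        data = {}
        for var in current.variables:
            base_amp = _SURFACE_PARAMS.get(var, (0.0, 1.0, (0, 0)))[1]
            anomaly = anomaly_amp * 0.25 * base_amp * _smooth_field(rng, nx, ny)
            data[var] = current.data[var] + deltas.get(var, 0.0) + anomaly
        members.append(
            ClimateGrid(data, current.x0, current.y0, current.cell, epoch="member")
        )
    # average as base + mean deviation so identical members average exactly
    mean_data = {
        var: members[0].data[var]
        + np.mean([m.data[var] - members[0].data[var] for m in members], axis=0)
        for var in current.variables
    }
    return ClimateGrid(
        mean_data, current.x0, current.y0, current.cell,
        epoch="future-mean", members=members,
    )


def write_fixture_set(
    outdir: str | Path,
    config: LandscapeConfig,
    future_deltas: dict[str, float] | None = None,
) -> dict:
    """Simulate everything and write a self-contained fixture directory.

    Writes ``genotypes.vcf``, ``sites.tsv``, ``truth.tsv``, ESRI ASCII
    rasters for current and future-mean climate, and ``manifest.json``
    recording the config and seed. Returns the manifest dict.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {outdir}: {exc}") from exc

    grid, sites = simulate_landscape(config)
    matrix = simulate_genotypes(sites, config)
    if future_deltas is None:
        future_deltas = {"bio4": 15.0, "bio6": 2.0, "bio15": 6.0, "bio16": -40.0}
    future = make_future_climate(grid, future_deltas, seed=config.seed)

    write_vcf(matrix, outdir / "genotypes.vcf")
    sites.to_csv(outdir / "sites.tsv", sep="\t", index=False, float_format="%.8g")
    assert matrix.truth is not None
    matrix.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.8g")
    raster_files = [
        p.name
        for p in write_climate_grid(grid, outdir, "current")
        + write_climate_grid(future, outdir, "future")
    ]
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "future_deltas": future_deltas,
        "files": ["genotypes.vcf", "sites.tsv", "truth.tsv", *raster_files],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
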