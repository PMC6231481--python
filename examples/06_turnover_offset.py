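"""Gradient-forest turnover functions and genetic offset under future climate.

Fits the forest to per-population allele frequencies on climate + MEM
predictors, reports predictor importance, transforms the landscape into
genetic importance values, and maps the genetic offset under a simulated
future climate.
"""
import numpy as np
import pandas as pd

from landgen import (
    CLIMATE_VARS,
    GfSettings,
    LandscapeConfig,
    fit_turnover,
    genetic_offset,
    make_future_climate,
    map_pca_rgb,
    pop_allele_freqs,
    prepare_responses,
    sample_range_points,
    simulate_genotypes,
    simulate_landscape,
    transform_points,
)
from landgen.mem import mem_predictors
from landgen.turnover import points_predictor_table

cfg = LandscapeConfig(n_neutral=100, n_highfst=0, n_clim=60, clim_effect=1.5, seed=9)
grid, sites = simulate_landscape(cfg)
matrix = simulate_genotypes(sites, cfg)

responses = prepare_responses(pop_allele_freqs(matrix))
mems = mem_predictors(sites)
mems.attrs["coords"] = sites.set_index("pop").loc[mems.index, ["lon", "lat"]]
predictors = pd.concat([sites.set_index("pop")[list(CLIMATE_VARS)], mems], axis=1)

model = fit_turnover(responses, predictors, GfSettings(n_trees=500, seed=1))
print("predictor importance (total turnover-function rise):")
print(model.importance_frame().round(4).to_string(index=False))
print(f"{len(model.positive_r2_snps)} of {responses.shape[1]} SNPs have "
      f"positive out-of-bag R^2 and contribute")

future = make_future_climate(grid, {"bio4": 15.0, "bio6": 2.0, "bio15": 6.0,
                                    "bio16": -40.0}, n_models=3, seed=cfg.seed)
points = sample_range_points(sites, n_points=2000, seed=0, grid=grid)
space = transform_points(model, points_predictor_table(grid, points, mems))
scores, rgb = map_pca_rgb(space)
off = genetic_offset(model, grid, future, points, mem_values=mems)
print(f"\ngenetic offset over {len(off)} range points: "
      f"mean {off['offset'].mean():.4f}, max {off['offset'].max():.4f}")
# Offset is the Euclidean distance between a location's current and future
# genetic importance values: large values mark places where present
# gene-climate associations are most disrupted by the projected change.
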