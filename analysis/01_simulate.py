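"""Generate the synthetic study system.

Writes a complete input set to scratch/study/ — six autocorrelated
environmental layers (one designed collinear pair), biased occurrence
records for three species in two modelling units plus a target-group
pool, a clustered population raster, expert-style range polygons, and
per-GCM future climates for two time steps — together with the pipeline
config and a manifest of seeds and true niche parameters.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import sys
from pathlib import Path

from snakemaps.scenario import ScenarioSpec, simulate_scenario

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
STUDY_DIR = Path("scratch/study")


def main() -> None:
    scen = ScenarioSpec()  # the default desk-scale study: 120x120, 7 GCMs
    config = simulate_scenario(STUDY_DIR, seed=SEED, scen=scen)
    print(f"study system written to {STUDY_DIR} (seed {SEED})")
    print(f"  grid: {scen.n_rows}x{scen.n_cols} cells at {scen.cell_size} degrees")
    print(f"  layers: {scen.n_layers} (collinear pairs: {list(scen.corr_pairs)})")
    print(f"  MUs: {config.mus}")
    print(f"  future steps: {sorted(config.futures)} x {scen.n_gcms} GCMs")
    print(f"  config: {STUDY_DIR / 'config.yaml'}")


if __name__ == "__main__":
    main()
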