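"""Pipeline configuration: every threshold and default in one place.

All constants the analysis depends on are surfaced here rather than
hard-coded, and a config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # dive-signal thresholds
    feeding_rate_threshold: float = 0.06  # degC/s
    feeding_min_amplitude: float = 0.1  # degC
    feeding_max_duration: float = 300.0  # s
    step_speed_threshold: float = 0.35  # m/s
    dive_min_depth: float = 3.0  # m, all dives
    foraging_min_depth: float = 50.0  # m, foraging-dive filter
    bout_gap_threshold: float = 1800.0  # s
    bottom_fraction: float = 0.8
    # ocean
    pf_isotherm: float = 5.0  # degC
    pf_sector: tuple = (50.0, 54.0)  # deg E
    pf_months: tuple = (1, 2, 3)  # summer, configurable
    ssta_box_lat: tuple = (-53.0, -47.0)
    ssta_box_lon: tuple = (49.0, 55.0)
    ssta_months: tuple = (2, 3)
    saiod_domain_lat: tuple = (-50.0, -10.0)
    saiod_domain_lon: tuple = (-50.0, 150.0)
    saiod_months: tuple = (2, 3)
    km_per_deg_lat: float = 111.2
    colony: tuple = (-46.43, 51.86)
    # population model
    prior_r_mean: float = 0.10
    prior_r_sd: float = 0.02
    prior_bc_sd: float = 10.0
    prior_sd_max: float = 3.0
    mcmc_chains: int = 2
    mcmc_iters: int = 5000  # desk scale; production uses 50,000
    mcmc_burnin: int = 1000  # desk scale; production uses 10,000
    # prey model
    cv_split: tuple = (36, 38)
    # GAM
    gam_knots: int = 10
    # synthetic-data defaults
    seed: int = 0
    n_years_counts: int = 30
    n_colonies: int = 4
    missing_frac: float = 0.439
    n_bouts: int = 74
    sst_years: int = 33
    planted_var_frac: float = 0.27
    pf_slope_km_per_degC: float = 130.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in raw.items()}
        return cls(**kwargs)
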