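"""Fixture generators: default configuration and synthetic supporting data.

The life table and NHS cost schedule written here are synthetic, stylised
stand-ins (Gompertz-Makeham mortality approximating UK national life tables;
a quadratic age-cost curve) for data sets that are not redistributable.
"""

from __future__ import annotations

from pathlib import Path

from .cohort import CohortSpec, sample_cohort, write_cohort_csv
from .costs import NhsCostSchedule
from .parameters import default_parameters, save_parameters
from .survival import LifeTable

__all__ = ["make_fixtures"]


def make_fixtures(out_dir, seed: int = 0, demo_cohort_size: int = 1000) -> dict:
    """Write default parameter YAML, life table, cost schedule and demo cohort.

    Returns a mapping of fixture name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = default_parameters()
    paths = {
        "parameters": out / "default_params.yaml",
        "life_table": out / "life_table_synthetic.csv",
        "nhs_costs": out / "nhs_costs_synthetic.csv",
        "cohort": out / "demo_cohort.csv",
    }
    save_parameters(params, paths["parameters"])
    LifeTable.gompertz_makeham(params.econ.horizon_age_cap) \
        .to_frame().to_csv(paths["life_table"], index=False)
    NhsCostSchedule.stylised(params.econ.horizon_age_cap) \
        .to_frame().to_csv(paths["nhs_costs"], index=False)
    write_cohort_csv(sample_cohort(demo_cohort_size, CohortSpec(), seed),
                     paths["cohort"])
    return paths
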