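"""Shared plumbing for the numbered analysis drivers.

Each driver is standalone: it loads the synthetic dataset written by
``01_simulate_dataset.py`` when present, and otherwise regenerates it
in memory from the same seed, so the scripts can run in any order.
"""
from __future__ import annotations

import argparse
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "synthetic"
TABLE_DIR = ROOT / "results" / "tables"


def make_parser(description: str) -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1,
                        help="simulation seed (default 1)")
    return parser


def study_config(seed: int):
    """The study conditions shared by every driver."""
    from paeval.simulate import SimConfig

    return SimConfig(seed=seed)  # defaults are the study conditions


def load_or_simulate(seed: int):
    """(records, series): from results/synthetic if written, else fresh."""
    from paeval import io as pio
    from paeval.simulate import simulate_landscape, simulate_register

    cfg = study_config(seed)
    reg_path = DATA_DIR / "register.geojson"
    grid_paths = sorted(DATA_DIR.glob("converted_*.asc"))
    if reg_path.exists() and len(grid_paths) == len(cfg.years):
        records = pio.read_register(reg_path, field_map={"site_id": "site_id"})
        years = [int(p.stem.split("_")[1]) for p in grid_paths]
        series = pio.load_series(grid_paths, years)
        return records, series
    records, _ = simulate_register(cfg)
    series, _ = simulate_landscape(cfg, records)
    return records, series
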