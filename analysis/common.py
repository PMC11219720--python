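"""Shared setup for the numbered analysis drivers.

The drivers operate on one simulated 15-pig experiment (three treatment
groups of five) generated deterministically from a single seed.  Raw
per-measurement tables are cached under ``scratch/`` (they are bulky);
summary tables land in ``results/``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from shockbia.io import (
    RunConfig,
    read_impedance_table,
    read_vitals_table,
    write_impedance_table,
    write_vitals_table,
)
from shockbia.simulator import SubjectParams, generate_dataset

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

SEED = 20240702
GROUPS = ("crystalloid", "crystalloid_dextrose", "crystalloid_albumin")


def default_config(**overrides) -> RunConfig:
    cfg = RunConfig(seed=SEED, out_dir=str(RESULTS))
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def load_cohort(seed: int = SEED) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load the cached simulated cohort, generating it if absent."""
    imp_path = SCRATCH / "impedance.csv"
    vit_path = SCRATCH / "vitals.csv"
    if imp_path.exists() and vit_path.exists():
        return read_impedance_table(imp_path), read_vitals_table(vit_path)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    imps, vits = [], []
    for gi, group in enumerate(GROUPS):
        imp, vit, truth = generate_dataset(
            5, group, params_template=SubjectParams(), seed=seed + 1000 * gi
        )
        imps.append(imp)
        vits.append(vit)
        truth.to_csv(SCRATCH / f"truth_{group}.csv", index=False)
    impedance = pd.concat(imps, ignore_index=True)
    vitals = pd.concat(vits, ignore_index=True)
    write_impedance_table(impedance, imp_path)
    write_vitals_table(vitals, vit_path)
    return impedance, vitals


def group_tables(impedance: pd.DataFrame, vitals: pd.DataFrame, group: str):
    mask_i = impedance["subject_id"].str.fullmatch(rf"{group}_\d+")
    mask_v = vitals["subject_id"].str.fullmatch(rf"{group}_\d+")
    return impedance[mask_i], vitals[mask_v]
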