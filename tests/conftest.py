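"""Shared fixtures: tiny hand-checkable designs and seeded synthetic panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hybridgca.datatypes import GenotypeMatrix
from hybridgca.simulate import SimConfig, simulate_crosses, simulate_parents


def make_genotypes(
    columns: list[str],
    positions: list[int] | None = None,
    chrom: str = "1",
    parents: list[str] | None = None,
    groups: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-site call strings.

    ``columns[j]`` is a string over {'0', '1', '.'} giving every parent's
    call at site j; all sites share ``chrom`` with REF=A, ALT=G.
    """
    n_par = len(columns[0])
    if parents is None:
        parents = [f"p{i + 1}" for i in range(n_par)]
    if positions is None:
        positions = [1000 * (j + 1) for j in range(len(columns))]
    conv = {"0": 0, "1": 1, ".": -1}
    calls = np.array(
        [[conv[ch] for ch in col] for col in columns], dtype=np.int8
    ).T  # -> parents x sites
    return GenotypeMatrix(
        parents=parents,
        chrom=np.array([chrom] * len(columns), dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * len(columns), dtype=object),
        alt=np.array(["G"] * len(columns), dtype=object),
        calls=calls,
        groups=groups,
    )


def cross_table_from_means(
    means: dict[tuple[str, str], float], n_reps: int = 1, group: str = "g1"
) -> pd.DataFrame:
    """Phenotype DataFrame with identical records per replication (trait Y)."""
    rows = []
    for (f, m), v in means.items():
        for rep in range(1, n_reps + 1):
            rows.append(
                {
                    "cross_id": f"{f}x{m}",
                    "female": f,
                    "male": m,
                    "group": group,
                    "rep": rep,
                    "Y": v,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def two_by_two_crosses() -> pd.DataFrame:
    """2x2 factorial with cross means 10/14/6/10: hand-checkable GCA."""
    return cross_table_from_means(
        {("f1", "m1"): 10.0, ("f1", "m2"): 14.0, ("f2", "m1"): 6.0, ("f2", "m2"): 10.0}
    )


@pytest.fixture(scope="session")
def default_panel():
    """A seeded synthetic NCII panel with default study-like conditions."""
    cfg = SimConfig(seed=1)
    gm, truth = simulate_parents(cfg)
    crosses = simulate_crosses(gm, truth, cfg)
    return cfg, gm, truth, crosses


@pytest.fixture(scope="session")
def clean_two_hap_panel():
    """24 parents, two haplotypes per block, no missing data: every planted
    block is exactly recoverable."""
    cfg = SimConfig(
        seed=11,
        n_female=13,
        n_male=11,
        haplotypes_per_block=2,
        missing_rate=0.0,
        n_blocks_per_chrom=4,
        n_chromosomes=2,
    )
    gm, truth = simulate_parents(cfg)
    return cfg, gm, truth
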