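"""Shared builders for the test suite.

Fixtures construct small summary tables, harmonised sets and LD matrices in
memory; nothing is read from disk except in explicit IO round-trip tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from metabomr.gwas_io import GwasSummaryTable, SnpAssociation, TraitInfo
from metabomr.harmonise import HarmonisedRecord, HarmonisedSet, LdMatrix


def make_record(
    snp_id: str = "rs1",
    ea: str = "A",
    oa: str = "G",
    eaf: float | None = 0.3,
    beta: float = 0.05,
    se: float = 0.01,
    pvalue: float = 1e-9,
    n: float | None = 10000.0,
) -> SnpAssociation:
    return SnpAssociation(snp_id, ea, oa, eaf, beta, se, pvalue, n)


def make_table(trait_id: str, records) -> GwasSummaryTable:
    return GwasSummaryTable(trait_id=trait_id, records=list(records))


def make_hset(bx, by, sx=None, sy=None, exposure_id="X", outcome_id="Y") -> HarmonisedSet:
    """HarmonisedSet from effect arrays (SEs default to 0.05)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sx = np.full_like(bx, 0.05) if sx is None else np.asarray(sx, dtype=float)
    sy = np.full_like(by, 0.05) if sy is None else np.asarray(sy, dtype=float)
    records = [
        HarmonisedRecord(
            snp_id=f"rs{i + 1}",
            beta_x=float(bx[i]),
            se_x=float(sx[i]),
            beta_y=float(by[i]),
            se_y=float(sy[i]),
            eaf=0.3,
        )
        for i in range(bx.size)
    ]
    return HarmonisedSet(exposure_id=exposure_id, outcome_id=outcome_id, records=records)


def random_hset(rng: np.random.Generator, k: int = 10, theta: float = 0.3) -> HarmonisedSet:
    """Random strong-instrument set with true causal slope ``theta``."""
    bx = rng.uniform(0.03, 0.1, k) * rng.choice([-1, 1], k)
    sx = rng.uniform(0.002, 0.01, k)
    sy = rng.uniform(0.002, 0.01, k)
    by = theta * bx + rng.normal(0, sy)
    return make_hset(bx, by, sx, sy)


def make_trait(
    trait_id: str,
    trait_class: str = "other",
    is_ratio: bool = False,
    is_composite: bool = False,
    lipoprotein_role: str = "none",
) -> TraitInfo:
    return TraitInfo(
        trait_id=trait_id,
        display_name=trait_id,
        trait_class=trait_class,
        is_ratio=is_ratio,
        is_composite=is_composite,
        lipoprotein_role=lipoprotein_role,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


@pytest.fixture
def ld_identity():
    def _make(snp_ids):
        return LdMatrix.identity(list(snp_ids))

    return _make
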