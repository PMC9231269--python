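"""Panel reduction: the three-stage exclusion procedure for NMR trait panels.

Metabolomics panels carry heavy redundancy (derived ratios, composite
measures, near-identical lipid measures within each lipoprotein subclass,
near-perfect genetic correlations).  Jointly modelling such traits in
multivariable MR causes multicollinearity, so the panel is reduced before
any MR is run:

1. drop derived ratios and composite measures (metadata flags);
2. among lipoprotein traits, keep only the total-lipids measure of each
   subclass (plus non-lipoprotein traits and lipid-composition /
   apolipoprotein measures), dropping within-subclass components;
3. estimate pairwise genetic correlation over the instrument union and,
   for every pair with rg^2 above the limit (default 0.985), remove one
   member, chosen by a deterministic priority order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gwas_io import GwasSummaryTable, TraitInfo, ValidationError

__all__ = [
    "TraitCorrelationMatrix",
    "FilterReport",
    "filter_ratios_composites",
    "select_lipoprotein_subset",
    "genetic_correlation_matrix",
    "prune_genetic_correlation",
    "RG2_PRUNE",
]

RG2_PRUNE = 0.985


@dataclass
class TraitCorrelationMatrix:
    """Symmetric genetic-correlation matrix over a trait panel."""

    trait_ids: list[str]
    rg: np.ndarray

    def __post_init__(self) -> None:
        self.rg = np.asarray(self.rg, dtype=float)
        n = len(self.trait_ids)
        if self.rg.shape != (n, n):
            raise ValidationError(f"rg matrix shape {self.rg.shape} != ({n}, {n})")
        if not np.allclose(self.rg, self.rg.T, atol=1e-8):
            raise ValidationError("rg matrix not symmetric")
        if np.any(np.abs(self.rg) > 1 + 1e-8):
            raise ValidationError("|rg| exceeds 1")

    @classmethod
    def read_tsv(cls, path) -> "TraitCorrelationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(trait_ids=[str(t) for t in df.index], rg=df.to_numpy(dtype=float))

    def write_tsv(self, path):
        pd.DataFrame(self.rg, index=self.trait_ids, columns=self.trait_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass
class FilterReport:
    """Outcome of one exclusion stage: kept + excluded = input traits."""

    kept: list[str]
    excluded: list[tuple[str, str, str]]  # (trait_id, stage, reason)

    @property
    def excluded_ids(self) -> list[str]:
        return [t for t, _, _ in self.excluded]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"trait_id": t, "status": "kept", "stage": "", "reason": ""} for t in self.kept]
        rows += [
            {"trait_id": t, "status": "excluded", "stage": stage, "reason": reason}
            for t, stage, reason in self.excluded
        ]
        return pd.DataFrame(rows, columns=["trait_id", "status", "stage", "reason"])


def merge_reports(first: FilterReport, second: FilterReport) -> FilterReport:
    """Compose two stages: ``second`` must operate on ``first.kept``."""
    return FilterReport(kept=list(second.kept), excluded=first.excluded + second.excluded)


def filter_ratios_composites(traits: Sequence[TraitInfo]) -> FilterReport:
    """Exclude every trait flagged as a derived ratio or composite measure."""
    kept, excluded = [], []
    for t in traits:
        if t.is_ratio:
            excluded.append((t.trait_id, "ratio_composite", "derived ratio"))
        elif t.is_composite:
            excluded.append((t.trait_id, "ratio_composite", "composite measure"))
        else:
            kept.append(t.trait_id)
    return FilterReport(kept=kept, excluded=excluded)


def select_lipoprotein_subset(traits: Sequence[TraitInfo]) -> FilterReport:
    """Among lipoprotein traits keep only total-lipids-per-subclass measures.

    Non-lipoprotein traits and the retained composition/apolipoprotein
    measures pass through unchanged; within-subclass component measures
    (cholesterol, triglycerides, particle concentration, ... inside one
    subclass) are excluded — they are not genetically separable from the
    subclass total.
    """
    kept, excluded = [], []
    for t in traits:
        if t.lipoprotein_role == "within-subclass-component":
            excluded.append(
                (t.trait_id, "lipoprotein_subset", "within-subclass component measure")
            )
        else:
            kept.append(t.trait_id)
    return FilterReport(kept=kept, excluded=excluded)


def genetic_correlation_matrix(
    tables: Sequence[GwasSummaryTable],
    instrument_union: Iterable[str],
) -> TraitCorrelationMatrix:
    """Weighted Pearson correlation of per-SNP effect estimates.

    For traits k, l the correlation of (beta_jk, beta_jl) over the instrument
    union is computed with weights 1/(se_jk * se_jl), pairwise-complete, and
    clipped to [-1, 1].  This is a pragmatic summary-statistic estimator of
    genetic correlation over the instrumented signal; a full matrix may be
    supplied from file instead (see :meth:`TraitCorrelationMatrix.read_tsv`).
    """
    union = sorted(set(instrument_union))
    if len(tables) < 2:
        raise ValidationError("need at least 2 traits for genetic correlation")
    if not union:
        raise ValidationError("instrument union is empty")
    per_trait: list[dict[str, tuple[float, float]]] = []
    for tab in tables:
        d = {r.snp_id: (r.beta, r.se) for r in tab.records if r.snp_id in set(union)}
        if len(d) < 0.5 * len(union):
            raise ValidationError(
                f"trait '{tab.trait_id}' is missing more than 50% of the instrument union "
                f"({len(d)}/{len(union)} present)"
            )
        per_trait.append(d)
    n = len(tables)
    rg = np.eye(n)
    for k in range(n):
        for l in range(k + 1, n):
            common = [s for s in union if s in per_trait[k] and s in per_trait[l]]
            bk = np.array([per_trait[k][s][0] for s in common])
            bl = np.array([per_trait[l][s][0] for s in common])
            w = np.array(
                [1.0 / (per_trait[k][s][1] * per_trait[l][s][1]) for s in common]
            )
            w = w / w.sum()
            mk, ml = w @ bk, w @ bl
            cov = w @ ((bk - mk) * (bl - ml))
            vk = w @ (bk - mk) ** 2
            vl = w @ (bl - ml) ** 2
            if vk <= 0 or vl <= 0:
                r = 0.0
            else:
                r = float(np.clip(cov / np.sqrt(vk * vl), -1.0, 1.0))
            rg[k, l] = rg[l, k] = r
    return TraitCorrelationMatrix(trait_ids=[t.trait_id for t in tables], rg=rg)


def prune_genetic_correlation(
    matrix: TraitCorrelationMatrix,
    r2_limit: float = RG2_PRUNE,
    priority: Sequence[str] | None = None,
) -> FilterReport:
    """Remove one member of every pair with rg^2 above ``r2_limit``.

    Pairs are visited in decreasing rg^2 order (ties broken by trait index);
    within a pair the trait later in ``priority`` (default: the matrix's
    input order) is removed; pairs whose members were already removed are
    skipped.
    """
    ids = matrix.trait_ids
    order = list(priority) if priority is not None else list(ids)
    rank = {t: order.index(t) for t in ids}
    n = len(ids)
    pairs = [
        (matrix.rg[i, j] ** 2, i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if matrix.rg[i, j] ** 2 > r2_limit
    ]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    removed: dict[str, str] = {}
    for rg2, i, j in pairs:
        a, b = ids[i], ids[j]
        if a in removed or b in removed:
            continue
        drop = b if rank[b] >= rank[a] else a
        keep = a if drop == b else b
        removed[drop] = f"rg2={rg2:.4f} with {keep}"
    kept = [t for t in ids if t not in removed]
    excluded = [(t, "genetic_correlation", reason) for t, reason in removed.items()]
    return FilterReport(kept=kept, excluded=excluded)
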