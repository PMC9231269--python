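"""Allele harmonisation, LD clumping and instrument selection.

Two-sample MR needs the SNP-exposure and SNP-outcome effects expressed per
copy of the *same* effect allele.  Outcome records are aligned to the
exposure's effect allele: swapped alleles negate the outcome beta, strand
complements are resolved, and palindromic SNPs (A/T or C/G, where strand is
ambiguous) are resolved from allele frequency when informative and removed
when the minor-allele frequency exceeds the ambiguity limit (default 42%).

Instrument selection is greedy LD clumping on a supplied pairwise-r matrix:
restrict to genome-wide significant SNPs (default p < 5e-8) and accept SNPs
in ascending p-order, discarding anything with r^2 >= 0.01 against an
accepted SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas_io import GwasSummaryTable, SnpAssociation, ValidationError

__all__ = [
    "HarmonisationError",
    "HarmonisedRecord",
    "HarmonisedSet",
    "LdMatrix",
    "is_palindromic",
    "harmonise_pair",
    "clump",
    "select_instruments",
]

logger = logging.getLogger("metabomr.harmonise")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# default thresholds
P_INSTRUMENT = 5e-8
R2_CLUMP = 0.01
MAF_PALINDROME_LIMIT = 0.42


class HarmonisationError(ValueError):
    pass


def _complement(allele: str) -> str | None:
    """Strand complement for single-base alleles; None for indels."""
    return _COMPLEMENT.get(allele)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or C/G SNPs, whose strand cannot be told from allele labels."""
    return _COMPLEMENT.get(effect_allele) == other_allele


@dataclass(frozen=True)
class HarmonisedRecord:
    """Exposure and outcome effects for one SNP, on a common effect allele."""

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float | None
    palindromic: bool = False
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (self.se_x > 0 and self.se_y > 0):
            raise ValidationError(f"{self.snp_id}: SEs must be positive")


@dataclass
class HarmonisedSet:
    """All harmonised instruments for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    records: list[HarmonisedRecord]
    removed: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_x, se_x, beta_y, se_y) as float arrays in record order."""
        bx = np.array([r.beta_x for r in self.records], dtype=float)
        sx = np.array([r.se_x for r in self.records], dtype=float)
        by = np.array([r.beta_y for r in self.records], dtype=float)
        sy = np.array([r.se_y for r in self.records], dtype=float)
        return bx, sx, by, sy


@dataclass
class LdMatrix:
    """Pairwise allelic correlations (signed r) over a SNP panel."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.snp_ids)
        if self.r.shape != (n, n):
            raise ValidationError(f"LD matrix shape {self.r.shape} != ({n}, {n})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValidationError("LD |r| exceeds 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(snp_ids=[str(s) for s in df.index], r=df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids)
        df.to_csv(path, sep="\t", float_format="%.10g")
        return path

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LdMatrix":
        return cls(snp_ids=list(snp_ids), r=np.eye(len(snp_ids)))


def _align_outcome(
    x: SnpAssociation, y: SnpAssociation
) -> tuple[float, float | None, bool] | None:
    """Align outcome record ``y`` to exposure ``x``'s effect allele.

    Returns (beta_y, eaf_y, label_flipped) with beta_y signed for x's effect
    allele, or None when the allele pairs are irreconcilable.  Handles direct
    match, swapped alleles, and strand complement; the frequency-based strand
    inference for palindromic SNPs is applied by the caller.
    """
    ea_x, oa_x, ea_y, oa_y = x.effect_allele, x.other_allele, y.effect_allele, y.other_allele
    if (ea_y, oa_y) == (ea_x, oa_x):
        return y.beta, y.eaf, False
    if (ea_y, oa_y) == (oa_x, ea_x):
        return -y.beta, None if y.eaf is None else 1.0 - y.eaf, True
    cea, coa = _complement(ea_y), _complement(oa_y)
    if cea is not None and coa is not None:
        if (cea, coa) == (ea_x, oa_x):
            return y.beta, y.eaf, False
        if (cea, coa) == (oa_x, ea_x):
            return -y.beta, None if y.eaf is None else 1.0 - y.eaf, True
    return None


def harmonise_pair(
    exposure: GwasSummaryTable,
    outcome: GwasSummaryTable,
    maf_palindrome_limit: float = MAF_PALINDROME_LIMIT,
) -> HarmonisedSet:
    """Harmonise the shared SNPs of an exposure/outcome table pair.

    Only the outcome side is ever modified; exposure betas keep their sign.
    Palindromic SNPs with min(eaf, 1-eaf) > ``maf_palindrome_limit`` on either
    side are removed as ambiguous; below the limit the strand is inferred by
    requiring the exposure and outcome EAFs to sit on the same side of 0.5.
    """
    shared = [s for s in exposure.snp_ids if s in outcome]
    if not shared:
        raise HarmonisationError(
            f"no shared SNPs between '{exposure.trait_id}' and '{outcome.trait_id}'"
        )
    records: list[HarmonisedRecord] = []
    removed: list[tuple[str, str]] = []
    for snp in shared:
        x = exposure.get(snp)
        y = outcome.get(snp)
        aligned = _align_outcome(x, y)
        if aligned is None:
            removed.append((snp, "incompatible_alleles"))
            continue
        beta_y, eaf_y, flipped = aligned
        palindromic = is_palindromic(x.effect_allele, x.other_allele)
        if palindromic:
            if x.eaf is None or eaf_y is None:
                removed.append((snp, "missing_eaf"))
                continue
            maf_x = min(x.eaf, 1.0 - x.eaf)
            maf_y = min(eaf_y, 1.0 - eaf_y)
            if maf_x > maf_palindrome_limit or maf_y > maf_palindrome_limit:
                removed.append((snp, "ambiguous_palindrome"))
                continue
            # frequency concordance resolves the strand: opposite sides of
            # 0.5 means the outcome reports the complementary strand
            if (x.eaf - 0.5) * (eaf_y - 0.5) < 0:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
                flipped = True
        records.append(
            HarmonisedRecord(
                snp_id=snp,
                beta_x=x.beta,
                se_x=x.se,
                beta_y=beta_y,
                se_y=y.se,
                eaf=x.eaf,
                palindromic=palindromic,
                flipped=flipped,
            )
        )
    return HarmonisedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        records=records,
        removed=removed,
    )


def clump(
    table: GwasSummaryTable,
    ld: LdMatrix,
    p_threshold: float = P_INSTRUMENT,
    r2_threshold: float = R2_CLUMP,
) -> GwasSummaryTable:
    """Greedy LD clumping: keep the most significant SNPs pairwise below
    ``r2_threshold``.

    SNPs at or above ``p_threshold`` are dropped first; remaining SNPs are
    taken in ascending p-value order (ties broken by snp_id) and accepted
    unless in LD (r^2 >= ``r2_threshold``) with an already-accepted SNP.
    SNPs absent from the LD matrix are dropped with a logged warning.
    """
    sig = [r for r in table.records if r.pvalue < p_threshold]
    missing_ld = [r.snp_id for r in sig if r.snp_id not in ld]
    if missing_ld:
        logger.warning(
            "%s: %d significant SNP(s) absent from LD matrix, dropped: %s",
            table.trait_id,
            len(missing_ld),
            missing_ld[:10],
        )
        sig = [r for r in sig if r.snp_id in ld]
    sig.sort(key=lambda r: (r.pvalue, r.snp_id))
    accepted: list[SnpAssociation] = []
    for cand in sig:
        if all(ld.r2(cand.snp_id, a.snp_id) < r2_threshold for a in accepted):
            accepted.append(cand)
    kept_ids = {r.snp_id for r in accepted}
    # preserve the input table's SNP order in the output
    return GwasSummaryTable(
        trait_id=table.trait_id,
        records=[r for r in table.records if r.snp_id in kept_ids],
        trait_units=table.trait_units,
    )


def select_instruments(
    exposure: GwasSummaryTable,
    outcome: GwasSummaryTable,
    ld: LdMatrix,
    p_threshold: float = P_INSTRUMENT,
    r2_threshold: float = R2_CLUMP,
    maf_palindrome_limit: float = MAF_PALINDROME_LIMIT,
) -> HarmonisedSet:
    """Clump the exposure table, then harmonise the survivors to the outcome.

    Zero surviving instruments yields a typed empty :class:`HarmonisedSet`
    (downstream dispatch reports it), never an exception.
    """
    clumped = clump(exposure, ld, p_threshold=p_threshold, r2_threshold=r2_threshold)
    if len(clumped) == 0 or not any(s in outcome for s in clumped.snp_ids):
        return HarmonisedSet(
            exposure_id=exposure.trait_id,
            outcome_id=outcome.trait_id,
            records=[],
            removed=[(s, "absent_from_outcome") for s in clumped.snp_ids],
        )
    return harmonise_pair(clumped, outcome, maf_palindrome_limit=maf_palindrome_limit)
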