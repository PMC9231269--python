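"""Reading, validating and writing GWAS summary statistics and trait metadata.

Summary-association tables are the sole data currency of two-sample Mendelian
randomisation: one row per SNP carrying the effect allele, the other allele,
the effect-allele frequency (EAF), the per-allele effect estimate beta (in SD
units of the trait), its standard error, the association p-value and the
sample size.  This module defines the record types every downstream module
consumes and the tab-separated file dialect used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "ValidationError",
    "SnpAssociation",
    "GwasSummaryTable",
    "TraitInfo",
    "TRAIT_CLASSES",
    "LIPOPROTEIN_ROLES",
    "DEFAULT_COLUMN_MAP",
    "read_summary_table",
    "write_summary_table",
    "read_trait_metadata",
    "write_trait_metadata",
]


class ConfigError(ValueError):
    """A file/column mapping problem (wrong header, missing column)."""


class ValidationError(ValueError):
    """Data violating a record invariant (bad SE, duplicate SNP id, ...)."""


#: recognised trait presentation classes for NMR metabolomics panels
TRAIT_CLASSES = frozenset(
    {
        "amino acids",
        "apolipoproteins",
        "cholesterol",
        "cholesterol esters",
        "fatty acids",
        "fluid balance",
        "glycolysis",
        "inflammation",
        "ketone bodies",
        "lipoprotein subclasses",
        "other lipids",
        "phospholipids",
        "triglycerides",
        "other",
    }
)

#: role of a trait within the lipoprotein-subclass hierarchy
LIPOPROTEIN_ROLES = frozenset(
    {"total-lipids-in-subclass", "within-subclass-component", "composition-measure", "none"}
)

#: generic GWAS TSV dialect: file column -> canonical field
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "snp": "snp_id",
    "ea": "effect_allele",
    "oa": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p": "pvalue",
    "n": "n",
}

_FIELDS = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n"]


@dataclass(frozen=True)
class SnpAssociation:
    """A single SNP-trait association from a GWAS summary table.

    ``beta`` is the additive per-allele effect of ``effect_allele`` in SD
    units of the trait, ``se`` its standard error.  ``eaf`` may be missing
    (``None``); harmonisation then refuses to resolve palindromic SNPs.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not self.snp_id:
            problems.append("empty snp_id")
        if not (self.se > 0):
            problems.append(f"se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append(f"eaf outside [0, 1]: {self.eaf}")
        if self.effect_allele == self.other_allele:
            problems.append(f"effect and other allele identical: {self.effect_allele}")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append(f"pvalue outside (0, 1]: {self.pvalue}")
        if not math.isfinite(self.beta):
            problems.append(f"non-finite beta: {self.beta}")
        return problems


@dataclass
class GwasSummaryTable:
    """Ordered collection of :class:`SnpAssociation` for one trait."""

    trait_id: str
    records: list[SnpAssociation]
    trait_units: str = "SD"
    #: (input row number, snp_id, reason) for rows dropped in permissive mode
    rejected_rows: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {r.snp_id: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            dups = sorted({r.snp_id for r in self.records if r.snp_id in seen or seen.add(r.snp_id)})
            raise ValidationError(f"duplicate snp_id in table '{self.trait_id}': {dups}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> SnpAssociation:
        return self.records[self._index[snp_id]]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, snp_ids: Iterable[str]) -> "GwasSummaryTable":
        """Table restricted to ``snp_ids``, keeping this table's order."""
        wanted = set(snp_ids)
        return GwasSummaryTable(
            trait_id=self.trait_id,
            records=[r for r in self.records if r.snp_id in wanted],
            trait_units=self.trait_units,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": np.nan if r.n is None else r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=_FIELDS)


@dataclass(frozen=True)
class TraitInfo:
    """Panel metadata for one metabolic trait."""

    trait_id: str
    display_name: str
    trait_class: str
    is_ratio: bool = False
    is_composite: bool = False
    lipoprotein_role: str = "none"

    def __post_init__(self) -> None:
        if self.trait_class not in TRAIT_CLASSES:
            raise ValidationError(
                f"unknown trait_class '{self.trait_class}' for trait '{self.trait_id}'"
            )
        if self.lipoprotein_role not in LIPOPROTEIN_ROLES:
            raise ValidationError(
                f"unknown lipoprotein_role '{self.lipoprotein_role}' for trait '{self.trait_id}'"
            )


def _to_float(value, *, allow_missing: bool) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if allow_missing:
            return None
        raise ValueError("missing value")
    if isinstance(value, str):
        if value.strip().upper() in {"", "NA", "NAN", "."}:
            if allow_missing:
                return None
            raise ValueError("missing value")
        return float(value)
    return float(value)


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait_id: str | None = None,
    permissive: bool = False,
) -> GwasSummaryTable:
    """Read a tab-separated GWAS summary table.

    ``column_map`` maps file columns to the canonical fields (default:
    :data:`DEFAULT_COLUMN_MAP`).  Rows violating :class:`SnpAssociation`
    invariants raise :class:`ValidationError` with a per-row report unless
    ``permissive`` is set, in which case they are dropped and recorded on
    ``rejected_rows`` (kept + rejected = input rows).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"summary table not found: {path}")
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    missing = [c for c in cmap if c not in df.columns and cmap[c] != "n"]
    if missing:
        raise ConfigError(f"{path}: missing mapped columns {missing}; found {list(df.columns)}")
    inv = {v: k for k, v in cmap.items()}

    records: list[SnpAssociation] = []
    rejected: list[tuple[int, str, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        snp = str(row_d.get(inv["snp_id"], "")).strip()
        try:
            rec = SnpAssociation(
                snp_id=snp,
                effect_allele=str(row_d[inv["effect_allele"]]).strip(),
                other_allele=str(row_d[inv["other_allele"]]).strip(),
                eaf=_to_float(row_d.get(inv["eaf"]), allow_missing=True),
                beta=_to_float(row_d[inv["beta"]], allow_missing=False),
                se=_to_float(row_d[inv["se"]], allow_missing=False),
                pvalue=_to_float(row_d[inv["pvalue"]], allow_missing=False),
                n=_to_float(row_d.get(inv.get("n", "n"), None), allow_missing=True),
            )
            problems = rec.validate()
        except (ValueError, KeyError) as exc:
            rec, problems = None, [f"unparseable row: {exc}"]
        if problems:
            rejected.append((i, snp, "; ".join(problems)))
        else:
            records.append(rec)

    if rejected and not permissive:
        lines = "\n".join(f"  row {i} (snp '{s}'): {why}" for i, s, why in rejected)
        raise ValidationError(f"{path}: {len(rejected)} invalid row(s):\n{lines}")

    table = GwasSummaryTable(
        trait_id=trait_id if trait_id is not None else path.stem,
        records=records,
    )
    table.rejected_rows = rejected
    return table


def write_summary_table(table: GwasSummaryTable, path: str | Path) -> Path:
    """Write ``table`` as a tab-separated file with the generic header.

    ``read_summary_table`` inverts this bit-exactly for string fields and to
    full precision for numerics (floats are serialised with ``repr``, whose
    shortest decimal round-trips IEEE doubles exactly).  Missing ``eaf``/``n``
    are written as the explicit ``NA`` token.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def fmt(x: float | None) -> str:
        return "NA" if x is None else repr(float(x))

    with open(path, "w") as fh:
        fh.write("snp\tea\toa\teaf\tbeta\tse\tp\tn\n")
        for r in table.records:
            fh.write(
                f"{r.snp_id}\t{r.effect_allele}\t{r.other_allele}\t{fmt(r.eaf)}\t"
                f"{fmt(r.beta)}\t{fmt(r.se)}\t{fmt(r.pvalue)}\t{fmt(r.n)}\n"
            )
    return path


_BOOL_TOKENS = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False, "": False}


def read_trait_metadata(path: str | Path) -> list[TraitInfo]:
    """Read the trait-metadata TSV (trait_id, display_name, trait_class,
    is_ratio, is_composite, lipoprotein_role)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"trait metadata not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    required = ["trait_id", "display_name", "trait_class", "is_ratio", "is_composite"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing metadata columns {missing}")
    traits = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        tid = d["trait_id"].strip()
        if tid in seen:
            raise ValidationError(f"{path}: duplicate trait_id '{tid}'")
        seen.add(tid)

        def to_bool(tok: str) -> bool:
            key = tok.strip().lower()
            if key not in _BOOL_TOKENS:
                raise ValidationError(f"{path}: bad boolean token '{tok}' for trait '{tid}'")
            return _BOOL_TOKENS[key]

        traits.append(
            TraitInfo(
                trait_id=tid,
                display_name=d["display_name"].strip(),
                trait_class=d["trait_class"].strip(),
                is_ratio=to_bool(d["is_ratio"]),
                is_composite=to_bool(d["is_composite"]),
                lipoprotein_role=(d.get("lipoprotein_role", "none") or "none").strip(),
            )
        )
    return traits


def write_trait_metadata(traits: Sequence[TraitInfo], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("trait_id\tdisplay_name\ttrait_class\tis_ratio\tis_composite\tlipoprotein_role\n")
        for t in traits:
            fh.write(
                f"{t.trait_id}\t{t.display_name}\t{t.trait_class}\t"
                f"{str(t.is_ratio).lower()}\t{str(t.is_composite).lower()}\t{t.lipoprotein_role}\n"
            )
    return path
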