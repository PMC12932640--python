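"""GWAS summary-statistic records, tables and tab-delimited I/O.

Conventions: positions are 1-based, cis windows are closed intervals,
only biallelic single-base SNPs are accepted; anything else is rejected
at read time with a per-row reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Default header of the tab-delimited summary-statistics format.
DEFAULT_COLUMNS = ("SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N")

#: Maps internal field names onto the default file header.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}


class SumStatFormatError(ValueError):
    """Raised when a summary-statistics file is structurally unreadable."""


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's marginal association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float

    def validate(self) -> None:
        """Raise ``ValueError`` when any field violates its domain."""
        if self.effect_allele not in VALID_BASES:
            raise ValueError(f"effect allele {self.effect_allele!r} is not a single base")
        if self.other_allele not in VALID_BASES:
            raise ValueError(f"other allele {self.other_allele!r} is not a single base")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele are identical")
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"eaf must be in (0,1), got {self.eaf}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue must be in (0,1], got {self.pvalue}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not np.isfinite(self.beta):
            raise ValueError(f"beta must be finite, got {self.beta}")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def z(self) -> float:
        return self.beta / self.se


class SumStatTable:
    """Ordered collection of :class:`SumStatRecord` for one trait.

    SNP ids are unique; insertion order is preserved.
    """

    def __init__(
        self,
        trait_id: str,
        records: Iterable[SumStatRecord] = (),
        trait_type: str = "quantitative",
    ) -> None:
        if trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        self.trait_id = trait_id
        self.trait_type = trait_type
        self._records: dict[str, SumStatRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SumStatRecord) -> None:
        if rec.snp_id in self._records:
            raise ValueError(f"duplicate snp_id {rec.snp_id!r} in table {self.trait_id!r}")
        self._records[rec.snp_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SumStatRecord]:
        return iter(self._records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._records

    def __getitem__(self, snp_id: str) -> SumStatRecord:
        return self._records[snp_id]

    def get(self, snp_id: str) -> SumStatRecord | None:
        return self._records.get(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return list(self._records)

    def subset(self, snp_ids: Iterable[str]) -> "SumStatTable":
        """New table restricted to ``snp_ids``, keeping this table's order."""
        wanted = set(snp_ids)
        return SumStatTable(
            self.trait_id,
            (r for r in self if r.snp_id in wanted),
            trait_type=self.trait_type,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {v: [] for v in DEFAULT_COLUMN_MAP.values()}
        for rec in self:
            for fname, col in DEFAULT_COLUMN_MAP.items():
                cols[col].append(getattr(rec, fname))
        return pd.DataFrame(cols, columns=list(DEFAULT_COLUMNS))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SumStatTable):
            return NotImplemented
        return (
            self.trait_id == other.trait_id
            and self.trait_type == other.trait_type
            and list(self._records.items()) == list(other._records.items())
        )


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-SNP gene annotation used for cis-window and coding filters."""

    snp_id: str
    gene: str
    tss_pos: int
    protein_altering: bool = False


@dataclass
class ReadReport:
    """Row-level outcome of a :func:`read_sumstats` call."""

    n_read: int = 0
    n_rejected: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)  # (line no, reason)


def _build_record(row: Mapping[str, object], column_map: Mapping[str, str]) -> SumStatRecord:
    def _get(fname: str) -> object:
        return row[column_map[fname]]

    rec = SumStatRecord(
        snp_id=str(_get("snp_id")),
        chrom=str(_get("chrom")),
        pos=int(_get("pos")),
        effect_allele=str(_get("effect_allele")).upper(),
        other_allele=str(_get("other_allele")).upper(),
        eaf=float(_get("eaf")),
        beta=float(_get("beta")),
        se=float(_get("se")),
        pvalue=float(_get("pvalue")),
        n=float(_get("n")),
    )
    rec.validate()
    return rec


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_id: str | None = None,
) -> tuple[SumStatTable, ReadReport]:
    """Read a tab-delimited summary-statistics file.

    Rows that violate record invariants (zero SE, out-of-range frequency,
    indels, ...) are rejected individually and reported; a missing column
    raises :class:`SumStatFormatError`.

    Returns the table and a :class:`ReadReport` with one entry per
    rejected row (1-based data line number, reason).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise SumStatFormatError(f"missing required column(s): {', '.join(missing)}")

    table = SumStatTable(trait_id or str(path), trait_type=trait_type)
    report = ReadReport()
    for i, row in enumerate(df.to_dict("records"), start=1):
        report.n_read += 1
        try:
            table.add(_build_record(row, cmap))
        except (ValueError, TypeError) as exc:
            report.n_rejected += 1
            report.rejections.append((i, str(exc)))
            logger.warning("rejected line %d of %s: %s", i, path, exc)
    return table, report


def write_sumstats(table: SumStatTable, path) -> None:
    """Write ``table`` in the default tab-delimited format.

    Numeric fields keep full ``repr`` precision so a read-back round-trip
    is exact to float resolution.
    """
    df = table.to_frame()
    # repr-precision floats; pandas default would truncate
    for col in ("EAF", "BETA", "SE", "P", "N"):
        df[col] = df[col].map(lambda v: format(float(v), ".17g"))
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict[str, VariantAnnotation]:
    """Read a variant annotation table (SNP, GENE, TSS, PROTEIN_ALTERING)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["SNP", "GENE", "TSS", "PROTEIN_ALTERING"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumStatFormatError(f"missing annotation column(s): {', '.join(missing)}")
    out: dict[str, VariantAnnotation] = {}
    for row in df.itertuples(index=False):
        out[str(row.SNP)] = VariantAnnotation(
            snp_id=str(row.SNP),
            gene=str(row.GENE),
            tss_pos=int(row.TSS),
            protein_altering=str(row.PROTEIN_ALTERING).strip().lower() in ("1", "true", "yes"),
        )
    return out


def write_annotations(annots: Iterable[VariantAnnotation], path) -> None:
    annots = list(annots)
    df = pd.DataFrame(
        {
            "SNP": [a.snp_id for a in annots],
            "GENE": [a.gene for a in annots],
            "TSS": [a.tss_pos for a in annots],
            "PROTEIN_ALTERING": [int(a.protein_altering) for a in annots],
        }
    )
    df.to_csv(path, sep="\t", index=False)
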