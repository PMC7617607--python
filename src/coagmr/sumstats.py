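"""Core containers and plain-text I/O for GWAS summary statistics.

The pipeline operates entirely on summary-level data: per-variant marginal
associations for each trait, a dense LD (allelic correlation) matrix per gene
region, and a BED-style gene annotation table. Coordinates follow the dominant
convention of each format: variant positions are 1-based, gene intervals are
0-based half-open (BED).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")

SUMSTAT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


class SumstatsError(ValueError):
    """Malformed summary-statistic input (schema or format level)."""


class RecordValidationError(SumstatsError):
    """A single record violates a field invariant."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait.

    ``beta`` is per effect-allele copy: per-SD units for quantitative traits,
    log-odds for binary traits.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float
    trait_id: str = ""
    trait_type: str = "quantitative"

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float | None:
        if self.eaf is None or np.isnan(self.eaf):
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def validate(self, strict_pval: bool = False) -> list[str]:
        """Return a list of invariant violations (empty when valid).

        The p-value is checked against the two-sided normal approximation
        |beta/se| within 10% relative tolerance; by default a mismatch is a
        warning (real summary files round p-values), with ``strict_pval`` it
        becomes a violation.
        """
        problems: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            problems.append(f"effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            problems.append(f"other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        if not self.se > 0:
            problems.append(f"se must be > 0, got {self.se}")
        if self.eaf is not None and not np.isnan(self.eaf):
            if not 0.0 <= self.eaf <= 1.0:
                problems.append(f"eaf {self.eaf} outside [0, 1]")
        if not 0.0 < self.pval <= 1.0:
            problems.append(f"pval {self.pval} outside (0, 1]")
        elif self.se > 0:
            expected = float(2.0 * stats.norm.sf(abs(self.beta / self.se)))
            # Rounded p-values near the float floor are not comparable.
            if expected > 1e-300 and self.pval > 1e-300:
                rel = abs(np.log(self.pval) - np.log(expected)) / abs(
                    np.log(expected) if expected < 1 else 1.0
                )
                consistent = (
                    abs(self.pval - expected) <= 0.1 * expected or rel <= 0.1
                )
                if not consistent:
                    msg = (
                        f"pval {self.pval:.3g} inconsistent with |beta/se| "
                        f"(expected {expected:.3g})"
                    )
                    if strict_pval:
                        problems.append(msg)
                    else:
                        warnings.warn(
                            f"{self.variant_id}: {msg}", stacklevel=2
                        )
        return problems


@dataclass
class SummaryStatSet:
    """All records for one trait from one cohort."""

    trait_id: str
    trait_type: str
    cohort_label: str
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise SumstatsError(f"duplicate variant_id(s): {sorted(dups)}")
        for r in self.records:
            if r.trait_id and r.trait_id != self.trait_id:
                raise SumstatsError(
                    f"record {r.variant_id} has trait_id {r.trait_id!r}, "
                    f"set is {self.trait_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index().get(variant_id)

    def _index(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records}

    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def with_records(self, records: Iterable[VariantAssociation]) -> "SummaryStatSet":
        return SummaryStatSet(
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            cohort_label=self.cohort_label,
            records=list(records),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)


@dataclass
class LDMatrix:
    """Dense allelic correlation matrix over an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise SumstatsError(
                f"LD matrix shape {self.r.shape} does not match {m} variant ids"
            )
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise SumstatsError("LD matrix asymmetric beyond 1e-8")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise SumstatsError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise SumstatsError("LD matrix has |r| > 1")
        eig_min = float(np.linalg.eigvalsh(self.r).min())
        if eig_min < -1e-8:
            raise SumstatsError(
                f"LD matrix not positive semidefinite (min eigenvalue {eig_min:.3g})"
            )

    def __len__(self) -> int:
        return len(self.variant_ids)

    def index_of(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in LD matrix") from None

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index_of(v) for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self.index_of(a), self.index_of(b)] ** 2)


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval, 0-based half-open, with optional cis flank.

    ``merged_with`` records genes folded into a single locus (the fibrinogen
    FGA-FGG convention: adjacent subunit genes with strong regional genetic
    correlation are treated as one locus).
    """

    gene_symbol: str
    chrom: str
    start: int
    end: int
    flank: int = 0
    merged_with: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise SumstatsError(
                f"{self.gene_symbol}: start {self.start} must be < end {self.end}"
            )
        if self.flank < 0:
            raise SumstatsError("flank must be >= 0")

    def contains(self, chrom: str, pos: int) -> bool:
        """Half-open membership test of a 1-based variant position."""
        if chrom != self.chrom:
            return False
        p0 = pos - 1
        return self.start - self.flank <= p0 < self.end + self.flank


# ---------------------------------------------------------------------------
# I/O


def read_sumstats(
    path: str | Path,
    trait_id: str,
    trait_type: str = "quantitative",
    cohort_label: str = "",
    strict_pval: bool = False,
) -> tuple[SummaryStatSet, pd.DataFrame]:
    """Read a tab-delimited summary-statistics file.

    Returns the validated set plus a per-row rejection report (empty frame when
    all rows pass). Rows violating a field invariant are dropped, not fatal; a
    missing column is a schema error.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "variant_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(f"{path}: missing required column(s) {missing}")

    records: list[VariantAssociation] = []
    rejected: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False)):
        eaf = None if pd.isna(row.eaf) else float(row.eaf)
        rec = VariantAssociation(
            variant_id=str(row.variant_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            eaf=eaf,
            beta=float(row.beta),
            se=float(row.se),
            pval=float(row.pval),
            n=float(row.n),
            trait_id=trait_id,
            trait_type=trait_type,
        )
        problems = rec.validate(strict_pval=strict_pval)
        if problems:
            rejected.append(
                {"row": i, "variant_id": rec.variant_id, "reason": "; ".join(problems)}
            )
        else:
            records.append(rec)
    report = pd.DataFrame(rejected, columns=["row", "variant_id", "reason"])
    ss = SummaryStatSet(
        trait_id=trait_id,
        trait_type=trait_type,
        cohort_label=cohort_label,
        records=records,
    )
    return ss, report


def write_sumstats(ss: SummaryStatSet, path: str | Path) -> None:
    """Write a SummaryStatSet as TSV (missing eaf encoded as NA)."""
    df = ss.to_frame()
    # repr-style float formatting keeps the round trip exact
    df.to_csv(
        path, sep="\t", index=False, na_rep="NA",
        float_format=lambda x: repr(float(x)),
    )


def read_ld(path: str | Path) -> LDMatrix:
    """Read a plain-text dense LD matrix: id header line, then matrix rows."""
    with open(path) as fh:
        header = fh.readline().split()
        rows = [line.split() for line in fh if line.strip()]
    if not header:
        raise SumstatsError(f"{path}: empty LD file")
    m = len(header)
    if len(rows) != m or any(len(r) != m for r in rows):
        raise SumstatsError(f"{path}: LD matrix is not {m}x{m}")
    mat = np.array([[float(x) for x in r] for r in rows])
    return LDMatrix(header, mat)


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ld.variant_ids) + "\n")
        for row in ld.r:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def read_gene_bed(path: str | Path, flank: int = 0) -> list[GeneRegion]:
    """Read a BED3+ gene annotation table (chrom, start, end, name)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
        comment="#",
    )
    return [
        GeneRegion(
            gene_symbol=str(row.name_),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            flank=flank,
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def write_gene_bed(regions: Sequence[GeneRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in regions:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_symbol}\n")


# ---------------------------------------------------------------------------
# Region subsetting


def subset_region(ss: SummaryStatSet, region: GeneRegion) -> SummaryStatSet:
    """Keep exactly the variants inside the (flanked) gene interval.

    Variant positions are 1-based; the region is 0-based half-open, so a
    variant is kept iff ``start - flank <= pos - 1 < end + flank`` on the
    matching chromosome. An empty result is returned, not raised.
    """
    return ss.with_records(
        r for r in ss.records if region.contains(r.chrom, r.pos)
    )


def flip_record(rec: VariantAssociation) -> VariantAssociation:
    """Re-express a record with the other allele as the effect allele."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
        beta=-rec.beta,
    )
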