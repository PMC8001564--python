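"""Domain types and I/O for GWAS summary statistics, plus the packaged
genetic instruments.

The core container is :class:`VariantAssociation` — one SNP's association
with one trait. Instruments (SNP sets robustly associated with an exposure)
are grouped in :class:`InstrumentSet`. The package ships the published
European GWAS meta-analysis instruments for blood total homocysteine
(18 SNPs, n=44,147), folate (3 SNPs, n=37,465) and cobalamin (14 SNPs,
n=45,576) as data files; these are per-SD effect sizes with effect allele,
frequency and p-value but no standard error, so SEs are reconstructed from
(beta, p) under the normal approximation — see :func:`se_from_beta_pval`.

On-disk canonical format: tab-separated with header
``rsid / effect_allele / other_allele / eaf / beta / se / pval / n``.
Other layouts (e.g. CKDGen meta-analysis dumps with
``RSID/Allele1/Allele2/Freq1/Effect/StdErr/P-value/n``) are read through a
dialect map from canonical field names to source column names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .errors import ConfigurationError, DataError, DomainError, RowParseError

__all__ = [
    "VariantAssociation",
    "InstrumentSet",
    "GWAS_SAMPLE_SIZES",
    "read_summary_stats",
    "write_summary_stats",
    "se_from_beta_pval",
    "pval_from_beta_se",
    "filter_genome_wide",
    "instrument_overlap",
    "load_instrument_fixture",
]

GENOME_WIDE_P = 5e-8

#: Discovery-GWAS sample sizes for the packaged exposure instruments.
GWAS_SAMPLE_SIZES = {"homocysteine": 44147, "folate": 37465, "cobalamin": 45576}

CANONICAL_COLUMNS = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
_MANDATORY = ["rsid", "effect_allele", "beta"]


@dataclass(frozen=True)
class VariantAssociation:
    """Summary statistics of a single variant for a single trait.

    ``beta`` is the additive per-effect-allele effect; for the packaged
    exposure instruments it is expressed per one SD of the (blood biomarker)
    phenotype. ``other_allele`` is optional because published instrument
    tables often print only the effect allele.
    """

    rsid: str
    effect_allele: str
    beta: float
    other_allele: str | None = None
    eaf: float | None = None
    se: float | None = None
    pval: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise DataError("rsid must be non-empty")
        if not self.effect_allele:
            raise DataError(f"{self.rsid}: effect_allele must be non-empty")
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        if self.other_allele is not None:
            object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise DataError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if self.se is not None and not self.se > 0:
            raise DataError(f"{self.rsid}: se {self.se} must be > 0")
        if self.pval is not None and not 0.0 < self.pval <= 1.0:
            raise DataError(f"{self.rsid}: pval {self.pval} outside (0, 1]")
        if self.n is not None and self.n <= 0:
            raise DataError(f"{self.rsid}: n {self.n} must be positive")

    def flipped(self) -> "VariantAssociation":
        """Re-express the association on the opposite allele.

        Swaps effect/other allele, negates beta and reflects the frequency.
        Requires ``other_allele`` to be present.
        """
        if self.other_allele is None:
            raise DataError(f"{self.rsid}: cannot flip without other_allele")
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class InstrumentSet:
    """An ordered set of instrument SNPs for one exposure."""

    exposure_name: str
    variants: list[VariantAssociation]
    sd_scaled: bool = True

    def __post_init__(self) -> None:
        rsids = [v.rsid for v in self.variants]
        if len(rsids) != len(set(rsids)):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise DataError(f"duplicate rsids in instrument set: {dupes}")

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


def se_from_beta_pval(beta: float, pval: float, two_sided: bool = True) -> float:
    """Reconstruct a standard error from an effect size and its p-value.

    Under the Wald/normal approximation, ``se = |beta| / z`` where ``z`` is
    the standard-normal quantile matching the (two-sided) p-value. The
    quantile is evaluated from the log of the p-value so that extremely
    small values (down to ~1e-300, common for genome-wide instruments) do
    not underflow.
    """
    if not 0.0 < pval < 1.0:
        raise DomainError(f"pval must be in (0, 1), got {pval}")
    if beta == 0:
        raise DomainError("beta must be nonzero to recover a standard error")
    logp = math.log(pval) - (math.log(2.0) if two_sided else 0.0)
    z = -special.ndtri_exp(logp)  # upper-tail quantile from log-probability
    return abs(beta) / z


def pval_from_beta_se(beta, se, two_sided: bool = True):
    """Two-sided normal p-value from an estimate and its SE.

    Computed through the log survival function and floored at the smallest
    positive double so the result stays in (0, 1] even for |z| > 38.
    """
    z = np.abs(np.asarray(beta, dtype=float) / np.asarray(se, dtype=float))
    logp = special.log_ndtr(-z) + (math.log(2.0) if two_sided else 0.0)
    p = np.exp(np.minimum(logp, 0.0))
    p = np.maximum(p, np.finfo(float).tiny)
    return p if p.shape else float(p)


def _infer_sep(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def _parse_row(row: Mapping[str, object]) -> VariantAssociation:
    def _get(key: str):
        val = row.get(key)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return None
        if isinstance(val, str) and val.strip() in ("", "NA", "."):
            return None
        return val

    def _num(key: str) -> float | None:
        val = _get(key)
        if val is None:
            return None
        try:
            return float(val)
        except (TypeError, ValueError):
            raise DataError(f"unparseable numeric for '{key}': {val!r}") from None

    n = _num("n")
    return VariantAssociation(
        rsid=str(_get("rsid") or ""),
        effect_allele=str(_get("effect_allele") or ""),
        other_allele=(str(v) if (v := _get("other_allele")) is not None else None),
        eaf=_num("eaf"),
        beta=_num("beta"),
        se=_num("se"),
        pval=_num("pval"),
        n=None if n is None else int(round(n)),
    )


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[VariantAssociation]:
    """Read per-variant summary statistics from delimited text.

    Parameters
    ----------
    path
        TSV or CSV file, optionally gzip-compressed.
    dialect
        Mapping from canonical field names (``rsid``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``) to
        the source file's column names. Omitted fields fall back to the
        canonical name if present in the header.
    strict
        If True (default), any malformed row aborts the read with a
        :class:`RowParseError` naming the offending lines; otherwise bad
        rows are silently dropped (use strict mode to see the per-line
        detail).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path), dtype=str)
    dialect = dict(dialect or {})
    rename: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        src = dialect.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon in _MANDATORY:
            raise ConfigurationError(
                f"mandatory column '{canon}' (source name '{src}') missing from {path.name}; "
                f"header has {list(df.columns)}"
            )
    df = df.rename(columns=rename)

    records: list[VariantAssociation] = []
    failures: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        line_no = i + 2  # header is line 1
        try:
            records.append(_parse_row(row))
        except DataError as exc:
            failures.append((line_no, str(exc)))
    if failures and strict:
        raise RowParseError(failures)
    return records


def write_summary_stats(records: Iterable[VariantAssociation], path: str | Path) -> None:
    """Write records in the canonical tab-separated layout (gzip by suffix)."""
    rows = [
        {
            "rsid": v.rsid,
            "effect_allele": v.effect_allele,
            "other_allele": v.other_allele,
            "eaf": v.eaf,
            "beta": v.beta,
            "se": v.se,
            "pval": v.pval,
            "n": v.n,
        }
        for v in records
    ]
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_genome_wide(
    variants: Sequence[VariantAssociation], threshold: float = GENOME_WIDE_P
) -> list[VariantAssociation]:
    """Keep variants with ``pval < threshold`` (default 5e-8), order preserved."""
    if not 0.0 < threshold < 1.0:
        raise DomainError(f"threshold must be in (0, 1), got {threshold}")
    return [v for v in variants if v.pval is not None and v.pval < threshold]


def instrument_overlap(a: InstrumentSet, b: InstrumentSet) -> list[str]:
    """Sorted rsids shared by two instrument sets."""
    return sorted(set(a.rsids) & set(b.rsids))


def _fixture_table() -> pd.DataFrame:
    with resources.files("mrkit.data").joinpath("instruments.tsv").open("rb") as fh:
        return pd.read_csv(
            fh,
            sep="\t",
            dtype={"rsid": str, "effect_allele": str},
            float_precision="round_trip",
        )


def load_instrument_fixture(exposure_name: str) -> InstrumentSet:
    """Load one of the packaged exposure instruments.

    ``exposure_name`` is one of ``homocysteine`` (18 SNPs), ``folate``
    (3 SNPs) or ``cobalamin`` (14 SNPs). Effect sizes are per SD of the
    blood biomarker; standard errors are reconstructed from the printed
    beta and p-value and therefore carry their rounding.
    """
    if exposure_name not in GWAS_SAMPLE_SIZES:
        raise LookupError(
            f"unknown exposure '{exposure_name}'; available: {sorted(GWAS_SAMPLE_SIZES)}"
        )
    table = _fixture_table()
    sub = table[table["exposure"] == exposure_name]
    n = GWAS_SAMPLE_SIZES[exposure_name]
    variants = [
        VariantAssociation(
            rsid=row.rsid,
            effect_allele=row.effect_allele,
            eaf=row.eaf,
            beta=row.beta,
            se=se_from_beta_pval(row.beta, row.pval),
            pval=row.pval,
            n=n,
        )
        for row in sub.itertuples()
    ]
    return InstrumentSet(exposure_name=exposure_name, variants=variants, sd_scaled=True)
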