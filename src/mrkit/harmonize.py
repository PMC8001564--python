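"""Harmonization of exposure and outcome summary statistics, and Steiger
directionality filtering.

Two-sample MR combines SNP-exposure and SNP-outcome associations estimated
in different studies, which may report effects on opposite alleles or
opposite strands. Harmonization re-expresses every outcome association on
the exposure's effect allele: matching alleles are kept as-is, swapped
alleles have the outcome beta negated and frequency reflected, and
palindromic variants (A/T or C/G pairs, where strand cannot be resolved
from the alleles alone) are either dropped or oriented by comparing allele
frequencies between the two studies.

Because the packaged exposure instruments print only the effect allele,
harmonization also works in effect-allele-only mode: the exposure effect
allele is matched against the outcome's two alleles, and a variant whose
effect allele matches neither is dropped as non-overlapping (strand cannot
be disambiguated without both exposure alleles).

Steiger filtering guards against reverse causation by removing variants
that explain more variance in the outcome than in the exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Literal, Sequence

import pandas as pd
from scipy import special

from .errors import DataError, DomainError, HarmonizationError
from .summary_data import InstrumentSet, VariantAssociation

__all__ = [
    "Action",
    "HarmonizedVariant",
    "HarmonizedSet",
    "harmonize",
    "variance_explained",
    "steiger_filter",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class Action(str, Enum):
    """Per-variant harmonization outcome."""

    KEPT_AS_IS = "kept_as_is"
    FLIPPED = "flipped"
    DROPPED_PALINDROMIC = "dropped_palindromic"
    DROPPED_NONOVERLAP = "dropped_nonoverlap"
    DROPPED_STEIGER = "dropped_steiger"


_KEPT = {Action.KEPT_AS_IS, Action.FLIPPED}


@dataclass(frozen=True)
class HarmonizedVariant:
    """Exposure and outcome effects aligned to the exposure's effect allele.

    Dropped variants keep their exposure-side fields for auditing but carry
    no weight downstream. ``r2_exp``/``r2_out`` are populated by Steiger
    filtering.
    """

    rsid: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    action: Action
    beta_out: float | None = None
    se_out: float | None = None
    eaf_exp: float | None = None
    eaf_out: float | None = None
    n_exp: int | None = None
    n_out: int | None = None
    pval_exp: float | None = None
    pval_out: float | None = None
    r2_exp: float | None = None
    r2_out: float | None = None

    @property
    def kept(self) -> bool:
        return self.action in _KEPT


@dataclass
class HarmonizedSet:
    exposure_name: str
    outcome_name: str
    variants: list[HarmonizedVariant]

    def __post_init__(self) -> None:
        rsids = [v.rsid for v in self.variants]
        if len(rsids) != len(set(rsids)):
            raise DataError("duplicate rsids in harmonized set")

    @property
    def kept(self) -> list[HarmonizedVariant]:
        return [v for v in self.variants if v.kept]

    def n_kept(self) -> int:
        return len(self.kept)

    def audit_frame(self) -> pd.DataFrame:
        """Per-SNP action log as a DataFrame (TSV-serializable)."""
        return pd.DataFrame(
            {
                "rsid": [v.rsid for v in self.variants],
                "action": [v.action.value for v in self.variants],
                "r2_exp": [v.r2_exp for v in self.variants],
                "r2_out": [v.r2_out for v in self.variants],
            }
        )


def _is_palindromic(a1: str, a2: str | None) -> bool:
    return a2 is not None and _COMPLEMENT.get(a1) == a2


def _straddle(f1: float, f2: float) -> bool:
    return (f1 - 0.5) * (f2 - 0.5) < 0


def harmonize(
    exposure: InstrumentSet,
    outcome: Sequence[VariantAssociation],
    palindromic_policy: Literal["drop", "infer_by_eaf"] = "infer_by_eaf",
    eaf_tolerance: float = 0.08,
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Align outcome associations to the exposure instrument's effect alleles.

    Parameters
    ----------
    palindromic_policy
        ``drop``: discard palindromic variants. ``infer_by_eaf`` (default):
        orient palindromic variants by allele frequency — drop when either
        study's frequency is within ``eaf_tolerance`` of 0.5 (orientation
        ambiguous), otherwise flip when the aligned frequencies straddle 0.5.
    eaf_tolerance
        Half-width of the ambiguous frequency band around 0.5 (default
        0.08, i.e. drop palindromes with frequency in [0.42, 0.58]).

    Raises
    ------
    HarmonizationError
        If the outcome contains duplicate rsids (ambiguous match) or no
        instrument SNP overlaps the outcome at all.
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise DomainError(f"unknown palindromic_policy {palindromic_policy!r}")

    by_rsid: dict[str, VariantAssociation] = {}
    for rec in outcome:
        if rec.rsid in by_rsid:
            raise HarmonizationError(
                f"duplicate outcome rows for rsid {rec.rsid}; resolve multi-allelic "
                "duplicates upstream"
            )
        by_rsid[rec.rsid] = rec

    out_variants: list[HarmonizedVariant] = []
    for ev in exposure.variants:
        base = dict(
            rsid=ev.rsid,
            effect_allele=ev.effect_allele,
            beta_exp=ev.beta,
            se_exp=ev.se,
            eaf_exp=ev.eaf,
            n_exp=ev.n,
            pval_exp=ev.pval,
        )
        ov = by_rsid.get(ev.rsid)
        if ov is None:
            out_variants.append(HarmonizedVariant(action=Action.DROPPED_NONOVERLAP, **base))
            continue

        palindromic = _is_palindromic(ov.effect_allele, ov.other_allele) or _is_palindromic(
            ev.effect_allele, ev.other_allele
        )

        # Tentative alignment from allele labels. Complement matches denote a
        # strand flip and are only trusted when the exposure prints both
        # alleles (in effect-allele-only mode strand cannot be disambiguated,
        # so an unmatched effect allele is dropped as non-overlapping).
        both_exp_alleles = ev.other_allele is not None
        if ev.effect_allele == ov.effect_allele:
            flip = False
        elif ov.other_allele is not None and ev.effect_allele == ov.other_allele:
            flip = True
        elif (
            both_exp_alleles
            and not palindromic
            and _COMPLEMENT.get(ev.effect_allele) == ov.effect_allele
        ):
            flip = False
        elif (
            both_exp_alleles
            and not palindromic
            and ov.other_allele is not None
            and _COMPLEMENT.get(ev.effect_allele) == ov.other_allele
        ):
            flip = True
        else:
            out_variants.append(HarmonizedVariant(action=Action.DROPPED_NONOVERLAP, **base))
            continue

        if palindromic:
            if palindromic_policy == "drop":
                out_variants.append(HarmonizedVariant(action=Action.DROPPED_PALINDROMIC, **base))
                continue
            if ev.eaf is None or ov.eaf is None:
                out_variants.append(HarmonizedVariant(action=Action.DROPPED_PALINDROMIC, **base))
                continue
            eaf_aligned = (1.0 - ov.eaf) if flip else ov.eaf
            if abs(ev.eaf - 0.5) < eaf_tolerance or abs(eaf_aligned - 0.5) < eaf_tolerance:
                out_variants.append(HarmonizedVariant(action=Action.DROPPED_PALINDROMIC, **base))
                continue
            if _straddle(ev.eaf, eaf_aligned):
                flip = not flip  # label match was on the opposite strand

        beta_out = -ov.beta if flip else ov.beta
        eaf_out = None if ov.eaf is None else ((1.0 - ov.eaf) if flip else ov.eaf)
        out_variants.append(
            HarmonizedVariant(
                action=Action.FLIPPED if flip else Action.KEPT_AS_IS,
                beta_out=beta_out,
                se_out=ov.se,
                eaf_out=eaf_out,
                n_out=ov.n,
                pval_out=ov.pval,
                **base,
            )
        )

    hset = HarmonizedSet(exposure.exposure_name, outcome_name, out_variants)
    if hset.n_kept() == 0:
        raise HarmonizationError(
            f"no overlapping SNPs between {exposure.exposure_name} instrument and {outcome_name}"
        )
    return hset


def variance_explained(
    assoc: VariantAssociation, method: Literal["t_statistic", "af_beta"] = "t_statistic"
) -> float:
    """Fraction of trait variance explained by one variant.

    ``t_statistic``: r^2 = t^2 / (t^2 + n - 2) with t recovered from the
    p-value via a log-space normal quantile — uses only printed quantities.
    ``af_beta``: r^2 = 2*eaf*(1-eaf)*beta^2, valid when beta is per-SD of
    the trait; usable when p/n are unavailable.
    """
    if method == "t_statistic":
        if assoc.pval is None or assoc.n is None:
            raise DomainError(f"{assoc.rsid}: t_statistic method needs pval and n")
        if assoc.n <= 2:
            raise DomainError(f"{assoc.rsid}: n must exceed 2")
        if assoc.beta == 0:
            return 0.0
        t = -special.ndtri_exp(math.log(assoc.pval) - math.log(2.0))
        return t * t / (t * t + assoc.n - 2)
    if method == "af_beta":
        if assoc.eaf is None:
            raise DomainError(f"{assoc.rsid}: af_beta method needs eaf")
        r2 = 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta**2
        if r2 >= 1.0:
            raise DomainError(f"{assoc.rsid}: af_beta r^2 {r2:.3f} >= 1; beta not per-SD?")
        return r2
    raise DomainError(f"unknown variance_explained method {method!r}")


def _r2_for(
    rsid: str,
    beta: float,
    eaf: float | None,
    pval: float | None,
    n: int | None,
    method: str,
) -> float:
    return variance_explained(
        VariantAssociation(rsid=rsid, effect_allele="A", beta=beta, eaf=eaf, pval=pval, n=n),
        method=method,
    )


def steiger_filter(
    hset: HarmonizedSet, method: Literal["t_statistic", "af_beta"] = "t_statistic"
) -> HarmonizedSet:
    """Drop variants explaining more variance in the outcome than the exposure.

    A variant is marked ``dropped_steiger`` when r^2(outcome) is strictly
    greater than r^2(exposure); ties are kept. Both r^2 values are recorded
    on every kept-or-dropped variant for the audit log. Order-independent.
    """
    out: list[HarmonizedVariant] = []
    for v in hset.variants:
        if not v.kept:
            out.append(v)
            continue
        r2_exp = _r2_for(v.rsid, v.beta_exp, v.eaf_exp, v.pval_exp, v.n_exp, method)
        r2_out = _r2_for(v.rsid, v.beta_out, v.eaf_out, v.pval_out, v.n_out, method)
        action = Action.DROPPED_STEIGER if r2_out > r2_exp else v.action
        out.append(replace(v, action=action, r2_exp=r2_exp, r2_out=r2_out))
    return HarmonizedSet(hset.exposure_name, hset.outcome_name, out)
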