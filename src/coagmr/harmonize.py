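"""Allele harmonization between exposure and outcome summary statistics.

Both data sets must express their effects relative to the same effect allele
before any ratio estimate is meaningful. Non-palindromic variants can always
be reconciled by swapping alleles (negating the outcome beta) and/or taking
strand complements. Palindromic variants (A/T or C/G) are strand-ambiguous:
they are oriented by effect-allele-frequency concordance when the minor
allele frequency is informative, and excluded when MAF > 0.42 in either data
set (frequencies that close to 0.5 cannot resolve the orientation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sumstats import VariantAssociation, flip_record

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_MAF_AMBIGUITY = 0.42


def complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedPair:
    """One variant with exposure and outcome effects on a shared effect allele."""

    variant_id: str
    beta_exposure: float = np.nan
    se_exposure: float = np.nan
    beta_outcome: float = np.nan
    se_outcome: float = np.nan
    eaf: float | None = None
    action: str = "none"  # none | swapped | strand_flipped | excluded:<reason>

    @property
    def excluded(self) -> bool:
        return self.action.startswith("excluded")

    @property
    def exclusion_reason(self) -> str | None:
        if not self.excluded:
            return None
        return self.action.split(":", 1)[1]


def _pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    action: str,
) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exposure.variant_id,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=outcome.beta,
        se_outcome=outcome.se,
        eaf=exposure.eaf,
        action=action,
    )


def _excluded(exposure: VariantAssociation, reason: str) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exposure.variant_id,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        eaf=exposure.eaf,
        action=f"excluded:{reason}",
    )


def harmonize(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    maf_ambiguity: float = DEFAULT_MAF_AMBIGUITY,
) -> HarmonizedPair:
    """Align the outcome record to the exposure's effect allele.

    Exclusion is a value (``action = "excluded:<reason>"``), not an exception.
    The ambiguity rule is applied to the MAF of both data sets; a palindromic
    variant with missing outcome frequency is excluded outright since its
    orientation cannot be checked.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    ea, oa = exposure.effect_allele, exposure.other_allele
    palindromic = is_palindromic(ea, oa)

    def match(out: VariantAssociation) -> str | None:
        if (out.effect_allele, out.other_allele) == (ea, oa):
            return "same"
        if (out.effect_allele, out.other_allele) == (oa, ea):
            return "swapped"
        return None

    m = match(outcome)
    if m is None and not palindromic:
        flipped = VariantAssociation(
            variant_id=outcome.variant_id,
            chrom=outcome.chrom,
            pos=outcome.pos,
            effect_allele=complement(outcome.effect_allele),
            other_allele=complement(outcome.other_allele),
            eaf=outcome.eaf,
            beta=outcome.beta,
            se=outcome.se,
            pval=outcome.pval,
            n=outcome.n,
            trait_id=outcome.trait_id,
            trait_type=outcome.trait_type,
        )
        m2 = match(flipped)
        if m2 == "same":
            return _pair(exposure, flipped, "strand_flipped")
        if m2 == "swapped":
            return _pair(exposure, flip_record(flipped), "strand_flipped")
        return _excluded(exposure, "allele_mismatch")
    if m is None:
        # palindromic: a strand flip maps the pair onto itself or its swap,
        # so a non-match is a genuine allele mismatch
        return _excluded(exposure, "allele_mismatch")

    if palindromic:
        mafs = [exposure.maf, outcome.maf]
        if any(v is None for v in mafs):
            return _excluded(exposure, "palindromic_missing_eaf")
        if any(v > maf_ambiguity for v in mafs):
            return _excluded(exposure, "palindromic_ambiguous")
        # orient by frequency concordance: the outcome's effect-allele
        # frequency should agree with the exposure's once aligned
        out = flip_record(outcome) if m == "swapped" else outcome
        assert exposure.eaf is not None and out.eaf is not None
        if abs(exposure.eaf - out.eaf) <= abs(exposure.eaf - (1.0 - out.eaf)):
            return _pair(exposure, out, "swapped" if m == "swapped" else "none")
        # frequencies disagree: the outcome record is on the other strand,
        # which for a palindromic pair relabels effect<->other allele
        return _pair(exposure, flip_record(out), "strand_flipped")

    if m == "swapped":
        return _pair(exposure, flip_record(outcome), "swapped")
    return _pair(exposure, outcome, "none")


def harmonize_sets(
    exposure_records: list[VariantAssociation],
    outcome_records: dict[str, VariantAssociation] | list[VariantAssociation],
    maf_ambiguity: float = DEFAULT_MAF_AMBIGUITY,
) -> list[HarmonizedPair]:
    """Harmonize each exposure record against the matching outcome record.

    Exposure variants absent from the outcome data set are excluded with
    reason ``missing_in_outcome``.
    """
    if isinstance(outcome_records, list):
        outcome_records = {r.variant_id: r for r in outcome_records}
    pairs = []
    for rec in exposure_records:
        out = outcome_records.get(rec.variant_id)
        if out is None:
            pairs.append(_excluded(rec, "missing_in_outcome"))
        else:
            pairs.append(harmonize(rec, out, maf_ambiguity))
    return pairs


def retained(pairs: list[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if not p.excluded]
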