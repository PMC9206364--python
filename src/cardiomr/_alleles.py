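"""Shared allele bookkeeping: strand complements and pairwise alignment."""

from __future__ import annotations

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or C/G variants: strand cannot be resolved from alleles alone."""
    return (effect_allele, other_allele) in PALINDROMIC_PAIRS


def match_orientation(
    ref_ea: str, ref_oa: str, ea: str, oa: str
) -> str | None:
    """Classify how ``(ea, oa)`` relates to the reference allele pair.

    Returns ``"same"`` (identical orientation, possibly after strand
    complement), ``"swapped"`` (effect/other exchanged, beta must be
    negated), or ``None`` if the pairs are irreconcilable.  For palindromic
    variants same/swapped cannot be told apart here; callers must use
    allele frequencies.
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return "swapped"
    cea, coa = COMPLEMENT.get(ea), COMPLEMENT.get(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return "same"
    if (cea, coa) == (ref_oa, ref_ea):
        return "swapped"
    return None
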