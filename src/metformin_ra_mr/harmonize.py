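"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS report each SNP's effect relative to a stated effect allele, but the
two studies need not agree on which allele that is, nor on the DNA strand they
read.  Before Wald ratios can be formed, the outcome record must be expressed
per copy of the exposure's effect allele:

* same alleles, same order  -> copy the outcome effect unchanged;
* alleles swapped           -> negate ``beta_out`` and complement ``eaf_out``;
* alleles on the other strand (A<->T, C<->G complement), possibly also
  swapped -> complement first, then apply the same two rules.

Palindromic SNPs (allele pair A/T or C/G) are identical to their own strand
complement, so "swapped" and "other strand" cannot be told apart from the
alleles alone.  When the effect-allele frequency is informative (far from
0.5) orientation can be recovered by requiring both studies' frequencies to
fall on the same side of 0.5; when the exposure EAF lies in the intermediate
window (default [0.42, 0.58]) or is missing, the SNP is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MrError
from .sumstats_io import Drop, GwasRecord, HarmonizedInstrument, InstrumentSet, VALID_ALLELES

__all__ = ["HarmonizeConfig", "is_palindromic", "harmonize_pair", "harmonize_all", "COMPLEMENT"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class HarmonizeConfig:
    """Tuning knobs for harmonization.

    ``intermediate_low``/``intermediate_high`` bound the effect-allele
    frequency window inside which a palindromic SNP's strand cannot be
    resolved by frequency; the window must be symmetric about 0.5.
    ``drop_palindromic_always`` drops every palindromic SNP regardless of
    frequency.
    """

    intermediate_low: float = 0.42
    intermediate_high: float = 0.58
    drop_palindromic_always: bool = False

    def __post_init__(self):
        if not (0 < self.intermediate_low < 0.5 < self.intermediate_high < 1):
            raise ValueError("need 0 < intermediate_low < 0.5 < intermediate_high < 1")
        if abs(self.intermediate_low + self.intermediate_high - 1.0) > 1e-12:
            raise ValueError("intermediate window must be symmetric about 0.5")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    for a, name in ((effect_allele, "effect_allele"), (other_allele, "other_allele")):
        if a not in VALID_ALLELES:
            raise MrError(f"{name} must be one of A/C/G/T, got {a!r}")
    if effect_allele == other_allele:
        raise MrError("alleles must be distinct")
    return COMPLEMENT[effect_allele] == other_allele


def _instrument(exp: GwasRecord, beta_out: float, out: GwasRecord) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exp.snp_id,
        chrom=exp.chrom,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        eaf_exposure=exp.eaf,
        beta_exp=exp.beta,
        se_exp=exp.se,
        p_exp=exp.pvalue,
        beta_out=beta_out,
        se_out=out.se,
        p_out=out.pvalue,
        n_exp=exp.n,
        n_out=out.n,
    )


def harmonize_pair(
    exp: GwasRecord, out: GwasRecord, cfg: HarmonizeConfig | None = None
) -> HarmonizedInstrument | Drop:
    """Align one outcome record to the exposure's effect allele.

    Returns a :class:`HarmonizedInstrument` on success, or a :class:`Drop`
    carrying the reason code (``palindromic_intermediate`` or
    ``allele_mismatch``).  Harmonization only ever changes the sign of
    ``beta_out`` (and the orientation of the outcome EAF); magnitudes and
    standard errors pass through untouched.
    """
    if exp.snp_id != out.snp_id:
        raise MrError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")
    cfg = cfg or HarmonizeConfig()

    palindromic = is_palindromic(exp.effect_allele, exp.other_allele)

    if palindromic:
        # outcome alleles must be the same ambiguous pair, in either order
        if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
            return Drop(exp.snp_id, "allele_mismatch", f"exposure {exp.effect_allele}/{exp.other_allele} vs outcome {out.effect_allele}/{out.other_allele}")
        if cfg.drop_palindromic_always:
            return Drop(exp.snp_id, "palindromic_intermediate", "palindromic SNPs dropped unconditionally by config")
        if exp.eaf is None or cfg.intermediate_low <= exp.eaf <= cfg.intermediate_high:
            eaf_txt = "missing" if exp.eaf is None else f"{exp.eaf:.4g}"
            return Drop(exp.snp_id, "palindromic_intermediate", f"exposure EAF {eaf_txt} within [{cfg.intermediate_low}, {cfg.intermediate_high}]")
        # nominal alignment on the literal alleles, then frequency check
        beta_out = out.beta if out.effect_allele == exp.effect_allele else -out.beta
        eaf_out = None
        if out.eaf is not None:
            eaf_out = out.eaf if out.effect_allele == exp.effect_allele else 1.0 - out.eaf
        if eaf_out is not None and (exp.eaf - 0.5) * (eaf_out - 0.5) < 0:
            beta_out = -beta_out  # frequencies disagree: the studies read opposite strands
        return _instrument(exp, beta_out, out)

    # non-palindromic: try direct, swapped, then strand-complemented forms
    ea, oa = out.effect_allele, out.other_allele
    if (ea, oa) == (exp.effect_allele, exp.other_allele):
        return _instrument(exp, out.beta, out)
    if (ea, oa) == (exp.other_allele, exp.effect_allele):
        return _instrument(exp, -out.beta, out)
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (exp.effect_allele, exp.other_allele):
        return _instrument(exp, out.beta, out)
    if (cea, coa) == (exp.other_allele, exp.effect_allele):
        return _instrument(exp, -out.beta, out)
    return Drop(exp.snp_id, "allele_mismatch", f"exposure {exp.effect_allele}/{exp.other_allele} vs outcome {ea}/{oa}")


def harmonize_all(
    exp_records,
    out_records,
    cfg: HarmonizeConfig | None = None,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> InstrumentSet:
    """Inner-join exposure and outcome records on rsID and harmonize each pair.

    Drops are recorded in the returned set's provenance, never raised.  The
    output preserves the exposure records' order.
    """
    cfg = cfg or HarmonizeConfig()
    out_by_id = {r.snp_id: r for r in out_records}
    instruments: list[HarmonizedInstrument] = []
    drops: list[Drop] = []
    n_overlap = 0
    for exp in exp_records:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue
        n_overlap += 1
        result = harmonize_pair(exp, out, cfg)
        if isinstance(result, Drop):
            drops.append(result)
        else:
            instruments.append(result)
    instr = InstrumentSet(instruments, exposure_name=exposure_name, outcome_name=outcome_name, provenance=drops)
    instr.note(
        f"harmonized {n_overlap} SNP(s) present in both GWAS "
        f"({len(exp_records) if hasattr(exp_records, '__len__') else 'n/a'} exposure records); "
        f"{len(drops)} dropped"
    )
    if n_overlap == 0:
        instr.note("zero overlap between exposure and outcome SNP sets")
    return instr
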