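"""Data model and text I/O for GWAS summary statistics and harmonized instruments.

Two-sample Mendelian randomization works entirely from published per-SNP
association summaries: for every variant, an effect size (beta) per copy of a
stated effect allele, its standard error, a p-value and, when available, the
effect-allele frequency and sample size.  This module defines the in-memory
records for one trait (:class:`GwasRecord`), for an exposure/outcome pair on a
common allele orientation (:class:`HarmonizedInstrument`), and for a full
instrument table with an audit trail (:class:`InstrumentSet`), together with
plain-text readers and writers in the beta/se/pval summary-statistics dialect
used by OpenGWAS exports.

The package bundles, as its reference dataset, the 32 harmonized instruments
of a published two-sample MR analysis of metformin use (UK Biobank GWAS
ukb-b-14609, 462,933 individuals) against rheumatoid arthritis (Okada et al.
2014 meta-analysis, ieu-a-832, 58,284 individuals); see
:func:`load_metformin_ra_instruments`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator

import pandas as pd

from .errors import ConfigurationError, RowValidationError

__all__ = [
    "VALID_ALLELES",
    "DROP_REASONS",
    "GwasRecord",
    "HarmonizedInstrument",
    "Drop",
    "InstrumentSet",
    "read_sumstats",
    "write_instruments",
    "read_instruments",
    "load_metformin_ra_instruments",
]

VALID_ALLELES = frozenset("ACGT")

#: machine-readable reason codes for dropping a SNP from an instrument set
DROP_REASONS = frozenset(
    {
        "palindromic_intermediate",
        "weak_instrument",
        "steiger_reverse",
        "clumped",
        "allele_mismatch",
    }
)

#: fixed column order of the harmonized-instrument TSV (bit-stable diffs)
INSTRUMENT_COLUMNS = (
    "snp", "chr", "ea", "oa", "eaf",
    "beta_exp", "se_exp", "p_exp",
    "beta_out", "se_out", "p_out", "f",
)


def _check_allele(allele: str, name: str) -> None:
    if allele not in VALID_ALLELES:
        raise ValueError(f"{name} must be one of A/C/G/T, got {allele!r}")


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary for a single trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` on the
    trait scale of the source GWAS (log-odds for a logistic scan, raw units
    for a linear one).  ``eaf``, ``n`` and ``pos`` are optional; ``pos`` (base
    pairs) is only needed for distance-based LD clumping.
    """

    snp_id: str
    chrom: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None
    pos: int | None = None

    def __post_init__(self):
        _check_allele(self.effect_allele, "effect_allele")
        _check_allele(self.other_allele, "other_allele")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.snp_id}: se must be positive and finite, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.snp_id}: pvalue must lie in (0, 1], got {self.pvalue}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: beta must be finite")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.snp_id}: n must be a positive integer")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP's paired exposure and outcome effects on a shared effect allele.

    Postcondition of harmonization: ``beta_exp`` and ``beta_out`` are both
    expressed per copy of ``effect_allele``.  ``eaf_exposure`` is the effect
    allele's frequency in the exposure GWAS.  ``f_stat`` is the per-SNP
    instrument-strength F statistic (filled in by the instrument filters;
    ``None`` until then).
    """

    snp_id: str
    chrom: str
    effect_allele: str
    other_allele: str
    eaf_exposure: float | None
    beta_exp: float
    se_exp: float
    p_exp: float
    beta_out: float
    se_out: float
    p_out: float
    f_stat: float | None = None
    n_exp: int | None = None
    n_out: int | None = None

    def __post_init__(self):
        _check_allele(self.effect_allele, "effect_allele")
        _check_allele(self.other_allele, "other_allele")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        for name in ("se_exp", "se_out"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{self.snp_id}: {name} must be positive and finite")
        for name in ("p_exp", "p_out"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{self.snp_id}: {name} must lie in (0, 1]")
        if self.eaf_exposure is not None and not (0 < self.eaf_exposure < 1):
            raise ValueError(f"{self.snp_id}: eaf_exposure must lie in (0, 1)")
        if self.f_stat is not None and not (self.f_stat >= 0 and math.isfinite(self.f_stat)):
            raise ValueError(f"{self.snp_id}: f_stat must be finite and >= 0")


@dataclass(frozen=True)
class Drop:
    """Provenance entry: one SNP removed from the instrument set."""

    snp_id: str
    reason: str
    detail: str = ""

    def __post_init__(self):
        if self.reason not in DROP_REASONS:
            raise ValueError(f"unknown drop reason {self.reason!r}")


@dataclass
class InstrumentSet:
    """An ordered collection of harmonized instruments with an audit trail.

    ``provenance`` records every dropped SNP exactly once with a
    machine-readable reason, plus free-text notes for each filter applied.
    """

    instruments: list[HarmonizedInstrument]
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    provenance: list[Drop] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [i.snp_id for i in self.instruments]
        if len(ids) != len(set(ids)):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate snp_ids in instrument set: {dup}")
        dropped = [d.snp_id for d in self.provenance]
        if len(dropped) != len(set(dropped)):
            dup = sorted({s for s in dropped if dropped.count(s) > 1})
            raise ValueError(f"SNP(s) dropped more than once in provenance: {dup}")

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)

    def __getitem__(self, snp_id: str) -> HarmonizedInstrument:
        for inst in self.instruments:
            if inst.snp_id == snp_id:
                return inst
        raise KeyError(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    def drop(self, snp_id: str, reason: str, detail: str = "") -> None:
        """Remove one instrument, recording the reason in provenance."""
        inst = self[snp_id]
        self.instruments.remove(inst)
        self.provenance.append(Drop(snp_id, reason, detail))
        self.validate()

    def replace_instrument(self, snp_id: str, new: HarmonizedInstrument) -> None:
        idx = self.snp_ids.index(snp_id)
        self.instruments[idx] = new

    def note(self, text: str) -> None:
        self.notes.append(text)

    def to_frame(self) -> pd.DataFrame:
        """Instrument table as a DataFrame in the canonical column order."""
        rows = []
        for i in self.instruments:
            rows.append(
                {
                    "snp": i.snp_id,
                    "chr": i.chrom,
                    "ea": i.effect_allele,
                    "oa": i.other_allele,
                    "eaf": i.eaf_exposure,
                    "beta_exp": i.beta_exp,
                    "se_exp": i.se_exp,
                    "p_exp": i.p_exp,
                    "beta_out": i.beta_out,
                    "se_out": i.se_out,
                    "p_out": i.p_out,
                    "f": i.f_stat,
                }
            )
        return pd.DataFrame(rows, columns=list(INSTRUMENT_COLUMNS))


# ---------------------------------------------------------------------------
# readers / writers

#: default header names recognised without an explicit column_map, per field
_DEFAULT_COLUMN_ALIASES = {
    "snp_id": ("snp", "snp_id", "rsid", "id", "markername"),
    "chrom": ("chr", "chrom", "chromosome"),
    "effect_allele": ("ea", "effect_allele", "a1", "allele1"),
    "other_allele": ("oa", "other_allele", "a2", "allele2"),
    "eaf": ("eaf", "af", "effect_allele_freq", "freq"),
    "beta": ("beta", "b", "effect"),
    "se": ("se", "stderr", "standard_error"),
    "pvalue": ("p", "pvalue", "pval", "p_value"),
    "n": ("n", "samplesize", "n_total"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
}
_REQUIRED_FIELDS = ("snp_id", "chrom", "effect_allele", "other_allele", "beta", "se", "pvalue")
_NA_STRINGS = {"", "na", "nan", "none", "."}


def _resolve_columns(header: list[str], column_map: dict | None) -> dict[str, str]:
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for fld, aliases in _DEFAULT_COLUMN_ALIASES.items():
        if fld in column_map:
            col = column_map[fld]
            if col not in header:
                raise ConfigurationError(f"column {col!r} (mapped for field {fld!r}) not in header {header}")
            resolved[fld] = col
        else:
            for a in aliases:
                if a in lower:
                    resolved[fld] = lower[a]
                    break
    missing = [f for f in _REQUIRED_FIELDS if f not in resolved]
    if missing:
        raise ConfigurationError(f"required column(s) not found or mapped: {missing}; header is {header}")
    return resolved


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip().lower() in _NA_STRINGS:
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(round(v))


def read_sumstats(
    path,
    column_map: dict | None = None,
    *,
    delimiter: str | None = None,
    on_invalid: str = "raise",
):
    """Read GWAS summary statistics from a TSV/CSV file with a header row.

    ``column_map`` maps field names (``snp_id``, ``chrom``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se``, ``pvalue``, optionally ``eaf``, ``n``,
    ``pos``) to header names; common aliases are recognised automatically.
    Alleles are upper-cased.  Rows failing type or range validation are
    rejected with their 1-based data-row number: ``on_invalid="raise"`` raises
    :class:`RowValidationError`, ``on_invalid="collect"`` returns
    ``(records, rejected)`` where ``rejected`` maps row numbers to messages.
    """
    if on_invalid not in ("raise", "collect"):
        raise ConfigurationError(f"on_invalid must be 'raise' or 'collect', got {on_invalid!r}")
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(df.columns), column_map)
    records: list[GwasRecord] = []
    rejected: dict[int, str] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        try:
            records.append(
                GwasRecord(
                    snp_id=str(raw[cols["snp_id"]]).strip(),
                    chrom=str(raw[cols["chrom"]]).strip(),
                    effect_allele=str(raw[cols["effect_allele"]]).strip().upper(),
                    other_allele=str(raw[cols["other_allele"]]).strip().upper(),
                    beta=float(raw[cols["beta"]]),
                    se=float(raw[cols["se"]]),
                    pvalue=float(raw[cols["pvalue"]]),
                    eaf=_opt_float(raw[cols["eaf"]]) if "eaf" in cols else None,
                    n=_opt_int(raw[cols["n"]]) if "n" in cols else None,
                    pos=_opt_int(raw[cols["pos"]]) if "pos" in cols else None,
                )
            )
        except (ValueError, TypeError) as exc:
            rejected[idx] = str(exc)
    if on_invalid == "collect":
        return records, rejected
    if rejected:
        raise RowValidationError(rejected)
    return records


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, str):
        return value
    return f"{value:.10g}"


def write_instruments(instr: InstrumentSet, path) -> None:
    """Write a harmonized-instrument table as TSV in the canonical column order.

    Numbers are written with 10 significant digits so that
    ``read_instruments(write_instruments(x)) == x`` field for field; missing
    optional fields are serialized as ``NA``.
    """
    instr.validate()
    lines = ["\t".join(INSTRUMENT_COLUMNS)]
    for i in instr.instruments:
        lines.append(
            "\t".join(
                [
                    i.snp_id, i.chrom, i.effect_allele, i.other_allele, _fmt(i.eaf_exposure),
                    _fmt(i.beta_exp), _fmt(i.se_exp), _fmt(i.p_exp),
                    _fmt(i.beta_out), _fmt(i.se_out), _fmt(i.p_out), _fmt(i.f_stat),
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_instruments(path, exposure_name: str = "exposure", outcome_name: str = "outcome") -> InstrumentSet:
    """Read a harmonized-instrument TSV written by :func:`write_instruments`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in INSTRUMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"instrument table missing column(s): {missing}")
    instruments = []
    for row in df.itertuples(index=False):
        raw = dict(zip(df.columns, row))
        instruments.append(
            HarmonizedInstrument(
                snp_id=raw["snp"].strip(),
                chrom=raw["chr"].strip(),
                effect_allele=raw["ea"].strip().upper(),
                other_allele=raw["oa"].strip().upper(),
                eaf_exposure=_opt_float(raw["eaf"]),
                beta_exp=float(raw["beta_exp"]),
                se_exp=float(raw["se_exp"]),
                p_exp=float(raw["p_exp"]),
                beta_out=float(raw["beta_out"]),
                se_out=float(raw["se_out"]),
                p_out=float(raw["p_out"]),
                f_stat=_opt_float(raw["f"]),
            )
        )
    return InstrumentSet(instruments, exposure_name=exposure_name, outcome_name=outcome_name)


def load_metformin_ra_instruments() -> InstrumentSet:
    """The bundled 32-instrument metformin-use / rheumatoid-arthritis table.

    These are the genome-wide-significant (p < 5e-8), LD-independent,
    non-palindromic instruments of the published metformin-use GWAS
    (ukb-b-14609), harmonized to the Okada et al. rheumatoid-arthritis
    meta-analysis (ieu-a-832), with the published per-SNP F statistics.
    Exposure betas are on the linear 0/1 treatment scale; outcome betas are
    log odds of RA.
    """
    ref = resources.files("metformin_ra_mr").joinpath("data/metformin_ra_instruments.tsv")
    with resources.as_file(ref) as path:
        instr = read_instruments(path, exposure_name="metformin use", outcome_name="rheumatoid arthritis")
    instr.note("bundled published instrument table (32 SNPs)")
    return instr
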