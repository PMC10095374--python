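"""Instrument selection and quality filters.

A valid genetic instrument must be robustly associated with the exposure and
statistically independent of the other instruments.  This module implements
the standard selection funnel for two-sample MR:

1. genome-wide significance (p < 5e-8, strict);
2. LD clumping (greedy by p, pairwise r-squared < 0.001 within 5000 kb);
3. per-SNP instrument-strength F statistic, excluding F < 10 as weak;
4. Steiger directionality filtering (drop SNPs that explain more variance in
   the outcome than in the exposure, a signature of reverse causation).

LD is never computed here: callers supply any pairwise r-squared source
through the :class:`LdProvider` contract (e.g. a precomputed matrix), or fall
back to a distance-only rule when positions are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, MrError
from .sumstats_io import Drop, GwasRecord, HarmonizedInstrument, InstrumentSet

__all__ = [
    "ClumpConfig",
    "LdProvider",
    "MatrixLdProvider",
    "select_significant",
    "ld_clump",
    "f_from_p",
    "f_from_beta_se",
    "f_statistic",
    "filter_weak",
    "steiger_filter",
]


@dataclass(frozen=True)
class ClumpConfig:
    """Selection thresholds: significance cutoff, LD r² cutoff, distance window."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 5000.0

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must lie in [0, 1]")
        if not self.window_kb > 0:
            raise ValueError("window_kb must be positive")


class LdProvider(Protocol):
    """Pairwise LD source: returns r² in [0, 1], or ``None`` when unknown."""

    def r2(self, snp_a: str, snp_b: str) -> float | None:  # pragma: no cover - contract
        ...


class MatrixLdProvider:
    """LD provider backed by a square r² matrix keyed by rsID.

    Accepts a nested dict ``{a: {b: r2}}`` or a labelled square DataFrame.
    Symmetry is enforced by lookup in both orders; the diagonal is 1.
    """

    def __init__(self, matrix):
        if isinstance(matrix, pd.DataFrame):
            self._m = {a: {b: float(matrix.loc[a, b]) for b in matrix.columns} for a in matrix.index}
        else:
            self._m = {a: dict(row) for a, row in matrix.items()}

    @classmethod
    def from_tsv(cls, path) -> "MatrixLdProvider":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def r2(self, snp_a: str, snp_b: str) -> float | None:
        if snp_a == snp_b:
            return 1.0
        v = self._m.get(snp_a, {}).get(snp_b)
        if v is None:
            v = self._m.get(snp_b, {}).get(snp_a)
        return None if v is None else float(v)


def select_significant(records, p_threshold: float = 5e-8):
    """Keep records with p strictly below the genome-wide threshold."""
    return [r for r in records if r.pvalue < p_threshold]


def _clump_order(records):
    # ascending p; ties broken lexicographically by rsID for determinism
    return sorted(records, key=lambda r: (r.pvalue, r.snp_id))


def ld_clump(records, cfg: ClumpConfig | None = None, ld: LdProvider | None = None):
    """Greedy LD clumping: scan SNPs in order of ascending p and keep each one
    only if it is not in LD (r² >= threshold) with any already-kept SNP.

    With an :class:`LdProvider`, pairs with known r² use the r² rule; pairs
    with unknown r² (and any pair when ``ld`` is None) use the distance rule:
    reject if a kept SNP on the same chromosome lies within ``window_kb``.
    Distance-only mode requires positions on the records.  Duplicate input
    rows (same rsID) beyond the first are ignored.
    """
    cfg = cfg or ClumpConfig()
    kept: list = []
    seen: set[str] = set()
    for rec in _clump_order(records):
        if rec.snp_id in seen:
            continue
        seen.add(rec.snp_id)
        independent = True
        for acc in kept:
            r2 = ld.r2(rec.snp_id, acc.snp_id) if ld is not None else None
            if r2 is not None:
                if r2 >= cfg.r2_threshold:
                    independent = False
                    break
            else:
                if rec.pos is None or acc.pos is None:
                    raise ConfigurationError(
                        f"no LD information for pair ({rec.snp_id}, {acc.snp_id}) and no positions "
                        "for the distance-only rule"
                    )
                if rec.chrom == acc.chrom and abs(rec.pos - acc.pos) <= cfg.window_kb * 1000:
                    independent = False
                    break
        if independent:
            kept.append(rec)
    return kept


def f_from_p(pvalue: float) -> float:
    """Instrument-strength F recovered from a two-sided p-value as z².

    z is the upper-tail standard-normal quantile at p/2, evaluated through the
    tail inverse so precision holds down to p ~ 1e-300.
    """
    if not (0 < pvalue <= 1):
        raise MrError(f"pvalue must lie in (0, 1], got {pvalue}")
    z = stats.norm.isf(pvalue / 2.0)
    return float(z * z)


def f_from_beta_se(beta: float, se: float) -> float:
    """Instrument-strength F as the squared Wald z = (beta/se)²."""
    if not se > 0:
        raise MrError("se must be positive")
    return float((beta / se) ** 2)


def f_statistic(instr: HarmonizedInstrument, mode: str = "from_p") -> float:
    """Per-SNP F statistic from the exposure association.

    ``from_p`` (default) inverts the exposure p-value; ``from_beta_se``
    squares the reported beta/se ratio.  On exact inputs the two agree; on
    a table rounded to few decimals ``from_p`` is the more faithful choice
    because printed p-values usually carry more relative precision.
    """
    if mode == "from_p":
        return f_from_p(instr.p_exp)
    if mode == "from_beta_se":
        return f_from_beta_se(instr.beta_exp, instr.se_exp)
    raise ConfigurationError(f"unknown F mode {mode!r}")


def filter_weak(instrs: InstrumentSet, f_min: float = 10.0, mode: str = "from_p") -> InstrumentSet:
    """Annotate every instrument with its F statistic and drop those below ``f_min``.

    Idempotent: re-running on the filtered output changes nothing.
    """
    kept = []
    weak = []
    for inst in instrs:
        f = f_statistic(inst, mode)
        inst = replace(inst, f_stat=f)
        if f < f_min:
            weak.append((inst.snp_id, f))
        else:
            kept.append(inst)
    out = InstrumentSet(
        kept,
        exposure_name=instrs.exposure_name,
        outcome_name=instrs.outcome_name,
        provenance=list(instrs.provenance),
        notes=list(instrs.notes),
    )
    for snp_id, f in weak:
        out.provenance.append(Drop(snp_id, "weak_instrument", f"F = {f:.4g} < {f_min:g}"))
    out.validate()
    out.note(f"weak-instrument filter (F >= {f_min:g}, mode={mode}): dropped {len(weak)}")
    return out


def _steiger_r2(z: float, n: int) -> float:
    # variance explained approximated from the Wald z and sample size
    return z * z / (z * z + n - 2)


def steiger_filter(
    instrs: InstrumentSet, n_exp: int | None = None, n_out: int | None = None
) -> InstrumentSet:
    """Directionality filter: keep a SNP only if it explains strictly more
    variance in the exposure than in the outcome (r²_X > r²_Y, with
    r² = z²/(z² + n − 2)).

    Sample sizes come from the instruments themselves when present, else from
    the ``n_exp``/``n_out`` arguments.  If either is unavailable for a SNP the
    whole filter is skipped with a warning (the decision is undefined without
    n), returning the set unchanged.
    """
    sizes = []
    for inst in instrs:
        ne = inst.n_exp if inst.n_exp is not None else n_exp
        no = inst.n_out if inst.n_out is not None else n_out
        if ne is None or no is None:
            warnings.warn(
                "Steiger filtering skipped: sample sizes unavailable for "
                f"{inst.snp_id} (and possibly others)",
                stacklevel=2,
            )
            out = InstrumentSet(
                list(instrs.instruments),
                exposure_name=instrs.exposure_name,
                outcome_name=instrs.outcome_name,
                provenance=list(instrs.provenance),
                notes=list(instrs.notes),
            )
            out.note("Steiger filter skipped (missing sample sizes)")
            return out
        sizes.append((ne, no))
    kept, dropped = [], []
    for inst, (ne, no) in zip(instrs, sizes):
        r2x = _steiger_r2(inst.beta_exp / inst.se_exp, ne)
        r2y = _steiger_r2(inst.beta_out / inst.se_out, no)
        if r2x > r2y:
            kept.append(inst)
        else:
            dropped.append((inst.snp_id, r2x, r2y))
    out = InstrumentSet(
        kept,
        exposure_name=instrs.exposure_name,
        outcome_name=instrs.outcome_name,
        provenance=list(instrs.provenance),
        notes=list(instrs.notes),
    )
    for snp_id, r2x, r2y in dropped:
        out.provenance.append(Drop(snp_id, "steiger_reverse", f"r2_exposure {r2x:.3g} <= r2_outcome {r2y:.3g}"))
    out.validate()
    out.note(f"Steiger directionality filter: dropped {len(dropped)}")
    return out
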