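"""Selection funnel: significance, LD clumping, F statistics, Steiger filter."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metformin_ra_mr.errors import ConfigurationError, MrError
from metformin_ra_mr.instruments import (
    ClumpConfig,
    MatrixLdProvider,
    f_from_beta_se,
    f_from_p,
    f_statistic,
    filter_weak,
    ld_clump,
    select_significant,
    steiger_filter,
)
from metformin_ra_mr.sumstats_io import InstrumentSet

from conftest import make_instrument, make_record


# --- significance ----------------------------------------------------------

def test_select_significant_strict_inequality():
    recs = [make_record("rs1", pvalue=5e-8), make_record("rs2", pvalue=4.9e-8)]
    kept = select_significant(recs, 5e-8)
    assert [r.snp_id for r in kept] == ["rs2"]


def test_select_significant_empty():
    assert select_significant([], 5e-8) == []


def test_bundled_instruments_all_genome_wide(bundled_instruments):
    assert all(i.p_exp < 5e-8 for i in bundled_instruments)


# --- LD clumping -----------------------------------------------------------

def _greedy_oracle(records, r2, threshold):
    """Independent greedy reference: enumerate all subsets and return the one
    that is consistent with the greedy criterion applied in p-order."""
    ordered = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    n = len(ordered)
    consistent = []
    for bits in itertools.product([0, 1], repeat=n):
        ok = True
        chosen: list = []
        for i, rec in enumerate(ordered):
            independent = all(r2[rec.snp_id][c.snp_id] < threshold for c in chosen)
            if bool(bits[i]) != independent:
                ok = False
                break
            if bits[i]:
                chosen.append(rec)
        if ok:
            consistent.append([r.snp_id for r in ordered if bits[ordered.index(r)]])
    assert len(consistent) == 1  # the greedy trace is unique
    return consistent[0]


def test_clump_matches_exhaustive_oracle_at_j10():
    rng = np.random.default_rng(42)
    records = [make_record(f"rs{k:02d}", pvalue=float(rng.uniform(1e-12, 1e-8))) for k in range(10)]
    ids = [r.snp_id for r in records]
    m = rng.uniform(0, 1, (10, 10)) ** 2
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    r2 = {a: {b: float(m[i, j]) for j, b in enumerate(ids)} for i, a in enumerate(ids)}
    threshold = 0.3
    kept = ld_clump(records, ClumpConfig(r2_threshold=threshold), MatrixLdProvider(r2))
    assert sorted(r.snp_id for r in kept) == sorted(_greedy_oracle(records, r2, threshold))


def test_clump_perfectly_linked_pair_keeps_most_significant():
    a = make_record("rsA", pvalue=1e-10)
    b = make_record("rsB", pvalue=1e-9)
    ld = MatrixLdProvider({"rsA": {"rsB": 1.0}})
    kept = ld_clump([b, a], ClumpConfig(r2_threshold=0.001), ld)
    assert [r.snp_id for r in kept] == ["rsA"]


def test_clump_all_independent_keeps_all():
    recs = [make_record(f"rs{k}", pvalue=10 ** -(9 + k)) for k in range(5)]
    ld = MatrixLdProvider({r.snp_id: {s.snp_id: 0.0 for s in recs} for r in recs})
    assert len(ld_clump(recs, ld=ld)) == 5


def test_clump_duplicate_rows_ignored():
    rec = make_record("rs1", pvalue=1e-10, pos=100)
    kept = ld_clump([rec, rec], ClumpConfig())
    assert len(kept) == 1


def test_clump_distance_fallback():
    a = make_record("rsA", chrom="1", pvalue=1e-12, pos=1_000_000)
    b = make_record("rsB", chrom="1", pvalue=1e-10, pos=2_000_000)       # within 5000 kb of a
    c = make_record("rsC", chrom="1", pvalue=1e-9, pos=20_000_000)       # far away
    d = make_record("rsD", chrom="2", pvalue=1e-8, pos=1_000_000)        # other chromosome
    kept = ld_clump([a, b, c, d])
    assert [r.snp_id for r in kept] == ["rsA", "rsC", "rsD"]


def test_clump_distance_mode_without_positions_is_config_error():
    with pytest.raises(ConfigurationError):
        ld_clump([make_record("rs1", pvalue=1e-10), make_record("rs2", pvalue=1e-9)])


def test_clump_output_is_antichain():
    rng = np.random.default_rng(7)
    recs = [make_record(f"rs{k}", pvalue=float(rng.uniform(1e-12, 1e-8))) for k in range(12)]
    ids = [r.snp_id for r in recs]
    m = rng.uniform(0, 0.8, (12, 12)); m = (m + m.T) / 2; np.fill_diagonal(m, 1.0)
    ld = MatrixLdProvider({a: {b: float(m[i, j]) for j, b in enumerate(ids)} for i, a in enumerate(ids)})
    cfg = ClumpConfig(r2_threshold=0.25)
    kept = ld_clump(recs, cfg, ld)
    for x, y in itertools.combinations(kept, 2):
        assert ld.r2(x.snp_id, y.snp_id) < cfg.r2_threshold


# --- F statistics ----------------------------------------------------------

def test_f_from_p_matches_exact_quantile_inversion():
    """Frozen against high-precision inversion (cross-checked with R qnorm)."""
    assert f_from_p(6.100e-9) == pytest.approx(33.80251352122072, abs=1e-8)
    assert f_from_p(1.099e-127) == pytest.approx(577.8534630145489, abs=1e-6)


def test_f_from_beta_se_unit_ratio():
    assert f_from_beta_se(0.004, 0.004) == pytest.approx(1.0)


def test_f_from_p_rejects_zero():
    with pytest.raises(MrError):
        f_from_p(0.0)


@given(st.floats(1e-300, 0.999, allow_subnormal=False), st.floats(1.001, 5.0, allow_subnormal=False))
def test_f_from_p_strictly_decreasing(p, factor):
    p2 = min(p * factor, 1.0)
    if p2 > p:
        assert f_from_p(p2) < f_from_p(p)


@given(st.floats(0.5, 20.0, allow_subnormal=False), st.booleans())
def test_f_modes_agree_on_unrounded_inputs(z, negative):
    """from_p and from_beta_se agree to 6 significant figures when the
    p-value is computed exactly from beta/se (no table rounding)."""
    from scipy import stats
    beta = (-z if negative else z) * 0.001
    se = 0.001
    p = 2 * stats.norm.sf(abs(beta) / se)
    inst = make_instrument(beta_exp=beta, se_exp=se, p_exp=p)
    assert f_statistic(inst, "from_p") == pytest.approx(f_statistic(inst, "from_beta_se"), rel=1e-6)


def test_filter_weak_drops_below_threshold_and_annotates():
    strong = make_instrument("rsS", p_exp=1e-10)
    weak = make_instrument("rsW", p_exp=2e-3)   # F ~ 9.5 < 10
    out = filter_weak(InstrumentSet([strong, weak]), f_min=10)
    assert out.snp_ids == ["rsS"]
    assert out["rsS"].f_stat == pytest.approx(f_from_p(1e-10))
    (drop,) = [d for d in out.provenance if d.reason == "weak_instrument"]
    assert drop.snp_id == "rsW"


def test_filter_weak_identity_at_zero_threshold():
    s = InstrumentSet([make_instrument("rs1", p_exp=0.9)])
    assert filter_weak(s, f_min=0).snp_ids == ["rs1"]


def test_filter_weak_idempotent(bundled_instruments):
    once = filter_weak(bundled_instruments)
    twice = filter_weak(once)
    assert once.snp_ids == twice.snp_ids
    assert [i.f_stat for i in once] == [i.f_stat for i in twice]


def test_bundled_instruments_all_strong(bundled_instruments):
    out = filter_weak(bundled_instruments)
    assert len(out) == 32
    assert min(i.f_stat for i in out) >= 10


# --- Steiger ---------------------------------------------------------------

def _r2_of(z, n):
    return z * z / (z * z + n - 2)


def test_steiger_keeps_forward_causal_snp():
    """Hand-computed variance-explained comparison at the study sample sizes."""
    inst = make_instrument(beta_exp=5.8 * 0.001, se_exp=0.001, p_exp=1e-8,
                           beta_out=2.0 * 0.02, se_out=0.02)
    s = steiger_filter(InstrumentSet([inst]), n_exp=462933, n_out=58284)
    assert _r2_of(5.8, 462933) > _r2_of(2.0, 58284)
    assert s.snp_ids == ["rs1"]


def test_steiger_boundary_equal_r2_dropped():
    inst = make_instrument(beta_exp=0.005, se_exp=0.001, p_exp=1e-6,
                           beta_out=0.1, se_out=0.02)  # z equal, n equal
    s = steiger_filter(InstrumentSet([inst]), n_exp=10000, n_out=10000)
    assert len(s) == 0
    assert s.provenance[0].reason == "steiger_reverse"


def test_steiger_monotone_in_z_at_fixed_n():
    inst = make_instrument(beta_exp=0.006, se_exp=0.001, p_exp=1e-9,
                           beta_out=0.04, se_out=0.02)  # |z_X|=6 > |z_Y|=2
    s = steiger_filter(InstrumentSet([inst]), n_exp=5000, n_out=5000)
    assert len(s) == 1


def test_steiger_missing_n_skips_with_warning(bundled_instruments):
    with pytest.warns(UserWarning, match="Steiger"):
        out = steiger_filter(bundled_instruments)
    assert out.snp_ids == bundled_instruments.snp_ids
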