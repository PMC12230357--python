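"""Instrument selection, greedy clumping and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

import mrpath.instruments as instr
from mrpath.errors import EmptyIntersectionError, NoInstrumentsError
from mrpath.estimators import ivw
from mrpath.instruments import FORWARD, REVERSE, InstrumentConfig, harmonize, select_instruments
from conftest import make_sumstats


def _exposure(pvals, **kw):
    rows = [
        {
            "snp": f"rs{i}",
            "effect_allele": "A",
            "other_allele": "G",
            "beta": 0.1,
            "se": 0.01,
            "pval": p,
        }
        for i, p in enumerate(pvals)
    ]
    return make_sumstats("exp", rows)


def test_p_threshold_counts():
    exp = _exposure([1e-9, 1e-7, 1e-6, 1e-4, 0.5])
    kept = select_instruments(exp, InstrumentConfig(p_threshold=5e-8))
    assert kept.nsnp == 1
    assert kept.data.loc[0, "snp"] == "rs0"


def test_reverse_preset_is_relaxed():
    exp = _exposure([1e-9, 1e-7, 1e-5])
    assert select_instruments(exp, FORWARD).nsnp == 1
    assert select_instruments(exp, REVERSE).nsnp == 2
    assert REVERSE.p_threshold == 5e-6


def test_uncorrelated_snps_all_kept():
    exp = _exposure([1e-9, 1e-9, 1e-9])
    ld = pd.DataFrame(np.eye(3), index=["rs0", "rs1", "rs2"], columns=["rs0", "rs1", "rs2"])
    assert select_instruments(exp, FORWARD, ld=ld).nsnp == 3


def test_no_instruments_is_typed_error():
    with pytest.raises(NoInstrumentsError):
        select_instruments(_exposure([0.1, 0.2]), FORWARD)


def test_missing_ld_and_positions_warns_independence(caplog):
    with caplog.at_level("WARNING"):
        select_instruments(_exposure([1e-9, 1e-9]), FORWARD)
    assert any("independence assumed" in r.message for r in caplog.records)


def _greedy_clump_oracle(pvals, r2, r2_max):
    """Independent re-implementation: walk by ascending p, keep unless in
    LD with a kept SNP."""
    order = np.argsort(pvals, kind="stable")
    kept = []
    for i in order:
        if all(r2[i, j] < r2_max for j in kept):
            kept.append(i)
    return sorted(kept)


@pytest.mark.parametrize("seed", range(8))
def test_greedy_clumping_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 10
    pvals = rng.uniform(1e-12, 1e-9, n)
    a = rng.uniform(0, 1, (n, n))
    r2 = (a + a.T) / 2
    np.fill_diagonal(r2, 1.0)
    ids = [f"rs{i}" for i in range(n)]
    exp = _exposure(pvals)
    ld = pd.DataFrame(r2, index=ids, columns=ids)
    cfg = InstrumentConfig(p_threshold=1e-5, r2_max=0.4)
    kept = select_instruments(exp, cfg, ld=ld)
    expected = [ids[i] for i in _greedy_clump_oracle(pvals, r2, 0.4)]
    assert sorted(kept.data["snp"]) == sorted(expected)


def test_position_window_clumping():
    exp = _exposure([1e-9, 1e-10, 1e-11])
    pos = pd.DataFrame(
        {"snp": ["rs0", "rs1", "rs2"], "chrom": [1, 1, 2], "bp": [1_000_000, 2_000_000, 1_500_000]}
    )
    cfg = InstrumentConfig(window_kb=10_000)
    kept = select_instruments(exp, cfg, positions=pos)
    # rs2 (best p) kept; rs1 next kept (other chrom); rs0 within 10Mb of rs1
    assert sorted(kept.data["snp"]) == ["rs1", "rs2"]


def _pair(exp_alleles, out_alleles, beta_out=0.05, eaf_exp=0.2, eaf_out=0.2):
    exp = make_sumstats(
        "exp",
        [
            {
                "snp": "rs1",
                "effect_allele": exp_alleles[0],
                "other_allele": exp_alleles[1],
                "eaf": eaf_exp,
                "beta": 0.1,
                "se": 0.01,
                "pval": 1e-9,
            }
        ],
    )
    out = make_sumstats(
        "out",
        [
            {
                "snp": "rs1",
                "effect_allele": out_alleles[0],
                "other_allele": out_alleles[1],
                "eaf": eaf_out,
                "beta": beta_out,
                "se": 0.02,
                "pval": 0.01,
            }
        ],
    )
    return exp, out


@pytest.mark.parametrize(
    "exp_a,out_a,eaf_out,action,beta",
    [
        (("A", "G"), ("A", "G"), 0.2, "kept", 0.05),
        (("A", "G"), ("G", "A"), 0.8, "flipped", -0.05),
        (("A", "G"), ("T", "C"), 0.2, "kept", 0.05),  # complementary strand
        (("A", "G"), ("C", "T"), 0.8, "flipped", -0.05),
        (("A", "G"), ("A", "C"), 0.2, "dropped-mismatch", 0.05),
        (("A", "T"), ("A", "T"), 0.2, "kept", 0.05),  # palindromic, clear eaf
        (("A", "T"), ("A", "T"), 0.8, "flipped", -0.05),  # eaf sides disagree
    ],
)
def test_harmonize_actions(exp_a, out_a, eaf_out, action, beta):
    exp, out = _pair(exp_a, out_a, eaf_out=eaf_out)
    h = harmonize(exp, out, "infer")
    assert h.data.loc[0, "action"] == action
    if action in ("kept", "flipped"):
        assert h.data.loc[0, "beta_out"] == pytest.approx(beta)


def test_palindromic_ambiguous_eaf_dropped():
    exp, out = _pair(("A", "T"), ("A", "T"), eaf_exp=0.50, eaf_out=0.50)
    h = harmonize(exp, out, "infer")
    assert h.data.loc[0, "action"] == "dropped-palindromic"
    assert h.nsnp == 0


def test_palindromic_policies():
    exp, out = _pair(("C", "G"), ("C", "G"), eaf_exp=0.5, eaf_out=0.5)
    assert harmonize(exp, out, "drop").nsnp == 0
    assert harmonize(exp, out, "keep").nsnp == 1
    assert harmonize(exp, out, "infer").nsnp == 0


def test_missing_eaf_palindromic_dropped_under_infer():
    exp, out = _pair(("A", "T"), ("A", "T"))
    exp.data["eaf"] = np.nan
    h = harmonize(exp, out, "infer")
    assert h.data.loc[0, "action"] == "dropped-palindromic"


def test_self_harmonization_keeps_everything():
    rng = np.random.default_rng(0)
    rows = []
    pairs = [("A", "G"), ("C", "T"), ("G", "T")]
    for i in range(9):
        ea, oa = pairs[i % 3]
        rows.append(
            {
                "snp": f"rs{i}",
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": float(rng.uniform(0.1, 0.9)),
                "beta": float(rng.normal()),
                "se": 0.01,
                "pval": 1e-9,
            }
        )
    s = make_sumstats("t", rows)
    h = harmonize(s, s)
    assert (h.data["action"] == "kept").all()
    assert np.allclose(h.data["beta_out"], h.data["beta_exp"])


def test_empty_intersection_is_typed_error():
    exp, out = _pair(("A", "G"), ("A", "G"))
    out.data["snp"] = ["rs999"]
    with pytest.raises(EmptyIntersectionError):
        harmonize(exp, out)


def test_flip_involution_and_estimate_invariance():
    """Pre-flipping the outcome table's orientation must not change IVW."""
    rng = np.random.default_rng(42)
    n = 20
    pairs = [("A", "G"), ("C", "T")]
    exp_rows, out_rows, out_rows_flipped = [], [], []
    for i in range(n):
        ea, oa = pairs[i % 2]
        bx = rng.uniform(0.05, 0.2)
        by = 0.5 * bx + rng.normal(0, 0.01)
        eaf = float(rng.uniform(0.1, 0.9))
        exp_rows.append(
            {"snp": f"rs{i}", "effect_allele": ea, "other_allele": oa,
             "eaf": eaf, "beta": bx, "se": 0.01, "pval": 1e-9}
        )
        out_rows.append(
            {"snp": f"rs{i}", "effect_allele": ea, "other_allele": oa,
             "eaf": eaf, "beta": by, "se": 0.01, "pval": 0.01}
        )
        out_rows_flipped.append(
            {"snp": f"rs{i}", "effect_allele": oa, "other_allele": ea,
             "eaf": 1 - eaf, "beta": -by, "se": 0.01, "pval": 0.01}
        )
    exp = make_sumstats("exp", exp_rows)
    h1 = harmonize(exp, make_sumstats("out", out_rows))
    h2 = harmonize(exp, make_sumstats("out", out_rows_flipped))
    assert (h2.data["action"] == "flipped").all()
    assert ivw(h1, "fixed").beta == pytest.approx(ivw(h2, "fixed").beta, abs=1e-14)
    # involution: flipping twice restores the original orientation
    assert np.allclose(h1.kept["beta_out"], h2.kept["beta_out"])
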