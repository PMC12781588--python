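"""Variant classification, domain annotation, and Fisher burden testing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import episignkit as ek
from episignkit.errors import ValidationError
from episignkit.variants import (
    DEFAULT_PP3_THRESHOLDS, TIERS, add_pp3_tiers, _tool_tier,
    STUDY_N_CASES, STUDY_N_CONTROLS,
)


def _variant_row(**kwargs):
    base = {
        "sample_id": "s1", "cohort": "case", "gene": "G",
        "hgvs_c": "c.1A>G", "hgvs_p": "p.(A1V)",
        "consequence": "missense", "residue_start": 100, "residue_end": 100,
        "ref_aa": "A", "alt_aa": "V",
        "mac_gnomad": 0, "mac_internal": 0, "mac_ukbb": 0,
        "cadd": np.nan, "revel": np.nan, "mpc": np.nan, "spliceai": np.nan,
    }
    base.update(kwargs)
    return base


def _table(rows):
    return pd.DataFrame(rows)


def test_ultrarare_filter():
    df = _table(
        [
            _variant_row(sample_id="keep", mac_gnomad=2, mac_internal=0, mac_ukbb=1),
            _variant_row(sample_id="drop", mac_gnomad=17),
            _variant_row(sample_id="zero"),
        ]
    )
    out = ek.filter_ultrarare(df)
    assert set(out["sample_id"]) == {"keep", "zero"}
    with pytest.raises(ValidationError):
        ek.filter_ultrarare(_table([_variant_row(mac_gnomad=-1)]))


def test_collapse_classes_and_splice_flag():
    df = ek.collapse_class(
        _table(
            [
                _variant_row(consequence="stop_gained"),
                _variant_row(consequence="frameshift"),
                _variant_row(consequence="splice_acceptor"),
                _variant_row(consequence="missense", spliceai=0.62),
                _variant_row(consequence="inframe_indel"),
                _variant_row(consequence="synonymous"),
                _variant_row(consequence="start_lost"),
            ]
        )
    )
    assert list(df["variant_class"]) == ["PTV", "PTV", "PTV", "PAV", "PAV", "SYN", "other"]
    assert df["splice_altering"].tolist() == [False, False, False, True, False, False, False]


def test_pp3_unanimous_strong():
    thresholds = {
        "revel": {"supporting": 0.3, "moderate": 0.5, "strong": 0.9},
        "cadd": {"supporting": 20.0, "moderate": 25.0, "strong": 30.0},
        "mpc": {"supporting": 1.0, "moderate": 2.0, "strong": 3.0},
    }
    v = _variant_row(revel=0.95, cadd=31.0, mpc=3.1)
    assert ek.pp3_tier(v, thresholds) == "strong"


def test_pp3_tie_resolves_to_weaker():
    thresholds = {
        "revel": {"supporting": 0.3, "moderate": 0.5, "strong": 0.9},
        "cadd": {"supporting": 20.0, "moderate": 25.0, "strong": 30.0},
    }
    v = _variant_row(revel=0.95, cadd=1.0)  # strong vs neutral
    assert ek.pp3_tier(v, thresholds) == "neutral"


def test_pp3_no_scores_warns_neutral():
    with pytest.warns(UserWarning):
        assert ek.pp3_tier(_variant_row()) == "neutral"


def test_pp3_matches_brute_force_reimplementation():
    rng = np.random.default_rng(6)
    for _ in range(100):
        v = _variant_row(
            revel=float(rng.uniform(0, 1)),
            cadd=float(rng.uniform(0, 40)),
            mpc=float(rng.uniform(0, 3)),
        )
        # independent ladder + modal-tier reimplementation
        per_tool = []
        for tool, ladder in DEFAULT_PP3_THRESHOLDS.items():
            tier = "neutral"
            for t in ("supporting", "moderate", "strong"):
                cut = ladder.get(t)
                if cut is not None and v[tool] >= cut:
                    tier = t
            per_tool.append(tier)
        counts = {t: per_tool.count(t) for t in set(per_tool)}
        modal = [t for t, c in counts.items() if c == max(counts.values())]
        expected = min(modal, key=TIERS.index)
        assert ek.pp3_tier(v) == expected


def test_domain_effect_flags():
    model = ek.load_domain_model()
    df = ek.collapse_class(
        _table(
            [
                _variant_row(hgvs_p="p.(Cys332Tyr)", residue_start=332, ref_aa="C", alt_aa="Y"),
                _variant_row(hgvs_p="p.(Arg353Cys)", residue_start=353, ref_aa="R", alt_aa="C"),
                _variant_row(hgvs_p="p.(A424V)", residue_start=424),
                _variant_row(hgvs_p="p.(A1000V)", residue_start=1000),
            ]
        )
    )
    ann = ek.annotate_domain_effects(df, model)
    assert ann["disulfide_disrupted"].tolist() == [True, False, False, False]
    assert ann["novel_cysteine"].tolist() == [False, True, False, False]
    assert ann["near_ligand_site"].tolist() == [False, False, True, False]
    assert bool(ann["in_egf_repeat"].iloc[0])
    with pytest.raises(ValidationError):
        ek.annotate_domain_effects(
            ek.collapse_class(_table([_variant_row(residue_start=99999)])), model
        )


def test_carrier_table_counts_each_sample_once():
    model = ek.load_domain_model()
    rows = [
        _variant_row(sample_id=f"case{i}", consequence="stop_gained") for i in range(17)
    ]
    rows.append(_variant_row(sample_id="case0", consequence="frameshift"))  # 2nd variant
    rows.append(_variant_row(sample_id="ctrl0", cohort="control", consequence="stop_gained"))
    df = ek.collapse_class(_table(rows))
    scenario = [s for s in ek.default_scenarios() if s.name == "PTVs"][0]
    table = ek.carrier_table(df, scenario, STUDY_N_CASES, STUDY_N_CONTROLS)
    assert table == (17, 3890, 1, 5156)


def test_carrier_table_matches_brute_force_scan():
    rates = {"PTV": (0.02, 0.005), "SYN": (0.01, 0.01)}
    tab = ek.generate_variant_cohort(400, 600, rates, seed=14)
    df = ek.collapse_class(tab)
    scenario = [s for s in ek.default_scenarios() if s.name == "PTVs"][0]
    a, b, c, d = ek.carrier_table(df, scenario, 400, 600)
    case_carriers = {
        r["sample_id"] for _, r in df.iterrows()
        if r["cohort"] == "case" and r["variant_class"] == "PTV"
    }
    ctrl_carriers = {
        r["sample_id"] for _, r in df.iterrows()
        if r["cohort"] == "control" and r["variant_class"] == "PTV"
    }
    assert (a, c) == (len(case_carriers), len(ctrl_carriers))
    assert a + b == 400 and c + d == 600


def test_fisher_printed_values():
    r = ek.fisher_enrichment((17, 3890, 1, 5156))
    assert r.p_raw == pytest.approx(6.41e-06, rel=0.02)
    assert r.or_sample == pytest.approx(22.53, abs=0.01)
    r2 = ek.fisher_enrichment((10, 3897, 1, 5156))
    assert r2.p_raw == pytest.approx(1.47e-03, rel=0.02)
    assert r2.or_sample == pytest.approx(13.23, abs=0.01)
    r3 = ek.fisher_enrichment((5, 95, 5, 95))
    assert r3.or_sample == pytest.approx(1.0)
    assert r3.p_raw == pytest.approx(1.0)


def _fisher_oracle(a, b, c, d):
    """Exhaustive two-sided p: sum over all tables with the observed
    margins whose probability does not exceed the observed table's."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    p_obs = hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p = hypergeom.pmf(x, n, row1, col1)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(11)
    for _ in range(25):
        a, b, c, d = rng.integers(0, 31, size=4)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        r = ek.fisher_enrichment((int(a), int(b), int(c), int(d)))
        assert r.p_raw == pytest.approx(_fisher_oracle(a, b, c, d), abs=1e-12)


def test_odds_ratio_swap_invariance():
    r1 = ek.fisher_enrichment((7, 13, 3, 27))
    r2 = ek.fisher_enrichment((3, 27, 7, 13))  # swap rows
    assert r1.or_sample == pytest.approx(1.0 / r2.or_sample)
    r3 = ek.fisher_enrichment((27, 3, 13, 7))  # swap rows AND columns
    assert r1.or_sample == pytest.approx(r3.or_sample)


def test_degenerate_table_flagged():
    r = ek.fisher_enrichment((0, 10, 0, 20))
    assert r.p_raw == 1.0 and not r.or_defined


def test_adjust_scenarios_fixed_battery_size():
    results = [ek.fisher_enrichment((17, 3890, 1, 5156), "PTVs")]
    adj = ek.adjust_scenarios(results, n_tests=17)
    assert adj[0].p_adj == pytest.approx(1.09e-04, rel=0.01)
    one = ek.adjust_scenarios(results, n_tests=1)
    assert one[0].p_adj == pytest.approx(results[0].p_raw)
    with pytest.raises(ValidationError):
        ek.adjust_scenarios(results * 3, n_tests=2)


def test_scenario_composability_egf_minus_disulfide():
    """Excluding disulfide-disrupting carriers from the EGF scenario leaves
    the complement: 17 EGF carriers with 9 disulfide-overlapping gives 8."""
    model = ek.load_domain_model()
    disulf = sorted(model.disulfide_residues)[:9]
    egf_pos = 100  # inside an EGF repeat, not a disulfide cysteine
    rows = [
        _variant_row(sample_id=f"case_d{i}", residue_start=r, ref_aa="C", alt_aa="Y")
        for i, r in enumerate(disulf)
    ] + [
        _variant_row(sample_id=f"case_e{i}", residue_start=egf_pos)
        for i in range(8)
    ]
    df = ek.annotate_domain_effects(ek.collapse_class(_table(rows)), model)
    scen = {s.name: s for s in ek.default_scenarios()}
    egf, _, _, _ = ek.carrier_table(df, scen["EGF-like repeats"], 3907, 5157)
    excl, _, _, _ = ek.carrier_table(
        df, scen["EGF-like repeats (excl. Disulfide bonds)"], 3907, 5157
    )
    overlap = egf - excl
    assert egf == 17 and overlap == 9 and excl == 8


def test_run_burden_recovers_planted_enrichment():
    rates = {
        "PTV": (17 / 3907, 1 / 5157),
        "SYN": (6 / 3907, 6 / 5157),
        "disulfide": (10 / 3907, 1 / 5157),
    }
    tab = ek.generate_variant_cohort(3907, 5157, rates, seed=2)
    model = ek.load_domain_model()
    res = ek.run_burden(tab, model, 3907, 5157).set_index("scenario")
    assert res.loc["PTVs", "p_raw"] < 0.01
    assert res.loc["Disulfide bonds", "p_raw"] < 0.05
    assert res.loc["SYN", "p_raw"] > 0.05
    assert len(res) == 17
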