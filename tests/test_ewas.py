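"""Probe-wise association engine: OLS oracle, BH properties, temporal ops."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methrisk.containers import MethylomeMatrix
from methrisk.ewas import (bh_adjust, comethylation_structure,
                           compare_structures, filter_probes, follow_forward,
                           probe_autocorrelation, run_ewas, select_dmps)


def _tiny_matrix(beta, probe_prefix="cg"):
    n, m = beta.shape
    probes = [f"{probe_prefix}{j:08d}" for j in range(1, m + 1)]
    ann = pd.DataFrame({
        "chrom": ["1"] * m, "pos": np.arange(1, m + 1) * 1000,
        "gene": [""] * m, "cross_reactive": False, "control_probe": False,
        "snp_at_sbe_maf_gt_5": False,
    }, index=pd.Index(probes, name="probe_id"))
    return MethylomeMatrix(
        beta=pd.DataFrame(beta, columns=probes,
                          index=[f"S{i}" for i in range(n)]),
        annotation=ann)


# ---------------------------------------------------------------- filtering

def test_filter_removes_flagged_probes(toy_annotation):
    kept = filter_probes(toy_annotation)
    assert len(kept) == 7
    assert list(kept) == [p for p in toy_annotation.index
                          if p not in {"cg00000002", "cg00000005", "cg00000008"}]


def test_filter_identity_without_flags(toy_annotation):
    clean = toy_annotation.copy()
    clean[["cross_reactive", "control_probe", "snp_at_sbe_maf_gt_5"]] = False
    assert list(filter_probes(clean)) == list(clean.index)


def test_filter_requires_flag_columns(toy_annotation):
    with pytest.raises(ValueError):
        filter_probes(toy_annotation.drop(columns=["control_probe"]))


# ------------------------------------------------------------------- OLS

def _normal_equations_oracle(X, y):
    """Textbook normal-equations OLS with classical SEs."""
    XtX_inv = np.linalg.inv(X.T @ X)
    b = XtX_inv @ X.T @ y
    resid = y - X @ b
    dof = X.shape[0] - X.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(s2 * np.diag(XtX_inv))
    t = b / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return b, se, t, p


def test_run_ewas_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    n, m = 6, 4
    beta = rng.uniform(0.2, 0.8, size=(n, m))
    M = _tiny_matrix(beta)
    outcome = pd.Series(rng.standard_normal(n), index=M.sample_ids)
    cov = pd.DataFrame({"sex": [0, 1, 0, 1, 0, 1]}, index=M.sample_ids)
    table = run_ewas(M, outcome, cov)
    X = np.column_stack([np.ones(n), outcome.to_numpy(), cov.to_numpy()])
    for j, pid in enumerate(M.probe_ids):
        b, se, t, p = _normal_equations_oracle(X, beta[:, j])
        row = table.loc[pid]
        assert abs(row["se"] - se[1]) < 1e-10
        assert abs(row["t"] - t[1]) < 1e-10
        assert abs(row["p"] - p[1]) < 1e-10
        std_b = b[1] * outcome.std(ddof=1) / beta[:, j].std(ddof=1)
        assert abs(row["std_beta"] - std_b) < 1e-10


def test_run_ewas_random_instances_match_oracle():
    rng = np.random.default_rng(1)
    for _ in range(5):
        n = int(rng.integers(15, 40))
        m = int(rng.integers(2, 8))
        beta = rng.uniform(0.05, 0.95, size=(n, m))
        M = _tiny_matrix(beta)
        outcome = pd.Series(rng.standard_normal(n), index=M.sample_ids)
        cov = pd.DataFrame(rng.standard_normal((n, 3)),
                           columns=list("abc"), index=M.sample_ids)
        table = run_ewas(M, outcome, cov)
        X = np.column_stack([np.ones(n), outcome.to_numpy(), cov.to_numpy()])
        for j, pid in enumerate(M.probe_ids):
            b, se, t, p = _normal_equations_oracle(X, beta[:, j])
            assert abs(table.loc[pid, "t"] - t[1]) < 1e-10
            assert abs(table.loc[pid, "p"] - p[1]) < 1e-10


def test_constant_probe_flagged_not_tested():
    rng = np.random.default_rng(2)
    beta = rng.uniform(0.3, 0.7, size=(10, 3))
    beta[:, 1] = 0.5
    M = _tiny_matrix(beta)
    outcome = pd.Series(rng.standard_normal(10), index=M.sample_ids)
    table = run_ewas(M, outcome)
    row = table.iloc[1]
    assert row["zero_variance"]
    assert np.isnan(row["p"]) and np.isnan(row["q"])
    assert row["direction_label"] == ""


def test_zero_variance_predictor_raises():
    M = _tiny_matrix(np.random.default_rng(3).uniform(0.3, 0.7, (8, 2)))
    with pytest.raises(ValueError):
        run_ewas(M, pd.Series(np.ones(8), index=M.sample_ids))


def test_direction_labels_follow_sign():
    rng = np.random.default_rng(4)
    n = 200
    x = rng.standard_normal(n)
    beta = np.column_stack([
        np.clip(0.5 - 0.05 * x + rng.normal(0, 0.01, n), 0.01, 0.99),
        np.clip(0.5 + 0.05 * x + rng.normal(0, 0.01, n), 0.01, 0.99),
    ])
    M = _tiny_matrix(beta)
    table = run_ewas(M, pd.Series(x, index=M.sample_ids))
    assert table.iloc[0]["std_beta"] < 0
    assert table.iloc[0]["direction_label"] == "hypomethylated"
    assert table.iloc[1]["direction_label"] == "hypermethylated"


# --------------------------------------------------------------------- BH

def _bh_bruteforce(p, m):
    """Direct enumeration of the step-up definition."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [None] * n
    for rank_pos, i in enumerate(order):
        candidates = [min(1.0, m * p[order[j]] / (j + 1))
                      for j in range(rank_pos, n)]
        q[i] = min(candidates)
    return np.array(q)


def test_bh_all_ones():
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])


def test_bh_small_example_matches_bruteforce():
    p = [0.01, 0.02, 0.03, 0.04]
    np.testing.assert_allclose(bh_adjust(p, m_total=4), _bh_bruteforce(p, 4),
                               atol=1e-12)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=10),
       st.integers(min_value=0, max_value=100))
def test_bh_matches_bruteforce_property(p, extra_m):
    m = len(p) + extra_m
    got = bh_adjust(p, m_total=m)
    want = _bh_bruteforce(p, m)
    np.testing.assert_allclose(got, want, atol=1e-12)
    # q monotone in p-rank
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(got[order]) >= -1e-12)
    assert np.all((got >= 0) & (got <= 1))


def test_bh_rejects_bad_inputs():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([0.1, 0.2], m_total=1)


# ------------------------------------------------------------- DMP sets

def test_select_dmps_thresholds():
    table = pd.DataFrame({
        "std_beta": [0.3, -0.2, 0.1],
        "p": [0.001, 0.001, 0.5],
        "q": [0.01, 0.01, 0.9],
    }, index=pd.Index(["cgB", "cgA", "cgC"], name="probe_id"))
    dmps = select_dmps(table, q_threshold=0.05)
    assert dmps.probe_ids == ["cgA", "cgB"]  # tie on p broken lexicographically
    assert len(select_dmps(table, q_threshold=1.0)) == 3
    none = select_dmps(table, q_threshold=1e-6)
    assert len(none) == 0


# ---------------------------------------------------- temporal operations

def test_follow_forward_identity_timepoint(small_cohort):
    _, (m1, _, cohort, truth, _, _) = small_cohort
    rng = np.random.default_rng(0)
    outcome = pd.Series(truth.liability.to_numpy(), index=m1.sample_ids)
    disc = run_ewas(m1, outcome)
    dmps = select_dmps(disc, q_threshold=0.05)
    assert len(dmps) >= 2
    rep = follow_forward(dmps, m1, outcome)  # same matrix -> must replicate
    merged = rep.join(disc, rsuffix="_disc")
    np.testing.assert_allclose(merged["t"], merged["t_disc"], atol=1e-10)
    np.testing.assert_allclose(merged["p"], merged["p_disc"], atol=1e-12)
    assert rep["replicated"].all()
    assert rep.attrs["missing_probes"] == []


def test_follow_forward_missing_probe_listed(small_cohort):
    _, (m1, m2, _, truth, _, _) = small_cohort
    outcome = pd.Series(truth.liability.to_numpy(), index=m1.sample_ids)
    disc = run_ewas(m1, outcome)
    dmps = select_dmps(disc, q_threshold=0.05)
    dropped = dmps.probe_ids[0]
    m2_sub = m2.subset_probes([p for p in m2.probe_ids if p != dropped])
    rep = follow_forward(dmps, m2_sub, outcome)
    assert rep.attrs["missing_probes"] == [dropped]
    assert dropped not in rep.index


def test_autocorrelation_identity_and_summary(small_cohort):
    _, (m1, m2, _, truth, _, _) = small_cohort
    probes = truth.dmp_ids
    table, summary = probe_autocorrelation(m1, m1, probes)
    np.testing.assert_allclose(table["r"], 1.0, atol=1e-12)
    for key in ("r_max", "r_min", "mean_abs_r", "n_significant"):
        assert key in summary
    # across real timepoints the planted autocorrelation is low
    _, s2 = probe_autocorrelation(m1, m2, probes)
    assert s2["mean_abs_r"] < 0.5


def test_autocorrelation_needs_shared_samples(small_cohort):
    _, (m1, m2, _, _, _, _) = small_cohort
    m2_cut = MethylomeMatrix(beta=m2.beta.iloc[:2], annotation=m2.annotation)
    with pytest.raises(ValueError):
        probe_autocorrelation(m1, m2_cut)


def test_comethylation_null_fraction_controlled():
    rng = np.random.default_rng(9)
    beta = rng.uniform(0.3, 0.7, size=(1000, 30))  # independent probes
    M = _tiny_matrix(beta)
    _, summary = comethylation_structure(M, list(M.probe_ids))
    assert summary["frac_significant"] <= 0.05


def test_compare_structures_self_similarity(small_cohort):
    _, (m1, _, _, truth, _, _) = small_cohort
    corr, _ = comethylation_structure(m1, truth.dmp_ids)
    out = compare_structures(corr, corr, n_permutations=99, seed=1)
    assert out["similarity"] == pytest.approx(1.0)
    assert out["mantel_p"] <= 0.05


def test_planted_comethylation_structure_persists(small_cohort):
    """Within-time DMP intercorrelation blocks are planted identically at
    both timepoints, so the structures should resemble each other even
    though per-probe autocorrelation is low."""
    _, (m1, m2, _, truth, _, _) = small_cohort
    c1, s1 = comethylation_structure(m1, truth.dmp_ids)
    c2, _ = comethylation_structure(m2, truth.dmp_ids)
    out = compare_structures(c1, c2, n_permutations=199, seed=2)
    assert out["similarity"] > 0.2
    assert out["mantel_p"] < 0.05


def test_power_for_study_scale_effects():
    """A planted standardized effect around 0.3 at the study's sample size
    (n = 244) should reach genome-wide q < 0.05 (m = 20,000) in at least
    half of the probe-cohort replicates — consistent with discovery-stage
    effect magnitudes of 0.27-0.34 being detectable."""
    from methrisk.simulate import SimConfig, simulate_cohort
    detected = total = 0
    for rep in range(10):
        cfg = SimConfig(n_samples=244, n_probes=20_000, n_dmps=5,
                        n_mqtl_dmps=0, dmp_effect_sd=0.105,
                        dmp_effect_jitter=0.0, exposure_effects={},
                        n_sex_probes=0, seed=3000 + rep)
        m1, _, _, truth, panel, _ = simulate_cohort(cfg)
        outcome = pd.Series(truth.liability.to_numpy(), index=m1.sample_ids)
        table = run_ewas(m1, outcome)
        hits = set(select_dmps(table).probe_ids)
        detected += len(hits & set(truth.dmp_ids))
        total += len(truth.dmp_ids)
    assert detected / total >= 0.5
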