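"""Weighted cumulative methylation risk score and its correlates."""

import numpy as np
import pandas as pd
import pytest

from methrisk.containers import RiskScore
from methrisk.ewas import DmpSet, run_ewas, select_dmps
from methrisk.mrs import (compute_mrs, exclude_mqtl_probes, onset_correlation,
                          screen_exposures)
from methrisk.published import discovery_table
from methrisk.simulate import EXPOSURE_COLUMNS, SimConfig, simulate_cohort


def _dmpset(weights: dict[str, float]) -> DmpSet:
    table = pd.DataFrame({
        "std_beta": list(weights.values()),
        "p": [1e-6] * len(weights),
        "q": [0.01] * len(weights),
    }, index=pd.Index(list(weights), name="probe_id"))
    return DmpSet(table=table)


def test_zero_weights_zero_scores(small_cohort):
    _, (m1, *_rest) = small_cohort
    probes = list(m1.probe_ids[:4])
    score = compute_mrs(m1, _dmpset({p: 0.0 for p in probes}))
    np.testing.assert_allclose(score.scores, 0.0)


def test_published_two_probe_arithmetic(small_cohort):
    """The first two published discovery weights (-0.34, 0.31) applied to
    beta values of 0.5 each give a score of exactly -0.015."""
    w = discovery_table()["std_beta"].iloc[:2].to_numpy()
    score = float(w @ np.array([0.5, 0.5]))
    assert score == pytest.approx(-0.015)
    # the same arithmetic through compute_mrs on a constructed matrix
    _, (m1, *_rest) = small_cohort
    probes = list(m1.probe_ids[:2])
    M = m1.subset_probes(probes)
    M.beta.iloc[:, :] = 0.5
    got = compute_mrs(M, _dmpset(dict(zip(probes, w))))
    np.testing.assert_allclose(got.scores, -0.015)


def test_missing_probe_raises(small_cohort):
    _, (m1, *_rest) = small_cohort
    with pytest.raises(KeyError, match="nope"):
        compute_mrs(m1, _dmpset({"nope": 0.3}))


def test_linearity_and_permutation_equivariance(small_cohort):
    _, (m1, *_rest) = small_cohort
    rng = np.random.default_rng(0)
    probes = list(m1.probe_ids[:6])
    w1 = dict(zip(probes, rng.normal(size=6)))
    w2 = dict(zip(probes, rng.normal(size=6)))
    s1 = compute_mrs(m1, _dmpset(w1)).scores
    s2 = compute_mrs(m1, _dmpset(w2)).scores
    s12 = compute_mrs(m1, _dmpset({p: w1[p] + w2[p] for p in probes})).scores
    np.testing.assert_allclose(s12, s1 + s2, atol=1e-12)

    perm = rng.permutation(m1.n_samples)
    from methrisk.containers import MethylomeMatrix
    m_perm = MethylomeMatrix(beta=m1.beta.iloc[perm], annotation=m1.annotation)
    sp = compute_mrs(m_perm, _dmpset(w1)).scores
    np.testing.assert_allclose(sp.to_numpy(), s1.iloc[perm].to_numpy())


def test_mrs_tracks_planted_liability(planted_cohort):
    _, (m1, _, cohort, truth, panel, _) = planted_cohort
    outcome = pd.Series(truth.liability.to_numpy(), index=m1.sample_ids)
    table = run_ewas(m1, outcome)
    dmps = select_dmps(table)
    score = compute_mrs(m1, dmps)
    assert np.corrcoef(score.scores, truth.liability)[0, 1] > 0.3


def test_weighted_beats_unweighted_on_average():
    """With heterogeneous, sign-mixed planted effects, weighting DMP betas by
    their discovery coefficients must track the liability better than a
    plain mean of the beta values, on average over replicates."""
    diffs = []
    for rep in range(20):
        cfg = SimConfig(n_samples=300, n_probes=400, n_dmps=20, n_mqtl_dmps=0,
                        n_panel_probes=30, n_sex_probes=0,
                        exposure_effects={}, seed=5000 + rep)
        m1, _, _, truth, _, _ = simulate_cohort(cfg)
        outcome = pd.Series(truth.liability.to_numpy(), index=m1.sample_ids)
        table = run_ewas(m1, outcome)
        dmps = DmpSet(table=table.loc[truth.dmp_ids, ["std_beta", "p", "q"]])
        weighted = compute_mrs(m1, dmps).scores
        unweighted = m1.beta[truth.dmp_ids].mean(axis=1)
        rw = np.corrcoef(weighted, truth.liability)[0, 1]
        ru = np.corrcoef(unweighted, truth.liability)[0, 1]
        diffs.append(abs(rw) - abs(ru))
    assert np.mean(diffs) > 0


def test_exclude_mqtl_probes_counts():
    probes = [f"cg{j:08d}" for j in range(65)]
    rng = np.random.default_rng(1)
    dmps = _dmpset(dict(zip(probes, rng.normal(size=65))))
    mqtl = pd.DataFrame({
        "probe_id": probes[:5],
        "type": ["cis", "cis", "cis", "cis", "trans"],
    })
    reduced, report = exclude_mqtl_probes(dmps, mqtl)
    assert len(reduced) == 60
    assert report["n_removed"] == 5
    assert report["n_cis"] == 4
    assert report["n_trans"] == 1
    # empty table -> identity
    same, rep0 = exclude_mqtl_probes(dmps, pd.DataFrame(columns=["probe_id", "type"]))
    assert len(same) == 65 and rep0["n_removed"] == 0


def test_reduced_score_highly_correlated_with_full(planted_cohort):
    _, (m1, _, _, truth, _, mqtl_table) = planted_cohort
    outcome = pd.Series(truth.liability.to_numpy(), index=m1.sample_ids)
    dmps = select_dmps(run_ewas(m1, outcome))
    reduced, report = exclude_mqtl_probes(dmps, mqtl_table)
    assert report["n_removed"] >= 1
    full = compute_mrs(m1, dmps).scores
    red = compute_mrs(m1, reduced, variant="mqtl_excluded").scores
    assert np.corrcoef(full, red)[0, 1] > 0.95


def test_screen_detects_only_the_planted_exposure():
    """With the score correlated at 0.25 with a binary exposure and five null
    exposures, the BH-corrected screen should flag exactly the planted one
    in at least 90% of replicates at n = 500."""
    rng = np.random.default_rng(2)
    n = 500
    hits_clean = 0
    for _ in range(50):
        smoke = (rng.random(n) < 0.2).astype(float)
        z = (smoke - smoke.mean()) / smoke.std()
        score_vals = 0.25 * z + np.sqrt(1 - 0.25 ** 2) * rng.standard_normal(n)
        idx = pd.Index([f"S{i}" for i in range(n)])
        exposures = pd.DataFrame(
            {"maternal_smoking": smoke,
             **{name: rng.standard_normal(n)
                for name in EXPOSURE_COLUMNS if name != "maternal_smoking"}},
            index=idx)
        score = RiskScore(scores=pd.Series(score_vals, index=idx),
                          weights=pd.Series(dtype=float))
        outcome = pd.Series(rng.standard_normal(n), index=idx)
        screen = screen_exposures(score, outcome, exposures)
        row = screen[screen["variable"] == "dnam_risk"].set_index("exposure")
        flagged = set(row.index[row["q"] < 0.05])
        if flagged == {"maternal_smoking"}:
            hits_clean += 1
    assert hits_clean >= 45


def test_screen_exposure_identical_to_score(small_cohort):
    _, (m1, _, cohort, truth, _, _) = small_cohort
    score = RiskScore(scores=truth.liability.copy(),
                      weights=pd.Series(dtype=float))
    exposures = cohort[list(EXPOSURE_COLUMNS)].copy()
    exposures["self"] = truth.liability
    screen = screen_exposures(score, truth.liability, exposures)
    row = screen[(screen["variable"] == "dnam_risk")
                 & (screen["exposure"] == "self")].iloc[0]
    assert row["r"] == pytest.approx(1.0)


def test_onset_correlation_planted_negative():
    in_band = 0
    for rep in range(20):
        cfg = SimConfig(n_samples=500, n_probes=120, n_dmps=3, n_mqtl_dmps=0,
                        n_panel_probes=20, n_sex_probes=0,
                        exposure_effects={}, seed=7000 + rep)
        _, _, cohort, truth, _, _ = simulate_cohort(cfg)
        score = RiskScore(scores=truth.liability.copy(),
                          weights=pd.Series(dtype=float))
        res = onset_correlation(score, cohort).set_index("substance")
        r = res.loc["cigarette", "r"]
        assert res.loc["cigarette", "n_endorse"] > 50
        if -0.45 <= r <= -0.15:
            in_band += 1
    assert in_band >= 18  # 90% of replicates
    assert (res["r"] < 0).all()


def test_onset_constant_subgroup_rejected(small_cohort):
    _, (m1, _, cohort, truth, _, _) = small_cohort
    bad = cohort.copy()
    bad.loc[bad["endorsed_cigarette"] == 1, "onset_age_cigarette"] = 15.0
    score = RiskScore(scores=truth.liability.copy(),
                      weights=pd.Series(dtype=float))
    with pytest.raises(ValueError):
        onset_correlation(score, bad, substances=("cigarette",))
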