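"""Synthetic data generation: known-truth series, certificates, WONDER fixtures."""

import numpy as np
import pandas as pd
import pytest

from opioid_its import design, synthetic, wonder


def test_population_table_zero_growth_constant():
    out = synthetic.generate_population_table(
        [("South", "All")], [2000, 2001, 2002], 1_000_000, 0)
    assert (out["population"] == 1_000_000).all()


def test_population_table_arithmetic_progression():
    out = synthetic.generate_population_table(
        [("South", "All")], [2000, 2001], 1_000_000, 36_500)
    assert out["population"].tolist() == [1_000_000, 1_036_500]


def test_population_table_rejects_collapse():
    with pytest.raises(ValueError, match="rejected"):
        synthetic.generate_population_table(
            [("South", "All")], [2000, 2001], 1_000_000, -1_000_000)


def test_population_table_rejects_noncontiguous_years():
    with pytest.raises(ValueError, match="contiguous"):
        synthetic.generate_population_table([("South", "All")], [2000, 2002], 1e6, 0)


def _flat_model(timeline, rate=0.2):
    beta = np.zeros(10)
    beta[0] = rate
    return synthetic.TrueModel(timeline=timeline,
                               coefficients={("South", "All"): beta}, noise="none")


def test_constant_rate_noiseless_counts(timeline):
    """Rate 0.2 per 100,000 on a million people -> exactly 2 deaths a month."""
    model = _flat_model(timeline)
    pop = synthetic.generate_population_table([("South", "All")],
                                              range(1999, 2001), 1_000_000, 0)
    out = synthetic.simulate_monthly_counts(model, pop, ((1999, 1), (2000, 12)), seed=1)
    assert np.allclose(out["deaths"], 2.0)
    assert np.allclose(out["rate"], 0.2)


def test_coefficient_length_validated(timeline):
    with pytest.raises(ValueError, match="10 columns"):
        synthetic.TrueModel(timeline=timeline,
                            coefficients={("South", "All"): np.zeros(9)})


def test_negative_expected_rate_names_month(timeline):
    beta = np.zeros(10)
    beta[0], beta[1] = 0.5, -0.01  # goes negative at t=51 (2003-03)
    model = synthetic.TrueModel(timeline=timeline,
                                coefficients={("South", "All"): beta}, noise="none")
    pop = synthetic.generate_population_table([("South", "All")],
                                              range(1999, 2006), 1e6, 0)
    with pytest.raises(ValueError, match="2003-03"):
        synthetic.simulate_monthly_counts(model, pop, ((1999, 1), (2005, 12)), seed=1)


def test_poisson_counts_match_expected_mean(timeline):
    """Monte-Carlo check: 10,000 month draws at lambda = 50."""
    strata = [(f"R{i}", "All") for i in range(10)]
    beta = np.zeros(10)
    beta[0] = 0.5  # 0.5/100k on 10M -> lambda = 50
    model = synthetic.TrueModel(
        timeline=timeline, coefficients={s: beta.copy() for s in strata},
        noise="poisson-counts")
    years = range(1999, 2083)  # 1000 months x 10 strata = 10,000 draws
    pop = synthetic.generate_population_table(strata, years, 10_000_000, 0)
    out = synthetic.simulate_monthly_counts(model, pop, ((1999, 1), (2082, 4)), seed=42)
    assert len(out) == 10_000
    assert abs(out["deaths"].mean() - 50) <= 3 * np.sqrt(50 / 10_000)


def test_same_seed_identical_series(timeline):
    model = synthetic.default_scenario()
    pop = synthetic.default_population(range(1999, 2001))
    a = synthetic.simulate_monthly_counts(model, pop, ((1999, 1), (2000, 12)), seed=9)
    b = synthetic.simulate_monthly_counts(model, pop, ((1999, 1), (2000, 12)), seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_gaussian_rate_noise_runs(timeline):
    model = synthetic.default_scenario(noise="gaussian-rate")
    model.ar1_rho = 0.5
    pop = synthetic.default_population(range(1999, 2001))
    out = synthetic.simulate_monthly_counts(model, pop, ((1999, 1), (2000, 12)), seed=9)
    assert (out["deaths"] >= 0).all()


# ---------------------------------------------------------------------------
# Certificates

def _counts_frame(n_cells=20, deaths=50, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "region": rng.choice(["South", "West"], n_cells),
        "gender": rng.choice(["Female", "Male"], n_cells),
        "year": 2020, "month": np.arange(n_cells) % 12 + 1,
        "deaths": float(deaths),
    })


def test_certificates_closed_loop_no_contaminants():
    counts = _counts_frame()
    certs = synthetic.simulate_certificates(counts, seed=5)
    kept = wonder.filter_opioid_deaths(certs)
    assert len(kept) == counts["deaths"].sum()
    # per stratum-month, the filter recovers the input counts exactly
    recovered = kept.groupby(["region", "gender", "year", "month"]).size()
    expected = counts.set_index(["region", "gender", "year", "month"])["deaths"]
    expected = expected.groupby(level=[0, 1, 2, 3]).sum()
    assert (recovered.sort_index() == expected.sort_index()).all()


def test_certificates_contaminant_count_and_rejection():
    counts = _counts_frame(n_cells=20, deaths=50)  # 1000 base records
    certs = synthetic.simulate_certificates(counts, seed=5, contaminant_fraction=0.3)
    n_cont = certs["is_contaminant"].sum()
    assert n_cont == round(1000 * 0.3 / 0.7)  # 429
    kept = wonder.filter_opioid_deaths(certs)
    assert not kept["is_contaminant"].any()
    assert len(kept) == 1000
    # conservation: passes + contaminants = total records
    assert len(certs) == 1000 + n_cont


def test_certificates_invalid_fraction():
    with pytest.raises(ValueError, match="fraction"):
        synthetic.simulate_certificates(_counts_frame(), seed=1, contaminant_fraction=1.0)


# ---------------------------------------------------------------------------
# WONDER fixture round trips

def _small_series(timeline, seed=3):
    model = synthetic.default_scenario()
    pop = synthetic.default_population(range(1999, 2002))
    return synthetic.simulate_monthly_counts(model, pop, ((1999, 1), (2001, 12)), seed=seed)


def test_fixture_round_trip_lossless(tmp_path, timeline):
    series = _small_series(timeline)
    f, p = synthetic.write_wonder_fixture(series, tmp_path, suppress_below=0,
                                          split=(2000, 6))
    merged = wonder.merge_final_provisional(
        wonder.parse_wonder_export(f), wonder.parse_wonder_export(p), cutoff=(2000, 6))
    joined = merged.merge(series, on=["region", "gender", "year", "month"])
    assert len(joined) == len(series)
    assert np.allclose(joined["count"], joined["deaths"])


def test_fixture_suppression_token(tmp_path, timeline):
    series = _small_series(timeline).head(3).copy()
    series.loc[series.index[1], "deaths"] = 7.0
    f, _ = synthetic.write_wonder_fixture(series, tmp_path, suppress_below=10,
                                          split=(2099, 1))
    assert "Suppressed" in (tmp_path / "final.txt").read_text()
    table = wonder.parse_wonder_export(f)
    assert table["suppressed"].sum() >= 1


def test_fixture_degenerate_split(tmp_path, timeline):
    """Split before all data: empty final file, everything provisional."""
    series = _small_series(timeline)
    f, p = synthetic.write_wonder_fixture(series, tmp_path, suppress_below=0,
                                          split=(1990, 1))
    assert wonder.parse_wonder_export(f).empty
    merged = wonder.merge_final_provisional(
        wonder.parse_wonder_export(f), wonder.parse_wonder_export(p), cutoff=(1990, 1))
    assert len(merged) == len(series)


def test_truth_yaml_round_trip(tmp_path):
    model = synthetic.default_scenario()
    path = tmp_path / "truth.yaml"
    model.to_yaml(path)
    back = synthetic.TrueModel.from_yaml(path)
    assert back.noise == model.noise
    assert back.timeline.names == model.timeline.names
    for k in model.coefficients:
        np.testing.assert_allclose(back.coefficients[k], model.coefficients[k])


def test_empirical_rate_converges_to_truth(timeline, true_beta):
    """With large populations the mean observed rate tracks mu_t (3-sigma MC)."""
    model = synthetic.TrueModel(timeline=timeline,
                                coefficients={("South", "All"): true_beta})
    pop = synthetic.generate_population_table([("South", "All")],
                                              range(1999, 2023), 5e7, 0)
    out = synthetic.simulate_monthly_counts(model, pop, ((1999, 1), (2022, 10)), seed=17)
    lam = out["expected_rate"] * out["population"] / 1e5
    z = (out["deaths"] - lam) / np.sqrt(lam)
    assert abs(z.mean()) <= 3 / np.sqrt(len(z))
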