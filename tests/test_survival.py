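"""Tree-lifetime statistics: records, Kaplan–Meier, log-rank, fates."""

import numpy as np
import pandas as pd
import pytest

from barreltree.registration import PresenceMatrix
from barreltree.survival import (
    SurvivalError,
    SurvivalRecord,
    classify_fate,
    derive_survival_records,
    elimination_fraction,
    km_estimate,
    length_by_survival,
    logrank_test,
    turnover_counts,
)


def _pm(rows, sessions=None):
    sessions = sessions or [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=sessions)
    table.index = pd.MultiIndex.from_tuples(
        table.index, names=["neuron_id", "tree_uid", "side"]
    )
    return PresenceMatrix(table=table)


def _rec(lifetime, censored, side="inner", uid="t"):
    return SurvivalRecord("n", uid, side, "s1", lifetime, censored)


# ---------------------------------------------------------------------------
# record derivation
# ---------------------------------------------------------------------------


def test_record_derivation_rules():
    pm = _pm(
        {
            ("n", "a", "inner"): list("APAAAAAA"),    # born s1, gone s2
            ("n", "b", "inner"): list("AAAAAPPP"),    # born s5, censored
            ("n", "c", "outer"): list("PPPPPPPP"),    # pre-existing: excluded
            ("n", "d", "outer"): list("APPUAAAA"),    # unknown at death time
        }
    )
    records = {r.tree_uid: r for r in derive_survival_records(pm)}
    assert records["a"].lifetime == 1 and not records["a"].censored
    assert records["b"].lifetime == 3 and records["b"].censored
    assert "c" not in records
    assert records["d"].interval_censored and records["d"].lifetime == 2


def test_window_bounds_birth_session():
    pm = _pm(
        {
            ("n", "a", "inner"): list("APPPPPPP"),
            ("n", "b", "inner"): list("AAAAAAPP"),
        }
    )
    records = derive_survival_records(pm, window=("s1", "s5"))
    assert [r.tree_uid for r in records] == ["a"]


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank vs brute force
# ---------------------------------------------------------------------------


def brute_km(durations, events):
    """Product-limit estimator computed directly from its definition."""
    times = sorted(set(durations[events]))
    s, out = 1.0, {}
    for t in times:
        n_risk = int((durations >= t).sum())
        d = int(((durations == t) & events).sum())
        s *= 1 - d / n_risk
        out[t] = s
    return out


def brute_logrank(d1, e1, d2, e2):
    """Log-rank chi-square from explicit 2x2 hypergeometric tables."""
    times = sorted(set(np.concatenate([d1[e1], d2[e2]])))
    O = E = V = 0.0
    for t in times:
        n1 = int((d1 >= t).sum())
        n2 = int((d2 >= t).sum())
        o1 = int(((d1 == t) & e1).sum())
        o2 = int(((d2 == t) & e2).sum())
        n, o = n1 + n2, o1 + o2
        if n < 2 or o == 0:
            continue
        E += o * n1 / n
        O += o1
        V += o * (n1 / n) * (n2 / n) * (n - o) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


def _random_records(rng, n, p_censor=0.3, max_t=8):
    recs = []
    for i in range(n):
        recs.append(
            _rec(int(rng.integers(1, max_t)), bool(rng.uniform() < p_censor),
                 uid=f"t{i}")
        )
    return recs


def test_km_with_no_deaths_is_flat_one():
    curve = km_estimate([_rec(3, True), _rec(5, True)])
    assert np.all(curve.survival == 1.0)


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(21)
    for _ in range(20):
        recs = _random_records(rng, int(rng.integers(3, 20)), p_censor=0.0)
        durations = np.array([r.lifetime for r in recs], float)
        curve = km_estimate(recs)
        for t, s in zip(curve.times, curve.survival):
            if t == 0:
                continue
            assert s == pytest.approx((durations > t).mean(), abs=1e-12)


def test_km_matches_brute_force_with_censoring():
    rng = np.random.default_rng(22)
    for _ in range(30):
        recs = _random_records(rng, int(rng.integers(4, 20)))
        d = np.array([r.lifetime for r in recs], float)
        e = np.array([not r.censored for r in recs])
        if not e.any():
            continue
        expect = brute_km(d, e)
        curve = km_estimate(recs)
        got = dict(zip(curve.times, curve.survival))
        for t, s in expect.items():
            assert got[t] == pytest.approx(s, abs=1e-12)


def test_km_confidence_band_brackets_estimate():
    rng = np.random.default_rng(23)
    recs = _random_records(rng, 25)
    curve = km_estimate(recs)
    ok = ~np.isnan(curve.ci_low)
    assert np.all(curve.ci_low[ok] <= curve.survival[ok] + 1e-12)
    assert np.all(curve.survival[ok] <= curve.ci_high[ok] + 1e-12)
    assert np.all(np.diff(curve.survival) <= 1e-12)


def test_logrank_matches_hypergeometric_oracle():
    rng = np.random.default_rng(24)
    checked = 0
    for _ in range(100):
        a = _random_records(rng, int(rng.integers(3, 21)))
        b = _random_records(rng, int(rng.integers(3, 21)))
        ea = np.array([not r.censored for r in a])
        eb = np.array([not r.censored for r in b])
        if ea.sum() + eb.sum() == 0:
            continue
        da = np.array([r.lifetime for r in a], float)
        db = np.array([r.lifetime for r in b], float)
        chi2, p = logrank_test(a, b)
        assert chi2 == pytest.approx(brute_logrank(da, ea, db, eb), rel=1e-9)
        checked += 1
    assert checked > 50


def test_identical_groups_give_null_logrank():
    recs = [_rec(t, c, uid=f"t{t}{c}") for t in (1, 2, 3) for c in (False, True)]
    chi2, p = logrank_test(recs, list(recs))
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_logrank_requires_events():
    with pytest.raises(SurvivalError):
        logrank_test([_rec(3, True)], [_rec(4, True)])


# ---------------------------------------------------------------------------
# elimination fraction
# ---------------------------------------------------------------------------


def test_elimination_fraction_printed_counts():
    outer = [_rec(1, False, "outer", uid=f"o{i}") for i in range(18)] + [
        _rec(3, False, "outer", uid=f"os{i}") for i in range(4)
    ]
    frac, k, n = elimination_fraction(outer, side="outer")
    assert (k, n) == (18, 22)
    assert round(100 * frac) == 82
    inner = [_rec(1, False, "inner", uid=f"i{i}") for i in range(5)] + [
        _rec(4, False, "inner", uid=f"is{i}") for i in range(11)
    ]
    frac, k, n = elimination_fraction(inner, side="inner")
    assert (k, n) == (5, 16)
    assert round(100 * frac) == 31


def test_all_censored_gives_zero_elimination():
    recs = [_rec(1, True, uid=f"t{i}") for i in range(5)]
    assert elimination_fraction(recs)[0] == 0.0


def test_infinite_horizon_without_censoring_is_one():
    recs = [_rec(t, False, uid=f"t{t}") for t in (1, 2, 5, 7)]
    assert elimination_fraction(recs, horizon=10**9)[0] == 1.0


# ---------------------------------------------------------------------------
# fates and length-vs-survival
# ---------------------------------------------------------------------------


def test_fate_classes():
    assert classify_fate(_rec(3, True, "inner")) == "surviving_in"
    assert classify_fate(_rec(2, False, "outer")) == "eliminated_out"


def test_length_by_survival_linear_cohort():
    # trees grow exactly 20 µm per surviving frame
    sessions = [f"s{i}" for i in range(5)]
    recs, rows = [], {}
    for i in range(6):
        lt = (i % 3) + 1
        recs.append(SurvivalRecord("n", f"t{i}", "inner", "s1", lt, False))
        vals = {s: np.nan for s in sessions}
        for k in range(lt):
            vals[sessions[1 + k]] = 20.0 * (k + 1)
        rows[("n", f"t{i}", "inner")] = vals
    lengths = pd.DataFrame.from_dict(rows, orient="index")[sessions]
    lengths.index = pd.MultiIndex.from_tuples(
        lengths.index, names=["neuron_id", "tree_uid", "side"]
    )
    table = length_by_survival(recs, lengths)
    for _, row in table.iterrows():
        assert row["mean"] == pytest.approx(20.0 * row["frames_survived"])


# ---------------------------------------------------------------------------
# turnover counts
# ---------------------------------------------------------------------------


def test_static_dataset_has_no_turnover():
    pm = _pm({("n", "a", "inner"): list("PPPP")})
    counts = turnover_counts(pm)
    assert counts["formed"].sum() == 0 and counts["eliminated"].sum() == 0


def test_injected_birth_and_death_counted():
    pm = _pm(
        {
            ("n", "a", "inner"): list("APPA"),
            ("n", "b", "outer"): list("PPPP"),
        }
    )
    counts = turnover_counts(pm).set_index("side")
    assert counts.loc["inner", "formed"] == 1
    assert counts.loc["inner", "eliminated"] == 1
    assert counts.loc["outer", "formed"] == 0


def test_edge_regime_turns_over_more_than_center_regime():
    from barreltree.registration import build_presence_matrix
    from barreltree.synthetic import SimConfig, gen_longitudinal_neurons

    def total_turnover(mix, seed):
        cfg = SimConfig(n_neurons=15, class_mix=mix)
        sim = gen_longitudinal_neurons(cfg, seed=seed)
        pm = build_presence_matrix(sim.dataset, barrel_map=sim.barrel_map)
        counts = turnover_counts(pm)
        return (counts["formed"].sum() + counts["eliminated"].sum()) / 15

    ess = total_turnover({"eSS": 1.0, "cSS": 0.0, "iSS": 0.0, "eSP": 0.0}, 5)
    css = total_turnover({"eSS": 0.0, "cSS": 1.0, "iSS": 0.0, "eSP": 0.0}, 5)
    assert ess > css
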