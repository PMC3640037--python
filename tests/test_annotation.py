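"""Binding-region features, motif scanning and the logistic direction model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from gcresponse.annotation import (
    PwmModel,
    SeparationWarning,
    default_gr_pwm,
    empirical_pvalues,
    fit_logistic,
    nearest_peak_features,
    primary_targets,
    pwm_scan,
    score_windows,
)


def _genes(tss_list, strands=None):
    n = len(tss_list)
    strands = strands or ["+"] * n
    return pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n)],
            "chrom": "chr1",
            "tss": tss_list,
            "strand": strands,
        }
    )


def _peaks(mids, tags=None, chrom="chr1"):
    mids = np.asarray(mids)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": mids - 50,
            "end": mids + 50,
            "name": [f"p{i}" for i in range(len(mids))],
            "tags": tags if tags is not None else np.ones(len(mids)),
        }
    )


_EMPTY = pd.DataFrame(columns=["chrom", "start", "end"])


class TestPrimaryTargets:
    def test_window_boundary_inclusive_at_100kb(self):
        genes = _genes([500_000])
        assert primary_targets(genes, _peaks([500_000])).iloc[0]
        assert primary_targets(genes, _peaks([600_000])).iloc[0]
        assert not primary_targets(genes, _peaks([600_001])).iloc[0]

    def test_matches_quadratic_oracle(self, rng):
        genes = _genes(list(rng.integers(0, 2_000_000, size=50)))
        peaks = _peaks(rng.integers(0, 2_000_000, size=60))
        flags = primary_targets(genes, peaks, window=100_000)
        mids = (peaks["start"] + peaks["end"]) / 2
        for _, g in genes.iterrows():
            expected = any(abs(g["tss"] - m) <= 100_000 for m in mids)
            assert flags[g["gene"]] == expected

    def test_unknown_chromosome_skipped(self):
        genes = _genes([1000])
        peaks = _peaks([1000], chrom="chr2")
        assert not primary_targets(genes, peaks).iloc[0]


class TestNearestPeakFeatures:
    def test_minus_strand_upstream_convention(self):
        genes = _genes([100_000], strands=["-"])
        rows = nearest_peak_features(
            genes, _peaks([105_000]), _EMPTY, _EMPTY, {"p0": False},
            pd.Series({"g0": 1.0}),
        )
        assert rows.iloc[0]["d"] == 1  # larger coordinate = upstream on minus strand
        rows = nearest_peak_features(
            genes, _peaks([95_000]), _EMPTY, _EMPTY, {"p0": False},
            pd.Series({"g0": 1.0}),
        )
        assert rows.iloc[0]["d"] == 0

    def test_zero_distance_when_midpoint_at_tss(self):
        rows = nearest_peak_features(
            _genes([100_000]), _peaks([100_000]), _EMPTY, _EMPTY,
            {"p0": True}, pd.Series({"g0": -1.0}),
        )
        assert rows.iloc[0]["D"] == 0.0
        assert rows.iloc[0]["M"] == 1
        assert rows.iloc[0]["label"] == 0

    def test_gene_without_cis_peak_omitted(self):
        rows = nearest_peak_features(
            _genes([100_000, 900_000]), _peaks([100_000]), _EMPTY, _EMPTY,
            {"p0": False}, pd.Series({"g0": 1.0, "g1": 1.0}),
        )
        assert list(rows["gene"]) == ["g0"]

    def test_features_match_bruteforce_oracle(self, rng):
        n_g, n_p = 30, 40
        genes = _genes(
            list(rng.integers(50_000, 3_000_000, size=n_g)),
            strands=list(rng.choice(["+", "-"], size=n_g)),
        )
        peaks = _peaks(rng.integers(50_000, 3_000_000, size=n_p),
                       tags=rng.integers(1, 100, size=n_p))
        ctcf_mids = rng.integers(0, 3_000_000, size=25)
        ctcf = pd.DataFrame(
            {"chrom": "chr1", "start": ctcf_mids - 200, "end": ctcf_mids + 200}
        )
        dn = rng.integers(0, 3_000_000, size=25)
        dnase = pd.DataFrame({"chrom": "chr1", "start": dn, "end": dn + 300})
        motif = {f"p{i}": bool(rng.integers(2)) for i in range(n_p)}
        lfc = pd.Series(rng.normal(size=n_g), index=[f"g{i}" for i in range(n_g)])

        rows = nearest_peak_features(genes, peaks, ctcf, dnase, motif, lfc)
        rows = rows.set_index("gene")

        mids = ((peaks["start"] + peaks["end"]) / 2).to_numpy()
        order = np.argsort(peaks["start"].to_numpy(), kind="mergesort")
        for _, g in genes.iterrows():
            dists = np.abs(g["tss"] - mids)
            best = min(order, key=lambda j: (dists[j], peaks["start"][j]))
            if dists[best] > 100_000:
                assert g["gene"] not in rows.index
                continue
            r = rows.loc[g["gene"]]
            assert r["D"] == dists[best]
            up = mids[best] < g["tss"] if g["strand"] == "+" else mids[best] > g["tss"]
            assert r["d"] == int(up)
            others = [
                abs(t - mids[best]) for t in genes["tss"] if t != g["tss"]
            ]
            assert r["C"] == int(min(others) < dists[best])
            lo, hi = sorted([g["tss"], mids[best]])
            cmids = (ctcf["start"] + ctcf["end"]) / 2
            assert r["c"] == int(any((cmids > lo) & (cmids < hi)))
            p = peaks.iloc[best]
            dh = any(
                (dnase["start"] < p["end"]) & (dnase["end"] > p["start"])
            )
            assert r["Dh"] == int(dh)
            assert r["M"] == int(motif[p["name"]])


class TestPwmScan:
    def test_consensus_scores_maximal_and_hits(self, rng):
        pwm = default_gr_pwm()
        consensus = "AGAACAGGGTGTTCT"
        background = "".join(rng.choice(list("ACGT"), size=50_000))
        res = pwm_scan("TT" + consensus + "AA", pwm, background)
        best = res.loc[res["score"].idxmax()]
        assert best["pos"] == 2 and best["hit"]
        all_scores = score_windows(background + consensus, pwm)["score"]
        assert best["score"] >= all_scores.max() - 1e-9

    def test_reverse_complement_scores_equal(self):
        pwm = default_gr_pwm()
        consensus = "AGAACAGGGTGTTCT"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(consensus))
        s_fwd = score_windows(consensus, pwm)["score"].max()
        s_rc = score_windows(rc, pwm)["score"].max()
        assert np.isclose(s_fwd, s_rc)

    def test_windows_with_n_skipped(self):
        pwm = default_gr_pwm()
        res = score_windows("N" * 20, pwm)
        assert res.empty

    def test_short_sequence_gives_no_hits(self, rng):
        background = "".join(rng.choice(list("ACGT"), size=1000))
        assert pwm_scan("ACGT", default_gr_pwm(), background).empty

    def test_empirical_p_matches_tetramer_enumeration(self, rng):
        # asymmetric 4-long PWM; exact null distribution by enumerating
        # all 256 tetramers under a uniform background
        probs = np.array(
            [
                [0.7, 0.1, 0.1, 0.4],
                [0.1, 0.6, 0.2, 0.2],
                [0.1, 0.2, 0.6, 0.2],
                [0.1, 0.1, 0.1, 0.2],
            ]
        )
        pwm = PwmModel.from_probabilities(probs)
        lo = pwm.log_odds
        exact_scores = [
            sum(lo[b, j] for j, b in enumerate(tet))
            for tet in itertools.product(range(4), repeat=4)
        ]
        background = "".join(rng.choice(list("ACGT"), size=200_000))
        null = score_windows(background, pwm)
        null_fwd = null[null["strand"] == "+"]["score"].to_numpy()
        for s in np.percentile(exact_scores, [50, 90, 99]):
            exact_p = np.mean([sc >= s for sc in exact_scores])
            emp_p = empirical_pvalues(np.array([s]), null_fwd)[0]
            se = np.sqrt(exact_p * (1 - exact_p) / null_fwd.size)
            assert abs(emp_p - exact_p) < max(3 * se, 0.005)


def _newton_logistic_oracle(X, y, tol=1e-12):
    """Independent ML fit by direct Newton iteration on the score."""

    def negll(b):
        eta = X @ b
        return -np.sum(y * eta - np.logaddexp(0, eta))

    def grad(b):
        mu = 1 / (1 + np.exp(-(X @ b)))
        return -X.T @ (y - mu)

    def hess(b):
        mu = 1 / (1 + np.exp(-(X @ b)))
        return (X.T * (mu * (1 - mu))) @ X

    res = optimize.minimize(
        negll, np.zeros(X.shape[1]), jac=grad, hess=hess,
        method="trust-exact", tol=tol,
    )
    return res.x


class TestLogisticFit:
    def test_matches_newton_oracle_on_small_dataset(self):
        rows = pd.DataFrame(
            {
                "x": [0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
                "label": [0, 1, 0, 1, 0, 1, 1, 1],
            }
        )
        fit = fit_logistic(rows, features=["x"], min_rows=0)
        X = np.column_stack([np.ones(8), rows["x"]])
        oracle = _newton_logistic_oracle(X, rows["label"].to_numpy(float))
        np.testing.assert_allclose(fit.summary["coef"], oracle, atol=1e-6)

    def test_matches_statsmodels_on_simulated_features(self, rng):
        import statsmodels.api as sm

        n = 500
        rows = pd.DataFrame(
            {
                "D": rng.uniform(0, 100_000, n),
                "d": rng.integers(2, size=n),
                "T": rng.integers(1, 100, n),
            }
        )
        eta = -0.3 + -1e-5 * rows["D"] + 0.4 * rows["d"] + 0.005 * rows["T"]
        rows["label"] = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic(rows, features=["D", "d", "T"])
        X = sm.add_constant(rows[["D", "d", "T"]].to_numpy(float))
        ref = sm.Logit(rows["label"], X).fit(disp=0)
        np.testing.assert_allclose(fit.summary["coef"], ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.summary["se"], ref.bse, rtol=1e-4)

    def test_null_features_give_null_coefficients(self, rng):
        n = 5000
        rows = pd.DataFrame(
            {
                "D": rng.uniform(0, 100_000, n),
                "d": rng.integers(2, size=n),
                "label": rng.integers(2, size=n),
            }
        )
        fit = fit_logistic(rows, features=["D", "d"])
        s = fit.summary.loc[["D", "d"]]
        assert np.all(np.abs(s["coef"] / s["se"]) < 3)

    def test_wald_interval_coverage_near_nominal(self):
        rng = np.random.default_rng(99)
        beta_d = -6e-6  # distance-effect scale
        covered = 0
        n_rep = 40
        for _ in range(n_rep):
            D = rng.uniform(0, 100_000, 1500)
            eta = 0.2 + beta_d * D
            y = (rng.uniform(size=1500) < 1 / (1 + np.exp(-eta))).astype(int)
            rows = pd.DataFrame({"D": D, "label": y})
            fit = fit_logistic(rows, features=["D"])
            c, se = fit.summary.loc["D", ["coef", "se"]]
            covered += int(c - 1.96 * se <= beta_d <= c + 1.96 * se)
        assert covered >= 33  # ~95% nominal at 40 replicates

    def test_separation_flagged(self, rng):
        rows = pd.DataFrame({"x": np.r_[np.zeros(15), np.ones(15)],
                             "label": np.r_[np.zeros(15), np.ones(15)].astype(int)})
        with pytest.warns(SeparationWarning):
            fit = fit_logistic(rows, features=["x"])
        assert fit.separation

    def test_rank_deficiency_names_columns(self, rng):
        n = 40
        x = rng.integers(2, size=n)
        rows = pd.DataFrame({"a": x, "b": x, "label": rng.integers(2, size=n)})
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(rows, features=["a", "b"])

    def test_requires_both_labels(self, rng):
        rows = pd.DataFrame({"x": rng.normal(size=30), "label": np.ones(30, int)})
        with pytest.raises(ValueError):
            fit_logistic(rows, features=["x"])
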