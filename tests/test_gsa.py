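import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from mirseq.containers import GeneSet, TargetMap
from mirseq.gsa import (
    DIRECTION_NEGATIVE,
    DIRECTION_POSITIVE,
    fit_logistic_gsa,
    gsa_collection,
    mirna_score,
    mirna_scores,
    mrna_scores,
    run_gsa,
)


def logistic_mle_oracle(x, y):
    """Independent maximizer of the logistic log-likelihood."""
    X = np.column_stack([np.ones_like(x), x])

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

    res = minimize(nll, np.zeros(2), method="BFGS", options={"gtol": 1e-10})
    return res.x[1]


class TestMirnaScore:
    @pytest.mark.parametrize(
        "p_adj,log2fc,expected",
        [
            (0.01, -2.0, -2.0),
            (0.01, 2.0, 2.0),
            (1.0, 5.0, 0.0),
            (1.0, -5.0, 0.0),
            (0.1, 0.0, 0.0),   # signum(0) = 0
        ],
    )
    def test_formula(self, p_adj, log2fc, expected):
        assert mirna_score(p_adj, log2fc) == expected

    def test_zero_p_floored(self):
        assert mirna_score(0.0, 1.0) == pytest.approx(300.0)
        assert mirna_score(0.0, -1.0) == pytest.approx(-300.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            mirna_score(1.5, 1.0)


class TestMrnaScores:
    def test_two_contributors(self):
        tm = TargetMap(
            targets={"miA": ("m1",), "miB": ("m1",)}, universe=("m1", "m2")
        )
        scores = pd.Series({"miA": 2.0, "miB": -1.0}, name="s_mirna")
        out = mrna_scores(scores, tm)
        assert out.loc["m1", "s_mrna"] == -1.0
        assert out.loc["m1", "n_targeting"] == 2

    def test_untargeted_mrna_scores_zero(self):
        tm = TargetMap(targets={"miA": ("m1",)}, universe=("m1", "m2"))
        out = mrna_scores(pd.Series({"miA": 3.0}), tm)
        assert out.loc["m2", "s_mrna"] == 0.0
        assert out.loc["m2", "n_targeting"] == 0

    def test_empty_target_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mrna_scores(pd.Series({"miA": 1.0}), TargetMap(targets={}, universe=("m1",)))

    def test_unmapped_mirnas_skipped(self):
        tm = TargetMap(targets={"miA": ("m1",)}, universe=("m1",))
        out = mrna_scores(pd.Series({"miA": 1.0, "miZ": 99.0}), tm)
        assert out.loc["m1", "s_mrna"] == -1.0

    def test_random_map_against_brute_force_sum(self, rng):
        mirnas = [f"mi{i}" for i in range(10)]
        mrnas = [f"m{i}" for i in range(30)]
        pairs = set()
        while len(pairs) < 100:
            pairs.add((mirnas[rng.integers(10)], mrnas[rng.integers(30)]))
        targets: dict[str, list[str]] = {}
        for mi, mr in sorted(pairs):
            targets.setdefault(mi, []).append(mr)
        tm = TargetMap(
            targets={k: tuple(v) for k, v in targets.items()},
            universe=tuple(mrnas),
        )
        scores = pd.Series({mi: rng.normal() for mi in mirnas})
        out = mrna_scores(scores, tm)
        for mr in mrnas:
            brute = -sum(scores[mi] for mi, m in pairs if m == mr)
            assert out.loc[mr, "s_mrna"] == pytest.approx(brute, abs=1e-12)


class TestFitLogistic:
    def test_agrees_with_likelihood_maximization_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(40, 120))
            x = rng.normal(size=n)
            beta_true = rng.uniform(-1.5, 1.5)
            y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + beta_true * x)))).astype(float)
            if y.sum() < 3 or y.sum() > n - 3:
                continue
            fit = fit_logistic_gsa(x, y)
            if not fit.usable:
                continue
            assert fit.coefficient == pytest.approx(
                logistic_mle_oracle(x, y), abs=1e-6
            )

    def test_agrees_with_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-0.8 * x))).astype(float)
        fit = fit_logistic_gsa(x, y)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert fit.coefficient == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.std_error == pytest.approx(ref.bse[1], rel=1e-4)

    def test_null_wald_level(self, rng):
        # Membership independent of the scores: Wald p-values should be
        # roughly uniform, so the 0.05 rejection rate stays near nominal.
        x = rng.normal(size=2000)
        hits = 0
        n_sets = 200
        for _ in range(n_sets):
            y = (rng.random(2000) < 0.2).astype(float)
            fit = fit_logistic_gsa(x, y)
            assert fit.usable and abs(fit.coefficient) < 1.0
            hits += fit.p_raw < 0.05
        assert 0.02 <= hits / n_sets <= 0.09

    def test_constant_predictor_flagged_degenerate(self):
        x = np.full(100, 1.3)
        y = np.zeros(100)
        y[:20] = 1
        fit = fit_logistic_gsa(x, y)
        assert fit.separation
        assert math.isinf(fit.std_error)

    def test_planted_negative_set_gives_negative_coefficient(self, rng):
        x = rng.normal(size=500)
        members = x < np.quantile(x, 0.1)
        y = members.astype(float)
        fit = fit_logistic_gsa(x, y)
        assert fit.coefficient < 0


class TestGsaCollection:
    def _score_table(self, rng, n=300):
        return pd.DataFrame(
            {"s_mrna": rng.normal(size=n), "n_targeting": 1, "mirnas": ""},
            index=[f"m{i}" for i in range(n)],
        ).rename_axis("mrna_id")

    def test_all_sets_skipped_gives_empty_table(self, rng, caplog):
        table = self._score_table(rng)
        tiny = [GeneSet("S1", "", ("m0", "m1"))]
        out = gsa_collection(table, tiny)
        assert out.empty
        assert "skipped" in caplog.text

    def test_direction_labels_follow_coefficient_sign(self, rng):
        # members biased toward one tail but interleaved with non-members
        # of similar score, so the fit stays finite
        table = self._score_table(rng)
        scores = table["s_mrna"].to_numpy()
        order = np.argsort(scores)
        low = tuple(table.index[order[:60:2]])
        high = tuple(table.index[order[-60::2]])
        out = gsa_collection(
            table, [GeneSet("LOW", "", low), GeneSet("HIGH", "", high)]
        ).set_index("set_id")
        assert out.loc["LOW", "coefficient"] < 0
        assert out.loc["LOW", "direction"] == DIRECTION_NEGATIVE
        assert out.loc["HIGH", "coefficient"] > 0
        assert out.loc["HIGH", "direction"] == DIRECTION_POSITIVE

    def test_bh_within_collection_and_sorted(self, rng):
        table = self._score_table(rng)
        sets = [
            GeneSet(f"S{i}", "", tuple(
                table.index[rng.choice(300, size=40, replace=False)]
            ))
            for i in range(8)
        ]
        out = gsa_collection(table, sets)
        assert (out["p_adj"].to_numpy()[:-1] <= out["p_adj"].to_numpy()[1:]).all()
        from mirseq.diffexp import bh_adjust
        merged = out.sort_values("set_id").reset_index()
        assert np.allclose(
            merged["p_adj"], bh_adjust(merged["p_raw"].to_numpy()), atol=1e-12
        )


class TestInvariants:
    def test_score_antisymmetry_and_coefficient_flip(self, small_study):
        from mirseq.diffexp import run_diffexp
        from mirseq.reads import apply_min_count

        _, _, counts, _, tm, gene_sets, _ = small_study
        de = run_diffexp(apply_min_count(counts))
        flipped = de.copy()
        flipped["log2fc"] = -flipped["log2fc"]
        s1 = mirna_scores(de)
        s2 = mirna_scores(flipped)
        assert np.allclose(s1.to_numpy(), -s2.to_numpy())
        m1 = mrna_scores(s1, tm)
        m2 = mrna_scores(s2, tm)
        assert np.allclose(m1["s_mrna"], -m2["s_mrna"])
        g1 = gsa_collection(m1, gene_sets).set_index("set_id")
        g2 = gsa_collection(m2, gene_sets).set_index("set_id")
        shared = g1.index.intersection(g2.index)
        assert np.allclose(
            g1.loc[shared, "coefficient"],
            -g2.loc[shared, "coefficient"],
            atol=1e-6,
        )

    def test_score_splitting_linearity(self):
        # Splitting one miRNA into two with the same targets and half the
        # score each leaves every mRNA score unchanged.
        tm1 = TargetMap(targets={"mi": ("m1", "m2")}, universe=("m1", "m2", "m3"))
        tm2 = TargetMap(
            targets={"miA": ("m1", "m2"), "miB": ("m1", "m2")},
            universe=("m1", "m2", "m3"),
        )
        out1 = mrna_scores(pd.Series({"mi": 4.0}), tm1)
        out2 = mrna_scores(pd.Series({"miA": 2.0, "miB": 2.0}), tm2)
        assert np.allclose(out1["s_mrna"], out2["s_mrna"])

    def test_sign_semantics_on_constructed_fixture(self):
        # One set holds only targets of a significantly UPregulated miRNA:
        # its members are strongly negatively scored, the coefficient must
        # be negative ("increased negative regulation"); mirror for down.
        universe = tuple(f"m{i}" for i in range(200))
        tm = TargetMap(
            targets={
                "mi-up-a": universe[:60],
                "mi-up-b": universe[:30],
                "mi-down-a": universe[60:120],
                "mi-down-b": universe[60:90],
            },
            universe=universe,
        )
        de = pd.DataFrame(
            {
                "mirna_id": ["mi-up-a", "mi-up-b", "mi-down-a", "mi-down-b"],
                "log2fc": [2.0, 1.0, -2.0, -1.0],
                "p_adj": [1e-3, 1e-2, 1e-3, 1e-2],
            }
        )
        scores = mirna_scores(de)
        table = mrna_scores(scores, tm)
        # each set holds only targets of one direction, straddling two
        # score levels and interleaved with equally scored non-members so
        # the fit stays finite
        up_set = GeneSet("UP_TARGETS", "", universe[15:45])
        down_set = GeneSet("DOWN_TARGETS", "", universe[75:105])
        out = gsa_collection(table, [up_set, down_set]).set_index("set_id")
        assert out.loc["UP_TARGETS", "coefficient"] < 0
        assert out.loc["UP_TARGETS", "direction"] == DIRECTION_NEGATIVE
        assert out.loc["DOWN_TARGETS", "coefficient"] > 0
        assert out.loc["DOWN_TARGETS", "direction"] == DIRECTION_POSITIVE


def test_run_gsa_recovers_planted_sets(small_study):
    from mirseq.diffexp import run_diffexp
    from mirseq.reads import apply_min_count

    _, _, counts, _, tm, gene_sets, truth = small_study
    de = run_diffexp(apply_min_count(counts))
    out = run_gsa(de, tm, {"custom": gene_sets}).set_index("set_id")
    for set_id, sign in truth.enriched_sets.items():
        assert set_id in out.index
        assert bool(out.loc[set_id, "significant"])
        assert np.sign(out.loc[set_id, "coefficient"]) == sign
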