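"""Smoothed logit, t-tests and the split-plot ANOVA decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from seedfate.classical import (
    SmoothedLogitParams,
    auto_smoothing_constant,
    smoothed_logit,
    smoothed_logit_fraction,
    splitplot_anova,
    t_test_vs_control,
)
from seedfate.plates import CONTROL, DesignError, ResponseKind, SeedFateError, Species
from seedfate.simulate import CellParams, SyntheticConfig, generate

from conftest import build_dataset, germination_dataset

G, M = ResponseKind.GERMINATION, ResponseKind.MORTALITY
BRTO, PLOV = Species.BRTO, Species.PLOV


class TestSmoothedLogit:
    def test_closed_forms(self):
        assert smoothed_logit(5, 10, 0.1) == pytest.approx(0.0)
        assert smoothed_logit(0, 10, 0.1) == pytest.approx(math.log(1 / 11))
        assert smoothed_logit(10, 10, 0.1) == pytest.approx(math.log(11))

    @given(x=st.integers(0, 20), c=st.floats(0.01, 2.0))
    def test_antisymmetry(self, x, c):
        assert smoothed_logit(x, 20, c) == pytest.approx(
            -smoothed_logit(20 - x, 20, c), abs=1e-12
        )

    def test_monotone_in_count(self):
        vals = [smoothed_logit(x, 10, 0.1) for x in range(11)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_constant_rejected(self):
        with pytest.raises(SeedFateError):
            smoothed_logit(3, 10, 0.0)
        with pytest.raises(SeedFateError):
            SmoothedLogitParams(c=-0.1)


class TestAutoConstant:
    def test_ten_seed_plates_give_point_one(self):
        ds = germination_dataset([3, 1, 5], [0, 2, 4])
        assert auto_smoothing_constant(ds, "summer", G) == pytest.approx(0.1)

    def test_twenty_seed_plates_give_point_o_five(self):
        ds = germination_dataset([3, 1, 5], [0, 2, 4], n_total=20)
        assert auto_smoothing_constant(ds, "summer", G) == pytest.approx(0.05)

    def test_all_zero_fractions_rejected(self):
        ds = germination_dataset([3, 1], [0, 2])
        with pytest.raises(DesignError, match="zero"):
            auto_smoothing_constant(ds, "summer", M)


class TestTTest:
    def test_identical_cells_null(self):
        ds = germination_dataset([1, 2, 3], [1, 2, 3])
        r = t_test_vs_control(ds, "01", BRTO, "summer", G, c=0.1)
        assert r.t_stat == 0.0 and r.p_value == 1.0
        assert r.df == 4

    def test_matches_pooled_variance_oracle(self):
        ds = germination_dataset([5, 7, 6, 8, 9], [1, 2, 1, 2, 3])
        c = 0.1
        r = t_test_vs_control(ds, "01", BRTO, "summer", G, c=c)
        yt = [smoothed_logit_fraction(x / 10, c) for x in (5, 7, 6, 8, 9)]
        yc = [smoothed_logit_fraction(x / 10, c) for x in (1, 2, 1, 2, 3)]
        ref = stats.ttest_ind(yt, yc, equal_var=True)
        assert r.t_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-12)
        # textbook pooled SE
        sp2 = (np.var(yt, ddof=1) + np.var(yc, ddof=1)) / 2
        assert r.se == pytest.approx(math.sqrt(sp2 * 2 / 5), rel=1e-12)

    def test_zero_variance_unequal_means_flagged(self):
        ds = germination_dataset([7, 7, 7], [2, 2, 2])
        r = t_test_vs_control(ds, "01", BRTO, "summer", G, c=0.1)
        assert r.degenerate and r.p_value == 0.0 and math.isinf(r.t_stat)

    def test_too_few_replicates_rejected(self):
        ds = germination_dataset([7], [2])
        with pytest.raises(DesignError, match="replicates"):
            t_test_vs_control(ds, "01", BRTO, "summer", G, c=0.1)


def projection_oracle_ss(y):
    """Sequential nested-least-squares sums of squares for a split plot.

    ``y`` has shape (S, R, 2).  Models grow intercept -> +strain ->
    +plate(strain) -> +species -> +strain:species; each SS is the drop in
    residual SS, and the residual SS of the full model closes the total.
    """
    S, R, K = y.shape
    obs = []
    rows = []
    for s in range(S):
        for r in range(R):
            for k in range(K):
                obs.append(y[s, r, k])
                rows.append((s, r, k))
    obs = np.array(obs)

    def dummies(levels, n_levels):
        m = np.zeros((len(rows), n_levels))
        for i, lv in enumerate(levels):
            m[i, lv] = 1.0
        return m

    strain = dummies([s for s, r, k in rows], S)
    plate = dummies([s * R + r for s, r, k in rows], S * R)
    species = dummies([k for s, r, k in rows], K)
    inter = dummies([s * K + k for s, r, k in rows], S * K)
    intercept = np.ones((len(rows), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, obs, rcond=None)
        resid = obs - X @ beta
        return float(resid @ resid)

    X = intercept
    out = {}
    prev = rss(X)
    for name, block in [
        ("strain", strain),
        ("plate(strain)", plate),
        ("species", species),
        ("strain:species", inter),
    ]:
        X = np.hstack([X, block])
        cur = rss(X)
        out[name] = prev - cur
        prev = cur
    out["residual"] = prev
    return out


class TestSplitPlotAnova:
    def test_full_design_df(self, standard_dataset):
        t = splitplot_anova(standard_dataset, "winter", G, c=0.1)
        inter = t.interaction
        assert (inter.df, t.row("residual").df) == (17, 72)
        assert t.row("strain").df == 17 and t.row("plate(strain)").df == 72
        total_df = sum(r.df for r in t.rows)
        assert total_df == 2 * 18 * 5 - 1

    def test_constant_response_degenerate(self):
        ds = build_dataset(
            {
                ("01", "summer"): [((3, 0, 7), (3, 0, 7))] * 2,
                ("02", "summer"): [((3, 0, 7), (3, 0, 7))] * 2,
                (CONTROL, "summer"): [((3, 0, 7), (3, 0, 7))] * 2,
            }
        )
        t = splitplot_anova(ds, "summer", G, c=0.1)
        assert t.degenerate
        assert all(r.ss == 0.0 for r in t.rows)
        assert t.interaction.f is None and t.interaction.p is None

    def test_unbalanced_design_rejected(self):
        ds = build_dataset(
            {
                ("01", "summer"): [((3, 0, 7), (2, 0, 8))] * 3,
                ("02", "summer"): [((4, 0, 6), (1, 0, 9))] * 2,
                (CONTROL, "summer"): [((1, 0, 9), (1, 0, 9))] * 2,
            }
        )
        with pytest.raises(DesignError, match="unbalanced"):
            splitplot_anova(ds, "summer", G, c=0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_ss_match_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ds = _random_small_dataset(rng, n_strains=3, n_reps=2)
        table = splitplot_anova(ds, "summer", G, c=0.1)
        y = _response_array(ds, c=0.1)
        oracle = projection_oracle_ss(y)
        for name, ss in oracle.items():
            got = table.row(name).ss
            assert got == pytest.approx(ss, rel=1e-8, abs=1e-10), name

    @given(seed=st.integers(0, 10_000))
    def test_ss_decomposition_closes(self, seed):
        rng = np.random.default_rng(seed)
        ds = _random_small_dataset(rng, n_strains=3, n_reps=3)
        table = splitplot_anova(ds, "summer", G, c=0.1)
        y = _response_array(ds, c=0.1)
        total = float(((y - y.mean()) ** 2).sum())
        assert sum(r.ss for r in table.rows) == pytest.approx(
            total, rel=1e-8, abs=1e-12
        )

    def test_interaction_power_with_host_specific_effect(self):
        # three strains carry a 0.3 host-specific germination shift; at the
        # full design size the interaction test should reject often
        cells = {}
        for sp in Species:
            cells[(CONTROL, sp, "summer")] = CellParams(0.3)
        strains = [f"{i:02d}" for i in range(1, 19)]
        for s in strains:
            for sp in Species:
                cells[(s, sp, "summer")] = CellParams(0.3)
        for s in strains[:3]:
            cells[(s, Species.BRTO, "summer")] = CellParams(0.6)
        hits = 0
        n_sims = 60
        for i in range(n_sims):
            cfg = SyntheticConfig(cells=cells, sigma_plate=0.5, rng_seed=1000 + i)
            ds = generate(cfg)
            c = auto_smoothing_constant(ds, "summer", G)
            t = splitplot_anova(ds, "summer", G, c=c)
            hits += t.interaction.p < 0.05
        assert hits / n_sims >= 0.5


def _random_small_dataset(rng, n_strains, n_reps):
    strains = [f"{i:02d}" for i in range(1, n_strains + 1)]
    cells = {}
    for g in strains + [CONTROL]:
        cells[(g, "summer")] = [
            (
                tuple(rng.multinomial(10, [0.3, 0.2, 0.5])),
                tuple(rng.multinomial(10, [0.4, 0.1, 0.5])),
            )
            for _ in range(n_reps)
        ]
    return build_dataset(cells)


def _response_array(ds, c):
    from seedfate.effects import cell_fractions

    strains = ds.strains()
    species = sorted(Species, key=lambda s: s.value)
    reps = len({r.replicate for r in ds.records if r.group == strains[0]})
    y = np.empty((len(strains), reps, 2))
    for i, s in enumerate(strains):
        for k, sp in enumerate(species):
            fr = cell_fractions(ds, s, sp, "summer", G)
            y[i, :, k] = [smoothed_logit_fraction(f, c) for f in fr]
    return y
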