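"""Hot-spot extraction, time budgets and the compositional permutation test."""

import numpy as np
import pandas as pd
import pytest

from energyscape.geometry import GridGeometry
from energyscape.hotspots import (
    Hotspot,
    compare_time_budget,
    compositional_permutation_test,
    extract_hotspots,
    hotspot_table,
)
from energyscape.landscape import CONTINUOUS_COVARIATES, LandscapeStack

CLASSES = ["developed_high", "deciduous_forest", "grassland", "wetland"]


def toy_stack(n=16):
    geom = GridGeometry(0.0, 0.0, 30.0, n, n)
    land = np.indices((n, n)).sum(axis=0) % 4
    stack = LandscapeStack(
        geometry=geom,
        land_cover=land,
        class_names=CLASSES,
        roads=np.zeros((n, n), bool),
    )
    rng = np.random.default_rng(0)
    for name in CONTINUOUS_COVARIATES:
        stack.layers[name] = rng.uniform(size=(n, n))
    return stack


class TestExtractHotspots:
    def test_quantile_cell_counts(self):
        # 100 masked cells with distinct values: q=0.05 -> 5 valley cells
        stack = toy_stack(10)
        pred = np.arange(100, dtype=float).reshape(10, 10)
        ud = np.full((10, 10), 0.01)
        hs = extract_hotspots(pred, ud, np.ones((10, 10), bool), stack, q=0.05)
        n_valley = sum(len(h.cells[0]) for h in hs if h.type == "valley")
        n_peak = sum(len(h.cells[0]) for h in hs if h.type == "peak")
        assert n_valley == 5 and n_peak == 5

    def test_valleys_peaks_disjoint(self, rng):
        stack = toy_stack(16)
        pred = rng.normal(size=(16, 16))
        ud = np.full((16, 16), 1 / 256)
        hs = extract_hotspots(pred, ud, np.ones((16, 16), bool), stack, q=0.1)
        v = set(zip(*np.concatenate([h.cells for h in hs if h.type == "valley"], axis=1)))
        p = set(zip(*np.concatenate([h.cells for h in hs if h.type == "peak"], axis=1)))
        assert not v & p

    def test_components_match_bfs_oracle(self, rng):
        stack = toy_stack(16)
        pred = rng.normal(size=(16, 16))
        mask = rng.uniform(size=(16, 16)) < 0.8
        ud = np.full((16, 16), 1 / 256)
        hs = extract_hotspots(pred, ud, mask, stack, q=0.15)
        for typ in ("valley", "peak"):
            sel = np.zeros((16, 16), bool)
            for h in hs:
                if h.type == typ:
                    sel[h.cells] = True
            comps = _bfs_components(sel)
            got = sorted(
                sorted(zip(*h.cells)) for h in hs if h.type == typ
            )
            assert sorted(comps) == got

    def test_constant_prediction_warns_empty(self):
        stack = toy_stack(10)
        with pytest.warns(UserWarning, match="coincide"):
            hs = extract_hotspots(
                np.ones((10, 10)),
                np.full((10, 10), 0.01),
                np.ones((10, 10), bool),
                stack,
                q=0.05,
            )
        assert hs == []

    def test_empty_mask_rejected(self):
        stack = toy_stack(10)
        with pytest.raises(ValueError):
            extract_hotspots(
                np.ones((10, 10)), np.ones((10, 10)), np.zeros((10, 10), bool), stack
            )


def _bfs_components(sel):
    """Naive 8-connectivity flood fill."""
    seen = np.zeros_like(sel)
    comps = []
    for i, j in zip(*np.nonzero(sel)):
        if seen[i, j]:
            continue
        stack_, comp = [(i, j)], []
        seen[i, j] = True
        while stack_:
            a, b = stack_.pop()
            comp.append((a, b))
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    u, v = a + da, b + db
                    if (
                        0 <= u < sel.shape[0]
                        and 0 <= v < sel.shape[1]
                        and sel[u, v]
                        and not seen[u, v]
                    ):
                        seen[u, v] = True
                        stack_.append((u, v))
        comps.append(sorted(comp))
    return comps


def make_hotspots(rng, n_ind=4, per_type=4, dwell_ratio=1.0, separated=False, area_time=False):
    hs = []
    for i in range(n_ind):
        for t, typ in enumerate(("valley", "peak")):
            for k in range(per_type):
                ncells = int(rng.integers(2, 12))
                area = ncells * 900.0
                base = rng.uniform(0.002, 0.01)
                share = base * (dwell_ratio if typ == "valley" else 1.0)
                if area_time:
                    share = area * 1e-6 * rng.uniform(0.9, 1.1)
                if separated:
                    prof = {
                        "dist_forest_edge": rng.normal(3.0 if typ == "valley" else -3.0, 0.5),
                        "prop_urban_240": rng.normal(0.2 if typ == "valley" else 0.8, 0.05),
                        "heterogeneity": rng.normal(),
                        "dist_roads": rng.normal(),
                    }
                else:
                    prof = {c: rng.normal() for c in CONTINUOUS_COVARIATES}
                hs.append(
                    Hotspot(
                        type=typ,
                        cells=(np.zeros(ncells, int), np.arange(ncells)),
                        area=area,
                        time_share=share,
                        env_profile=prof,
                        individual_id=f"I{i}",
                    )
                )
    return hs


class TestTimeBudget:
    def test_null_covers_zero(self, rng):
        hs = make_hotspots(rng, dwell_ratio=1.0)
        out = compare_time_budget(hs)
        est, se = out.loc["is_valley", "est"], out.loc["is_valley", "se"]
        assert abs(est) < 2.5 * se

    def test_planted_dwell_recovered(self, rng):
        hs = make_hotspots(rng, dwell_ratio=3.0)
        out = compare_time_budget(hs)
        assert out.loc["is_valley", "est"] > 0
        assert out.loc["is_valley", "p"] < 0.05

    def test_area_effect_positive_by_construction(self, rng):
        hs = make_hotspots(rng, area_time=True)
        out = compare_time_budget(hs)
        assert out.loc["area", "est"] > 0

    def test_single_type_rejected(self, rng):
        hs = [h for h in make_hotspots(rng) if h.type == "valley"]
        with pytest.raises(ValueError):
            compare_time_budget(hs)


class TestCompositionalPermutation:
    def test_planted_separation_detected(self, rng):
        hs = make_hotspots(rng, separated=True)
        res = compositional_permutation_test(hs, n_perm=199, seed=0)
        assert res["p"] <= 0.05
        assert res["pseudo_f"] > 1

    def test_matches_skbio_pseudo_f(self, rng):
        from skbio.stats.distance import DistanceMatrix, permanova

        hs = make_hotspots(rng, n_ind=1, per_type=8)
        res = compositional_permutation_test(hs, n_perm=49, seed=1, include_area=False)
        tab = hotspot_table(hs)
        P = tab[list(CONTINUOUS_COVARIATES)].to_numpy()
        Z = (P - P.mean(0)) / P.std(0)
        D = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(2))
        ref = permanova(DistanceMatrix(D), tab["type"].tolist(), permutations=49)
        assert res["pseudo_f"] == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_invalid_n_perm_rejected(self, rng):
        with pytest.raises(ValueError):
            compositional_permutation_test(make_hotspots(rng), n_perm=0)

    def test_seed_stability_within_mc_error(self, rng):
        hs = make_hotspots(rng, separated=False)
        ps = [
            compositional_permutation_test(hs, n_perm=199, seed=s)["p"]
            for s in range(4)
        ]
        se = np.sqrt(np.mean(ps) * (1 - np.mean(ps)) / 199)
        assert np.ptp(ps) <= 6 * se + 1e-9
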