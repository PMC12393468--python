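"""Ring geometry, LR scoring, distance decay and permutation significance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spotcell import context as ctx
from spotcell.io import LREntry, LRTable, SpotMatrix


def _spots_at(coords, is_vas, n_genes=3):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return SpotMatrix(
        counts=np.ones((n, n_genes), dtype=int),
        spot_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{i}" for i in range(n_genes)],
        x=coords[:, 0],
        y=coords[:, 1],
        sample_id="S1",
        group="AC",
        is_vas=np.asarray(is_vas, dtype=bool),
    )


def brute_force_levels(coords, is_vas, radii=(200.0, 400.0, 600.0)):
    """Oracle: per-spot min distance over all VAS spots, binned explicitly."""
    coords = np.asarray(coords, dtype=float)
    vas = coords[np.asarray(is_vas, bool)]
    out = []
    for i, (x, y) in enumerate(coords):
        if is_vas[i]:
            out.append("VAS")
            continue
        if len(vas) == 0:
            out.append("4")
            continue
        d = min(np.hypot(x - vx, y - vy) for vx, vy in vas)
        if d <= radii[0]:
            out.append("1")
        elif d <= radii[1]:
            out.append("2")
        elif d <= radii[2]:
            out.append("3")
        else:
            out.append("4")
    return np.asarray(out, dtype=object)


class TestRingLevels:
    def test_worked_distance_examples(self):
        coords = [(0, 0), (0, 150), (300, 400), (0, 650)]
        sm = _spots_at(coords, [True, False, False, False])
        ra = ctx.ring_levels(sm)
        assert list(ra.level) == ["VAS", "1", "3", "4"]
        assert np.allclose(ra.distance_px, [0.0, 150.0, 500.0, 650.0])

    def test_nearest_vessel_tie_break(self):
        coords = [(0, 0), (1000, 0), (250, 0)]
        sm = _spots_at(coords, [True, True, False])
        ra = ctx.ring_levels(sm)
        assert ra.level[2] == "2"
        assert ra.distance_px[2] == pytest.approx(250.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        coords = rng.uniform(0, 2000, size=(n, 2))
        is_vas = rng.random(n) < 0.05
        is_vas[0] = True  # guarantee at least one vessel spot
        sm = _spots_at(coords, is_vas)
        ra = ctx.ring_levels(sm)
        assert np.array_equal(ra.level, brute_force_levels(coords, is_vas))

    def test_no_vas_sample_warns_all_level_four(self):
        sm = _spots_at([(0, 0), (10, 10)], [False, False])
        with pytest.warns(UserWarning, match="no VAS"):
            ra = ctx.ring_levels(sm)
        assert (ra.level == "4").all()
        assert np.isinf(ra.distance_px).all()

    def test_non_increasing_radii_rejected(self):
        sm = _spots_at([(0, 0)], [True])
        with pytest.raises(ValueError, match="increasing"):
            ctx.ring_levels(sm, radii=(400.0, 200.0, 600.0))


class TestGroupProfile:
    def test_zero_trim_is_plain_mean(self):
        expr = np.log1p(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
        labels = ["a", "a", "a"]
        out = ctx.group_profile(expr, labels, trim=0.0, normalized=True)
        assert np.allclose(out.loc["a"], [3.0, 4.0])

    def test_hand_trimmed_outlier(self):
        values = np.array([0.0, 0.0, 0.0, 0.0, 100.0])
        expr = np.log1p(values)[:, None]
        out = ctx.group_profile(expr, ["a"] * 5, trim=0.2, normalized=True)
        assert out.loc["a"].iloc[0] == pytest.approx(0.0)

    def test_constant_vector_invariant_to_trim(self):
        expr = np.log1p(np.full((12, 2), 7.0))
        for trim in (0.0, 0.1, 0.25):
            out = ctx.group_profile(expr, ["a"] * 12, trim=trim, normalized=True)
            assert np.allclose(out.loc["a"], 7.0)

    def test_small_group_falls_back_to_mean(self):
        expr = np.log1p(np.array([[0.0], [0.0], [30.0]]))
        out = ctx.group_profile(expr, ["a"] * 3, trim=0.25, normalized=True)
        assert out.loc["a"].iloc[0] == pytest.approx(10.0)


class TestLRStrength:
    ENTRY = LREntry("NT", "L", ["R1", "R2"], "L-(R1+R2)")

    def test_zero_ligand_zero_strength(self):
        prof = pd.Series({"L": 0.0, "R1": 2.0, "R2": 2.0})
        L, R, raw, s = ctx.lr_strength(prof, prof, self.ENTRY)
        assert s == 0.0

    def test_half_saturation_identity(self):
        # raw = Kh exactly -> Hill term 0.5
        prof = pd.Series({"L": 1.0, "R1": 0.5, "R2": 0.5})
        _, _, raw, s = ctx.lr_strength(prof, prof, self.ENTRY, Kh=0.5)
        assert raw == pytest.approx(0.5)
        assert s == pytest.approx(0.5)

    def test_geometric_mean_subunits(self):
        prof = pd.Series({"L": 1.0, "R1": 4.0, "R2": 1.0})
        _, R, _, _ = ctx.lr_strength(prof, prof, self.ENTRY)
        assert R == pytest.approx(2.0)

    def test_missing_gene_warns_and_zeroes(self):
        prof = pd.Series({"L": 1.0, "R1": 1.0})
        with pytest.warns(UserWarning, match="R2"):
            _, _, _, s = ctx.lr_strength(prof, prof, self.ENTRY)
        assert s == 0.0

    def test_hill_strictly_increasing_in_raw(self):
        raws = np.linspace(0.01, 5, 30)
        hills = raws / (0.5 + raws)
        assert (np.diff(hills) > 0).all()


class TestDistanceWeights:
    def test_zero_distance_unit_weight(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        labels = ["a", "a", "b", "b"]
        W, lam = ctx.distance_weights(coords, labels)
        assert W.loc["a", "a"] == 1.0

    def test_weight_at_lambda_is_inverse_e(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        labels = ["a", "b"]
        W, lam = ctx.distance_weights(coords, labels)
        assert lam == pytest.approx(10.0)
        assert W.loc["a", "b"] == pytest.approx(np.exp(-1.0))

    def test_collinear_domains_monotone_decay(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
        labels = ["a", "b", "c"]
        W, _ = ctx.distance_weights(coords, labels)
        assert W.loc["a", "b"] > W.loc["a", "c"]

    def test_single_label_trivial(self):
        W, lam = ctx.distance_weights(np.zeros((3, 2)), ["a"] * 3)
        assert W.shape == (1, 1) and W.iloc[0, 0] == 1.0


def _pair(lig="gL", rec="gR"):
    return LRTable([LREntry("NT", lig, [rec], f"{lig}-{rec}")])


class TestBuildNetwork:
    def test_directional_planted_topology(self):
        """Ligand expressed only in DG, receptor only in CA4: the single
        nonzero entry is DG -> CA4."""
        rng = np.random.default_rng(6)
        n = 120
        labels = np.array(["DG"] * 40 + ["CA4"] * 40 + ["SR"] * 40, dtype=object)
        expr = np.zeros((n, 2))
        expr[labels == "DG", 0] = np.log1p(rng.uniform(50, 100, 40))
        expr[labels == "CA4", 1] = np.log1p(rng.uniform(50, 100, 40))
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        net = ctx.build_network(
            expr, labels, _pair(), gene_ids=["gL", "gR"], coords=coords,
            normalized=True, expr_scale=1.0,
        )
        nonzero = net.entries[net.entries["strength"] > 0]
        assert len(nonzero) == 1
        assert (nonzero.iloc[0]["sender"], nonzero.iloc[0]["receiver"]) == ("DG", "CA4")

    def test_all_zero_expression_all_zero_strengths(self):
        labels = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        net = ctx.build_network(
            np.zeros((20, 2)), labels, _pair(), gene_ids=["gL", "gR"],
            mode="cell_cell", normalized=True,
        )
        assert (net.entries["strength"] == 0).all()

    def test_raising_ligand_never_decreases_outgoing(self):
        rng = np.random.default_rng(7)
        labels = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        base = np.abs(rng.normal(1, 0.2, size=(60, 2)))
        boosted = base.copy()
        boosted[labels == "a", 0] *= 5
        out = []
        for expr in (base, boosted):
            net = ctx.build_network(
                np.log1p(expr), labels, _pair(), gene_ids=["gL", "gR"],
                mode="cell_cell", normalized=True, expr_scale=1.0,
            )
            out.append(net.nodes.set_index("node").loc["a", "outgoing"])
        assert out[1] >= out[0]

    def test_strength_decreases_with_centroid_distance(self):
        labels = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        rng = np.random.default_rng(8)
        expr = np.log1p(np.abs(rng.normal(2, 0.1, size=(40, 2))))
        strengths = []
        for gap in (10.0, 2000.0):
            coords = np.column_stack(
                [np.concatenate([np.zeros(20), np.full(20, gap)]), np.zeros(40)]
            )
            net = ctx.build_network(
                expr, labels, _pair(), gene_ids=["gL", "gR"], coords=coords,
                normalized=True, expr_scale=1.0, lam=500.0,
            )
            e = net.entries
            strengths.append(
                float(e[(e.sender == "a") & (e.receiver == "b")]["strength"].iloc[0])
            )
        assert strengths[1] < strengths[0]

    def test_node_sums_match_entry_sums(self):
        rng = np.random.default_rng(9)
        labels = rng.choice(["a", "b", "c"], 60)
        expr = np.log1p(np.abs(rng.normal(1, 1, size=(60, 2))))
        net = ctx.build_network(
            expr, labels, _pair(), gene_ids=["gL", "gR"], mode="cell_cell",
            normalized=True,
        )
        for _, row in net.nodes.iterrows():
            e = net.entries
            assert row["outgoing"] == pytest.approx(
                e[e.sender == row["node"]]["strength"].sum()
            )
            assert row["incoming"] == pytest.approx(
                e[e.receiver == row["node"]]["strength"].sum()
            )

    def test_empty_lr_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ctx.build_network(np.ones((4, 1)), ["a"] * 4, LRTable([]), mode="cell_cell")


class TestPermutationSignificance:
    def test_low_n_perm_rejected(self):
        with pytest.raises(ValueError, match="20"):
            ctx.permutation_significance(
                np.ones((4, 2)), ["a", "a", "b", "b"], _pair(), n_perm=5
            )

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(10)
        expr = np.log1p(np.abs(rng.normal(1, 1, size=(50, 2))))
        labels = rng.choice(["a", "b"], 50)
        kw = dict(gene_ids=["gL", "gR"], mode="cell_cell", n_perm=25,
                  normalized=True)
        n1 = ctx.permutation_significance(expr, labels, _pair(), seed=3, **kw)
        n2 = ctx.permutation_significance(expr, labels, _pair(), seed=3, **kw)
        assert n1.entries["p_raw"].equals(n2.entries["p_raw"])

    def test_null_p_values_super_uniform(self):
        """Exchangeable labels: P(p <= alpha) <= alpha + 1/(n_perm+1) at
        every alpha (pooled over independent replicates)."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(25):
            expr = np.log1p(rng.lognormal(0, 1, size=(60, 2)))
            labels = rng.choice(["a", "b"], 60)
            net = ctx.permutation_significance(
                expr, labels, _pair(), gene_ids=["gL", "gR"], mode="cell_cell",
                n_perm=49, seed=int(rng.integers(2**31)), normalized=True,
            )
            ps.extend(net.entries["p_raw"].tolist())
        ps = np.asarray(ps)
        for alpha in (0.02, 0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 1 / 50 + 0.03

    def test_bonferroni_uses_entry_count(self):
        rng = np.random.default_rng(12)
        expr = np.log1p(np.abs(rng.normal(1, 1, size=(40, 2))))
        labels = rng.choice(["a", "b"], 40)
        net = ctx.permutation_significance(
            expr, labels, _pair(), gene_ids=["gL", "gR"], mode="cell_cell",
            n_perm=30, seed=0, normalized=True,
        )
        m = len(net.entries)
        expect = np.minimum(1.0, net.entries["p_raw"] * m)
        assert np.allclose(net.entries["p_adj"], expect)


class TestRingDGE:
    def test_equal_levels_rejected(self, annotated_psm):
        annotated, _ = annotated_psm
        with pytest.raises(ValueError, match="differ"):
            ctx.ring_dge(annotated, "Ast", "1", "1")

    def test_insufficient_cells_named(self):
        from spotcell.psm import PseudoCellMatrix

        meta = pd.DataFrame(
            {
                "cell_id": ["c0", "c1"],
                "spot_id": ["s0", "s1"],
                "type_origin": ["Ast", "Ast"],
                "type_inferred": ["", ""],
                "domain": ["CA1", "CA1"],
                "sample_id": ["S", "S"],
                "group": ["AC", "AC"],
                "level": ["1", "3"],
                "theta": [0.5, 0.5],
            }
        )
        psm = PseudoCellMatrix(
            counts=np.ones((2, 3), dtype=int),
            fractional=np.ones((2, 3)),
            gene_ids=np.asarray(["g0", "g1", "g2"], dtype=object),
            meta=meta,
        )
        with pytest.raises(ValueError, match="level"):
            ctx.ring_dge(psm, "Ast", "1", "3")
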