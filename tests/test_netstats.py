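"""FC matrices, effect sizes, NBS correction and lobe-block statistics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from bsfc import synth
from bsfc._glm import DesignError
from bsfc.netstats import (
    FCMatrix,
    edge_index,
    edgewise_group_stats,
    fc_matrix,
    fisher_z,
    hedges_g,
    load_partition,
    lobe_block_permutation,
    lobe_block_residuals,
    nbs_correction,
)
from bsfc.preproc import BOLDRun


def _fc_from_data(data, labels=None, **kw):
    labels = labels or [f"P{i:02d}" for i in range(data.shape[0])]
    run = BOLDRun(data=data, region_labels=labels, tr=2.0,
                  subject=kw.pop("subject", "O"), group=kw.pop("group", "SW"))
    m = fc_matrix(run)
    m.subject, m.group = run.subject, run.group
    return m


def _null_cohort(rng, n_parcels=16, n_bs=8, n_sw=6, n_vol=80):
    mats, groups, subjects = [], [], []
    for i in range(n_bs + n_sw):
        g = "BS" if i < n_bs else "SW"
        s = "O" if i % 2 == 0 else "T"
        mats.append(
            _fc_from_data(rng.standard_normal((n_parcels, n_vol)), subject=s, group=g)
        )
        groups.append(g)
        subjects.append(s)
    return mats, groups, subjects


class TestFCMatrix:
    def test_duplicated_parcel_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        data = np.vstack([x, x.copy(), rng.standard_normal(100)])
        m = _fc_from_data(data)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_sinusoids_uncorrelated(self):
        t = np.arange(200)
        data = np.vstack([np.sin(2 * np.pi * t / 20), np.cos(2 * np.pi * t / 20)])
        m = _fc_from_data(data)
        assert abs(m.values[0, 1]) < 1e-10

    def test_zero_variance_parcel_named(self):
        data = np.vstack([np.zeros(50), np.random.default_rng(1).standard_normal(50)])
        run = BOLDRun(data=data, region_labels=["DEAD", "ALIVE"], tr=2.0,
                      subject="O", group="SW")
        with pytest.raises(ValueError, match="DEAD"):
            fc_matrix(run)

    def test_factor_block_matches_loading_closed_form(self):
        blocks = (synth.LatentBlock("b", ("P00", "P01", "P02"), baseline_loading=0.7),)
        params = synth.BOLDSimParams(
            n_parcels=6, n_volumes=3000, coupling_betas=np.zeros(6),
            latent_block_spec=blocks, nuisance_gain=0.0, noise_sd=0.5,
        )
        run = synth.simulate_bold_run(
            None, params, "O", "SW", seed=2,
            region_labels=[f"P{i:02d}" for i in range(6)],
        )
        m = fc_matrix(run)
        expected = 0.49 / (0.49 + 0.25)
        got = np.mean([m.values[i, j] for i, j in combinations(range(3), 2)])
        assert abs(got - expected) <= 0.05


class TestFisherZ:
    def test_closed_form_values(self):
        vals = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -0.5], [0.5, -0.5, 1.0]])
        m = FCMatrix(values=vals, region_labels=["a", "b", "c"], scale="r")
        z = fisher_z(m)
        assert z.values[0, 1] == 0.0
        assert z.values[0, 2] == pytest.approx(0.5493, abs=1e-4)
        assert z.scale == "z"

    def test_inverse_identity(self):
        rng = np.random.default_rng(3)
        m = _fc_from_data(rng.standard_normal((5, 60)))
        z = fisher_z(m)
        back = np.tanh(z.values)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(back[off], m.values[off], atol=1e-12)

    def test_unit_correlation_rejected(self):
        vals = np.corrcoef(np.random.default_rng(4).standard_normal((3, 10)))
        vals[0, 1] = vals[1, 0] = 1.0  # exactly collinear pair
        m = FCMatrix(values=vals, region_labels=["a", "b", "c"], scale="r")
        with pytest.raises(ValueError, match="infinite"):
            fisher_z(m)


class TestHedgesG:
    def test_identical_samples_zero(self):
        assert hedges_g([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_example(self):
        # J = 1 - 3/(4*4-9) = 4/7; s_pooled = sqrt(2); diff = -1
        assert hedges_g([0, 2], [1, 3]) == pytest.approx(-0.404, abs=5e-4)

    def test_antisymmetric_under_swap(self):
        x, y = [0.0, 1.5, 2.0], [2.5, 3.0, 4.5]
        assert hedges_g(x, y) == pytest.approx(-hedges_g(y, x))

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError, match="pooled variance"):
            hedges_g([1.0, 1.0], [2.0, 2.0])

    def test_matches_reference_implementation(self):
        import pingouin as pg

        rng = np.random.default_rng(12)
        for _ in range(5):
            x, y = rng.standard_normal(7), rng.standard_normal(5) + 0.5
            assert hedges_g(x, y) == pytest.approx(
                pg.compute_effsize(x, y, eftype="hedges"), abs=1e-10
            )


class TestEdgewiseStats:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((10, 80))
        mats = []
        for g in ("BS", "BS", "SW", "SW"):
            mats.append(_fc_from_data(base + 0.0, group=g, subject="O"))
        out = edgewise_group_stats(mats)
        assert np.allclose(out["t"], 0.0, atol=1e-6)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(6)
        mats = [_fc_from_data(rng.standard_normal((6, 50)), group="BS") for _ in range(4)]
        with pytest.raises(DesignError):
            edgewise_group_stats(mats)

    def test_null_type_i_rate(self):
        rng = np.random.default_rng(7)
        rates = []
        for _ in range(300):
            mats, groups, subjects = _null_cohort(rng, n_parcels=8, n_bs=6, n_sw=5)
            out = edgewise_group_stats(mats, groups, subjects)
            rates.append(np.mean(out["p"] < 0.05))
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_injected_block_effect_detected(self):
        labels = [f"P{i:02d}" for i in range(12)]
        block = synth.LatentBlock("hit", tuple(labels[:5]),
                                  baseline_loading=0.2, bs_loading_delta=0.7)
        params = synth.BOLDSimParams(
            n_parcels=12, coupling_betas=np.zeros(12),
            latent_block_spec=(block,), nuisance_gain=0.0,
        )
        pattern, _ = synth.simulate_bs_pattern(
            synth.BSSimParams(total_duration=400.0, sample_rate=50.0), seed=99
        )
        mats, groups, subjects = [], [], []
        for i in range(16):
            g = "BS" if i < 9 else "SW"
            run = synth.simulate_bold_run(pattern if g == "BS" else None, params,
                                          "O" if i % 2 else "T",
                                          g, seed=100 + i, region_labels=labels)
            # loading delta applies only to BS runs inside the generator
            m = fc_matrix(run)
            m.group, m.subject = g, run.subject
            mats.append(m)
            groups.append(g)
            subjects.append(run.subject)
        out = edgewise_group_stats(mats, groups, subjects)
        i, j = edge_index(12)
        hit = (i < 5) & (j < 5)
        assert np.median(np.abs(out["t"][hit])) > np.median(np.abs(out["t"][~hit]))


class TestNBS:
    def test_trivial_threshold_gives_single_component(self):
        rng = np.random.default_rng(8)
        mats, groups, subjects = _null_cohort(rng, n_parcels=8)
        out = nbs_correction(mats, groups, subjects, edge_alpha=0.999, n_perm=100,
                             seed=0)
        labs = out.component_labels
        assert (labs >= 0).mean() > 0.95  # almost every edge suprathreshold
        assert len({l for l in labs if l >= 0}) == 1

    def test_relabeling_invariance_of_max_component(self):
        rng = np.random.default_rng(9)
        mats, groups, subjects = _null_cohort(rng, n_parcels=10)
        out = nbs_correction(mats, groups, subjects, edge_alpha=0.2, n_perm=100, seed=1)
        perm = rng.permutation(10)
        mats2 = [
            FCMatrix(values=m.values[np.ix_(perm, perm)],
                     region_labels=[m.region_labels[k] for k in perm],
                     scale="r", subject=m.subject, group=m.group)
            for m in mats
        ]
        out2 = nbs_correction(mats2, groups, subjects, edge_alpha=0.2, n_perm=100, seed=1)
        sizes = sorted(np.bincount(out.component_labels[out.component_labels >= 0]).tolist())
        sizes2 = sorted(np.bincount(out2.component_labels[out2.component_labels >= 0]).tolist())
        assert sizes == sizes2

    def test_no_suprathreshold_edges_empty_result(self):
        # two tightly matched groups: nothing survives an extreme threshold
        rng = np.random.default_rng(10)
        mats, groups, subjects = _null_cohort(rng, n_parcels=6, n_bs=4, n_sw=4)
        out = nbs_correction(mats, groups, subjects, edge_alpha=1e-12, n_perm=100, seed=2)
        assert not out.significant.any()
        assert out.component_pvalues == {}

    def test_recovers_injected_clique(self):
        labels = [f"P{k:02d}" for k in range(30)]
        clique = tuple(labels[3:11])
        blocks = (synth.LatentBlock("pert", clique, baseline_loading=0.3,
                                    bs_loading_delta=0.6),)
        params = synth.BOLDSimParams(
            n_parcels=30, latent_block_spec=blocks,
            coupling_beta_mean=0.0, coupling_beta_sd=0.0, nuisance_gain=0.0,
        )
        runs = (
            tuple(synth.RunSpec("O", "BS", 10.0, f"b{i}") for i in range(8))
            + tuple(synth.RunSpec("T", "BS", 10.0, f"c{i}") for i in range(4))
            + tuple(synth.RunSpec("O", "SW", 0.0, f"s{i}") for i in range(5))
            + tuple(synth.RunSpec("T", "SW", 0.0, f"t{i}") for i in range(4))
        )
        spec = synth.CohortSpec(("O", "T"), runs)
        records = synth.simulate_cohort(spec, params, seed=21, region_labels=labels,
                                        with_eeg=False, pattern_sample_rate=50.0)
        mats = [fc_matrix(b) for _, b in records]
        out = nbs_correction(mats, n_perm=500, seed=3)
        i, j = edge_index(30)
        in_clique = np.isin(np.array(labels)[i], clique) & np.isin(np.array(labels)[j], clique)
        assert out.significant[in_clique].mean() >= 0.8


class TestLobeBlocks:
    def _toy(self):
        labels = [f"R{i}" for i in range(6)]
        partition = pd.Series(["A"] * 3 + ["B"] * 3, index=labels)
        return labels, partition

    def test_hand_computed_case(self):
        labels, partition = self._toy()
        mask = np.zeros((6, 6), dtype=bool)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            mask[i, j] = mask[j, i] = True
        res = lobe_block_residuals(mask, partition, labels)
        row = res[(res.lobe_i == "A") & (res.lobe_j == "A")].iloc[0]
        assert row.expected == pytest.approx(0.6)
        assert row.z == pytest.approx(3.098, abs=1e-3)

    def test_saturated_mask_zero_residuals(self):
        labels, partition = self._toy()
        mask = ~np.eye(6, dtype=bool)
        res = lobe_block_residuals(mask, partition, labels)
        assert np.allclose(res.z, 0.0, atol=1e-12)

    def test_residual_conservation(self):
        rng = np.random.default_rng(11)
        labels, partition = self._toy()
        for _ in range(20):
            mask = np.zeros((6, 6), dtype=bool)
            i, j = np.triu_indices(6, 1)
            pick = rng.choice(15, size=rng.integers(1, 15), replace=False)
            mask[i[pick], j[pick]] = True
            mask |= mask.T
            res = lobe_block_residuals(mask, partition, labels)
            assert abs((res.observed - res.expected).sum()) < 1e-10
            assert res.observed.sum() == mask.sum() / 2

    def test_empty_mask_rejected(self):
        labels, partition = self._toy()
        with pytest.raises(ValueError, match="no disrupted"):
            lobe_block_residuals(np.zeros((6, 6), dtype=bool), partition, labels)

    def test_permutation_matches_exact_enumeration(self):
        # D=2 on 6 nodes: enumerate all C(15,2)=105 placements exactly
        labels, partition = self._toy()
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        mask[0, 2] = mask[2, 0] = True
        perm = lobe_block_permutation(mask, partition, labels, n_perm=5000, seed=4)
        obs = lobe_block_residuals(mask, partition, labels)
        i, j = np.triu_indices(6, 1)
        blocks_of_edges = [
            tuple(sorted((partition[labels[a]], partition[labels[b]])))
            for a, b in zip(i, j)
        ]
        names = list(zip(perm.lobe_i, perm.lobe_j))
        m_b = perm.possible_edges.to_numpy()
        E = 2 * m_b / 15
        for row_idx, key in enumerate(names):
            z_obs = obs.z.iloc[row_idx]
            count = 0
            total = 0
            for e1 in range(15):
                for e2 in range(e1 + 1, 15):
                    O = sum(1 for e in (e1, e2) if tuple(sorted(blocks_of_edges[e])) == key)
                    z = (O - E[row_idx]) / np.sqrt(E[row_idx])
                    count += z >= z_obs
                    total += 1
            assert abs(perm.p.iloc[row_idx] - count / total) <= 0.02

    def test_all_edges_in_small_block_is_extreme(self):
        labels, partition = self._toy()
        mask = np.zeros((6, 6), dtype=bool)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            mask[i, j] = mask[j, i] = True
        res = lobe_block_permutation(mask, partition, labels, n_perm=2000, seed=5)
        p_aa = res[(res.lobe_i == "A") & (res.lobe_j == "A")].p.iloc[0]
        assert p_aa == res.p.min()
        assert p_aa < 0.05

    def test_partition_loads_and_covers_94(self, region_labels):
        part = load_partition()
        assert len(part) == 94
        assert set(part.index) == set(region_labels)
        assert part.value_counts().min() >= 2
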