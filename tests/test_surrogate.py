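import numpy as np
import pytest

from apscreen.agglaws import net_side_chain_charge
from apscreen.seqspace import Peptide, lhs_sample
from apscreen.surrogate import (
    DEFAULT_PARAMS,
    SurrogateParams,
    fit_position_weights,
    label_dataset,
    make_transfer_fixture,
    surrogate_ap,
)


def flat_params(**kw) -> SurrogateParams:
    defaults = dict(
        position_weights=np.zeros((20, 10)),
        pair_bonus=0.0,
        charge_penalty=0.0,
        mix_boost=0.0,
        noise_sd=0.0,
        base=1.0,
    )
    defaults.update(kw)
    return SurrogateParams(**defaults)


class TestSurrogateAp:
    def test_degenerate_params_constant_output(self):
        p = flat_params()
        for s in ("AAAAA", "WWWWW", "NRMMR+DMGID", "KKKKKKKKKK"):
            assert surrogate_ap(s, p) == 1.0

    def test_deterministic_given_seed(self):
        a = surrogate_ap("NRMMR", DEFAULT_PARAMS, seed=42)
        b = surrogate_ap("NRMMR", DEFAULT_PARAMS, seed=42)
        assert a == b
        assert a != surrogate_ap("NRMMR", DEFAULT_PARAMS, seed=43)

    def test_mixture_label_symmetric_under_swap(self):
        p = DEFAULT_PARAMS
        assert surrogate_ap("NRMMR+DMGID", p, 7) == surrogate_ap("DMGID+NRMMR", p, 7)

    def test_opposite_charge_mixture_beats_component_mean(self):
        p = flat_params(mix_boost=0.12)
        single1 = surrogate_ap("KRKRK", p)
        single2 = surrogate_ap("DEDED", p)
        mix = surrogate_ap("KRKRK+DEDED", p)
        assert mix > (single1 + single2) / 2

    def test_like_charge_mixture_not_boosted(self):
        p = flat_params(mix_boost=0.12)
        mix = surrogate_ap("KRKRK+KKKKK", p)
        assert mix == pytest.approx(1.0)

    def test_aromatic_adjacency_bonus(self):
        p = flat_params(pair_bonus=0.05)
        assert surrogate_ap("FFAAA", p) == pytest.approx(1.05)
        assert surrogate_ap("FAFAF", p) == pytest.approx(1.0)

    def test_charge_penalty(self):
        p = flat_params(charge_penalty=0.02)
        assert surrogate_ap("KKKKK", p) == pytest.approx(1.0 - 0.02 * 5)

    def test_clipping(self):
        p = flat_params(charge_penalty=1.0)
        assert surrogate_ap("KKKKK", p) == 0.8


class TestLabelDataset:
    def test_range_and_determinism_on_lhs_sample(self):
        peps = lhs_sample(5, 8000, seed=0)
        d1 = label_dataset(peps, DEFAULT_PARAMS, seed=0)
        d2 = label_dataset(peps, DEFAULT_PARAMS, seed=0)
        assert len(d1) == 8000
        assert np.isfinite(d1.labels).all()
        assert (d1.labels >= 0.8).all() and (d1.labels <= 2.6).all()
        np.testing.assert_array_equal(d1.labels, d2.labels)

    def test_labels_independent_of_dataset_order(self):
        peps = lhs_sample(5, 100, seed=1)
        fwd = label_dataset(peps, DEFAULT_PARAMS, seed=5)
        rev = label_dataset(peps[::-1], DEFAULT_PARAMS, seed=5)
        np.testing.assert_array_equal(fwd.labels, rev.labels[::-1])

    def test_zero_noise_equals_deterministic_part(self):
        p0 = DEFAULT_PARAMS.with_(noise_sd=0.0)
        peps = lhs_sample(5, 50, seed=2)
        d = label_dataset(peps, p0, seed=0)
        again = label_dataset(peps, p0, seed=99)  # seed irrelevant at noise 0
        np.testing.assert_array_equal(d.labels, again.labels)

    def test_provenance_recorded(self):
        d = label_dataset([Peptide("NRMMR")], DEFAULT_PARAMS, seed=3)
        assert d.provenance["seed"] == 3
        assert d.provenance["generator"] == "surrogate"


class TestParameterRecovery:
    def test_position_weights_recovered_from_noiseless_labels(self, rng):
        # purely additive regime: no pairwise/charge terms, no noise
        params = DEFAULT_PARAMS.with_(
            pair_bonus=0.0, charge_penalty=0.0, noise_sd=0.0
        )
        peps = lhs_sample(5, 50_000, seed=9)
        data = label_dataset(peps, params, seed=0)
        recovered = fit_position_weights(
            [s.components[0] for s in data.systems], data.labels
        )
        truth = params.position_weights[:, :5]
        truth_centered = truth - truth.mean(axis=0, keepdims=True)
        assert np.max(np.abs(recovered - truth_centered)) < 1e-9


class TestTransferFixture:
    def test_opposite_pair_delta_equals_planted_boost_at_zero_noise(self):
        p = DEFAULT_PARAMS.with_(noise_sd=0.0)
        (rec,) = [
            r
            for r in make_transfer_fixture(20, p, seed=4)
            if r.opposite_charged
        ][:1]
        expected = p.mix_boost * abs(rec.charge1) * abs(rec.charge2)
        assert rec.delta_mix == pytest.approx(expected, abs=1e-12)

    def test_neutral_pair_mixture_equals_average(self):
        p = DEFAULT_PARAMS.with_(noise_sd=0.0)
        s1, s2 = "GGGGG", "AAAAA"
        mix = surrogate_ap(f"{s1}+{s2}", p)
        ave = (surrogate_ap(s1, p) + surrogate_ap(s2, p)) / 2
        assert mix == pytest.approx(ave, abs=1e-12)

    def test_most_records_gain_from_mixing(self):
        records = make_transfer_fixture(300, DEFAULT_PARAMS, seed=0)
        frac = np.mean([r.delta_mix > 0 for r in records])
        assert frac > 0.9

    def test_fixture_is_charge_enriched(self):
        records = make_transfer_fixture(300, DEFAULT_PARAMS, seed=0)
        frac_opposite = np.mean([r.opposite_charged for r in records])
        assert frac_opposite > 0.85

    def test_avepen_identity(self):
        for r in make_transfer_fixture(10, DEFAULT_PARAMS, seed=1):
            assert r.ap_avepen == pytest.approx((r.ap_pen1 + r.ap_pen2) / 2, abs=0)


def test_default_weights_follow_group_ordering():
    # aromatics > aliphatic hydrophobics > polarizable > M/P > charged
    w = DEFAULT_PARAMS.position_weights
    from apscreen.seqspace import ALPHABET

    mean_w = {r: w[i].mean() for i, r in enumerate(ALPHABET)}
    arom = min(mean_w[r] for r in "FYW")
    aliph = max(mean_w[r] for r in "CILV")
    charged = max(mean_w[r] for r in "DEKR")
    assert arom > aliph > charged
    assert net_side_chain_charge("NRMMR") == 2  # sanity of the charge helper
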