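"""Movement-gradient maps, the first-order perturbation law, databank
retrieval and the closed-loop micro-stimulation protocol."""

import numpy as np
import pytest

from biornn import StimulusProtocol, simulate
from biornn.gradients import (
    build_databank,
    closed_loop_protocol,
    micro_current,
    movement_gradient,
    select_target_neurons,
    verify_taylor,
)
from conftest import make_micro_model


@pytest.fixture(scope="module")
def jaw_proto():
    return StimulusProtocol(
        dt=2.0, duration_ms=400.0, onsets_ms={"whisker": 50.0, "auditory": 300.0}
    )


def jaw_model(dynamics="sigmoid", seed=0, v_thr=1.0):
    m = make_micro_model(dynamics=dynamics, jaw=True, dt=2.0, seed=seed,
                         dale=True, local_inhibition=True, v_thr=v_thr)
    m.jaw.w = np.abs(m.jaw.w)  # movement driven positively by excitation
    m.jaw.project_()
    return m


@pytest.fixture(scope="module")
def sig_jaw(jaw_proto):
    return jaw_model("sigmoid")


@pytest.fixture(scope="module")
def spk_jaw(jaw_proto):
    # active regime (~30 Hz): near-threshold events keep the surrogate alive
    return jaw_model("spiking", v_thr=0.4)


class TestGradientMap:
    def test_zero_readout_zero_gradient(self, jaw_proto):
        m = jaw_model()
        m.jaw.w[:] = 0.0
        g = movement_gradient(m, jaw_proto, seed=0)
        assert np.allclose(g.g, 0.0)

    def test_map_shape_and_determinism(self, sig_jaw, jaw_proto):
        g1 = movement_gradient(sig_jaw, jaw_proto, seed=3)
        g2 = movement_gradient(sig_jaw, jaw_proto, seed=3)
        assert g1.g.shape == (jaw_proto.n_steps, sig_jaw.n)
        assert np.allclose(g1.g, g2.g, atol=1e-10)
        assert g1.Y == g2.Y

    def test_finite_difference_on_current(self, sig_jaw, jaw_proto):
        # dY/du at 50 random coordinates vs central differences
        gmap = movement_gradient(sig_jaw, jaw_proto, seed=5)
        T, N = gmap.g.shape
        rng = np.random.default_rng(1)
        coords = list(zip(rng.integers(5, T - 5, 50), rng.integers(0, N, 50)))
        h = 1e-4
        worst = 0.0
        for (t, j) in coords:
            du = np.zeros((T, N))
            du[t, j] = h
            yp = simulate(sig_jaw, jaw_proto, 1, seed=5, extra_current=du).y.sum()
            du[t, j] = -h
            ym = simulate(sig_jaw, jaw_proto, 1, seed=5, extra_current=du).y.sum()
            num = (yp - ym) / (2 * h)
            if abs(num) > 1e-8:
                worst = max(worst, abs(num - gmap.g[t, j]) / abs(num))
        assert worst < 1e-4

    def test_excitatory_inhibitory_opposite_signs(self, sig_jaw, jaw_proto):
        # binned trial-averaged map: excitation drives the movement up,
        # inhibition down, in the area feeding the readout
        maps = [movement_gradient(sig_jaw, jaw_proto, seed=8, trial_id=i) for i in range(5)]
        g = np.mean([m.g for m in maps], axis=0)
        win = slice(50, 150)
        exc = sig_jaw.neurons.excitatory
        inh = sig_jaw.neurons.inhibitory
        assert g[win, :][:, exc].sum() > 0
        assert g[win, :][:, inh].sum() < 0


class TestTaylor:
    def test_zero_amplitude(self, sig_jaw, jaw_proto):
        gmap = movement_gradient(sig_jaw, jaw_proto, seed=2)
        du = np.zeros_like(gmap.g)
        dY, pred, eps = verify_taylor(sig_jaw, gmap, du, jaw_proto)
        assert dY == pred == 0.0

    def test_residual_decays_with_amplitude(self, sig_jaw, jaw_proto):
        # first-order law: relative residual shrinks over three decades
        gmap = movement_gradient(sig_jaw, jaw_proto, seed=2)
        rng = np.random.default_rng(3)
        targets = rng.choice(sig_jaw.n, 20, replace=False)
        base = micro_current(jaw_proto.n_steps, sig_jaw.n, targets, (100, 150), 1.0)
        amps = [1e-1, 1e-2, 1e-3]
        rel = []
        for a in amps:
            dY, pred, eps = verify_taylor(sig_jaw, gmap, a * base, jaw_proto)
            rel.append(abs(eps) / max(abs(dY), 1e-12))
        assert rel[0] > rel[1] > rel[2]
        slope = np.polyfit(np.log(amps), np.log([abs(e) + 1e-15 for e in (
            [verify_taylor(sig_jaw, gmap, a * base, jaw_proto)[2] for a in amps])]), 1)[0]
        assert slope >= 1.0

    def test_spiking_sign_agreement(self, spk_jaw, jaw_proto):
        # surrogate gradients predict the sign of dY on most micro-perturbations
        rng = np.random.default_rng(4)
        agree = total = 0
        for trial in range(25):
            gmap = movement_gradient(spk_jaw, jaw_proto, seed=60, trial_id=trial)
            for mode in ("high", "low"):
                sel = select_target_neurons(gmap, (100, 150), mode=mode, k=20)
                du = micro_current(jaw_proto.n_steps, spk_jaw.n, sel, (100, 150), 0.3)
                dY, pred, _ = verify_taylor(spk_jaw, gmap, du, jaw_proto)
                if abs(dY) > 1e-9:
                    total += 1
                    agree += int(np.sign(dY) == np.sign(pred))
        assert total >= 30
        assert agree / total > 0.8


class TestTargetSelection:
    def _gmap(self, sig_jaw, jaw_proto):
        return movement_gradient(sig_jaw, jaw_proto, seed=6)

    def test_high_mode_matches_full_sort(self, sig_jaw, jaw_proto):
        gmap = self._gmap(sig_jaw, jaw_proto)
        win = (100, 150)
        sel = select_target_neurons(gmap, win, "high", k=20)
        sums = gmap.g[win[0] : win[1]].sum(axis=0)
        want = np.argsort(sums)[::-1][:20]
        assert set(sel) == set(want)

    def test_k_equals_n_returns_everything(self, sig_jaw, jaw_proto):
        gmap = self._gmap(sig_jaw, jaw_proto)
        for mode in ("high", "low", "zero_norm", "shuffled"):
            sel = select_target_neurons(gmap, (100, 150), mode, k=sig_jaw.n)
            assert sorted(sel) == list(range(sig_jaw.n))

    def test_shuffled_seeded(self, sig_jaw, jaw_proto):
        gmap = self._gmap(sig_jaw, jaw_proto)
        a = select_target_neurons(gmap, (100, 150), "shuffled", k=10, seed=1)
        b = select_target_neurons(gmap, (100, 150), "shuffled", k=10, seed=1)
        c = select_target_neurons(gmap, (100, 150), "shuffled", k=10, seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_k_too_large_rejected(self, sig_jaw, jaw_proto):
        gmap = self._gmap(sig_jaw, jaw_proto)
        with pytest.raises(ValueError):
            select_target_neurons(gmap, (100, 150), "high", k=sig_jaw.n + 1)


class TestDatabank:
    @pytest.fixture()
    def bank(self, sig_jaw, jaw_proto):
        if not hasattr(TestDatabank, "_bank"):
            TestDatabank._bank = build_databank(
                sig_jaw, jaw_proto, n_trials=60, t_star_ms=200.0, seed=9
            )
        return TestDatabank._bank

    def test_size_and_self_query(self, bank):
        assert bank.n_trials == 60
        assert len(bank.gradmaps) == 60
        idx, dist = bank.query(bank.spikes[:5])
        assert np.array_equal(idx, np.arange(5))
        assert np.allclose(dist, 0.0, atol=1e-9)

    def test_nearest_neighbor_matches_linear_scan(self, bank, sig_jaw, jaw_proto):
        q = simulate(sig_jaw, jaw_proto, 7, seed=123, trial_ids=np.arange(500, 507))
        idx, dist = bank.query(q.z)
        keys_q = bank.key_of(q.z)
        d2 = ((keys_q[:, None, :] - bank.keys[None, :, :]) ** 2).sum(-1)
        assert np.array_equal(idx, d2.argmin(axis=1))
        assert np.allclose(dist, d2.min(axis=1), rtol=1e-8)

    def test_empty_bank_rejected(self, bank):
        import dataclasses

        empty = dataclasses.replace(bank, spikes=bank.spikes[:0], keys=bank.keys[:0])
        with pytest.raises(ValueError):
            empty.query(bank.spikes[:1])


class TestClosedLoop:
    def test_zero_amplitude_episodes(self, spk_jaw, jaw_proto):
        bank = build_databank(spk_jaw, jaw_proto, n_trials=20, t_star_ms=200.0, seed=10)
        df = closed_loop_protocol(spk_jaw, bank, "high", 10, seed=0, amplitude=0.0)
        assert np.allclose(df["dY"], 0.0)

    def test_mode_ordering_spiking(self, spk_jaw, jaw_proto):
        # high-gradient targeting drives the movement up, low-gradient down,
        # shuffled in between (surrogate-gradient maps, spiking preparation)
        bank = build_databank(spk_jaw, jaw_proto, n_trials=40, t_star_ms=200.0, seed=11)
        means = {}
        for mode in ("high", "low", "shuffled"):
            df = closed_loop_protocol(spk_jaw, bank, mode, 60, seed=1, amplitude=0.3)
            means[mode] = df["dY"].mean()
        assert means["high"] > means["shuffled"] > means["low"]

    def test_zero_norm_smallest_effect_sigmoid(self, sig_jaw, jaw_proto):
        # with exact gradients, stimulating the 40 neurons of smallest
        # gradient norm moves the movement less than the high-gradient 20
        bank = build_databank(sig_jaw, jaw_proto, n_trials=40, t_star_ms=200.0, seed=12)
        means = {}
        for mode in ("high", "zero_norm"):
            df = closed_loop_protocol(sig_jaw, bank, mode, 40, seed=2)
            means[mode] = df["dY"].mean()
        assert abs(means["zero_norm"]) < abs(means["high"])
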