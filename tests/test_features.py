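"""Prototype, xDAWN and shrunk-covariance construction tests."""

import numpy as np
import pytest

from nirsaware import augment_and_covary, compute_prototypes, fit_xdawn
from nirsaware.features import erp_covariances, oas_shrinkage
from tests.conftest import make_synthetic_epochs


class TestPrototypes:
    def test_identical_trials_reproduced(self, synthetic_epochs):
        ep = synthetic_epochs(n_trials=10, seed=1)
        tpl = ep.data[0].copy()
        ep.data[ep.labels == "IMAGERY"] = tpl
        protos = compute_prototypes(ep, np.arange(10))
        assert np.allclose(protos["IMAGERY"].mean, tpl)

    def test_two_trial_average(self, synthetic_epochs):
        ep = synthetic_epochs(n_trials=4, seed=2)
        train = np.arange(4)
        protos = compute_prototypes(ep, train)
        im = ep.data[ep.labels == "IMAGERY"]
        assert np.allclose(protos["IMAGERY"].mean, (im[0] + im[1]) / 2)

    def test_untrained_trials_do_not_leak(self, synthetic_epochs):
        ep = synthetic_epochs(n_trials=20, seed=3)
        train = np.arange(10)
        before = compute_prototypes(ep, train)
        ep.data[15] += 100.0
        after = compute_prototypes(ep, train)
        for cls in before:
            assert np.array_equal(before[cls].mean, after[cls].mean)

    def test_missing_class_rejected(self, synthetic_epochs):
        ep = synthetic_epochs(n_trials=10, seed=4)
        only_imagery = np.flatnonzero(ep.labels == "IMAGERY")
        with pytest.raises(ValueError, match="absent"):
            compute_prototypes(ep, only_imagery)


class TestXdawn:
    @pytest.mark.parametrize("f", [2, 4, 6])
    def test_filter_count(self, f):
        ep = make_synthetic_epochs(n_trials=30, n_channels=8, n_samples=30,
                                   effect=1.0, seed=5)
        filt = fit_xdawn(ep, np.arange(30), f)
        for cls in ("IMAGERY", "NO_IMAGERY"):
            assert filt.filters[cls].shape == (f, 8)
            assert np.linalg.matrix_rank(filt.filters[cls]) == f

    def _evoked_snr(self, w, pattern, epochs):
        """Evoked power over total power of the projection w."""
        p = epochs.data[epochs.labels == "IMAGERY"].mean(axis=0)
        num = float(w @ p @ p.T @ w)
        cov = np.tensordot(epochs.data, epochs.data, axes=([0, 2], [0, 2]))
        den = float(w @ cov @ w)
        return num / den

    def test_first_filter_beats_every_channel(self):
        ep = make_synthetic_epochs(n_trials=40, n_channels=8, n_samples=40,
                                   effect=0.8, seed=6)
        filt = fit_xdawn(ep, np.arange(40), 2)
        w0 = filt.filters["IMAGERY"][0]
        snr0 = self._evoked_snr(w0, None, ep)
        for c in range(8):
            e = np.zeros(8)
            e[c] = 1.0
            assert snr0 >= self._evoked_snr(e, None, ep) - 1e-12

    def test_first_filter_beats_random_projections(self):
        # brute-force oracle: 10,000 random unit directions
        ep = make_synthetic_epochs(n_trials=40, n_channels=8, n_samples=40,
                                   effect=0.8, seed=7)
        filt = fit_xdawn(ep, np.arange(40), 2)
        snr0 = self._evoked_snr(filt.filters["IMAGERY"][0], None, ep)
        rng = np.random.default_rng(8)
        dirs = rng.normal(size=(10_000, 8))
        best = max(self._evoked_snr(d, None, ep) for d in dirs)
        assert snr0 >= best - 1e-12

    def test_too_many_filters_rejected(self):
        ep = make_synthetic_epochs(n_trials=20, n_channels=4, seed=9)
        with pytest.raises(ValueError):
            fit_xdawn(ep, np.arange(20), 6)


class TestAugmentedCovariances:
    @pytest.mark.parametrize("chrom,channels", [("HBO", 8), ("HBR", 8),
                                                ("BOTH", 16)])
    def test_dimension_is_4f_regardless_of_channels(self, chrom, channels):
        ep = make_synthetic_epochs(n_trials=24, n_channels=channels,
                                   n_samples=30, effect=0.5, seed=10,
                                   chromophore=chrom)
        train = np.arange(24)
        protos = compute_prototypes(ep, train)
        filt = fit_xdawn(ep, train, 4)
        spd = augment_and_covary(ep, protos, filt)
        assert spd.matrices.shape == (24, 16, 16)

    def test_outputs_are_spd_and_trace_preserving(self):
        ep = make_synthetic_epochs(n_trials=24, n_channels=8, n_samples=30,
                                   effect=0.5, seed=11)
        train = np.arange(24)
        protos = compute_prototypes(ep, train)
        filt = fit_xdawn(ep, train, 6)
        spd = augment_and_covary(ep, protos, filt)
        for i, m in enumerate(spd.matrices):
            assert np.allclose(m, m.T)
            assert np.linalg.eigvalsh(m).min() > 0
        # trace preservation against the unshrunk sample covariance
        fp = np.vstack([filt.filters["IMAGERY"] @ protos["IMAGERY"].mean,
                        filt.filters["NO_IMAGERY"] @ protos["NO_IMAGERY"].mean])
        v_all = np.vstack([filt.filters["IMAGERY"], filt.filters["NO_IMAGERY"]])
        for i in range(24):
            aug = np.vstack([fp, v_all @ ep.data[i]])
            z = aug - aug.mean(axis=1, keepdims=True)
            s = z @ z.T / aug.shape[1]
            assert np.trace(spd.matrices[i]) == pytest.approx(np.trace(s))

    def test_more_rows_than_samples_still_spd(self):
        # 24 augmented rows from only 12 samples: shrinkage must rescue rank
        ep = make_synthetic_epochs(n_trials=16, n_channels=8, n_samples=12,
                                   effect=0.3, seed=12)
        train = np.arange(16)
        spd = augment_and_covary(ep, compute_prototypes(ep, train),
                                 fit_xdawn(ep, train, 6))
        assert np.linalg.eigvalsh(spd.matrices).min() > 0
        assert np.all(spd.shrinkage > 0)


class TestOAS:
    def test_matches_published_closed_form(self):
        # longhand scalar evaluation of the published shrinkage intensity
        rng = np.random.default_rng(13)
        x = rng.normal(size=(10, 40))        # rows = variables
        ours, rho = oas_shrinkage(x)
        z = x - x.mean(axis=1, keepdims=True)
        d, n = x.shape
        s = z @ z.T / n
        tr = np.trace(s)
        tr2 = np.trace(s @ s)
        expected_rho = min(((1 - 2 / d) * tr2 + tr ** 2)
                           / ((n + 1 - 2 / d) * (tr2 - tr ** 2 / d)), 1.0)
        assert rho == pytest.approx(expected_rho)
        expected = (1 - rho) * s + rho * tr / d * np.eye(d)
        assert np.allclose(ours, expected)

    def test_close_to_sklearn_variant(self):
        # sklearn's OAS drops the 2/p correction terms; for moderate p the
        # two estimators must nearly coincide
        from sklearn.covariance import oas as sk_oas

        rng = np.random.default_rng(13)
        x = rng.normal(size=(30, 200))
        ours, rho = oas_shrinkage(x)
        theirs, rho_sk = sk_oas(x.T, assume_centered=False)
        assert rho == pytest.approx(rho_sk, rel=0.05)
        assert np.allclose(ours, theirs, atol=5e-3)

    def test_rho_bounds_and_sample_size_monotonicity(self):
        # a non-spherical true covariance: with more samples the empirical
        # covariance earns more trust, so shrinkage toward the spherical
        # target must fall
        rng = np.random.default_rng(14)
        a = rng.normal(size=(8, 8))
        rhos = []
        for n in (15, 60, 240, 960):
            r = np.mean([oas_shrinkage(a @ rng.normal(size=(8, n)))[1]
                         for _ in range(20)])
            rhos.append(r)
            assert 0.0 <= r <= 1.0
        assert all(x > y for x, y in zip(rhos, rhos[1:]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            oas_shrinkage(np.zeros((3, 10)))


def test_epochset_and_spdset_round_trip(tmp_path):
    ep = make_synthetic_epochs(n_trials=12, n_channels=4, n_samples=16,
                               effect=0.4, seed=20)
    ep.provenance = {"config": {"ppf": 6.0}}
    p = tmp_path / "epochs.npz"
    ep.save(p)
    back = type(ep).load(p)
    assert np.array_equal(back.data, ep.data)
    assert np.array_equal(back.labels, ep.labels)
    assert back.chromophore == ep.chromophore
    assert back.provenance == ep.provenance

    train = np.arange(12)
    spd = augment_and_covary(ep, compute_prototypes(ep, train),
                             fit_xdawn(ep, train, 2))
    q = tmp_path / "spd.npz"
    spd.save(q)
    back = type(spd).load(q)
    assert np.array_equal(back.matrices, spd.matrices)
    assert np.array_equal(back.shrinkage, spd.shrinkage)


def test_null_classes_converge_with_trial_count():
    """On pure noise the class centers approach each other (relative to the
    within-class spread) as the number of trials grows."""
    from nirsaware import class_distinctiveness

    def class_dis(n_trials, seed):
        ep = make_synthetic_epochs(n_trials=n_trials, n_channels=6,
                                   n_samples=40, effect=0.0, seed=seed)
        train = np.arange(n_trials)
        spd = augment_and_covary(ep, compute_prototypes(ep, train),
                                 fit_xdawn(ep, train, 2))
        return class_distinctiveness(spd)

    small = np.mean([class_dis(12, s) for s in range(5)])
    large = np.mean([class_dis(96, s) for s in range(5)])
    assert large < small
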