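"""IDX images, synthetic digits, noise model, PCA reduction, entropy, curve."""

import struct

import numpy as np
import pytest
from scipy import stats

from proglimit.missing_info import (
    IdxFormatError,
    ImageSample,
    SimulationConfig,
    add_noise,
    cindex_vs_entropy,
    cindex_vs_noise,
    generate_synthetic_digits,
    normalized_entropy,
    read_idx_images,
    reduce_pca2,
    simulate_survival,
    write_idx_images,
)


@pytest.fixture(scope="module")
def digits():
    return generate_synthetic_digits(400, seed=1)


# ---------------------------------------------------------------- IDX format


def test_idx_round_trip(tmp_path, digits):
    sample = ImageSample(images=digits.images[:3])
    p = tmp_path / "imgs.idx"
    write_idx_images(sample, p)
    back = read_idx_images(p)
    np.testing.assert_array_equal(back.images, sample.images)
    assert back.source == "idx_file"


def test_idx_truncated_file(tmp_path, digits):
    p = tmp_path / "trunc.idx"
    write_idx_images(ImageSample(images=digits.images[:3]), p)
    data = p.read_bytes()
    p.write_bytes(data[: len(data) - 100])
    with pytest.raises(IdxFormatError, match="truncated"):
        read_idx_images(p)


def test_idx_bad_magic_and_dims(tmp_path):
    p = tmp_path / "bad.idx"
    p.write_bytes(struct.pack(">IIII", 0x00000801, 2, 28, 28) + b"\0" * (2 * 784))
    with pytest.raises(IdxFormatError, match="magic"):
        read_idx_images(p)
    p.write_bytes(struct.pack(">IIII", 0x00000803, 2, 16, 16) + b"\0" * (2 * 256))
    with pytest.raises(IdxFormatError, match="28x28"):
        read_idx_images(p)


def test_idx_big_endian_header_honoured(tmp_path):
    """A handcrafted 2-image file: n must come from big-endian fields."""
    payload = bytes(range(256)) * 5 + bytes(288)  # 1568 bytes = 2 * 784
    p = tmp_path / "two.idx"
    p.write_bytes(struct.pack(">IIII", 0x00000803, 2, 28, 28) + payload)
    sample = read_idx_images(p)
    assert sample.n == 2
    assert sample.images[0, 0, 5] == 5  # row-major pixel order preserved


# ----------------------------------------------------------- synthetic digits


def test_synthetic_digits_deterministic_and_bounded(digits):
    again = generate_synthetic_digits(400, seed=1)
    np.testing.assert_array_equal(digits.images, again.images)
    other = generate_synthetic_digits(400, seed=2)
    assert not np.array_equal(digits.images, other.images)
    assert digits.images.dtype == np.uint8
    assert digits.images.max() <= 255 and digits.images.min() >= 0


def test_synthetic_digits_have_leading_structure():
    """The stroke family lives on a low-dimensional manifold: the leading two
    principal components must carry a non-trivial share of pixel variance."""
    sample = generate_synthetic_digits(2000, seed=3)
    X = sample.images.reshape(sample.n, -1).astype(float)
    X -= X.mean(axis=0)
    eigs = np.linalg.eigvalsh(np.cov(X, rowvar=False))
    share = eigs[-2:].sum() / eigs.sum()
    assert share > 0.10  # pinned from the generator's observed geometry


# ------------------------------------------------------------------- noising


def test_noise_zero_is_identity(digits):
    out = add_noise(digits, 0.0, seed=5)
    np.testing.assert_array_equal(out.images, digits.images)


def test_noise_one_erases_the_input(digits):
    a = add_noise(digits, 1.0, seed=5)
    b = add_noise(generate_synthetic_digits(400, seed=77), 1.0, seed=5)
    np.testing.assert_array_equal(a.images, b.images)  # input-independent
    # intensities approximately uniform over [0, 255]
    counts = np.bincount(a.images.ravel(), minlength=256)
    assert stats.chisquare(counts).pvalue > 1e-6


def test_noise_fraction_within_binomial_bounds(digits):
    p = 0.5
    noised = add_noise(digits, p, seed=9)
    changed = (noised.images != digits.images).reshape(digits.n, -1).sum(axis=1)
    # a replaced pixel can coincide with the original value (prob 1/256);
    # bound the replacement count by binomial(784, p) 99.99% bounds
    lo = stats.binom.ppf(5e-5, 784, p * (1 - 1 / 256))
    hi = stats.binom.ppf(1 - 5e-5, 784, p)
    assert (changed >= lo).all() and (changed <= hi).all()


def test_noise_validates_fraction(digits):
    with pytest.raises(ValueError):
        add_noise(digits, 1.5, seed=0)


# ---------------------------------------------------------------------- PCA


def test_pca_scores_unit_variance(digits):
    pcs = reduce_pca2(digits)
    assert pcs.shape == (digits.n, 2)
    np.testing.assert_allclose(pcs.std(axis=0), [1.0, 1.0], atol=1e-9)
    assert abs(np.corrcoef(pcs.T)[0, 1]) < 1e-8  # uncorrelated scores


def test_pca_recovers_rank2_structure():
    rng = np.random.default_rng(4)
    u = rng.normal(size=(500, 2))
    basis = rng.normal(size=(2, 784))
    imgs = 128 + 20 * (u @ basis)
    imgs = np.clip(imgs, 0, 255).astype(np.uint8)
    sample = ImageSample(images=imgs.reshape(500, 28, 28))
    X = sample.images.reshape(500, -1).astype(float)
    X -= X.mean(axis=0)
    eigs = np.linalg.eigvalsh(np.cov(X, rowvar=False))
    # quantization adds a little broadband noise; structure stays dominant
    assert eigs[-2:].sum() / eigs.sum() > 0.95


# ------------------------------------------------------------------ survival


def test_survival_closed_forms():
    pcs = np.array([[0.0, 0.0], [0.5, 0.5], [2.0, -2.0]])
    t = simulate_survival(pcs, mst=10.0, skew=0.6)
    assert t[0] == pytest.approx(10.0)          # PC1+PC2 = 0 -> T = MST
    assert t[1] == pytest.approx(10 * np.exp(0.6))  # = 18.221...
    assert t[2] == pytest.approx(10.0)
    assert (t > 0).all()
    t0 = simulate_survival(np.random.default_rng(0).normal(size=(50, 2)), skew=0.0)
    np.testing.assert_allclose(t0, 10.0)        # degenerate skew


# ------------------------------------------------------------------- entropy


def test_entropy_constant_image_is_zero():
    assert normalized_entropy(np.full((28, 28), 7, dtype=np.uint8)) == 0.0


def test_entropy_two_level_closed_form():
    img = np.zeros((28, 28), dtype=np.uint8)
    img.reshape(-1)[:392] = 255
    assert normalized_entropy(img) == pytest.approx(np.log(2) / np.log(256))


def test_entropy_max_spread_image_near_one():
    # 784 pixels over 256 levels, as equal as possible: 3 or 4 pixels per level
    vals = np.concatenate([np.repeat(np.arange(256), 3), np.arange(16)])
    img = vals.astype(np.uint8).reshape(28, 28)
    counts = np.bincount(img.ravel(), minlength=256)
    p = counts / 784
    oracle = -np.sum(p[p > 0] * np.log(p[p > 0])) / np.log(256)
    h = normalized_entropy(img)
    assert h == pytest.approx(oracle)
    assert h > 0.99


# ------------------------------------------------------------ the full curve


@pytest.fixture(scope="module")
def small_curve(digits):
    cfg = SimulationConfig(n_images=400, noise_levels=(0.0, 0.5, 1.0), reps=8, seed=21)
    return cindex_vs_noise(digits, cfg)


def test_curve_endpoints(small_curve):
    # no noise: perfect ordering up to finite-sample slack of the Cox
    # direction at this reduced stack size (exact at the full 2000 images)
    assert small_curve.median_c[0] >= 0.999
    assert abs(small_curve.median_c[-1] - 0.5) < 0.05  # full noise: coin flip


def test_curve_monotone_within_error(small_curve):
    c, se = small_curve.median_c, small_curve.se_median
    for i in range(len(c) - 1):
        assert c[i + 1] <= c[i] + 2 * (se[i] + se[i + 1])


def test_curve_entropy_increases_with_noise(small_curve):
    h = small_curve.mean_entropy
    assert h[-1] > h[0]
    table = cindex_vs_entropy(small_curve)
    assert len(table) == 3
    assert list(table.columns) == ["noise", "mean_entropy", "median_c"]


def test_missing_plus_initial_information_is_hundred(small_curve):
    np.testing.assert_allclose(
        small_curve.missing_information + small_curve.initial_information, 100.0
    )


def test_cox_fit_sign_robust(digits):
    """Flipping the sign of a PC before the Cox fit leaves C unchanged."""
    from proglimit._cox import cox_newton
    from proglimit.concordance import concordance

    pcs = reduce_pca2(digits)
    time = simulate_survival(pcs)
    noised = add_noise(digits, 0.4, seed=3)
    npcs = reduce_pca2(noised)
    event = np.ones(digits.n, dtype=int)

    def c_of(x):
        f = cox_newton(x, time, event, ridge=1e-3)
        return concordance(x @ f.beta, time, event)

    c1 = c_of(npcs)
    c2 = c_of(npcs * np.array([-1.0, 1.0]))
    c3 = c_of(npcs * np.array([-1.0, -1.0]))
    assert c1 == pytest.approx(c2, abs=1e-6)
    assert c1 == pytest.approx(c3, abs=1e-6)


def test_simulation_config_validation():
    with pytest.raises(ValueError, match="sorted"):
        SimulationConfig(noise_levels=(0.5, 0.0))
    with pytest.raises(ValueError, match="0, 1"):
        SimulationConfig(noise_levels=(0.0, 1.5))
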