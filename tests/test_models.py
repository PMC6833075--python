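"""Architecture fidelity, fusion arithmetic and loss closed forms.

The layer tables are transcribed here independently, token for token, and
compared against the generated specs; parameter counts are checked against
a separate hand arithmetic oracle.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from painfusion.errors import ConfigurationError, ValidationError
from painfusion.models import (
    FusionWeights,
    LossWeights,
    aggregate_outputs,
    build_early_fusion_arch,
    build_eda_arch,
    build_emg_ecg_arch,
    build_late_fusion_arch,
    build_mid_fusion_arch,
    combined_loss,
    count_trainable_parameters,
    cross_entropy,
    elu,
    softmax,
)

# ---------------------------------------------------------------------------
# independent transcriptions of the published layer tables
# token: (kind, n_kernels_or_units, kernel_size, stride)

EDA_TABLE = []
for nk in (16, 16, 32, 32, 64, 64, 128):
    EDA_TABLE += [("conv1d", nk, 3, 1), ("batch_norm",), ("max_pool", 2, 2)]
EDA_TABLE += [
    ("flatten",),
    ("dense", 1024),
    ("dropout",),
    ("dense", 512),
    ("dropout",),
    ("dense", "c"),
]

EMG_ECG_TABLE = []
for i, nk in enumerate((16, 16, 32, 32, 64, 64, 128)):
    EMG_ECG_TABLE += [("conv1d", nk, 11, 1), ("batch_norm",), ("max_pool", 2, 2)]
    if i < 6:
        EMG_ECG_TABLE.append(("dropout",))
EMG_ECG_TABLE += [
    ("flatten",),
    ("dropout",),
    ("dense", 1024),
    ("dropout",),
    ("dense", 512),
    ("dropout",),
    ("dense", "c"),
]

EARLY_FUSION_TABLE = [
    ("conv2d", 16, (2, 11), (1, 1)),
    ("conv2d", 16, (2, 11), (1, 1)),
    ("batch_norm",),
    ("max_pool", (1, 2), (1, 2)),
    ("dropout",),
]
for nk in (32, 32, 64, 64):
    EARLY_FUSION_TABLE += [
        ("conv2d", nk, (1, 11), (1, 1)),
        ("batch_norm",),
        ("max_pool", (1, 2), (1, 2)),
        ("dropout",),
    ]
EARLY_FUSION_TABLE = EARLY_FUSION_TABLE[:-1]  # no dropout before flatten
EARLY_FUSION_TABLE += [
    ("flatten",),
    ("dropout",),
    ("dense", 1024),
    ("dropout",),
    ("dense", 512),
    ("dropout",),
    ("dense", "c"),
]


def _tokens(spec, c):
    out = []
    for lay in spec.layers:
        if lay.kind in ("conv1d", "conv2d"):
            out.append((lay.kind, lay.n, lay.size, lay.stride))
        elif lay.kind == "max_pool":
            out.append(("max_pool", lay.size, lay.stride))
        elif lay.kind == "dense":
            out.append(("dense", "c" if lay.n == c else lay.n))
        else:
            out.append((lay.kind,))
    return out


class TestTableFidelity:
    @pytest.mark.parametrize("c", [2, 5])
    def test_eda_layers_match_transcription(self, c):
        assert _tokens(build_eda_arch(c), c) == EDA_TABLE

    @pytest.mark.parametrize("c", [2, 5])
    def test_emg_ecg_layers_match_transcription(self, c):
        assert _tokens(build_emg_ecg_arch(c), c) == EMG_ECG_TABLE

    @pytest.mark.parametrize("c", [2, 5])
    def test_early_fusion_layers_match_transcription(self, c):
        assert _tokens(build_early_fusion_arch(c), c) == EARLY_FUSION_TABLE

    def test_kernel_sizes(self):
        eda = build_eda_arch(2)
        assert all(l.size == 3 for l in eda.layers if l.kind == "conv1d")
        emg = build_emg_ecg_arch(2)
        assert all(l.size == 11 for l in emg.layers if l.kind == "conv1d")

    def test_class_count_validated(self):
        for builder in (build_eda_arch, build_emg_ecg_arch, build_early_fusion_arch):
            with pytest.raises(ConfigurationError):
                builder(1)

    def test_mid_fusion_structure(self):
        spec = build_mid_fusion_arch(5)
        assert len(spec.branches) == 3
        assert spec.fusion == "concat"
        assert spec.layers[-1].activation == "softmax"
        # each trunk ends just before its softmax layer, at the 512-unit dropout
        for b in spec.branches:
            assert b.layers[-1].kind == "dropout"
            assert b.layers[-2].n == 512

    def test_late_fusion_structure(self):
        spec = build_late_fusion_arch(2)
        assert len(spec.branches) == 3
        assert spec.fusion == "weighted_average"
        assert spec.loss_weights == LossWeights()
        for b in spec.branches:
            assert b.layers[-1].kind == "dense" and b.layers[-1].activation == "softmax"


# ---------------------------------------------------------------------------
# parameter-count oracle (independent arithmetic)


def _oracle_count(table, c, input_shape):
    """Walk a transcription with explicit weight arithmetic."""
    if len(input_shape) == 2:
        length, channels = input_shape
        rows = None
    else:
        rows, length, channels = input_shape
    total = 0
    for tok in table:
        kind = tok[0]
        if kind == "conv1d":
            _, nk, k, _s = tok
            total += nk * (k * channels + 1)
            channels = nk
        elif kind == "conv2d":
            _, nk, (kh, kw), _s = tok
            total += nk * (kh * kw * channels + 1)
            channels = nk
            rows = rows - kh + 1
        elif kind == "batch_norm":
            total += 2 * channels
        elif kind == "max_pool":
            length //= 2
        elif kind == "flatten":
            channels = length * channels * (rows if rows else 1)
            length = 1
        elif kind == "dense":
            units = c if tok[1] == "c" else tok[1]
            total += units * (channels + 1)
            channels = units
    return total


class TestParameterCounts:
    @pytest.mark.parametrize("c", [2, 5])
    def test_eda_count_matches_oracle(self, c):
        assert count_trainable_parameters(build_eda_arch(c)) == _oracle_count(
            EDA_TABLE, c, (1152, 1)
        )

    @pytest.mark.parametrize("c", [2, 5])
    def test_emg_ecg_count_matches_oracle(self, c):
        assert count_trainable_parameters(build_emg_ecg_arch(c)) == _oracle_count(
            EMG_ECG_TABLE, c, (1152, 1)
        )

    @pytest.mark.parametrize("c", [2, 5])
    def test_early_fusion_count_matches_oracle(self, c):
        assert count_trainable_parameters(build_early_fusion_arch(c)) == _oracle_count(
            EARLY_FUSION_TABLE, c, (3, 1152, 1)
        )

    @pytest.mark.parametrize("c", [2, 5])
    def test_fusion_counts_match_oracle(self, c):
        uni = _oracle_count(EDA_TABLE, c, (1152, 1)) + 2 * _oracle_count(
            EMG_ECG_TABLE, c, (1152, 1)
        )
        assert count_trainable_parameters(build_late_fusion_arch(c)) == uni + 3
        # mid fusion: trunks lose their softmax layer, head adds 1536 -> c
        trunk_loss = (512 * c + c)
        expected_mid = uni - 3 * trunk_loss + (3 * 512 * c + c)
        assert count_trainable_parameters(build_mid_fusion_arch(c)) == expected_mid

    def test_first_conv_and_last_dense_examples(self):
        # 16 kernels of size 3 on 1 channel -> 16*(3+1); dense 512 -> 2 classes
        assert _oracle_count([("conv1d", 16, 3, 1)], 2, (1152, 1)) == 64
        assert _oracle_count([("flatten",), ("dense", "c")], 2, (512, 1)) == 1026

    def test_flatten_widths(self):
        from painfusion.nn.network import infer_shapes

        eda = build_eda_arch(2)
        shapes = list(infer_shapes(eda.layers, eda.input_shape))
        flat = next(so for lay, _si, so in shapes if lay.kind == "flatten")
        assert flat == (9 * 128,)
        ef = build_early_fusion_arch(2)
        shapes = list(infer_shapes(ef.layers, ef.input_shape))
        flat = next(so for lay, _si, so in shapes if lay.kind == "flatten")
        assert flat == (36 * 64,)
        # modality rows collapse 3 -> 2 -> 1 across the two 2x11 convolutions
        conv_outs = [so for lay, _si, so in shapes if lay.kind == "conv2d"]
        assert conv_outs[0][0] == 2 and conv_outs[1][0] == 1


# ---------------------------------------------------------------------------
# activations, aggregation and losses


class TestOps:
    def test_elu_closed_forms(self):
        assert elu(0.0) == 0.0
        assert elu(2.5) == 2.5
        assert elu(-1.0) == pytest.approx(math.exp(-1) - 1, abs=1e-12)

    def test_elu_monotone_and_continuous(self):
        x = np.linspace(-6, 6, 4001)
        y = elu(x)
        assert np.all(np.diff(y) > 0)
        assert abs(elu(1e-12) - elu(-1e-12)) < 1e-10

    def test_softmax_uniform_and_closed_form(self):
        np.testing.assert_allclose(softmax(np.zeros(5)), 0.2)
        np.testing.assert_allclose(softmax([0.0, math.log(3)]), [0.25, 0.75])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8), st.floats(-1000, 1000))
    @settings(deadline=None, max_examples=50)
    def test_softmax_shift_invariance(self, scores, shift):
        a = softmax(np.array(scores))
        b = softmax(np.array(scores) + shift)
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert a.sum() == pytest.approx(1.0)

    def test_cross_entropy_closed_forms(self):
        y = np.array([1.0, 0.0])
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)
        assert cross_entropy(y, [0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-9)
        y5 = np.eye(5)[0]
        assert cross_entropy(y5, np.full(5, 0.2)) == pytest.approx(math.log(5), abs=1e-9)


class TestAggregation:
    def test_consensus_case(self):
        theta = np.tile([0.3, 0.7], (3, 1))
        e = aggregate_outputs(theta, FusionWeights(alpha=(1 / 3, 1 / 3, 1 / 3)))
        np.testing.assert_allclose(e, np.array([0.3, 0.7]) / 3)

    def test_degenerate_weighting_selects_single_branch(self):
        theta = np.array([[0.9, 0.1], [0.2, 0.8], [0.5, 0.5]])
        e = aggregate_outputs(theta, FusionWeights(alpha=(1.0, 0.0, 0.0)))
        np.testing.assert_allclose(e, theta[0] / 3)

    def test_hand_computed_example(self):
        theta = np.array([[0.9, 0.1], [0.4, 0.6], [0.2, 0.8]])
        e = aggregate_outputs(theta, FusionWeights(alpha=(0.5, 0.25, 0.25)))
        assert e[0] == pytest.approx((0.45 + 0.10 + 0.05) / 3, abs=1e-12)

    def test_matches_loop_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            theta = rng.dirichlet(np.ones(4), size=3)
            alpha = rng.dirichlet(np.ones(3))
            e = aggregate_outputs(theta, FusionWeights(alpha=tuple(alpha)))
            oracle = np.zeros(4)
            for j in range(4):
                for i in range(3):
                    oracle[j] += alpha[i] * theta[i, j] / 3.0
            np.testing.assert_allclose(e, oracle, atol=1e-12)

    def test_dropping_average_factor(self):
        theta = np.tile([0.5, 0.5], (3, 1))
        e = aggregate_outputs(
            theta, FusionWeights(alpha=(1 / 3, 1 / 3, 1 / 3)), average_factor=False
        )
        assert e.sum() == pytest.approx(1.0)

    def test_invalid_rows_rejected(self):
        theta = np.array([[0.9, 0.2], [0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ValidationError, match="sum to 1"):
            aggregate_outputs(theta, FusionWeights(alpha=(1 / 3, 1 / 3, 1 / 3)))

    def test_fusion_weights_constraints(self):
        with pytest.raises(ValidationError):
            FusionWeights(alpha=(0.5, 0.6, -0.1))
        with pytest.raises(ValidationError):
            FusionWeights(alpha=(0.5, 0.2, 0.2))
        w = FusionWeights.from_logits([0.0, 0.0, 0.0])
        np.testing.assert_allclose(w.as_array(), 1 / 3)


class TestCombinedLoss:
    def test_zero_losses(self):
        assert combined_loss([0.0, 0.0, 0.0], 0.0) == 0.0

    def test_defaults_weighting(self):
        assert combined_loss([1.0, 1.0, 1.0], 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_branch_only_reduction(self):
        w = LossWeights(lambda_modalities=(1.0, 1.0, 1.0), lambda_agg=0.0)
        assert combined_loss([0.5, 0.25, 0.25], 7.0, w) == pytest.approx(1.0)

    @given(st.lists(st.floats(0, 10), min_size=3, max_size=3), st.floats(0, 10))
    @settings(deadline=None, max_examples=30)
    def test_linearity_in_each_term(self, ls, lagg):
        base = combined_loss(ls, lagg)
        bumped = combined_loss([ls[0] + 1.0] + ls[1:], lagg)
        assert bumped - base == pytest.approx(0.2, abs=1e-9)
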