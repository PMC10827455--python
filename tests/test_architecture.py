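"""Model assembly, exact parameter auditing, freeze ladder, width search.

The oracle here is independent per-layer arithmetic written out from the
convolution/batch-norm parameter formulas; the package's graph-walking
audit must agree with it on every spec tested.
"""

import numpy as np
import pytest

import histolearn as H
from histolearn import architecture as A
from histolearn import nn


# --- independent closed-form oracle (kept separate from the package) -------

def oracle_conv(k, cin, cout, bias=True):
    return k * k * cin * cout + (cout if bias else 0)


def oracle_bn(c):
    return 4 * c


def oracle_bottleneck(cin, f, expansion, project):
    fout = f * expansion
    t = (oracle_conv(1, cin, f) + oracle_bn(f)
         + oracle_conv(3, f, f) + oracle_bn(f)
         + oracle_conv(1, f, fout) + oracle_bn(fout))
    if project:
        t += oracle_conv(1, cin, fout) + oracle_bn(fout)
    return t


def oracle_total(spec: H.ArchitectureSpec) -> int:
    total = oracle_conv(7, 3, spec.stem_channels) + oracle_bn(spec.stem_channels)
    cin = spec.stem_channels
    h = -(-spec.input_size[0] // 4)   # stem stride 2 + pool stride 2
    for si, stage in enumerate(spec.stages_included[1:]):
        f = spec.stage_widths[si]
        if stage != "conv2":
            h = -(-h // 2)
        for b in range(spec.blocks_per_stage[si]):
            total += oracle_bottleneck(cin, f, spec.expansion, b == 0)
            cin = f * spec.expansion
    channels = cin
    if spec.branch_widths is not None:
        f1, f3, f5 = spec.branch_widths
        total += (oracle_conv(1, cin, f1, spec.conv_bias)
                  + oracle_conv(3, cin, f3, spec.conv_bias)
                  + oracle_conv(5, cin, f5, spec.conv_bias))
        channels = f1 + f3 + f5 + cin
    if spec.head_batchnorm:
        total += oracle_bn(channels)
    feats = channels * h * h if spec.head == "flatten" else channels
    return total + (feats + 1) * spec.head_units


# --- backbone ---------------------------------------------------------------

class TestBackbone:
    def test_truncated_backbone_parameter_count(self):
        spec = H.ArchitectureSpec(stages_included=("conv1", "conv2", "conv3"),
                                  branch_widths=None)
        backbone = H.build_backbone(spec)
        total = sum(int(np.prod(s)) for layer in backbone.walk()
                    for _, s, _ in layer.param_specs())
        assert total == 1_460_096
        assert total == A.closed_form_backbone_count(spec)

    def test_conv3_output_geometry(self):
        spec = H.ArchitectureSpec(stages_included=("conv1", "conv2", "conv3"),
                                  branch_widths=None)
        assert H.build_backbone(spec).out_shape((3, 224, 224)) == (512, 28, 28)

    def test_stem_convolution_count(self):
        # 7x7x3 kernel, 64 filters, with bias
        conv = H.build_backbone(H.ArchitectureSpec.baseline()).layers[0]
        assert sum(int(np.prod(s)) for _, s, _ in conv.param_specs()) == 9_472

    def test_stage_prefix_enforced(self):
        with pytest.raises(ValueError):
            H.ArchitectureSpec(stages_included=("conv1", "conv3"))


class TestNaiveInception:
    def test_concat_channels(self):
        frag = H.build_naive_inception(512, (64, 64, 64))
        assert frag.out_shape((512, 28, 28)) == (704, 28, 28)

    def test_all_branches_preserve_spatial_size(self):
        frag = H.build_naive_inception(512, (3, 5, 7))
        for br in frag.branches:
            assert br.out_shape((512, 28, 28))[1:] == (28, 28)

    def test_maxpool_branch_parameter_free(self):
        frag = H.build_naive_inception(512, (1, 1, 1))
        assert frag.branches[3].param_specs() == []

    @pytest.mark.parametrize("widths", [(1, 1, 1), (64, 64, 64), (7, 31, 200)])
    def test_branch_counts_follow_conv_arithmetic(self, widths):
        f1, f3, f5 = widths
        frag = H.build_naive_inception(512, widths)
        total = sum(int(np.prod(s)) for layer in frag.walk()
                    for _, s, _ in layer.param_specs())
        assert total == 513 * f1 + 4609 * f3 + 12801 * f5


class TestAssembleAndCount:
    def test_baseline_total_parameter_count(self):
        model = H.assemble_model(H.ArchitectureSpec.baseline())
        _, total = H.count_parameters(model)
        assert total == 23_788_418

    def test_dense_head_count(self):
        model = H.assemble_model(H.ArchitectureSpec.baseline())
        dense = [l for l in model.layers() if l.name == "head.dense"][0]
        # flatten of 7x7x2048 into a biased 2-unit layer
        assert sum(int(np.prod(s)) for _, s, _ in dense.param_specs()) \
            == (7 * 7 * 2048 + 1) * 2 == 200_706

    @pytest.mark.parametrize("seed", range(10))
    def test_audit_agrees_with_closed_form_oracle_on_random_specs(self, seed):
        rng = np.random.default_rng(seed)
        spec = H.ArchitectureSpec(
            stages_included=("conv1", "conv2", "conv3"),
            branch_widths=tuple(int(w) for w in rng.integers(1, 513, 3)),
            head=["flatten", "gap"][rng.integers(2)],
            conv_bias=bool(rng.integers(2)),
            head_batchnorm=bool(rng.integers(2)))
        model = H.assemble_model(spec)
        _, total = H.count_parameters(model)
        assert total == oracle_total(spec) == A.closed_form_total(spec)

    def test_assembly_deterministic(self, small_spec):
        a = H.assemble_model(small_spec).layer_shape_list()
        b = H.assemble_model(small_spec).layer_shape_list()
        assert a == b

    def test_forward_emits_probability_vector(self, small_spec, rng):
        model = H.assemble_model(small_spec).initialize(0)
        proba = model.predict_proba(rng.random((3, 64, 64, 3)).astype(np.float32))
        assert proba.shape == (3, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1, atol=1e-6)


class TestFreezeLadder:
    def test_config_1_freezes_entire_backbone(self):
        model = H.assemble_model(H.ArchitectureSpec.small())
        H.apply_freeze_config(model, H.FreezeConfig.from_id(1))
        for layer in model.layers():
            if layer.block.startswith("conv"):
                assert not layer.trainable
            elif layer.block in ("inception", "head"):
                assert layer.trainable

    def test_config_4_trains_everything(self):
        model = H.assemble_model(H.ArchitectureSpec.small())
        H.apply_freeze_config(model, H.FreezeConfig.from_id(4))
        assert all(layer.trainable for layer in model.layers())

    def test_trainable_totals_strictly_increase(self):
        model = H.assemble_model(A.reference_spec())
        totals = []
        for cid in (1, 2, 3, 4):
            H.apply_freeze_config(model, H.FreezeConfig.from_id(cid))
            totals.append(H.count_parameters(model, trainable_only=True)[1])
        assert all(a < b for a, b in zip(totals, totals[1:]))

    def test_ladder_is_nested(self):
        sets = [H.FreezeConfig.from_id(i).trainable_blocks for i in (1, 2, 3, 4)]
        assert all(a < b for a, b in zip(sets, sets[1:]))
        assert all({"inception", "head"} <= s for s in sets)

    def test_unknown_config_fatal(self):
        with pytest.raises(ValueError):
            H.FreezeConfig.from_id(5)


class TestWidthSearch:
    def test_infeasible_budget_reports_diagnostic(self):
        backbone_only = A.closed_form_backbone_count(
            H.ArchitectureSpec(stages_included=("conv1", "conv2", "conv3"),
                               branch_widths=None))
        with pytest.raises(ValueError, match="does not exceed"):
            H.find_reference_widths(backbone_only)

    def test_no_exact_match_reports_nearest(self):
        # a budget one parameter above the minimum-width model cannot be hit
        minimal = A.closed_form_total(
            H.ArchitectureSpec(stages_included=("conv1", "conv2", "conv3"),
                               branch_widths=(1, 1, 1), head="gap",
                               conv_bias=False))
        with pytest.raises(ValueError, match="nearest"):
            H.find_reference_widths(minimal - 3)

    def test_returned_spec_recounts_to_budget(self):
        spec = H.find_reference_widths(H.PROPOSED_PARAMETER_BUDGET)
        _, total = H.count_parameters(H.assemble_model(spec))
        assert total == H.PROPOSED_PARAMETER_BUDGET

    def test_reference_model_under_one_sixth_of_baseline(self):
        assert H.PROPOSED_PARAMETER_BUDGET * 6 < 23_788_418


def test_trainable_only_excludes_moving_statistics(small_spec):
    model = H.assemble_model(small_spec)
    H.apply_freeze_config(model, H.FreezeConfig.from_id(4))
    _, full = H.count_parameters(model)
    _, trainable = H.count_parameters(model, trainable_only=True)
    moving = sum(2 * layer.c for layer in model.layers()
                 if isinstance(layer, nn.BatchNorm2D))
    assert full - trainable == moving
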