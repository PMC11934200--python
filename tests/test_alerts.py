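"""Verdict rule, confidence/weight filters and alert aggregation."""

import pytest
from rdkit import Chem

from toxalert.alerts import (
    FragmentAttribution,
    aggregate_alerts,
    attribute_fragments,
    render_highlights,
    select_confident_actives,
    verdict,
)
from toxalert.explain import LocalExplanation
from toxalert.featurize import fingerprint


def expl(mol_id, prob, weights=()):
    return LocalExplanation(mol_id=mol_id, model_probability=prob,
                            weights=list(weights), surrogate_fit_quality=1.0)


def attr(mol_id, frag, weight, bit=0, atoms=(0,)):
    return FragmentAttribution(mol_id=mol_id, bit=bit, fragment_smiles=frag,
                               atom_indices=list(atoms), weight=weight)


class TestConfidenceFilter:
    @pytest.mark.parametrize("prob,label,kept", [
        (0.79, 1, False),   # below threshold
        (0.80, 1, True),    # at threshold
        (0.95, 0, False),   # not a true disruptor
        (0.95, 1, True),
        (0.40, 1, False),   # predicted inactive
    ])
    def test_rule(self, prob, label, kept):
        out = select_confident_actives([expl("m", prob)], [label])
        assert (len(out) == 1) is kept

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            select_confident_actives([expl("m", 0.9)], [1, 0])


class TestAttribution:
    def test_inactive_bit_contributes_nothing(self):
        fp = fingerprint("CCO")
        off = next(i for i in range(fp.n_bits) if not fp.bits[i])
        e = expl("m", 0.9, [(off, 0.5)])
        assert attribute_fragments(e, fp) == []

    def test_one_bit_one_environment(self):
        fp = fingerprint("CCO")
        bit = next(b for b, envs in fp.environments.items() if len(envs) == 1)
        out = attribute_fragments(expl("m", 0.9, [(bit, 0.4)]), fp)
        assert len(out) == 1 and out[0].weight == 0.4

    def test_collision_shares_one_weight(self):
        fp = fingerprint("COC")  # symmetric methyls collide on one bit
        bit = next(b for b, envs in fp.environments.items() if len(envs) > 1)
        out = attribute_fragments(expl("m", 0.9, [(bit, 0.4)]), fp)
        assert len(out) == len(fp.environments[bit]) >= 2
        assert {a.weight for a in out} == {0.4}


class TestVerdict:
    def test_positive_sum_wins(self):
        v = verdict([attr("m", "C", 0.3), attr("m", "O", -0.1)])
        assert v.is_disruptor
        assert v.positive_sum == pytest.approx(0.3)
        assert v.negative_sum == pytest.approx(0.1)

    def test_all_negative_is_non_disruptor(self):
        assert not verdict([attr("m", "C", -0.2), attr("m", "O", -0.1)]).is_disruptor

    def test_empty_is_non_disruptor(self):
        assert not verdict([], mol_id="m").is_disruptor

    def test_signed_conservation(self):
        attrs = [attr("m", "C", 0.3), attr("m", "O", -0.1), attr("m", "N", 0.05)]
        v = verdict(attrs)
        assert v.positive_sum - v.negative_sum == pytest.approx(
            sum(a.weight for a in attrs))


class TestAggregation:
    def test_occurrences_and_total(self):
        entries = aggregate_alerts([attr("m1", "F1", 0.3), attr("m2", "F1", 0.5)])
        assert len(entries) == 1
        assert entries[0].occurrences == 2
        assert entries[0].total_weight == pytest.approx(0.8)

    def test_weight_floor_removes_small_weights(self):
        entries = aggregate_alerts([attr("m1", "F1", 0.05), attr("m2", "F2", 0.3)])
        assert [e.fragment_smiles for e in entries] == ["F2"]

    def test_empty_input_is_valid_empty_table(self):
        assert aggregate_alerts([]) == []

    def test_collision_rows_not_double_counted_per_molecule(self):
        rows = [attr("m1", "F1", 0.4, bit=1), attr("m1", "F1", 0.4, bit=2)]
        pair_mode = aggregate_alerts(rows)
        row_mode = aggregate_alerts(rows, count_rows=True)
        assert pair_mode[0].occurrences == 1
        assert row_mode[0].occurrences == 2

    def test_sorted_by_total_weight_then_ties(self):
        rows = [attr("a", "FA", 0.2), attr("b", "FB", 0.6),
                attr("c", "FC", 0.2), attr("d", "FC", 0.2)]
        entries = aggregate_alerts(rows)
        assert [e.fragment_smiles for e in entries] == ["FB", "FC", "FA"]

    @pytest.mark.parametrize("floors", [(0.1, 0.2), (0.15, 0.3)])
    def test_raising_floor_is_monotone(self, floors):
        import numpy as np

        rng = np.random.default_rng(0)
        rows = [attr(f"m{i % 7}", f"F{i % 5}", float(rng.uniform(0, 0.6)))
                for i in range(60)]
        lo, hi = floors
        low = {e.fragment_smiles: e for e in aggregate_alerts(rows, weight_floor=lo)}
        high = aggregate_alerts(rows, weight_floor=hi)
        for e in high:
            assert e.occurrences <= low[e.fragment_smiles].occurrences
            assert e.total_weight <= low[e.fragment_smiles].total_weight + 1e-12

    def test_floor_on_totals_mode(self):
        rows = [attr("m1", "F1", 0.06), attr("m2", "F1", 0.06)]
        assert aggregate_alerts(rows) == []                       # per-attribution floor
        kept = aggregate_alerts(rows, floor_on_totals=True)       # 0.12 total survives
        assert len(kept) == 1 and kept[0].total_weight == pytest.approx(0.12)


class TestHighlights:
    def test_single_attribution_highlight(self):
        mol = Chem.MolFromSmiles("CCO")
        h = render_highlights(mol, [attr("m", "CC", 0.5, atoms=(0, 1))])
        assert h["union_atoms"] == [0, 1]
        assert len(h["fragments"]) == 1
        assert h["fragments"][0]["bonds"] == [0]  # the C-C bond

    def test_overlap_union_preserves_identity(self):
        mol = Chem.MolFromSmiles("CCO")
        h = render_highlights(mol, [attr("m", "CC", 0.5, atoms=(0, 1)),
                                    attr("m", "CO", 0.4, atoms=(1, 2))])
        assert h["union_atoms"] == [0, 1, 2]
        assert [f["fragment_smiles"] for f in h["fragments"]] == ["CC", "CO"]

    def test_empty_highlight(self):
        mol = Chem.MolFromSmiles("CCO")
        h = render_highlights(mol, [])
        assert h["fragments"] == [] and h["union_atoms"] == []
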