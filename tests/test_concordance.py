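"""Confusion matrix construction, per-class reduction and the seven metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gtconcord.callset_io import CONFUSION_CLASSES, GenotypeClass
from gtconcord.concordance import (
    ConfusionMatrix,
    build_confusion_matrix,
    compute_metrics,
    reduce_by_class,
    symmetrize_metrics,
    write_metrics_table,
)
from gtconcord.sanger import load_validation_table, SangerStatus, _site_local_classes

from conftest import make_pair


# --- independent oracle: a literal per-class transcription of the procedure ---

def oracle_metrics(counts):
    """Brute-force metric computation from a 6x6 count list, pure python."""
    total = sum(sum(row) for row in counts)
    reduced = {}
    for k in range(6):
        tp = counts[k][k]
        fn = sum(counts[k][j] for j in range(6)) - tp
        fp = sum(counts[i][k] for i in range(6)) - tp
        tn = total - tp - fn - fp
        reduced[k] = (tp, fn, fp, tn)
    precision = sum(
        (tp / (tp + fp)) * ((tp + fp) / total)
        for tp, fn, fp, tn in reduced.values() if tp + fp > 0
    )
    sensitivity = sum(
        (tp / (tp + fn)) * ((tp + fn) / total)
        for tp, fn, fp, tn in reduced.values() if tp + fn > 0
    )
    present = [
        k for k in range(6)
        if sum(counts[k]) > 0 or sum(counts[i][k] for i in range(6)) > 0
    ]
    accuracies = [(reduced[k][0] + reduced[k][3]) / total for k in present]
    specs = [
        reduced[k][3] / (reduced[k][3] + reduced[k][2])
        for k in present if reduced[k][3] + reduced[k][2] > 0
    ]
    trace = sum(counts[k][k] for k in range(6))
    aa = counts[0][0]
    nonref_rows = total - sum(counts[0])
    return {
        "genotype_concordance": trace / total,
        "nonref_genotype_concordance":
            (trace - aa) / (total - aa) if total > aa else None,
        "nonref_sensitivity":
            (trace - aa) / nonref_rows if nonref_rows > 0 else None,
        "sensitivity": sensitivity,
        "precision": precision,
        "specificity": sum(specs) / len(specs) if specs else None,
        "accuracy": sum(accuracies) / len(accuracies) if accuracies else None,
    }


matrices = st.lists(st.integers(0, 30), min_size=36, max_size=36).map(
    lambda v: np.array(v, dtype=np.int64).reshape(6, 6)
)
nonzero_matrices = matrices.filter(lambda m: m.sum() > 0)


class TestBuildConfusionMatrix:
    def test_single_concordant_pair(self):
        cm = build_confusion_matrix([make_pair(concordant=True)])
        assert cm.counts[0, 0] == 1 and cm.total == 1

    def test_empty_collection_gives_zero_matrix(self):
        cm = build_confusion_matrix([])
        assert cm.total == 0
        assert all(v is None for v in compute_metrics(cm).to_dict().values())

    def test_sanger_resolved_rows_give_trace_13_of_16(self):
        """Of the 16 Sanger-resolved validation rows, WGS matches Sanger in 13."""
        rows = [r for r in load_validation_table()
                if r.sanger.status is SangerStatus.RESOLVED_DIPLOID]
        assert len(rows) == 16
        n_match = sum(r.sanger.alleles == r.wgs.alleles for r in rows)
        assert n_match == 13
        from gtconcord.callset_io import PairedCall, GenotypeCall, Platform
        pairs = []
        for r in rows:
            cls_s, cls_w, _ = _site_local_classes(r)
            pairs.append(PairedCall(
                r.site, GenotypeCall(r.site, r.sanger.alleles, Platform.SANGER),
                r.wgs, cls_s, cls_w))
        cm = build_confusion_matrix(pairs)
        assert cm.trace == 13 and cm.total == 16

    def test_swapping_roles_transposes(self, make_paired_calls):
        pairs = make_paired_calls(10, 4)
        cm = build_confusion_matrix(pairs)
        swapped = build_confusion_matrix([
            type(p)(p.site, p.call_test, p.call_truth, p.class_test, p.class_truth)
            for p in pairs
        ])
        assert (cm.counts.T == swapped.counts).all()


class TestReduceByClass:
    def test_embedded_two_class_toy(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0:2, 0:2] = [[5, 1], [2, 4]]
        red = reduce_by_class(ConfusionMatrix(counts), GenotypeClass.AA)
        assert (red.tp, red.fn, red.fp, red.tn) == (5, 1, 2, 4)

    def test_diagonal_matrix_has_no_errors(self):
        cm = ConfusionMatrix(np.diag([3, 1, 4, 1, 5, 9]))
        for cls in CONFUSION_CLASSES:
            red = reduce_by_class(cm, cls)
            assert red.fp == red.fn == 0

    def test_zero_matrix(self):
        red = reduce_by_class(ConfusionMatrix(np.zeros((6, 6))), GenotypeClass.CC)
        assert (red.tp, red.fn, red.fp, red.tn) == (0, 0, 0, 0)

    @given(nonzero_matrices)
    def test_cells_partition_the_total(self, counts):
        cm = ConfusionMatrix(counts)
        for cls in CONFUSION_CLASSES:
            assert reduce_by_class(cm, cls).total == cm.total


class TestComputeMetrics:
    def test_perfect_diagonal_scores_one_everywhere(self):
        cm = ConfusionMatrix(np.diag([10, 5, 3, 2, 1, 1]))
        m = compute_metrics(cm)
        assert all(v == pytest.approx(1.0) for v in m.to_dict().values())

    def test_three_class_toy_micro_average(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0:3, 0:3] = [[5, 1, 0], [0, 4, 0], [1, 0, 5]]
        m = compute_metrics(ConfusionMatrix(counts))
        assert m.genotype_concordance == pytest.approx(14 / 16)
        assert m.precision == pytest.approx(14 / 16)
        assert m.sensitivity == pytest.approx(14 / 16)

    @given(nonzero_matrices)
    def test_matches_brute_force_oracle(self, counts):
        ours = compute_metrics(ConfusionMatrix(counts)).to_dict()
        ref = oracle_metrics(counts.tolist())
        for key, want in ref.items():
            got = ours[key]
            if want is None:
                assert got is None, key
            else:
                assert got == pytest.approx(want, abs=1e-12), key

    @given(nonzero_matrices)
    def test_micro_average_identity(self, counts):
        m = compute_metrics(ConfusionMatrix(counts))
        gc = m.genotype_concordance
        assert m.precision == pytest.approx(gc, abs=1e-12)
        assert m.sensitivity == pytest.approx(gc, abs=1e-12)

    @given(nonzero_matrices)
    def test_mean_accuracy_bounds_concordance(self, counts):
        m = compute_metrics(ConfusionMatrix(counts))
        assert m.accuracy >= m.genotype_concordance - 1e-12

    @given(nonzero_matrices)
    def test_transpose_duality_per_class(self, counts):
        cm = ConfusionMatrix(counts)
        cmt = cm.transpose()
        for cls in CONFUSION_CLASSES:
            a, b = reduce_by_class(cm, cls), reduce_by_class(cmt, cls)
            assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)

    @given(nonzero_matrices, st.integers(1, 7))
    def test_invariant_under_cell_scaling(self, counts, factor):
        base = compute_metrics(ConfusionMatrix(counts)).to_dict()
        scaled = compute_metrics(ConfusionMatrix(counts * factor)).to_dict()
        for key in base:
            if base[key] is None:
                assert scaled[key] is None
            else:
                assert scaled[key] == pytest.approx(base[key], abs=1e-12)


class TestSymmetrizeMetrics:
    def test_symmetric_matrix_unchanged(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0:2, 0:2] = [[5, 2], [2, 7]]
        cm = ConfusionMatrix(counts)
        assert symmetrize_metrics(cm) == compute_metrics(cm)

    @given(nonzero_matrices)
    def test_concordance_invariant_under_symmetrization(self, counts):
        cm = ConfusionMatrix(counts)
        assert symmetrize_metrics(cm).genotype_concordance == pytest.approx(
            compute_metrics(cm).genotype_concordance)

    def test_precision_already_symmetric(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0:2, 0:2] = [[5, 1], [3, 7]]
        cm = ConfusionMatrix(counts)
        # weighted precision equals trace/total for any matrix, so the
        # truth/test alternation cannot change it
        assert symmetrize_metrics(cm).precision == pytest.approx(
            compute_metrics(cm).precision)


def test_write_metrics_table_roundtrip(tmp_path):
    import json
    import pandas as pd

    m = compute_metrics(ConfusionMatrix(np.diag([5, 3, 2, 0, 0, 0])))
    write_metrics_table({"cmp": m}, tmp_path / "m.json")
    write_metrics_table({"cmp": m}, tmp_path / "m.tsv")
    loaded = json.loads((tmp_path / "m.json").read_text())
    assert loaded["cmp"]["genotype_concordance"] == 1.0
    df = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col=0)
    assert df.loc["cmp", "precision"] == 1.0
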