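import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiboost._alphabet import CANONICAL_ALPHABET, all_kmers
from epiboost.antigen_scales import (
    ScaleFileError,
    apply_scale,
    build_scale,
    count_kmers,
    load_scale,
    save_scale,
    KmerScale,
)

from conftest import make_dataset


def brute_force_raw(dataset, k, pseudocount):
    """Independent oracle: enumerate windows by hand and evaluate the
    smoothed log-ratio formula directly, with no shared code path."""
    pos_windows, neg_windows = [], []
    for p in dataset:
        target = pos_windows if p.label == 1 else neg_windows
        for i in range(len(p.sequence)):
            w = p.sequence[i : i + k]
            if len(w) == k:
                target.append(w)
    vocab = 20 ** k
    out = {}
    for m in set(pos_windows) | set(neg_windows):
        f_pos = (pos_windows.count(m) + pseudocount) / (
            len(pos_windows) + pseudocount * vocab
        )
        f_neg = (neg_windows.count(m) + pseudocount) / (
            len(neg_windows) + pseudocount * vocab
        )
        out[m] = math.log(f_pos / f_neg)
    return out


def swap_labels(dataset):
    from epiboost.peptide_data import EpitopeDataset, Peptide

    return EpitopeDataset(
        name=dataset.name + "-swapped",
        peptides=[
            Peptide(p.id, p.sequence, 1 - p.label) for p in dataset
        ],
    )


class TestCountKmers:
    def test_dipeptide_windows(self):
        ds = make_dataset([("AAAC", 1), ("CCCC", 0)])
        table = count_kmers(ds, 2)
        assert table.counts_pos == {"AA": 2, "AC": 1}
        assert table.total_pos == 3

    def test_short_peptide_contributes_nothing(self):
        ds = make_dataset([("A", 1), ("CC", 0)])
        table = count_kmers(ds, 2)
        assert table.total_pos == 0 and table.total_neg == 1

    def test_trimer_single_window(self):
        ds = make_dataset([("ACA", 1), ("GGG", 0)])
        table = count_kmers(ds, 3)
        assert table.counts_pos == {"ACA": 1} and table.total_pos == 1

    def test_unlabeled_rejected(self):
        from epiboost.peptide_data import EpitopeDataset, Peptide

        ds = EpitopeDataset("u", [Peptide("p", "ACDK")])
        with pytest.raises(Exception):
            count_kmers(ds, 2)


class TestBuildScale:
    def test_hand_computed_log_ratio(self):
        # positives {AAAC}, negatives {CCGA}, pseudocount 1:
        # raw(AA) = ln((2+1)/(3+400)) - ln((0+1)/(3+400)) = ln 3
        ds = make_dataset([("AAAC", 1), ("CCGA", 0)])
        scale = build_scale(count_kmers(ds, 2), pseudocount=1.0)
        assert scale.raw["AA"] == pytest.approx(math.log(3), abs=1e-12)

    def test_identical_classes_give_zero(self):
        ds = make_dataset([("ACDK", 1), ("ACDK", 0), ("WYTT", 1), ("WYTT", 0)])
        scale = build_scale(count_kmers(ds, 2))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in scale.raw.values())
        assert all(v == 0.0 for v in scale.normalized.values())

    def test_antisymmetry_under_class_swap(self, tiny_dataset):
        fwd = build_scale(count_kmers(tiny_dataset, 2))
        rev = build_scale(count_kmers(swap_labels(tiny_dataset), 2))
        assert fwd.raw.keys() == rev.raw.keys()
        for m in fwd.raw:
            assert fwd.raw[m] == pytest.approx(-rev.raw[m], abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_brute_force_oracle(self, rng, k):
        from conftest import random_dataset

        for trial in range(5):
            ds = random_dataset(rng, 4, 4, min_len=3, max_len=9)
            scale = build_scale(count_kmers(ds, k), pseudocount=1.0)
            oracle = brute_force_raw(ds, k, 1.0)
            assert scale.raw.keys() == oracle.keys()
            for m, v in oracle.items():
                assert scale.raw[m] == pytest.approx(v, abs=1e-12)

    def test_normalization_bounds_hit_exactly(self, tiny_dataset):
        scale = build_scale(count_kmers(tiny_dataset, 2))
        values = np.array(list(scale.normalized.values()))
        assert values.min() == -1.0 and values.max() == 1.0
        assert ((values >= -1) & (values <= 1)).all()

    def test_ranking_preserved_by_normalization(self, tiny_dataset):
        scale = build_scale(count_kmers(tiny_dataset, 2))
        kmers = sorted(scale.raw)
        raw_order = sorted(kmers, key=scale.raw.__getitem__)
        norm_order = sorted(kmers, key=scale.normalized.__getitem__)
        assert raw_order == norm_order

    def test_empty_class_rejected(self):
        ds = make_dataset([("A", 1), ("CCCC", 0)])  # positives have no 2-mers
        with pytest.raises(ValueError):
            build_scale(count_kmers(ds, 2))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.text(alphabet=CANONICAL_ALPHABET, min_size=2, max_size=8),
            st.sampled_from([0, 1]),
        ),
        min_size=4,
        max_size=8,
    )
)
def test_antisymmetry_property(pairs):
    ds = make_dataset(pairs)
    if ds.n_pos == 0 or ds.n_neg == 0:
        return
    table = count_kmers(ds, 2)
    if table.total_pos == 0 or table.total_neg == 0:
        return
    fwd = build_scale(table)
    rev = build_scale(count_kmers(swap_labels(ds), 2))
    for m in fwd.raw:
        assert fwd.raw[m] == pytest.approx(-rev.raw[m], abs=1e-12)


class TestApplyScale:
    def make_scale(self, normalized, k=2):
        return KmerScale(
            k=k,
            raw=dict(normalized),
            normalized=dict(normalized),
            pseudocount=1.0,
        )

    def test_single_window(self):
        from epiboost.peptide_data import Peptide

        scale = self.make_scale({"AC": -1.0})
        assert apply_scale(Peptide("p", "AC"), scale) == -1.0

    def test_hand_average(self):
        from epiboost.peptide_data import Peptide

        scale = self.make_scale({"AA": 1.0, "AC": -1.0})
        value = apply_scale(Peptide("p", "AAAC"), scale)
        assert value == pytest.approx((1.0 + 1.0 - 1.0) / 3)

    def test_unseen_kmers_use_default(self):
        from epiboost.peptide_data import Peptide

        scale = self.make_scale({"AA": 1.0})
        scale.default_value = 0.5
        # windows WW, WA, AA -> (0.5 + 0.5 + 1.0)/3
        assert apply_scale(Peptide("p", "WWAA"), scale) == pytest.approx((0.5 + 0.5 + 1.0) / 3)

    def test_short_peptide_warns_and_returns_zero(self, caplog):
        from epiboost.peptide_data import Peptide

        scale = self.make_scale({"AAA": 1.0}, k=3)
        with caplog.at_level("WARNING"):
            assert apply_scale(Peptide("p", "AC"), scale) == 0.0
        assert "shorter" in caplog.text

    def test_profile_mode(self):
        from epiboost.peptide_data import Peptide

        scale = self.make_scale({"AA": 1.0, "AC": -0.5})
        vec = apply_scale(Peptide("p", "AAAC"), scale, mode="profile")
        assert vec.shape == (400,)
        kmers = all_kmers(2)
        assert vec[kmers.index("AA")] == pytest.approx(2 / 3 * 1.0)
        assert vec[kmers.index("AC")] == pytest.approx(1 / 3 * -0.5)
        assert np.count_nonzero(vec) == 2


class TestScalePersistence:
    def test_round_trip(self, tmp_path, tiny_dataset):
        scale = build_scale(count_kmers(tiny_dataset, 2))
        path = tmp_path / "aap.tsv"
        save_scale(scale, path)
        back = load_scale(path)
        assert back.k == scale.k
        assert back.raw.keys() == scale.raw.keys()
        for m in scale.raw:
            assert back.raw[m] == pytest.approx(scale.raw[m], abs=1e-12)
            assert back.normalized[m] == pytest.approx(scale.normalized[m], abs=1e-12)

    def test_duplicate_row_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "#k=2\n#pseudocount=1.0\n#default=0.0\n"
            "kmer\traw\tnormalized\nAA\t0.1\t0.1\nAA\t0.2\t0.2\n"
        )
        with pytest.raises(ScaleFileError, match="duplicate"):
            load_scale(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "nohdr.tsv"
        path.write_text("kmer\traw\tnormalized\nAA\t0.1\t0.1\n")
        with pytest.raises(ScaleFileError, match="metadata"):
            load_scale(path)
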