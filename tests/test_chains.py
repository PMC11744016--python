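"""Chain parsing, attribute merging, fragment geometry and fold assignment."""

import numpy as np
import pandas as pd
import pytest

from atpresi.categories import GAP
from atpresi.chains import (
    ProteinChain,
    assign_folds,
    attribute_table,
    load_dataset,
    make_fragments,
    merge_attributes,
    read_chain_file,
    save_dataset,
    write_chain_file,
)


def _write(tmp_path, fasta, labels):
    fa = tmp_path / "chains.fasta"
    fa.write_text(fasta)
    (tmp_path / "chains.lab").write_text(labels)
    return fa


class TestReadChainFile:
    def test_basic_parse(self, tmp_path):
        fa = _write(tmp_path, ">c1\nACD\n", ">c1\n010\n")
        (chain,) = read_chain_file(fa)
        assert chain.chain_id == "c1"
        assert chain.sequence == "ACD"
        assert chain.labels.tolist() == [0, 1, 0]

    def test_label_length_mismatch(self, tmp_path):
        fa = _write(tmp_path, ">c1\nACD\n", ">c1\n01\n")
        with pytest.raises(ValueError, match="c1.*mismatch"):
            read_chain_file(fa)

    def test_non_alphabet_character_reports_position(self, tmp_path):
        fa = _write(tmp_path, ">c1\nAZD\n", ">c1\n010\n")
        with pytest.raises(ValueError, match="position 2"):
            read_chain_file(fa)

    def test_unknown_residue_behind_flag(self, tmp_path):
        fa = _write(tmp_path, ">c1\nAXD\n", ">c1\n010\n")
        with pytest.raises(ValueError):
            read_chain_file(fa)
        (chain,) = read_chain_file(fa, allow_unknown=True)
        assert chain.sequence == "AXD"

    def test_interleaved_dialect(self, tmp_path):
        path = tmp_path / "deposited.txt"
        path.write_text(">1abcA\nACDEF\n00100\n\n>2xyzB\nGHIK\n0001\n")
        chains = read_chain_file(path, dialect="sdcnn_github")
        assert [c.chain_id for c in chains] == ["1abcA", "2xyzB"]
        assert chains[0].labels.tolist() == [0, 0, 1, 0, 0]
        assert chains[1].sequence == "GHIK"

    def test_native_round_trip_is_byte_identical(self, tmp_path):
        fasta, labels = ">a\nACDEFG\n>b\nKLMN\n", ">a\n010010\n>b\n1000\n"
        fa = _write(tmp_path, fasta, labels)
        chains = read_chain_file(fa)
        out_fa = tmp_path / "out.fasta"
        write_chain_file(chains, out_fa)
        assert out_fa.read_text() == fasta
        assert (tmp_path / "out.lab").read_text() == labels


class TestMergeAttributes:
    def _table(self, chain_id, n, **overrides):
        frame = pd.DataFrame(
            {
                "chain_id": [chain_id] * n,
                "residue_index": np.arange(1, n + 1),
                "ss": ["H"] * n,
                "rsa": [0.3] * n,
                "phi": [-100.0] * n,
                "psi": [30.0] * n,
            }
        )
        for col, values in overrides.items():
            frame[col] = values
        return frame

    def _chain(self):
        return ProteinChain("c1", "ACD", np.array([0, 1, 0]))

    def test_full_merge(self):
        (merged,) = merge_attributes([self._chain()], self._table("c1", 3))
        assert merged.has_attributes
        assert merged.rsa.tolist() == [0.3, 0.3, 0.3]

    def test_out_of_range_residue_index(self):
        table = self._table("c1", 3, residue_index=[1, 2, 4])
        with pytest.raises(ValueError, match="missing|out of range"):
            merge_attributes([self._chain()], table)

    def test_angle_out_of_range(self):
        table = self._table("c1", 3, phi=[-200.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="angle out of range"):
            merge_attributes([self._chain()], table)

    def test_rsa_out_of_range(self):
        table = self._table("c1", 3, rsa=[0.2, 1.5, 0.2])
        with pytest.raises(ValueError, match="rsa"):
            merge_attributes([self._chain()], table)

    def test_round_trip_through_attribute_table(self, micro_chains):
        merged = merge_attributes(
            [ProteinChain(c.chain_id, c.sequence, c.labels) for c in micro_chains],
            attribute_table(micro_chains),
        )
        for orig, back in zip(micro_chains, merged):
            assert np.allclose(orig.phi, back.phi)
            assert list(orig.ss) == list(back.ss)


class TestMakeFragments:
    def test_window_geometry(self):
        chain = ProteinChain("c1", "ACD", np.array([0, 1, 0]))
        frags = make_fragments(chain, L=17)
        assert len(frags) == 3
        assert frags[0].residues == GAP * 8 + "ACD" + GAP * 6
        assert frags[0].label == 0 and frags[1].label == 1
        assert all(f.L == 17 for f in frags)

    def test_single_residue_chain(self):
        chain = ProteinChain("c1", "W", np.array([1]))
        (frag,) = make_fragments(chain, L=17)
        assert frag.residues.count(GAP) == 16
        assert frag.residues[8] == "W"

    def test_even_window_rejected(self):
        chain = ProteinChain("c1", "ACD", np.array([0, 1, 0]))
        with pytest.raises(ValueError):
            make_fragments(chain, L=16)

    def test_gap_positions_match_chain_coordinates(self, small_dataset):
        chain = small_dataset[0]
        for frag in make_fragments(chain, L=17):
            for offset, symbol in enumerate(frag.residues):
                coord = frag.center_index - 8 + offset
                outside = coord < 0 or coord >= len(chain)
                assert (symbol == GAP) == outside
                assert np.isnan(frag.rsa[offset]) == outside

    def test_fragment_count_equals_residue_count(self, small_dataset):
        for chain in small_dataset:
            assert len(make_fragments(chain)) == len(chain)


class TestAssignFolds:
    def _chains(self, n):
        return [ProteinChain(f"c{i}", "ACDEF", np.array([0, 1, 0, 0, 0])) for i in range(n)]

    def test_balanced_sizes(self):
        split = assign_folds(self._chains(10), n_folds=5, seed=0)
        sizes = np.bincount(list(split.fold_assignments.values()))[1:]
        assert sizes.tolist() == [2, 2, 2, 2, 2]

    def test_260_chains_give_52_per_fold(self):
        split = assign_folds(self._chains(260), n_folds=5, seed=3)
        sizes = np.bincount(list(split.fold_assignments.values()))[1:]
        assert sizes.tolist() == [52] * 5

    def test_deterministic_per_seed(self):
        chains = self._chains(13)
        a = assign_folds(chains, seed=7).fold_assignments
        b = assign_folds(chains, seed=7).fold_assignments
        c = assign_folds(chains, seed=8).fold_assignments
        assert a == b
        assert a != c

    def test_too_few_chains(self):
        with pytest.raises(ValueError):
            assign_folds(self._chains(4), n_folds=5)


def test_dataset_json_round_trip(tmp_path, small_dataset):
    path = tmp_path / "ds.json"
    save_dataset(small_dataset, path)
    loaded = load_dataset(path)
    assert [c.chain_id for c in loaded] == [c.chain_id for c in small_dataset]
    for a, b in zip(small_dataset, loaded):
        assert a.sequence == b.sequence
        assert a.labels.tolist() == b.labels.tolist()
        assert np.allclose(a.rsa, b.rsa, atol=1e-6)
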