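"""Conversion-label rules and distal-mutation negative augmentation."""

from __future__ import annotations

import numpy as np
import pytest

from structcpi.calb import (AugmentationConfig, ConversionRecord,
                            augment_negatives, eligible_distal_residues,
                            parse_mutation, read_conversion_table,
                            relative_labels, threshold_labels,
                            write_labeled_dataset)
from structcpi.fixtures import make_augmentation_fixture


def _rec(vid, conversion, smiles="CC", mutations=()):
    return ConversionRecord(vid, list(mutations), smiles, conversion)


# -------------------------------------------------------------- thresholds

def test_threshold_labels_reproduce_cutoff_convention():
    records = [_rec("a", 10.0), _rec("b", 15.0), _rec("c", 35.0)]
    assert threshold_labels(records, 15) == [0, 1, 1]   # >= rule at the cutoff
    assert threshold_labels(records, 30) == [0, 0, 1]
    assert threshold_labels(records, 40) == [0, 0, 0]
    assert threshold_labels([], 15) == []


def test_threshold_labels_monotone_in_cutoff():
    rng = np.random.default_rng(0)
    records = [_rec(f"v{i}", float(c)) for i, c in enumerate(rng.uniform(0, 100, 50))]
    prev = threshold_labels(records, 15)
    for cutoff in (30, 40, 75):
        cur = threshold_labels(records, cutoff)
        assert all(c <= p for c, p in zip(cur, prev))  # raising cutoff never flips 0->1
        prev = cur


def test_threshold_labels_reject_out_of_range():
    with pytest.raises(ValueError, match="v0"):
        threshold_labels([_rec("v0", 120.0)], 15)


# ---------------------------------------------------------- relative rule

def test_relative_labels_comparable_or_higher_rule():
    records = [
        _rec("wt", 40.0),                                    # wild type
        _rec("m1", 50.0, mutations=[("W", 104, "C")]),
        _rec("m2", 40.0, mutations=[("A", 281, "E")]),
        _rec("m3", 30.0, mutations=[("V", 149, "G")]),
    ]
    assert relative_labels(records, tolerance=0.0) == [1, 1, 1, 0]


def test_relative_labels_tolerance_absorbs_experimental_error():
    records = [_rec("wt", 40.0), _rec("m", 37.0, mutations=[("S", 50, "A")])]
    assert relative_labels(records, tolerance=0.0) == [1, 0]
    assert relative_labels(records, tolerance=5.0) == [1, 1]


def test_relative_labels_invariant_to_per_substrate_shift():
    records = [_rec("wt", 40.0), _rec("m", 35.0, mutations=[("S", 50, "A")])]
    shifted = [_rec("wt", 60.0), _rec("m", 55.0, mutations=[("S", 50, "A")])]
    assert relative_labels(records) == relative_labels(shifted)


def test_relative_labels_require_wild_type_reference():
    with pytest.raises(ValueError, match="CCO"):
        relative_labels([_rec("m", 50.0, smiles="CCO",
                              mutations=[("W", 104, "C")])])


# ------------------------------------------------------ distal eligibility

def test_all_near_structure_has_no_eligible_residues():
    structure, triad = make_augmentation_fixture(n_near=30, n_far=0, seed=1)
    config = AugmentationConfig(triad_positions=triad)
    assert eligible_distal_residues(structure, config) == []


def test_constructed_151_far_residues_are_all_eligible():
    structure, triad = make_augmentation_fixture(n_near=40, n_far=151, seed=2)
    config = AugmentationConfig(triad_positions=triad)
    assert len(eligible_distal_residues(structure, config)) == 151


def test_raising_min_distance_never_adds_positions():
    structure, triad = make_augmentation_fixture(n_near=20, n_far=30, seed=3)
    sets = [set(eligible_distal_residues(
        structure, AugmentationConfig(triad_positions=triad, min_distance=d)))
        for d in (15.0, 20.0, 28.0, 35.0)]
    for smaller, larger in zip(sets[1:], sets[:-1]):
        assert smaller <= larger


def test_missing_triad_residue_rejected():
    structure, _ = make_augmentation_fixture(n_near=5, n_far=5, seed=4)
    with pytest.raises(ValueError, match="999"):
        eligible_distal_residues(structure,
                                 AugmentationConfig(triad_positions=(1, 2, 999)))


# ----------------------------------------------------------- augmentation

def test_negative_count_is_k_times_eligible_positions():
    structure, triad = make_augmentation_fixture(n_near=40, n_far=151, seed=5)
    records = [_rec("wt", 40.0, smiles=s) for s in ("CC", "CCO", "c1ccccc1")]
    config = AugmentationConfig(triad_positions=triad, mutations_per_position=8,
                                seed=11)
    negatives = augment_negatives(structure, records, config)
    assert len(negatives) == 151 * 8 == 1208
    assert all(n.conversion == 0.0 and n.provenance == "augmented"
               for n in negatives)


def test_no_eligible_positions_yield_no_negatives():
    structure, triad = make_augmentation_fixture(n_near=10, n_far=0, seed=6)
    config = AugmentationConfig(triad_positions=triad)
    assert augment_negatives(structure, [_rec("wt", 10.0)], config) == []


def test_every_negative_is_single_point_distal_and_non_wildtype():
    structure, triad = make_augmentation_fixture(n_near=12, n_far=20, seed=7)
    config = AugmentationConfig(triad_positions=triad, mutations_per_position=5,
                                seed=12)
    eligible = set(eligible_distal_residues(structure, config))
    aa_by_pos = {r[0]: r[1] for r in structure.residues}
    negatives = augment_negatives(structure, [_rec("wt", 10.0)], config)
    for neg in negatives:
        assert len(neg.mutations) == 1
        wt_aa, pos, mut_aa = neg.mutations[0]
        assert pos in eligible
        assert wt_aa == aa_by_pos[pos] and mut_aa != wt_aa
    # within a position the substituted residues are distinct
    by_pos: dict[int, set] = {}
    for neg in negatives:
        _, pos, mut_aa = neg.mutations[0]
        by_pos.setdefault(pos, set()).add(mut_aa)
    assert all(len(v) == 5 for v in by_pos.values())


def test_augmentation_reproducible_per_seed():
    structure, triad = make_augmentation_fixture(n_near=8, n_far=15, seed=8)
    records = [_rec("wt", 10.0, smiles=s) for s in ("CC", "CCO")]
    config = AugmentationConfig(triad_positions=triad, seed=99)
    a = augment_negatives(structure, records, config)
    b = augment_negatives(structure, records, config)
    assert [(x.variant_id, x.substrate_smiles) for x in a] \
        == [(y.variant_id, y.substrate_smiles) for y in b]
    other = augment_negatives(structure, records,
                              AugmentationConfig(triad_positions=triad, seed=100))
    assert [(x.variant_id, x.substrate_smiles) for x in a] \
        != [(y.variant_id, y.substrate_smiles) for y in other]


def test_combined_class_ratio_matches_construction():
    structure, triad = make_augmentation_fixture(n_near=20, n_far=151, seed=9)
    positives = [_rec(f"v{i}", 50.0, mutations=[("A", 4, "G")])
                 for i in range(145)]
    config = AugmentationConfig(triad_positions=triad, mutations_per_position=8,
                                seed=10)
    negatives = augment_negatives(structure, positives + [_rec("wt", 40.0)], config)
    assert len(positives) / len(negatives) == pytest.approx(145 / 1208)


def test_k_above_19_rejected():
    with pytest.raises(ValueError, match="19"):
        AugmentationConfig(mutations_per_position=20)


# ------------------------------------------------------------------- I/O

def test_conversion_table_round_trip(tmp_path):
    path = tmp_path / "conv.tsv"
    path.write_text("variant_id\tmutations\tsmiles\tconversion_pct\n"
                    "wt\t\tCC\t40.0\n"
                    "m1\tW104C\tCC\t55.0\n"
                    "m2\tW104C;A281E\tCCO\t12.5\n")
    records = read_conversion_table(path)
    assert records[0].is_wildtype
    assert records[1].mutations == [("W", 104, "C")]
    assert records[2].mutations == [("W", 104, "C"), ("A", 281, "E")]
    labels = threshold_labels(records, 15)
    out = tmp_path / "labeled.tsv"
    write_labeled_dataset(out, records, labels, label_rule="threshold>=15%")
    import pandas as pd

    df = pd.read_csv(out, sep="\t")
    assert list(df["label"]) == [1, 1, 0]
    assert set(df["provenance"]) == {"observed"}


def test_malformed_mutation_token_rejected():
    with pytest.raises(ValueError, match="104C"):
        parse_mutation("104C")
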