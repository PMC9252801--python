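import numpy as np
import pytest

from protloc.curation import (
    RawEntry,
    filter_hpa_style,
    filter_swissprot_style,
    load_default_mapping,
)
from protloc.homology import check_test_independence, global_identity
from protloc.seq_io import LabeledSequence, LocalizationLabelSet, ProteinRecord
from protloc.vocab import AMINO_ACIDS


def entry(**overrides) -> RawEntry:
    base = dict(
        id="E1",
        sequence="M" + "AKV" * 20,
        is_eukaryote=True,
        is_fragment=False,
        encoded_in="nucleus",
        sublocations=(("Nucleolus", ("ECO:0000269",)),),
        hpa_reliability=None,
    )
    base.update(overrides)
    return RawEntry(**base)


def test_length_filter_is_strictly_greater_than_40():
    kept41, _ = filter_swissprot_style([entry(sequence="A" * 41)])
    kept40, report = filter_swissprot_style([entry(sequence="A" * 40)])
    assert len(kept41) == 1
    assert len(kept40) == 0
    assert report.removed["too_short"] == 1


def test_fragment_removed_and_counted():
    kept, report = filter_swissprot_style([entry(is_fragment=True)])
    assert kept == []
    assert report.removed["fragment"] == 1


def test_label_set_is_union_of_mapped_terms():
    e = entry(sublocations=(("Nucleolus", ("ECO:0000269",)),
                            ("Cytosol", ("ECO:0000269",))))
    (ls,), _ = filter_swissprot_style([e])
    assert set(ls.localization.labels) == {"Nucleus", "Cytoplasm"}


def test_only_experimentally_evidenced_terms_contribute():
    e = entry(sublocations=(("Nucleolus", ("ECO:0000250",)),
                            ("Cytosol", ("ECO:0000269",))))
    (ls,), _ = filter_swissprot_style([e])
    assert ls.localization.labels == ("Cytoplasm",)


def test_no_experimental_evidence_removes_entry():
    e = entry(sublocations=(("Nucleolus", ("ECO:0000250",)),))
    kept, report = filter_swissprot_style([e])
    assert kept == []
    assert report.removed["no_experimental_evidence"] == 1


def test_organelle_encoded_and_prokaryotic_removed():
    kept, report = filter_swissprot_style([
        entry(id="A", encoded_in="mitochondrion"),
        entry(id="B", is_eukaryote=False),
    ])
    assert kept == []
    assert report.removed["not_nucleus_encoded"] == 1
    assert report.removed["not_eukaryote"] == 1


def test_report_counts_are_a_partition_of_the_input():
    entries = [
        entry(id="A"),
        entry(id="B", is_fragment=True),
        entry(id="C", sequence="A" * 30),
        entry(id="D", sublocations=(("Flagellum", ("ECO:0000269",)),)),
    ]
    kept, report = filter_swissprot_style(entries)
    assert report.input_count == 4
    assert sum(report.removed.values()) + report.retained == 4
    assert report.retained == len(kept) == 1


def test_empty_mapping_is_a_configuration_error():
    with pytest.raises(ValueError):
        filter_swissprot_style([entry()], mapping={})


def test_every_retained_sequence_has_labels_and_min_length():
    rng = np.random.default_rng(0)
    entries = []
    for i in range(30):
        n = int(rng.integers(20, 120))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=n))
        subloc = (("Nucleolus", ("ECO:0000269",)),) if i % 3 else \
            (("Unknown place", ("ECO:0000269",)),)
        entries.append(entry(id=f"E{i}", sequence=seq, sublocations=subloc,
                             is_fragment=bool(i % 7 == 0)))
    kept, _ = filter_swissprot_style(entries)
    for ls in kept:
        assert ls.record.length >= 41
        assert len(ls.localization) >= 1


def test_hpa_keeps_only_enhanced_and_supported():
    entries = [
        entry(id="A", hpa_reliability="Enhanced",
              sublocations=(("Nucleoplasm", ()),)),
        entry(id="B", hpa_reliability="Supported",
              sublocations=(("Cytosol", ()),)),
        entry(id="C", hpa_reliability="Approved",
              sublocations=(("Cytosol", ()),)),
        entry(id="D", hpa_reliability="Uncertain",
              sublocations=(("Cytosol", ()),)),
    ]
    kept = filter_hpa_style(entries)
    assert {ls.record.id for ls in kept} == {"A", "B"}
    assert kept[0].localization.labels == ("Nucleus",)


def test_hpa_all_uncertain_gives_empty_output():
    entries = [entry(id=f"E{i}", hpa_reliability="Uncertain") for i in range(3)]
    assert filter_hpa_style(entries) == []


def test_hpa_missing_reliability_is_an_error():
    with pytest.raises(ValueError):
        filter_hpa_style([entry(hpa_reliability=None)])


def test_hpa_restricted_to_benchmark_compartments():
    e = entry(hpa_reliability="Enhanced",
              sublocations=(("Peroxisome", ()), ("Nucleoplasm", ())))
    (ls,) = filter_hpa_style([e])
    # Peroxisome is outside the six-class benchmark subset
    assert ls.localization.labels == ("Nucleus",)


def test_default_mapping_loads_and_targets_vocabulary():
    mapping = load_default_mapping()
    assert mapping["cytosol"] == "Cytoplasm"
    assert mapping["chloroplast"] == "Plastid"


def _labeled(sid: str, seq: str) -> LabeledSequence:
    return LabeledSequence(
        record=ProteinRecord(sid, seq),
        localization=LocalizationLabelSet.from_labels(["Cytoplasm"]),
    )


def test_identical_sequence_in_both_sets_is_reported():
    seq = "MKVLWAYRQP" * 6
    violations = check_test_independence([_labeled("T", seq)],
                                         [_labeled("R", seq)])
    assert violations == [("T", "R", 1.0)]


def test_random_unrelated_sequences_pass_independence_check(rng):
    # oracle: the violation list must agree with exhaustive pairwise identity
    letters = list(AMINO_ACIDS)
    test = [_labeled(f"T{i}", "".join(rng.choice(letters, size=100)))
            for i in range(8)]
    train = [_labeled(f"R{i}", "".join(rng.choice(letters, size=100)))
             for i in range(8)]
    violations = check_test_independence(test, train)
    expected = [
        (t.record.id, r.record.id)
        for t in test for r in train
        if global_identity(t.record.sequence, r.record.sequence) > 0.30
    ]
    assert [(a, b) for a, b, _ in violations] == expected
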