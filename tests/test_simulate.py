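"""The planted-signal generator: grammar, determinism, composition."""

import io

import numpy as np
import pytest
from scipy import stats

from targetpep.alphabet import SIGNAL_CLASSES, net_charge
from targetpep.seqio import ProteinRecord, write_annotations, write_fasta
from targetpep.simulate import (
    MOTIF_MODELS,
    MotifModel,
    SyntheticConfig,
    class_count_report,
    generate_dataset,
    plant_signal,
)


def _fasta_bytes(records, annotations):
    import tempfile, pathlib

    with tempfile.TemporaryDirectory() as d:
        fa = pathlib.Path(d) / "a.fasta"
        tsv = pathlib.Path(d) / "a.tsv"
        write_fasta(fa, records)
        write_annotations(tsv, annotations)
        return fa.read_bytes() + tsv.read_bytes()


def test_motif_model_invariants():
    with pytest.raises(ValueError, match="exactly 4"):
        MotifModel("ER", (3, 4), "C_TERMINAL", {})
    with pytest.raises(ValueError, match="exactly 3"):
        MotifModel("PTS", (3, 4), "C_TERMINAL", {})
    with pytest.raises(ValueError, match="reserved for TH"):
        MotifModel("SP", (5, 10), "AFTER_CH", {})


def test_plant_er_motif_at_c_terminus(rng):
    record = ProteinRecord("P1", "G" * 50)
    out, ann = plant_signal(record, MOTIF_MODELS["ER"], rng)
    assert (ann.start, ann.end) == (47, 50)
    assert len(out.sequence) == 50
    motif = out.sequence[46:]
    assert motif[0] in "KHR" and motif[1] in "DE" and motif[3] == "L"


def test_plant_th_follows_existing_ch(rng):
    record = ProteinRecord("P1", "G" * 150)
    record, ch = plant_signal(record, MOTIF_MODELS["CH"], rng)
    record, th = plant_signal(record, MOTIF_MODELS["TH"], rng, [ch])
    assert th.start == ch.end + 1
    with pytest.raises(ValueError, match="existing CH"):
        plant_signal(ProteinRecord("P2", "G" * 150), MOTIF_MODELS["TH"], rng)


def test_plant_nls_is_internal(rng):
    for _ in range(50):
        record = ProteinRecord("P1", "G" * 80)
        _, ann = plant_signal(record, MOTIF_MODELS["NLS"], rng)
        assert 5 <= ann.length <= 20
        assert ann.start >= 2
        assert ann.end <= 79


def test_generate_dataset_deterministic_per_seed():
    config = SyntheticConfig(
        n_per_class={"SP": 10}, seed=7, long_fraction=0.0
    )
    out1 = generate_dataset(config)
    out2 = generate_dataset(config)
    assert _fasta_bytes(*out1) == _fasta_bytes(*out2)
    # a different seed changes the bytes
    out3 = generate_dataset(SyntheticConfig(
        n_per_class={"SP": 10}, seed=8, long_fraction=0.0))
    assert _fasta_bytes(*out1) != _fasta_bytes(*out3)


def test_generate_dataset_counts_and_signal_free():
    config = SyntheticConfig(
        n_per_class={c: 5 for c in SIGNAL_CLASSES},
        fraction_no_signal=0.2,
        long_fraction=0.0,
        seed=3,
    )
    records, annotations = generate_dataset(config)
    counts = class_count_report(annotations)
    for cls in SIGNAL_CLASSES:
        expected = 10 if cls == "CH" else 5  # TH proteins also carry CH
        assert counts.protein[cls] == expected
    n_signal = 40
    assert len(records) == n_signal + round(n_signal * 0.25)
    annotated = {a.protein_id for a in annotations}
    free = [r for r in records if r.id not in annotated]
    assert len(free) == 10


def test_generate_dataset_all_signal_free():
    config = SyntheticConfig(
        n_per_class={c: 0 for c in SIGNAL_CLASSES},
        fraction_no_signal=1.0,
        long_fraction=0.0,
        seed=0,
    )
    records, annotations = generate_dataset(config)
    assert len(records) == 20 and annotations == []


def test_planted_annotations_never_overlap_or_exceed_bounds():
    config = SyntheticConfig(
        n_per_class={c: 25 for c in SIGNAL_CLASSES},
        long_fraction=0.05,
        seed=11,
    )
    records, annotations = generate_dataset(config)
    lengths = {r.id: len(r.sequence) for r in records}
    by_protein = {}
    for a in annotations:
        assert 1 <= a.start <= a.end <= lengths[a.protein_id]
        by_protein.setdefault(a.protein_id, []).append(a)
    total_segments = 0
    for anns in by_protein.values():
        anns.sort(key=lambda a: a.start)
        total_segments += len(anns)
        for x, y in zip(anns, anns[1:]):
            assert x.end < y.start
    assert total_segments >= 1000 / 4  # plenty of planted segments checked


def test_mt_segments_are_net_positive():
    config = SyntheticConfig(
        n_per_class={"MT": 100}, long_fraction=0.0, seed=5
    )
    records, annotations = generate_dataset(config)
    seqs = {r.id: r.sequence for r in records}
    charges = [
        net_charge(seqs[a.protein_id][a.start - 1 : a.end])
        for a in annotations
    ]
    assert np.mean(charges) > 0
    assert "KKKRK" and net_charge("KKKRK") == 5  # charge rule sanity


def test_sp_interiors_are_hydrophobic_enriched():
    # one-sided binomial test of L/I/V frequency vs the uniform background
    config = SyntheticConfig(
        n_per_class={"SP": 60}, long_fraction=0.0, seed=9
    )
    records, annotations = generate_dataset(config)
    seqs = {r.id: r.sequence for r in records}
    hits = total = 0
    for a in annotations:
        interior = seqs[a.protein_id][a.start + 2 : a.end - 3]
        hits += sum(c in "LIV" for c in interior)
        total += len(interior)
    background_rate = 3 / 20
    res = stats.binomtest(hits, total, background_rate, alternative="greater")
    assert res.pvalue < 1e-10


def test_class_count_report_segment_vs_protein_level():
    from targetpep.seqio import SignalAnnotation

    anns = [
        SignalAnnotation("P1", "NLS", 5, 10),
        SignalAnnotation("P1", "NLS", 20, 30),
        SignalAnnotation("P2", "SP", 1, 20),
    ]
    counts = class_count_report(anns)
    assert counts.protein["NLS"] == 1 and counts.segment["NLS"] == 2
    assert counts.protein["SP"] == 1 and counts.segment["SP"] == 1
    empty = class_count_report([])
    assert all(v == 0 for v in empty.protein.values())


def test_duplicate_clusters_share_annotations():
    config = SyntheticConfig(
        n_per_class={"SP": 5},
        long_fraction=0.0,
        n_duplicate_clusters=2,
        duplicate_cluster_size=3,
        seed=2,
    )
    records, annotations = generate_dataset(config)
    dup_ids = [r.id for r in records if "dup" in r.id]
    assert len(dup_ids) == 4
    ann_ids = {a.protein_id for a in annotations}
    for did in dup_ids:
        parent = did.split("dup")[0]
        if parent in ann_ids:
            assert did in ann_ids


def test_config_from_file_and_unknown_key_rejection(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(
        "n_per_class:\n  SP: 3\nlength_range: [90, 120]\nseed: 4\n"
        "long_fraction: 0.0\n"
    )
    config = SyntheticConfig.from_file(path)
    assert config.n_per_class == {"SP": 3}
    assert config.length_range == (90, 120)
    records, _ = generate_dataset(config)
    assert all(90 <= len(r) <= 120 for r in records)
    path.write_text("bogus_key: 1\n")
    with pytest.raises(ValueError, match="bogus_key"):
        SyntheticConfig.from_file(path)
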