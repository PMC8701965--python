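import numpy as np
import pytest

from circmil.attention_map import (AttentionProfile, collapse_attention,
                                   export_for_meme, extract_splices,
                                   meme_command, splice_summary,
                                   write_profiles, write_splice_bed)
from circmil.instancing import WindowGeometry, extract_instances
from circmil.seqio import SequenceRecord


def make_profile(scaled, rid="t"):
    scaled = np.asarray(scaled, dtype=float)
    return AttentionProfile(record_id=rid, seq_len=len(scaled),
                            raw=scaled.copy(), scaled=scaled)


def naive_collapse(bag, alpha):
    """Oracle: per-position mean over covering windows by double loop."""
    L, w = bag.seq_len, bag.geometry.window
    raw = np.zeros(L)
    for p in range(L):
        covering = []
        for i, s in enumerate(bag.starts):
            positions = {(s + j) % L for j in range(w)}
            if p in positions:
                covering.append(alpha[i])
        if covering:
            raw[p] = float(np.mean(covering))
    return raw


def test_collapse_two_window_worked_case():
    rec = SequenceRecord("x", "ACGTACGTAC")
    bag = extract_instances(rec, WindowGeometry(window=5, step=5))
    prof = collapse_attention(bag, np.array([0.8, 0.2]))
    np.testing.assert_allclose(prof.raw[:5], 0.8)
    np.testing.assert_allclose(prof.raw[5:], 0.2)
    np.testing.assert_allclose(prof.scaled[:5], 1.0)
    np.testing.assert_allclose(prof.scaled[5:], 0.0)


def test_collapse_uniform_alpha_scales_to_zero():
    rec = SequenceRecord("x", "ACGTACGTACGT")
    bag = extract_instances(rec, WindowGeometry(window=6, step=6))
    prof = collapse_attention(bag, np.full(len(bag), 1.0 / len(bag)))
    assert np.ptp(prof.raw) == pytest.approx(0.0, abs=1e-15)
    np.testing.assert_array_equal(prof.scaled, 0.0)


def test_collapse_matches_naive_oracle_on_random_bags(rng):
    for _ in range(50):
        L = int(rng.integers(10, 80))
        w = int(rng.integers(2, 30))
        s = int(rng.integers(1, 15))
        seq = "".join("ATGC"[c] for c in rng.integers(0, 4, L))
        bag = extract_instances(SequenceRecord("x", seq), WindowGeometry(w, s))
        alpha = rng.random(len(bag))
        alpha /= alpha.sum()
        prof = collapse_attention(bag, alpha)
        np.testing.assert_allclose(prof.raw, naive_collapse(bag, alpha),
                                   atol=1e-12)


def test_collapse_sum_mode_and_alpha_mismatch(rng):
    rec = SequenceRecord("x", "ACGTACGTAC")
    bag = extract_instances(rec, WindowGeometry(window=5, step=5))
    prof = collapse_attention(bag, np.array([0.5, 0.5]), aggregate="sum")
    np.testing.assert_allclose(prof.raw, 0.5)
    with pytest.raises(ValueError):
        collapse_attention(bag, np.array([1.0]))
    with pytest.raises(ValueError):
        collapse_attention(bag, np.array([0.5, 0.5]), aggregate="median")


def test_collapse_monotone_in_single_covering_instance():
    """Raising one instance's attention never lowers the raw score at
    positions only it covers."""
    rec = SequenceRecord("x", "ACGTACGTAC")
    bag = extract_instances(rec, WindowGeometry(window=5, step=5))
    lo = collapse_attention(bag, np.array([0.3, 0.7])).raw[:5]
    hi = collapse_attention(bag, np.array([0.6, 0.4])).raw[:5]
    assert (hi >= lo).all()


def test_splice_minimum_length_boundary():
    base = np.zeros(30)
    base[5:13] = 0.9                      # run of exactly 8
    splices = extract_splices(make_profile(base), "A" * 30)
    assert len(splices) == 1
    assert (splices[0].start, splices[0].end) == (5, 13)
    assert splices[0].subsequence == "A" * 8

    base7 = np.zeros(30)
    base7[5:12] = 0.9                     # run of 7: below "length > 7"
    assert extract_splices(make_profile(base7), "A" * 30) == []


def test_splice_threshold_strictly_above():
    vals = np.zeros(30)
    vals[10:20] = 0.6                     # exactly at threshold: excluded
    assert extract_splices(make_profile(vals), "C" * 30) == []
    vals[10:20] = 0.600001
    assert len(extract_splices(make_profile(vals), "C" * 30)) == 1


def test_splice_positions_all_above_threshold(rng):
    scaled = rng.random(200)
    seq = "".join("ATGC"[c] for c in rng.integers(0, 4, 200))
    for sp in extract_splices(make_profile(scaled), seq):
        assert (scaled[sp.start:sp.end] > 0.6).all()
        assert len(sp) >= 8 or sp.group_id  # fragments may be shorter than 8
        assert sp.subsequence == seq[sp.start:sp.end]


def test_splice_crossing_junction_reports_two_fragments():
    vals = np.zeros(40)
    vals[34:] = 0.9
    vals[:6] = 0.9                        # circular run 34..45 (len 12)
    seq = "ACGT" * 10
    splices = extract_splices(make_profile(vals), seq)
    assert len(splices) == 2
    assert {(s.start, s.end) for s in splices} == {(34, 40), (0, 6)}
    assert len({s.group_id for s in splices}) == 1
    # whole-sequence run stays a single splice
    full = extract_splices(make_profile(np.full(40, 0.9)), seq)
    assert len(full) == 1 and (full[0].start, full[0].end) == (0, 40)


def test_meme_export_and_command(tmp_path, capsys):
    vals = np.zeros(50)
    vals[3:15] = 0.95
    vals[30:41] = 0.85
    seq = "ACGTACGTAC" * 5
    splices = extract_splices(make_profile(vals, "tr1"), seq)
    assert len(splices) == 2
    out = tmp_path / "splices.fasta"
    cmd = export_for_meme(splices, out)
    assert "-mod zoops -minw 6 -maxw 50" in cmd
    assert "-objfun classic -markov_order 0" in cmd
    assert cmd == meme_command(out)
    text = out.read_text()
    headers = [l for l in text.splitlines() if l.startswith(">")]
    assert len(headers) == 2
    assert len(set(headers)) == 2          # unique ids per splice
    assert export_for_meme([], tmp_path / "none.fasta") is None
    assert not (tmp_path / "none.fasta").exists()


def test_splice_summary_histograms():
    lengths, per_transcript = splice_summary({})
    assert lengths == {} and per_transcript == {}

    vals = np.zeros(120)
    for s in (0, 20, 40, 60):
        vals[s:s + 10] = 0.9
    splices = extract_splices(make_profile(vals, "t1"), "A" * 120)
    lengths, per_transcript = splice_summary({"t1": splices})
    assert per_transcript == {4: 1}
    assert lengths == {10: 4}
    assert min(lengths) >= 8


def test_profile_and_bed_exports(tmp_path):
    prof = make_profile(np.linspace(0, 1, 10), "t1")
    write_profiles([prof], tmp_path / "prof.tsv")
    lines = (tmp_path / "prof.tsv").read_text().strip().split("\n")
    assert len(lines) == 11
    vals = np.zeros(30)
    vals[2:14] = 0.9
    splices = extract_splices(prof := make_profile(vals, "t1"), "G" * 30)
    write_splice_bed(splices, tmp_path / "bed.tsv")
    row = (tmp_path / "bed.tsv").read_text().strip().split("\n")[1].split("\t")
    assert row[:3] == ["t1", "3", "14"]    # 1-based inclusive
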