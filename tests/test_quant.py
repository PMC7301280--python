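import numpy as np
import pandas as pd
import pytest

from proteoage.quant import (
    DigestionRule,
    digest_and_count_observable,
    filter_psms,
    compute_ibaq,
    split_precursor_to_channels,
    summarize_protein_groups,
    tryptic_peptides,
)
from proteoage.synthetic import generate_protein_sequences, generate_psm_table


# --- digestion -------------------------------------------------------------


def brute_force_observable(sequence: str, rule: DigestionRule = DigestionRule()) -> int:
    """Independent enumerator: scan all substrings, keep those whose
    boundaries are valid tryptic termini with no internal cleavage site."""
    s = sequence.strip().upper()
    n = len(s)

    def cleaves_after(k):  # cleavage between k and k+1
        return s[k] in "KR" and k + 1 < n and s[k + 1] != "P"

    found = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not (rule.min_length <= j - i <= rule.max_length):
                continue
            left_ok = i == 0 or cleaves_after(i - 1)
            right_ok = j == n or cleaves_after(j - 1)
            internal = any(cleaves_after(k) for k in range(i, j - 1))
            if left_ok and right_ok and not internal:
                found.add(s[i:j])
    return len(found)


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("MKWVTFISLLK", 1),  # fragments MK + WVTFISLLK; only one in window
        ("AAAKPAAAAAAAR", 1),  # K before P is not cleaved: single 13-mer
        ("AAAA", 0),  # below the length window
        ("", 0),
    ],
)
def test_observable_peptide_counts(sequence, expected):
    assert digest_and_count_observable(sequence) == expected


def test_kp_suppression_yields_single_fragment():
    assert tryptic_peptides("AAAKPAAAAAAAR") == ["AAAKPAAAAAAAR"]


def test_digestion_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(7)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWYX"))
    for _ in range(100):
        length = int(rng.integers(1, 61))
        seq = "".join(rng.choice(alphabet, size=length))
        assert digest_and_count_observable(seq) == brute_force_observable(seq), seq


# --- PSM filtering ---------------------------------------------------------


def _psm(psm_id, score=50.0, reporters=None, reverse=False, contaminant=False,
         peptide="WVTFISLLK", protein="P1", precursor=1e6, unique=True):
    row = {
        "psm_id": psm_id,
        "peptide_sequence": peptide,
        "protein_group_id": protein,
        "is_unique_peptide": unique,
        "search_score": score,
        "precursor_intensity": precursor,
        "is_reverse": reverse,
        "is_contaminant": contaminant,
        "run_id": "r1",
    }
    reporters = reporters if reporters is not None else [1e4] * 10
    for i, v in enumerate(reporters):
        row[f"reporter_{i + 1}"] = v
    return row


def test_filter_psms_criteria():
    table = pd.DataFrame(
        [
            _psm("keep"),
            _psm("low_score", score=14.9),
            _psm("all_low_reporters", reporters=[999.0] * 10),
            _psm("one_channel_at_limit", reporters=[999.0] * 9 + [1000.0]),
            _psm("reverse_high_score", score=100.0, reverse=True),
            _psm("contaminant", contaminant=True),
        ]
    )
    kept, report = filter_psms(table)
    assert set(kept["psm_id"]) == {"keep", "one_channel_at_limit"}
    assert report.n_low_score == 1
    assert report.n_low_reporter == 1
    assert report.n_reverse == 1
    assert report.n_contaminant == 1


def test_filter_psms_idempotent():
    table = pd.DataFrame([_psm(f"p{i}", score=10 + 2 * i) for i in range(10)])
    once, _ = filter_psms(table)
    twice, report = filter_psms(once)
    pd.testing.assert_frame_equal(once, twice)
    assert report.n_retained == report.n_input


def test_filter_psms_empty_result_errors():
    table = pd.DataFrame([_psm("only", score=1.0)])
    with pytest.raises(ValueError, match="all PSMs removed"):
        filter_psms(table)


# --- summarization ---------------------------------------------------------


def test_identical_peptides_summarize_to_centered_vector():
    reporters = [1e4 * (i + 1) for i in range(10)]
    other = [2e4] * 10
    table = pd.DataFrame(
        [_psm(f"p{i}", reporters=reporters, peptide=f"PEPTIDE{i}K") for i in range(3)]
        + [_psm(f"q{i}", reporters=other, peptide=f"AAAA{i}K", protein="P2") for i in range(3)]
    )
    result = summarize_protein_groups(table)
    # median of identical peptide rows = that row, post per-channel centering
    all_logs = np.log2(np.array([reporters] * 3 + [other] * 3))
    centered = np.log2(reporters) - np.median(all_logs, axis=0)
    np.testing.assert_allclose(result.data.loc["P1"].to_numpy(), centered, atol=1e-12)


def test_peptide_with_zero_channel_excluded():
    good = [1e4] * 10
    bad = [1e4] * 6 + [0.0] + [1e4] * 3  # zero in channel 7
    table = pd.DataFrame(
        [
            _psm("a", reporters=good, peptide="AAAAK"),
            _psm("b", reporters=good, peptide="CCCCK"),
            _psm("c", reporters=bad, peptide="DDDDK"),
        ]
    )
    result = summarize_protein_groups(table)
    assert result.n_unique_peptides["P1"] == 2


def test_single_unique_peptide_protein_dropped():
    table = pd.DataFrame(
        [
            _psm("a", peptide="AAAAK", protein="P1"),
            _psm("b", peptide="CCCCK", protein="P2"),
            _psm("c", peptide="DDDDK", protein="P2"),
        ]
    )
    result = summarize_protein_groups(table)
    assert list(result.data.index) == ["P2"]


def test_summarization_invariant_to_psm_order(rng):
    seqs = generate_protein_sequences(20, seed=4)
    table, _ = generate_psm_table(seqs, seed=4)
    kept, _ = filter_psms(table)
    shuffled = kept.sample(frac=1.0, random_state=9).reset_index(drop=True)
    a = summarize_protein_groups(kept).data.sort_index()
    b = summarize_protein_groups(shuffled).data.sort_index()
    pd.testing.assert_frame_equal(a, b)


# --- precursor splitting and iBAQ -----------------------------------------


def test_proportional_split_conserves_precursor():
    scale = 7.7e3
    table = pd.DataFrame(
        [_psm("a", reporters=[0.5 * scale, 0.3 * scale, 0.2 * scale], precursor=1e6)]
    )
    split = split_precursor_to_channels(table)
    unc = split[[f"uncorrected_reporter_{i}" for i in (1, 2, 3)]].to_numpy()[0]
    np.testing.assert_allclose(unc, [5e5, 3e5, 2e5], rtol=1e-12)
    assert np.isclose(unc.sum(), 1e6, rtol=1e-12)


def test_peptide_ratios_are_channel_medians_renormalized():
    table = pd.DataFrame(
        [
            _psm("a", reporters=[0.5, 0.5, 0.0], precursor=100.0),
            _psm("b", reporters=[0.3, 0.7, 0.0], precursor=100.0),
        ]
    )
    split = split_precursor_to_channels(table)
    unc = split[[f"uncorrected_reporter_{i}" for i in (1, 2, 3)]].to_numpy()[0]
    np.testing.assert_allclose(unc / unc.sum(), [0.4, 0.6, 0.0], rtol=1e-12)
    assert np.isclose(unc.sum(), 200.0, rtol=1e-12)  # summed precursor total


def test_equal_channels_give_symmetric_correction():
    table = pd.DataFrame(
        [_psm(f"p{i}", reporters=[1e4] * 10, peptide=f"PEP{i}K") for i in range(4)]
    )
    split = split_precursor_to_channels(table)
    cols = [f"reporter_{i + 1}" for i in range(10)]
    values = split[cols].to_numpy()
    assert np.allclose(values, values[:, [0]])  # every channel identical


def test_ibaq_arithmetic_and_scale_invariance():
    # single-channel table: ratio and correction are both 1, so each
    # peptide's channel intensity equals its precursor area of 3e5
    table = pd.DataFrame(
        [
            _psm("a", reporters=[1.0], peptide="AAAAK", precursor=3e5),
            _psm("b", reporters=[1.0], peptide="CCCCK", precursor=3e5),
        ]
    )
    split = split_precursor_to_channels(table)
    ibaq = compute_ibaq(split, {"P1": 4}, normalize=False)
    np.testing.assert_allclose(ibaq.data.to_numpy(), 6e5 / 4, rtol=1e-12)

    # doubling all intensities of one channel is undone by normalization
    seqs = generate_protein_sequences(15, seed=6)
    table, _ = generate_psm_table(seqs, seed=6)
    kept, _ = filter_psms(table)
    split = split_precursor_to_channels(kept)
    counts = {p: 5 for p in split["protein_group_id"].unique()}
    base = compute_ibaq(split, counts)
    doubled = split.copy()
    doubled["reporter_1"] = doubled["reporter_1"] * 2
    pd.testing.assert_frame_equal(
        compute_ibaq(doubled, counts).data, base.data, rtol=1e-9
    )


def test_ibaq_zero_observable_excluded():
    table = pd.DataFrame([_psm("a", reporters=[1.0] * 10, precursor=1e5)])
    split = split_precursor_to_channels(table)
    ibaq = compute_ibaq(split, {"P1": 0}, normalize=False)
    assert len(ibaq.data) == 0
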