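import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gh13csr import SyntheticConfig, generate_family, generate_truth_msa
from gh13csr.csr import (
    DEFAULT_LAYOUT,
    CsrLayout,
    CsrSpan,
    Fingerprint,
    extract_fingerprints,
    infer_reference_by_conservation,
    locate_anchors,
    trim_beta_segment,
)
from gh13csr.registry import ReferenceAnnotation
from gh13csr.seqio import Msa
from gh13csr.synthetic_data import reference_annotation


class TestLayout:
    def test_partitions_55_columns(self):
        lay = DEFAULT_LAYOUT
        assert lay.total_width == 55
        covered = []
        for span in lay.spans:
            covered.extend(range(span.start, span.end + 1))
        assert covered == list(range(1, 56))

    def test_landmark_positions(self):
        lay = DEFAULT_LAYOUT
        assert lay.triad_columns == (28, 37, 46)
        assert lay.chloride_columns == (26, 44, 50)
        assert lay.csr_of(28) == "CSR-II"
        assert lay.csr_of(37) == "CSR-III"
        assert lay.csr_of(46) == "CSR-IV"
        assert lay.csr_of(26) == "CSR-II"
        assert lay.csr_of(44) == "CSR-IV"
        assert lay.csr_of(50) == "CSR-VII"

    def test_span_widths(self):
        widths = {s.name: s.width for s in DEFAULT_LAYOUT.spans}
        assert widths == {
            "CSR-VIII": 3, "CSR-VI": 9, "CSR-I": 6, "CSR-V": 5,
            "CSR-II": 9, "CSR-III": 8, "CSR-IV": 6, "CSR-VII": 9,
        }

    def test_non_contiguous_layout_rejected(self):
        spans = list(DEFAULT_LAYOUT.spans)
        spans[1] = CsrSpan("CSR-VI", 5, 12)
        with pytest.raises(ValueError, match="contiguous"):
            CsrLayout(spans=tuple(spans))

    def test_fingerprint_length_enforced(self):
        with pytest.raises(ValueError, match="length"):
            Fingerprint(accession="A", sequence="SHORT")


@pytest.fixture(scope="module")
def anchored(truth_alignment):
    msa, ref, truths = truth_alignment
    return msa, ref, truths, locate_anchors(msa, ref)


class TestLocateAnchors:
    def test_gap_free_msa_maps_identically(self):
        cfg = SyntheticConfig(seed=2, n_sequences=3, linker_length_ranges=((5, 5),) * 7)
        records, truths = generate_family(cfg)
        msa = generate_truth_msa(records, truths)
        anchors = locate_anchors(msa, reference_annotation(truths[0]))
        for name, cols in anchors.csr_columns.items():
            start = truths[0].csr_starts[name]
            assert cols == tuple(range(start, start + DEFAULT_LAYOUT.width(name)))

    def test_truth_msa_spans_equal_planted_columns(self, anchored):
        msa, _, truths, anchors = anchored
        max_len = [max(t.linker_lengths[g] for t in truths) for g in range(7)]
        col = truths[0].signal_length
        for k, name in enumerate(DEFAULT_LAYOUT.order):
            w = DEFAULT_LAYOUT.width(name)
            assert anchors.csr_columns[name] == tuple(range(col + 1, col + w + 1))
            col += w
            if k < 7:
                col += max_len[k]

    def test_wrong_triad_residue_is_an_error(self, truth_alignment):
        msa, ref, _ = truth_alignment
        bad = ReferenceAnnotation(
            accession=ref.accession,
            subfamily=ref.subfamily,
            csr_starts=dict(ref.csr_starts),
            triad_positions=(
                ref.triad_positions[0] + 1,  # off by one: not an Asp
                ref.triad_positions[1],
                ref.triad_positions[2],
            ),
        )
        with pytest.raises(ValueError, match="catalytic triad mismatch"):
            locate_anchors(msa, bad)

    def test_reference_missing_from_msa(self, truth_alignment):
        msa, ref, _ = truth_alignment
        stranger = ReferenceAnnotation(
            accession="NOPE", subfamily=ref.subfamily,
            csr_starts=dict(ref.csr_starts), triad_positions=ref.triad_positions,
        )
        with pytest.raises(KeyError):
            locate_anchors(msa, stranger)

    def test_gap_inside_reference_csr_rejected(self):
        # hand-built alignment: reference row has a gap inside CSR-VIII
        cfg = SyntheticConfig(seed=2, n_sequences=2, linker_length_ranges=((5, 5),) * 7)
        records, truths = generate_family(cfg)
        msa = generate_truth_msa(records, truths)
        row = msa.rows[0]
        broken = row[:1] + "-" + row[1:]
        other = msa.rows[1][:1] + "A" + msa.rows[1][1:]
        bad_msa = Msa(msa.row_ids, [broken, other])
        ref = reference_annotation(truths[0])
        with pytest.raises(ValueError, match="gap inside"):
            locate_anchors(bad_msa, ref)

    def test_anchors_invariant_under_gapped_flanks(self, anchored):
        msa, ref, _, anchors = anchored
        pad = 4
        padded = Msa(msa.row_ids, ["-" * pad + row + "-" * pad for row in msa.rows])
        shifted = locate_anchors(padded, ref)
        for name in DEFAULT_LAYOUT.order:
            assert shifted.csr_columns[name] == tuple(
                c + pad for c in anchors.csr_columns[name]
            )


class TestTrimBetaSegment:
    def test_full_width_anchors_leave_msa_unchanged(self):
        cfg = SyntheticConfig(seed=5, n_sequences=4)
        records, truths = generate_family(cfg)
        msa = generate_truth_msa(records, truths)
        anchors = locate_anchors(msa, reference_annotation(truths[0]))
        trimmed = trim_beta_segment(msa, anchors)
        assert trimmed.width == msa.width  # no signal/tail -> nothing to cut
        assert trimmed.rows == msa.rows

    def test_flanks_are_cut(self):
        cfg = SyntheticConfig(
            seed=5, n_sequences=4, signal_peptide_length=10, c_tail_length=10,
            linker_length_ranges=((6, 6),) * 7,
        )
        records, truths = generate_family(cfg)
        msa = generate_truth_msa(records, truths)
        anchors = locate_anchors(msa, reference_annotation(truths[0]))
        trimmed = trim_beta_segment(msa, anchors)
        assert trimmed.width == msa.width - 20
        assert len(trimmed) == len(msa)

    def test_single_row(self):
        cfg = SyntheticConfig(seed=6, n_sequences=1, signal_peptide_length=5)
        records, truths = generate_family(cfg)
        msa = generate_truth_msa(records, truths)
        anchors = locate_anchors(msa, reference_annotation(truths[0]))
        trimmed = trim_beta_segment(msa, anchors)
        assert len(trimmed) == 1
        assert trimmed.width == msa.width - 5


class TestExtractFingerprints:
    def test_length_is_always_55(self, anchored):
        msa, _, _, anchors = anchored
        fps = extract_fingerprints(msa, anchors)
        assert all(len(fp.sequence) == 55 for fp in fps)

    def test_reference_triad_letters(self, anchored):
        msa, ref, _, anchors = anchored
        fps = {fp.accession: fp for fp in extract_fingerprints(msa, anchors)}
        fp = fps[ref.accession]
        assert (fp.at(28), fp.at(37), fp.at(46)) == ("D", "E", "D")

    def test_truth_msa_reproduces_planted_fingerprints(self, anchored):
        msa, _, truths, anchors = anchored
        fps = extract_fingerprints(msa, anchors)
        truth = {t.accession: t.fingerprint for t in truths}
        assert all(fp.sequence == truth[fp.accession] for fp in fps)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_recovery_holds_for_any_seed(self, seed):
        cfg = SyntheticConfig(seed=seed, n_sequences=6, substitution_rate=0.1)
        records, truths = generate_family(cfg)
        msa = generate_truth_msa(records, truths)
        anchors = locate_anchors(msa, reference_annotation(truths[0]))
        fps = extract_fingerprints(msa, anchors)
        assert [fp.sequence for fp in fps] == [t.fingerprint for t in truths]

    def test_missing_span_is_an_error(self, anchored):
        msa, _, _, anchors = anchored
        crippled = anchors.__class__(
            reference=anchors.reference,
            csr_columns={k: v for k, v in anchors.csr_columns.items() if k != "CSR-V"},
            triad_columns=anchors.triad_columns,
            beta1_start=anchors.beta1_start,
            beta8_end=anchors.beta8_end,
        )
        with pytest.raises(ValueError, match="CSR-V"):
            extract_fingerprints(msa, crippled)


class TestConservationFallback:
    def test_recovers_truth_anchoring_on_noisy_linker_family(self):
        # conserved CSR blocks over noisy linkers is exactly the contrast
        # the heuristic needs; a noise-free family would be featureless
        cfg = SyntheticConfig(seed=30, n_sequences=10, substitution_rate=0.3)
        records, truths = generate_family(cfg)
        msa = generate_truth_msa(records, truths)
        inferred = infer_reference_by_conservation(msa)
        anchors = locate_anchors(msa, inferred)
        fps = extract_fingerprints(msa, anchors)
        truth = {t.accession: t.fingerprint for t in truths}
        assert all(fp.sequence == truth[fp.accession] for fp in fps)
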