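import numpy as np
import pytest

from sigassign import (
    SBS96_LABELS,
    ActivityMatrix,
    MutationRecord,
    MutationalCatalog,
    SchemaError,
    SignatureSet,
    ValidationError,
    build_catalog_from_mutations,
    classify_sbs96,
    custom_schema,
    read_activities,
    read_catalog,
    read_mutations,
    read_signatures,
    sbs96_schema,
    write_activities,
    write_catalog,
    write_signatures,
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class TestSchema:
    def test_sbs96_has_canonical_labels(self):
        schema = sbs96_schema()
        assert schema.size == 96
        assert schema.channels[0] == "A[C>A]A"
        assert schema.channels[-1] == "T[T>G]T"
        assert len(set(schema.channels)) == 96

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            custom_schema(["x", "x", "y"])

    def test_named_schema_size_enforced(self):
        with pytest.raises(SchemaError):
            custom_schema(["a", "b"], name="DBS78")


class TestClassifySbs96:
    @pytest.mark.parametrize(
        "context, ref, alt, label",
        [
            ("ACA", "C", "A", "A[C>A]A"),  # first channel of the ordering
            ("TGT", "G", "T", "A[C>A]A"),  # purine ref: revcomp of the above
            ("TCT", "C", "G", "T[C>G]T"),
            ("ATC", "T", "C", "A[T>C]C"),
            ("GAG", "A", "T", "C[T>A]C"),  # A>T maps to T>A on the other strand
        ],
    )
    def test_known_classifications(self, context, ref, alt, label):
        idx = classify_sbs96(context, ref, alt)
        assert SBS96_LABELS[idx] == label

    def test_first_channel_is_index_zero(self):
        assert classify_sbs96("ACA", "C", "A") == 0

    def test_exhaustive_strand_involution(self):
        """classify(ctx, ref, alt) == classify(revcomp ctx, comp ref, comp alt)

        Checked over all 192 valid SBS inputs against a brute-force table
        built directly from the complement rule.
        """
        bases = "ACGT"
        checked = 0
        for p5 in bases:
            for ref in bases:
                for p3 in bases:
                    for alt in bases:
                        if alt == ref:
                            continue
                        ctx = p5 + ref + p3
                        # independent oracle: normalize by hand
                        if ref in "CT":
                            expected = f"{p5}[{ref}>{alt}]{p3}"
                        else:
                            expected = (
                                f"{COMPLEMENT[p3]}[{COMPLEMENT[ref]}>"
                                f"{COMPLEMENT[alt]}]{COMPLEMENT[p5]}"
                            )
                        idx = classify_sbs96(ctx, ref, alt)
                        assert SBS96_LABELS[idx] == expected
                        assert idx == classify_sbs96(
                            revcomp(ctx), COMPLEMENT[ref], COMPLEMENT[alt]
                        )
                        checked += 1
        assert checked == 192

    @pytest.mark.parametrize(
        "context, ref, alt",
        [
            ("ACA", "A", "G"),  # context center != ref
            ("ACA", "C", "C"),  # ref == alt
            ("ANA", "N", "T"),  # non-ACGT
            ("ACGT", "C", "T"),  # wrong length
        ],
    )
    def test_invalid_inputs_rejected(self, context, ref, alt):
        with pytest.raises(ValidationError):
            classify_sbs96(context, ref, alt)


class TestCatalogIO:
    def test_zero_sample_round_trip(self, tmp_path):
        catalog = MutationalCatalog(
            sbs96_schema(), ["S1"], np.zeros((96, 1), dtype=int)
        )
        path = tmp_path / "cat.tsv"
        write_catalog(catalog, path)
        back = read_catalog(path)
        assert back.schema.name == "SBS96"
        assert back.counts.sum() == 0
        assert back.sample_ids == ["S1"]

    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(96, 4))
        catalog = MutationalCatalog(sbs96_schema(), ["a", "b", "c", "d"], counts)
        path = tmp_path / "cat.tsv"
        write_catalog(catalog, path)
        back = read_catalog(path)
        np.testing.assert_array_equal(back.counts, catalog.counts)
        assert back.sample_ids == catalog.sample_ids
        assert back.schema.channels == catalog.schema.channels

    def test_shuffled_rows_are_reordered(self, tmp_path):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=(96, 3))
        perm = rng.permutation(96)
        lines = ["MutationType\tx\ty\tz"]
        for i in perm:
            row = "\t".join(str(c) for c in counts[i])
            lines.append(f"{SBS96_LABELS[i]}\t{row}")
        path = tmp_path / "shuffled.tsv"
        path.write_text("\n".join(lines) + "\n")
        back = read_catalog(path)
        # the reader must invert exactly the permutation the test applied
        np.testing.assert_array_equal(back.counts, counts)

    def test_unknown_label_set_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        lines = ["MutationType\ts"] + [f"{l}\t1" for l in SBS96_LABELS[:-1]] + ["BOGUS\t1"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError):
            read_catalog(path, schema=sbs96_schema())

    def test_negative_and_fractional_counts_rejected(self, tmp_path):
        for bad in ("-3", "2.5"):
            path = tmp_path / f"bad{bad}.tsv"
            lines = ["MutationType\ts"] + [f"{l}\t{bad}" for l in SBS96_LABELS]
            path.write_text("\n".join(lines) + "\n")
            with pytest.raises(ValidationError):
                read_catalog(path)

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        lines = ["MutationType\ts\ts"] + [f"{l}\t0\t0" for l in SBS96_LABELS]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError):
            read_catalog(path)


class TestSignatureIO:
    def test_columns_already_normalized_unchanged(self, tmp_path):
        profiles = np.zeros((96, 2))
        profiles[0, 0] = 0.25
        profiles[1, 0] = 0.75
        profiles[2, 1] = 1.0
        sigs = SignatureSet(sbs96_schema(), ["SBS_A", "SBS_B"], profiles)
        path = tmp_path / "sigs.tsv"
        write_signatures(sigs, path)
        back = read_signatures(path)
        np.testing.assert_allclose(back.profiles, profiles, atol=1e-15)
        assert back.signature_ids == ["SBS_A", "SBS_B"]

    def test_small_deviation_renormalized_exactly(self):
        profiles = np.zeros((96, 1))
        profiles[0, 0] = 0.9995  # sum within the 1e-3 tolerance
        sigs = SignatureSet(sbs96_schema(), ["S"], profiles)
        assert abs(sigs.profiles[:, 0].sum() - 1.0) < 1e-12

    def test_large_deviation_rejected(self):
        profiles = np.zeros((96, 1))
        profiles[0, 0] = 0.90
        with pytest.raises(ValidationError):
            SignatureSet(sbs96_schema(), ["S"], profiles)

    def test_negative_entry_rejected(self):
        profiles = np.zeros((96, 1))
        profiles[0, 0] = 1.1
        profiles[1, 0] = -0.1
        with pytest.raises(ValidationError):
            SignatureSet(sbs96_schema(), ["S"], profiles)


class TestMutationLists:
    def test_empty_record_list(self):
        catalog, records = build_catalog_from_mutations([])
        assert catalog.counts.shape == (96, 0)
        assert records == []

    def test_three_records_one_channel(self):
        records = [
            MutationRecord("T1", "1", 100, "C", "A", "ACA"),
            MutationRecord("T1", "1", 200, "C", "A", "ACA"),
            MutationRecord("T1", "2", 300, "G", "T", "TGT"),  # revcomp of A[C>A]A
        ]
        catalog, annotated = build_catalog_from_mutations(records)
        assert catalog.sample_ids == ["T1"]
        assert catalog.counts[0, 0] == 3  # all three in A[C>A]A
        assert catalog.counts.sum() == 3
        assert all(r.channel_index == 0 for r in annotated)

    def test_per_sample_conservation(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        records = []
        per_sample = {"a": 17, "b": 9}
        for sample, n in per_sample.items():
            for _ in range(n):
                ref = bases[rng.integers(4)]
                alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
                ctx = bases[rng.integers(4)] + ref + bases[rng.integers(4)]
                records.append(MutationRecord(sample, "1", 1, ref, alt, ctx))
        catalog, _ = build_catalog_from_mutations(records)
        assert catalog.counts.sum() == len(records)
        for i, sample in enumerate(catalog.sample_ids):
            assert catalog.counts[:, i].sum() == per_sample[sample]

    def test_missing_context_names_the_record(self):
        records = [MutationRecord("T9", "7", 1234, "C", "T", None)]
        with pytest.raises(ValidationError, match="T9 7:1234"):
            build_catalog_from_mutations(records)

    def test_read_mutation_list(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text(
            "sample\tchrom\tpos\tref\talt\tcontext\n"
            "T1\t1\t100\tC\tA\tACA\n"
            "T1\tX\t42\tG\tT\tTGT\n"
        )
        records = read_mutations(path)
        assert len(records) == 2
        assert records[1].chrom == "X"
        assert records[1].pos == 42

    def test_multiallelic_rejected(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text(
            "sample\tchrom\tpos\tref\talt\tcontext\nT1\t1\t100\tC\tA,G\tACA\n"
        )
        with pytest.raises(ValidationError):
            read_mutations(path)


class TestActivityIO:
    def test_round_trip(self, tmp_path):
        am = ActivityMatrix(["s1", "s2", "s3"], ["a", "b"], [[5, 0], [7, 2], [0, 9]])
        path = tmp_path / "acts.tsv"
        write_activities(am, path)
        back = read_activities(path)
        np.testing.assert_array_equal(back.values, am.values)
        assert back.signature_ids == am.signature_ids
        assert back.sample_ids == am.sample_ids

    def test_layout_samples_rows_signatures_columns(self, tmp_path):
        am = ActivityMatrix(["s1", "s2", "s3"], ["a", "b"], np.zeros((3, 2), dtype=int))
        path = tmp_path / "acts.tsv"
        write_activities(am, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["Samples", "s1", "s2", "s3"]
        assert len(lines) == 3  # header + 2 sample rows
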