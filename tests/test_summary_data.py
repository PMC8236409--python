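"""Reading, harmonization, panel alignment and strata meta-analysis."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediation import (
    SummaryDataError,
    align_panels,
    harmonize,
    meta_analyze_strata,
    read_summary_table,
    write_summary_table,
)
from mrmediation.summary_data import VariantAssociation

from conftest import make_dataset, make_record


HEADER = "variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"


def write_rows(tmp_path, rows, header=HEADER, name="table.tsv"):
    path = tmp_path / name
    path.write_text(header + "".join(rows))
    return path


class TestReadSummaryTable:
    def test_well_formed_rows_all_read(self, tmp_path):
        path = write_rows(
            tmp_path,
            [
                "rs1\tA\tG\t0.3\t0.1\t0.01\t1e-10\t100000\n",
                "rs2\tC\tT\t0.5\t-0.05\t0.02\t0.012\t100000\n",
                "rs3\tAT\tA\t0.1\t0.0\t0.01\t1.0\t100000\n",
            ],
        )
        ds = read_summary_table(path, "bmi", "continuous")
        assert len(ds) == 3
        assert ds["rs2"].beta == -0.05
        assert ds["rs3"].effect_allele == "AT"  # indels at face value

    def test_invalid_se_row_dropped_with_warning(self, tmp_path, caplog):
        path = write_rows(
            tmp_path,
            [
                "rs1\tA\tG\t0.3\t0.1\t0.0\t1e-10\t100000\n",  # se = 0
                "rs2\tA\tG\t0.3\t0.1\t0.01\t1e-10\t100000\n",
            ],
        )
        with caplog.at_level(logging.WARNING):
            ds = read_summary_table(path, "bmi", "continuous")
        assert len(ds) == 1 and "rs2" in ds
        assert any("invariants" in r.message for r in caplog.records)

    def test_missing_eaf_column_accepted_and_roundtrips(self, tmp_path):
        header = "variant_id\teffect_allele\tother_allele\tbeta\tse\tpvalue\tn\n"
        path = write_rows(
            tmp_path,
            ["rs1\tA\tG\t0.123456789\t0.01\t1e-10\t100000\n"],
            header=header,
        )
        ds = read_summary_table(path, "bmi", "continuous")
        assert ds["rs1"].eaf is None
        # round-trip oracle: write then read preserves every present field
        out = tmp_path / "rt.tsv"
        write_summary_table(ds, out)
        back = read_summary_table(out, "bmi", "continuous")
        assert back.records == ds.records
        # and a second write is byte-identical
        out2 = tmp_path / "rt2.tsv"
        write_summary_table(back, out2)
        assert out.read_bytes() == out2.read_bytes()

    def test_missing_mandatory_column_fatal(self, tmp_path):
        path = write_rows(
            tmp_path,
            ["rs1\tA\tG\t0.3\t0.01\t1e-10\t100000\n"],
            header="variant_id\teffect_allele\tother_allele\teaf\tse\tpvalue\tn\n",
        )
        with pytest.raises(SummaryDataError, match="beta"):
            read_summary_table(path, "bmi", "continuous")

    def test_duplicate_variant_keeps_first(self, tmp_path, caplog):
        path = write_rows(
            tmp_path,
            [
                "rs1\tA\tG\t0.3\t0.1\t0.01\t1e-10\t100000\n",
                "rs1\tA\tG\t0.3\t0.9\t0.01\t1e-10\t100000\n",
            ],
        )
        with caplog.at_level(logging.WARNING):
            ds = read_summary_table(path, "bmi", "continuous")
        assert ds["rs1"].beta == 0.1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_column_aliases(self, tmp_path):
        path = write_rows(
            tmp_path,
            ["rs1\tA\tG\t0.1\t0.01\n"],
            header="SNP\tA1\tA2\tb\tstderr\n",
        )
        ds = read_summary_table(
            path,
            "bmi",
            "continuous",
            aliases={
                "variant_id": "SNP",
                "effect_allele": "A1",
                "other_allele": "A2",
                "beta": "b",
                "se": "stderr",
            },
        )
        assert ds["rs1"].beta == 0.1

    def test_inconsistent_pvalue_warns_but_keeps(self, tmp_path, caplog):
        # z = 10 implies p ~ 1.5e-23; stored p = 0.5 is wildly off
        path = write_rows(tmp_path, ["rs1\tA\tG\t0.3\t0.1\t0.01\t0.5\t100000\n"])
        with caplog.at_level(logging.WARNING):
            ds = read_summary_table(path, "bmi", "continuous")
        assert len(ds) == 1
        assert any("inconsistent" in r.message for r in caplog.records)


class TestHarmonize:
    def test_matching_orientation_unchanged(self):
        ref = make_dataset("x", [make_record("rs1", 0.10)])
        other = make_dataset("y", [make_record("rs1", 0.05)])
        out = harmonize(ref, other)
        assert out["rs1"].beta == 0.05

    def test_swapped_alleles_negate_beta_and_reflect_eaf(self):
        ref = make_dataset("x", [make_record("rs1", 0.10, effect="A", other="G")])
        other = make_dataset("y", [make_record("rs1", 0.05, effect="G", other="A", eaf=0.3)])
        out = harmonize(ref, other)
        assert out["rs1"].beta == -0.05
        assert out["rs1"].eaf == pytest.approx(0.7)
        assert (out["rs1"].effect_allele, out["rs1"].other_allele) == ("A", "G")

    def test_unmatchable_alleles_dropped(self, caplog):
        ref = make_dataset("x", [make_record("rs1", 0.10, effect="A", other="G")])
        other = make_dataset("y", [make_record("rs1", 0.05, effect="A", other="C")])
        with caplog.at_level(logging.WARNING):
            with pytest.raises(SummaryDataError):
                harmonize(ref, other)  # nothing left after the drop

    def test_palindromic_variants_kept_at_face_value(self):
        ref = make_dataset("x", [make_record("rs1", 0.10, effect="A", other="T", eaf=0.9)])
        other = make_dataset("y", [make_record("rs1", 0.05, effect="T", other="A", eaf=0.1)])
        out = harmonize(ref, other)  # swap rule applies; no frequency check
        assert out["rs1"].beta == -0.05

    def test_zero_shared_variants_fatal(self):
        ref = make_dataset("x", [make_record("rs1", 0.1)])
        other = make_dataset("y", [make_record("rs2", 0.1)])
        with pytest.raises(SummaryDataError, match="shared"):
            harmonize(ref, other)

    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_double_swap_restores_exactly(self, beta, eaf):
        ref = make_dataset("x", [make_record("rs1", 0.1, effect="A", other="G")])
        rec = make_record("rs1", beta, effect="G", other="A", eaf=eaf)
        once = harmonize(ref, make_dataset("y", [rec]))
        # swapping back against the original orientation restores beta and eaf
        back_ref = make_dataset("z", [make_record("rs1", 0.1, effect="G", other="A")])
        twice = harmonize(back_ref, once)
        assert twice["rs1"].beta == beta  # negation is exact
        assert twice["rs1"].eaf == pytest.approx(eaf, abs=1e-15)

    def test_idempotent_on_aligned_data(self, rng):
        ref = make_dataset("x", [make_record(f"rs{i}", rng.normal()) for i in range(8)])
        other = make_dataset(
            "y",
            [
                make_record(f"rs{i}", rng.normal(), effect="G", other="A")
                for i in range(0, 8, 2)
            ]
            + [make_record(f"rs{i}", rng.normal()) for i in range(1, 8, 2)],
        )
        once = harmonize(ref, other)
        twice = harmonize(ref, once)
        assert twice.records == once.records


class TestAlignPanels:
    def test_intersection_of_variants(self):
        a = make_dataset("x", [make_record(f"rs{i}", 0.1) for i in range(8)])
        b = make_dataset("y", [make_record(f"rs{i}", 0.2) for i in range(3, 11)])
        panel = align_panels([a, b])
        assert panel.n_variants == 5
        assert panel.traits == ["x", "y"]

    def test_allele_incompatibility_propagates(self):
        a = make_dataset("x", [make_record(f"rs{i}", 0.1) for i in range(3)])
        b = make_dataset("y", [make_record(f"rs{i}", 0.2) for i in range(3)])
        c_recs = [make_record("rs0", 0.3, effect="C", other="T")] + [
            make_record(f"rs{i}", 0.3) for i in (1, 2)
        ]
        c = make_dataset("z", c_recs)
        panel = align_panels([a, b, c])
        assert "rs0" not in panel.variant_ids and panel.n_variants == 2

    def test_composition_matches_pairwise_oracle(self, rng):
        # random panels: each cell equals the pairwise-harmonized value
        def random_ds(name, swap_mask):
            recs = []
            for i in range(10):
                if swap_mask[i]:
                    recs.append(
                        make_record(f"rs{i}", rng.normal(), effect="G", other="A", eaf=0.4)
                    )
                else:
                    recs.append(make_record(f"rs{i}", rng.normal(), eaf=0.4))
            return make_dataset(name, recs)

        a = random_ds("a", [False] * 10)
        b = random_ds("b", rng.random(10) < 0.5)
        c = random_ds("c", rng.random(10) < 0.5)
        panel = align_panels([a, b, c])
        hb, hc = harmonize(a, b), harmonize(a, c)
        for i, vid in enumerate(panel.variant_ids):
            assert panel.beta[i, 1] == hb[vid].beta
            assert panel.beta[i, 2] == hc[vid].beta

    def test_invariant_to_nonreference_order(self, rng):
        a = make_dataset("a", [make_record(f"rs{i}", rng.normal()) for i in range(6)])
        b = make_dataset("b", [make_record(f"rs{i}", rng.normal()) for i in range(6)])
        c = make_dataset("c", [make_record(f"rs{i}", rng.normal()) for i in range(6)])
        p1 = align_panels([a, b, c])
        p2 = align_panels([a, c, b])
        np.testing.assert_array_equal(p1.beta[:, 1], p2.beta[:, 2])
        np.testing.assert_array_equal(p1.beta[:, 2], p2.beta[:, 1])
        assert p1.variant_ids == p2.variant_ids

    def test_empty_intersection_fatal(self):
        a = make_dataset("x", [make_record("rs1", 0.1)])
        b = make_dataset("y", [make_record("rs2", 0.1)])
        with pytest.raises(SummaryDataError):
            align_panels([a, b])


class TestMetaAnalyzeStrata:
    def test_identical_strata_halve_variance(self):
        a = make_dataset("fg", [make_record("rs1", 0.10, se=0.02)])
        b = make_dataset("fg", [make_record("rs1", 0.10, se=0.02)])
        out = meta_analyze_strata(a, b)
        assert out["rs1"].beta == pytest.approx(0.10)
        assert out["rs1"].se == pytest.approx(0.02 / math.sqrt(2), abs=1e-12)

    def test_equal_weights_average(self):
        a = make_dataset("fg", [make_record("rs1", 0.0, se=0.01)])
        b = make_dataset("fg", [make_record("rs1", 0.2, se=0.01)])
        out = meta_analyze_strata(a, b)
        assert out["rs1"].beta == pytest.approx(0.10, abs=1e-15)

    def test_unequal_ses_match_formula_oracle(self, rng):
        recs_a, recs_b = [], []
        for i in range(20):
            recs_a.append(make_record(f"rs{i}", rng.normal(), se=rng.uniform(0.01, 0.05)))
            recs_b.append(make_record(f"rs{i}", rng.normal(), se=rng.uniform(0.01, 0.05)))
        a, b = make_dataset("fg", recs_a), make_dataset("fg", recs_b)
        out = meta_analyze_strata(a, b)
        for i in range(20):
            ra, rb = recs_a[i], recs_b[i]
            wa, wb = ra.se**-2, rb.se**-2
            exp_beta = (ra.beta * wa + rb.beta * wb) / (wa + wb)
            exp_se = (wa + wb) ** -0.5
            got = out[f"rs{i}"]
            assert got.beta == pytest.approx(exp_beta, abs=1e-12)
            assert got.se == pytest.approx(exp_se, abs=1e-12)
            assert got.n == ra.n + rb.n

    def test_self_meta_exactly_halves_variance(self, rng):
        a = make_dataset(
            "fg", [make_record(f"rs{i}", rng.normal(), se=rng.uniform(0.01, 0.05)) for i in range(5)]
        )
        out = meta_analyze_strata(a, a)
        for vid, rec in a.records.items():
            assert out[vid].se**2 == pytest.approx(rec.se**2 / 2, rel=1e-14)
            assert out[vid].beta == pytest.approx(rec.beta, rel=1e-14)
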