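import pytest
from hypothesis import given, settings, strategies as st

from detoxevol.curation import (CurationConfig, HitRecord, ProteinRecord,
                                build_complement_table,
                                confirm_family_membership, filter_by_length,
                                filter_hits_by_evalue,
                                select_longest_isoform)


def protein(pid, length, gene=None, species="Hhal"):
    return ProteinRecord(protein_id=pid, gene_id=gene or pid,
                         species_tag=species, length=length)


class TestLengthFilter:
    @pytest.mark.parametrize("length,kept", [(99, False), (100, True),
                                             (101, True), (1, False)])
    def test_boundary_is_strict(self, length, kept):
        """'Shorter than 100 amino acids' discards 99 and keeps 100."""
        records, log = filter_by_length([protein("p", length)])
        assert bool(records) is kept
        assert bool(log) is not kept

    def test_empty_input(self):
        assert filter_by_length([]) == ([], [])

    def test_count_conservation_and_reasons(self):
        records = [protein("a", 50), protein("b", 150), protein("c", 99)]
        kept, log = filter_by_length(records)
        assert len(kept) + len(log) == len(records)
        assert {e.record_id for e in log} == {"a", "c"}
        assert all("100aa" in e.reason for e in log)


class TestIsoformSelection:
    def test_longest_kept(self):
        records = [protein("p1", 120, gene="G"), protein("p2", 340, gene="G")]
        kept, log = select_longest_isoform(records)
        assert [r.protein_id for r in kept] == ["p2"]
        assert [e.record_id for e in log] == ["p1"]

    def test_tie_breaks_on_smallest_protein_id(self):
        records = [protein("pB", 200, gene="G"), protein("pA", 200, gene="G")]
        kept, _ = select_longest_isoform(records)
        assert kept[0].protein_id == "pA"

    def test_single_isoform_unchanged(self):
        records = [protein("p1", 111, gene="G")]
        kept, log = select_longest_isoform(records)
        assert kept == records and log == []


class TestEvalueFilter:
    def test_threshold_is_strict(self):
        hits = [HitRecord("q", "t", 1.0e-4), HitRecord("q", "t2", 9.9e-5)]
        kept = filter_hits_by_evalue(hits, threshold=1e-4)
        assert [h.target_id for h in kept] == ["t2"]

    def test_empty_and_invalid(self):
        assert filter_hits_by_evalue([]) == []
        with pytest.raises(ValueError):
            HitRecord("q", "t", -1.0)
        with pytest.raises(ValueError):
            filter_hits_by_evalue([], threshold=0)


class TestFilterProperties:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=500), max_size=30),
           st.integers(min_value=1, max_value=300))
    def test_length_filter_idempotent_and_conserving(self, lengths, cutoff):
        records = [protein(f"p{i}", n) for i, n in enumerate(lengths)]
        kept, log = filter_by_length(records, cutoff)
        assert len(kept) + len(log) == len(records)
        again, log2 = filter_by_length(kept, cutoff)
        assert again == kept and log2 == []

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e-2,
                              allow_nan=False), max_size=30))
    def test_evalue_filter_idempotent(self, evalues):
        hits = [HitRecord(f"q{i}", "t", e) for i, e in enumerate(evalues)]
        kept = filter_hits_by_evalue(hits)
        assert filter_hits_by_evalue(kept) == kept


class TestDomainConfirmation:
    def test_domain_to_superfamily(self):
        records = [protein("p1", 200), protein("p2", 200), protein("p3", 200),
                   protein("p4", 200)]
        domains = {"p1": {"PF00067"}, "p2": {"PF00135"},
                   "p3": {"PF02798"}, "p4": set()}
        kept, log, conflicts = confirm_family_membership(records, domains)
        assert {r.protein_id: r.superfamily for r in kept} == \
            {"p1": "CYP", "p2": "CCE", "p3": "GST"}
        assert [e.record_id for e in log] == ["p4"]
        assert conflicts == []

    def test_conflicts_flagged_not_assigned_silently(self):
        records = [protein("p1", 200)]
        domains = {"p1": {"PF00067", "PF00135"}}
        kept, _, conflicts = confirm_family_membership(records, domains)
        assert conflicts == ["p1"]
        assert len(kept) == 1

    def test_missing_annotation_discarded_with_reason(self):
        kept, log, _ = confirm_family_membership([protein("p1", 200)], {})
        assert kept == [] and log[0].reason == "no_domain_annotation"


class TestComplementAssembly:
    def test_counts_and_sum_derived_totals(self):
        records = []
        groups = {}
        spec = {("CYP", "CYP3"): 3, ("CYP", "CYP4"): 2, ("GST", "Sigma"): 4}
        i = 0
        for (fam, group), n in spec.items():
            for _ in range(n):
                pid = f"p{i}"
                i += 1
                records.append(ProteinRecord(pid, pid, "Hhal", 200,
                                             superfamily=fam))
                groups[pid] = group
        table = build_complement_table(records, groups)
        assert table.get("Hhal", "CYP", "CYP3") == 3
        assert table.superfamily_total("Hhal", "CYP") == 5
        assert table.grand_total("Hhal") == 9

    def test_unlabeled_record_rejected(self):
        with pytest.raises(ValueError):
            build_complement_table([protein("p1", 200)], {"p1": "CYP3"})

    def test_unknown_species_rejected(self):
        rec = ProteinRecord("p1", "p1", "Zzzz", 200, superfamily="CYP")
        with pytest.raises(ValueError):
            build_complement_table([rec], {"p1": "CYP3"},
                                   known_species=["Hhal"])

    def test_empty_set_all_zero(self):
        table = build_complement_table([], {})
        assert table.frame.empty


class TestRecordInvariants:
    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            protein("p", 0)

    def test_sequence_length_must_match(self):
        with pytest.raises(ValueError):
            ProteinRecord("p", "p", "Hhal", 5, sequence="AAA")

    def test_defaults_match_published_settings(self):
        config = CurationConfig()
        assert config.min_protein_length == 100
        assert config.evalue_threshold == 1e-4
        assert config.superfamily_domains["CYP"] == {"PF00067"}
        assert config.superfamily_domains["GST"] == {"PF02798", "PF00043"}
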