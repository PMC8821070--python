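import itertools

import pytest

from cpgmeth import classify_dnmt, generate_domtblout, parse_domtblout, select_candidates
from cpgmeth.dnmt import classify_file, presence_summary

NON_CATALYTIC = [
    "DNMT1_RFD", "zf_CXXC", "BAH",       # DNMT1-diagnostic
    "PWWP", "ADD_DNMT3",                  # DNMT3-diagnostic
    "DMAP_binding", "CH",                 # annotated, never diagnostic
]


def oracle_classify(domains):
    """Independent hand-written lookup for the rule system.

    Written directly from the family definitions, structured differently
    from the implementation (explicit counting, no set algebra reuse).
    """
    has = lambda d: d in domains
    n1 = sum(map(has, ("DNMT1_RFD", "zf_CXXC", "BAH")))
    n3 = sum(map(has, ("PWWP", "ADD_DNMT3")))
    if n1 > 0 and n3 > 0:
        return ("ambiguous", "not_applicable")
    if n3 == 0 and n1 == 3:
        return ("DNMT1", "full")
    if n3 == 0 and n1 in (1, 2):
        return ("DNMT1", "partial")
    if n1 == 0 and n3 == 2:
        return ("DNMT3", "full")
    if n1 == 0 and n3 == 1:
        return ("DNMT3", "partial")
    return ("DNMT2", "not_applicable")


class TestClassify:
    @pytest.mark.parametrize(
        "domains,expected_class,expected_completeness",
        [
            ({"DNA_methylase", "DNMT1_RFD", "zf_CXXC", "BAH"}, "DNMT1", "full"),
            ({"DNA_methylase", "BAH"}, "DNMT1", "partial"),
            ({"DNA_methylase", "DNMT1_RFD", "zf_CXXC"}, "DNMT1", "partial"),
            ({"DNA_methylase", "PWWP", "ADD_DNMT3"}, "DNMT3", "full"),
            ({"DNA_methylase", "PWWP"}, "DNMT3", "partial"),
            ({"DNA_methylase"}, "DNMT2", "not_applicable"),
            ({"DNA_methylase", "PWWP", "BAH"}, "ambiguous", "not_applicable"),
        ],
    )
    def test_family_rules(self, domains, expected_class, expected_completeness):
        call = classify_dnmt(domains)
        assert call.dnmt_class == expected_class
        assert call.completeness == expected_completeness

    def test_requires_catalytic_domain(self):
        with pytest.raises(ValueError, match="DNA_methylase"):
            classify_dnmt({"PWWP"})

    def test_extra_nondiagnostic_domains_flagged(self):
        call = classify_dnmt({"DNA_methylase", "DMAP_binding"})
        assert call.dnmt_class == "DNMT2"
        assert "extra_domain" in call.flags

    def test_ambiguous_needs_review(self):
        call = classify_dnmt({"DNA_methylase", "ADD_DNMT3", "zf_CXXC"})
        assert call.needs_review

    def test_exhaustive_truth_table_against_oracle(self):
        # all 2^7 architectures over the non-catalytic domains
        for r in range(len(NON_CATALYTIC) + 1):
            for combo in itertools.combinations(NON_CATALYTIC, r):
                domains = {"DNA_methylase", *combo}
                call = classify_dnmt(domains)
                assert (call.dnmt_class, call.completeness) == oracle_classify(domains), domains

    def test_depends_only_on_set_not_order(self):
        a = classify_dnmt(["DNA_methylase", "PWWP", "ADD_DNMT3"])
        b = classify_dnmt(["ADD_DNMT3", "DNA_methylase", "PWWP", "PWWP"])
        assert (a.dnmt_class, a.completeness) == (b.dnmt_class, b.completeness)


DOMTBL_ROW = (
    "{prot} - 900 {model} {acc} 120 {ev} 250.0 0.1 1 1 {ev} {ev} "
    "250.0 0.1 1 120 10 129 10 129 0.95 description here\n"
)
HEADER = "# target name ...\n"


class TestParseAndSelect:
    def test_parse_fixture_fields(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(
            HEADER
            + DOMTBL_ROW.format(prot="p1", model="DNA_methylase", acc="PF00145.20", ev="1e-40")
        )
        (hit,) = parse_domtblout(p)
        assert hit.protein_id == "p1"
        assert hit.domain_name == "DNA_methylase"
        assert hit.pfam_acc == "PF00145"
        assert hit.full_seq_evalue == 1e-40
        assert (hit.env_start, hit.env_end) == (10, 129)
        assert hit.known

    def test_hyphenated_model_names_canonicalized(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(DOMTBL_ROW.format(prot="p1", model="DNMT1-RFD", acc="PF12047.1", ev="1e-10"))
        (hit,) = parse_domtblout(p)
        assert hit.domain_name == "DNMT1_RFD"

    def test_comment_only_file(self, tmp_path):
        p = tmp_path / "empty.domtblout"
        p.write_text("# nothing\n#\n")
        assert parse_domtblout(p) == []

    def test_malformed_rows_name_the_line(self, tmp_path):
        p = tmp_path / "bad.domtblout"
        p.write_text(HEADER + "p1 - 900 DNA_methylase PF00145.1 120 not_a_number\n")
        with pytest.raises(ValueError, match=":2:"):
            parse_domtblout(p)
        p.write_text(
            HEADER
            + DOMTBL_ROW.format(prot="p1", model="DNA_methylase", acc="PF00145.1", ev="oops")
        )
        with pytest.raises(ValueError, match=":2:"):
            parse_domtblout(p)

    def test_unknown_domain_kept_but_flagged(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(DOMTBL_ROW.format(prot="p1", model="WD40", acc="PF00400.1", ev="1e-12"))
        (hit,) = parse_domtblout(p)
        assert not hit.known

    def test_candidate_selection_cutoff_is_strict(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(
            DOMTBL_ROW.format(prot="p1", model="DNA_methylase", acc="PF00145.1", ev="1e-40")
            + DOMTBL_ROW.format(prot="p2", model="DNA_methylase", acc="PF00145.1", ev="0.001")
            + DOMTBL_ROW.format(prot="p3", model="PWWP", acc="PF00855.1", ev="1e-40")
            + DOMTBL_ROW.format(prot="p1", model="PWWP", acc="PF00855.1", ev="0.5")
        )
        arch = select_candidates(parse_domtblout(p))
        assert set(arch) == {"p1"}
        # accessory domains join the architecture at any e-value
        assert arch["p1"] == {"DNA_methylase", "PWWP"}


class TestSyntheticRoundTrip:
    def test_requested_classes_reproduced(self, tmp_path):
        classes = {
            "p_full1": ("DNMT1", "full"),
            "p_part1": ("DNMT1", "partial"),
            "p_2": ("DNMT2", "not_applicable"),
            "p_full3": ("DNMT3", "full"),
            "p_part3": ("DNMT3", "partial"),
            "p_amb": ("ambiguous", "not_applicable"),
            "p_none": ("none", "not_applicable"),
        }
        path = tmp_path / "species.domtblout"
        generate_domtblout(classes, path, seed=1)
        calls = {c.protein_id: (c.dnmt_class, c.completeness) for c in classify_file(path)}
        assert "p_none" not in calls  # sub-threshold hit never becomes a candidate
        for pid, expected in classes.items():
            if expected[0] == "none":
                continue
            assert calls[pid] == expected

    def test_unachievable_request_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unachievable"):
            generate_domtblout({"p": ("DNMT2", "full")}, tmp_path / "x", seed=0)

    def test_many_random_requests_round_trip(self, tmp_path):
        import numpy as np

        rng = np.random.default_rng(99)
        achievable = [
            ("DNMT1", "full"), ("DNMT1", "partial"),
            ("DNMT3", "full"), ("DNMT3", "partial"),
            ("DNMT2", "not_applicable"), ("ambiguous", "not_applicable"),
        ]
        classes = {
            f"prot_{i:03d}": achievable[rng.integers(len(achievable))]
            for i in range(100)
        }
        path = tmp_path / "many.domtblout"
        generate_domtblout(classes, path, seed=7)
        calls = {c.protein_id: (c.dnmt_class, c.completeness) for c in classify_file(path)}
        assert sum(calls[p] == classes[p] for p in classes) == 100


def test_presence_summary_levels():
    calls = [
        classify_dnmt({"DNA_methylase", "BAH"}, "a"),
        classify_dnmt({"DNA_methylase"}, "b"),
    ]
    s = presence_summary(calls)
    assert s == {"DNMT1": "present_partial", "DNMT2": "present", "DNMT3": "absent"}
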