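"""Letter assignment by clade placement, positional rescue, architecture
strings and family-type calls."""

import dendropy
import pytest

from srcrpipe.nomenclature import (ArchitectureString, LetterAssignment,
                                   NomenclatureError, architecture_string,
                                   assign_letters, classify_family,
                                   positional_refine)

REF_ARCHS = [a.split("-") for a in (
    "a-b-c-d-e-d-b-c-d-e-d'", "h-i-j-k-b-c-d-e-d'", "m-l-b-c-n-d-e-d'")]


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)


def test_two_leaf_tree_query_takes_reference_letter():
    t = _tree("(q1|1:1,ref:1);")
    out = assign_letters(t, {"ref": "b"})
    assert out == [LetterAssignment("q1", 1, "b", "clade", 1.0)]


def test_query_sister_to_single_reference():
    t = _tree("((q1|1:1,refm:1)1.00:1,(refb:1,refc:1)1.00:1,refd:4);")
    out = assign_letters(t, {"refm": "m", "refb": "b", "refc": "c",
                             "refd": "d"})
    a = {(x.protein_id, x.domain_index): x for x in out}[("q1", 1)]
    assert (a.letter, a.method, a.support) == ("m", "clade", 1.0)


def test_low_support_clade_does_not_assign():
    t = _tree("((q1|1:1,refm:1)0.40:1,(refb:1,refc:1)1.00:1,refd:4);")
    out = assign_letters(t, {"refm": "m", "refb": "b", "refc": "c",
                             "refd": "d"}, threshold=0.70)
    # smallest supported side containing q1 is the complement of (refb,refc):
    # {q1, refm, refd} -> letters {m, d} mixed -> undesignated
    assert out[0].letter == "undesignated"


def test_reference_free_supported_cluster_gets_shared_new_letter():
    # every reference-containing side around the query cherry is
    # letter-mixed, so the cherry sits apart from all known classes
    t = _tree("((qa|1:1,qb|1:1)0.95:1,(refb:1,refc:1)0.95:1,"
              "(refd:1,refe:1)0.95:1);")
    out = assign_letters(t, {"refb": "b", "refc": "c", "refd": "d",
                             "refe": "e"})
    by = {x.protein_id: x for x in out}
    assert by["qa"].method == "new_letter"
    assert by["qa"].letter == by["qb"].letter == "o"


def test_new_letters_never_reuse_reference_alphabet():
    # two query-only clusters, all enclosing reference sides letter-mixed
    t = _tree("((qa|1:1,qb|1:1)0.95:1,((qc|1:1,qd|1:1)0.95:1,"
              "(refn:1,refd:1)0.95:1)0.95:1,(refb:1,refe:1)0.95:1);")
    out = assign_letters(t, {"refn": "n", "refd": "d", "refb": "b",
                             "refe": "e"})
    letters = {x.letter for x in out if x.method == "new_letter"}
    assert letters == {"o", "p"}
    assert not letters & {"a", "b", "c", "d", "d'", "e",
                          "h", "i", "j", "k", "l", "m", "n"}


def test_d_dprime_mixture_resolved_by_terminal_position():
    t = _tree("((q1|4:1,(refd:1,refdp:1)0.95:1)0.95:1,(q1|9:1,refd2:1)0.40:1,"
              "refb:4);")
    refs = {"refd": "d", "refdp": "d'", "refd2": "d", "refb": "b"}
    out = assign_letters(t, refs)
    by = {(x.protein_id, x.domain_index): x for x in out}
    # q1|4 is interior (protein has 9 domains) -> d; q1|9 is terminal.
    # q1|9's smallest supported side containing a reference is the
    # complement of the (q1|4, d, d') clade: contains b and d -> mixed.
    assert by[("q1", 4)].letter == "d"
    assert by[("q1", 4)].method == "clade"
    assert by[("q1", 9)].letter == "undesignated"


def test_dprime_assigned_to_terminal_domain():
    t = _tree("((q1|9:1,(refd:1,refdp:1)0.95:1)0.95:1,refb:4,refc:4);")
    out = assign_letters(t, {"refd": "d", "refdp": "d'", "refb": "b",
                             "refc": "c"})
    by = {(x.protein_id, x.domain_index): x for x in out}
    assert by[("q1", 9)].letter == "d'"


def test_assignment_invariant_under_leaf_order(default_family):
    nwk1 = "((q1|1:1,refm:1)0.9:1,(refb:1,q2|1:1)0.9:1,refd:4);"
    nwk2 = "(refd:4,(q2|1:1,refb:1)0.9:1,(refm:1,q1|1:1)0.9:1);"
    refs = {"refm": "m", "refb": "b", "refd": "d"}
    o1 = {(a.protein_id, a.domain_index): (a.letter, a.method)
          for a in assign_letters(_tree(nwk1), refs)}
    o2 = {(a.protein_id, a.domain_index): (a.letter, a.method)
          for a in assign_letters(_tree(nwk2), refs)}
    assert o1 == o2


def test_reference_letter_outside_alphabet_rejected():
    t = _tree("(q1|1:1,ref:1);")
    with pytest.raises(NomenclatureError, match="alphabet"):
        assign_letters(t, {"ref": "z"})


def _assign(pid, idx, letter, method="clade", support=0.9):
    return LetterAssignment(pid, idx, letter, method, support)


def test_positional_refine_promotes_unique_context():
    assigns = [_assign("p", 1, "c"),
               _assign("p", 2, "undesignated", "undesignated", None),
               _assign("p", 3, "e")]
    out = positional_refine(assigns, REF_ARCHS)
    assert out[1].letter == "d" and out[1].method == "positional"


def test_positional_refine_ambiguous_context_stays_undesignated():
    archs = REF_ARCHS + [["c", "k", "e"]]       # second c-?-e context
    assigns = [_assign("p", 1, "c"),
               _assign("p", 2, "undesignated", "undesignated", None),
               _assign("p", 3, "e")]
    out = positional_refine(assigns, archs)
    assert out[1].letter == "undesignated"


def test_positional_refine_noop_on_fully_assigned():
    assigns = [_assign("p", i, l) for i, l in enumerate("bcd", 1)]
    assert positional_refine(assigns, REF_ARCHS) == assigns


def test_positional_refine_never_overrides_clade_calls():
    assigns = [_assign("p", 1, "c"), _assign("p", 2, "b"),
               _assign("p", 3, "e")]
    out = positional_refine(assigns, REF_ARCHS)
    assert [a.letter for a in out] == ["c", "b", "e"]
    assert all(a.method == "clade" for a in out)


def test_architecture_string_rendering():
    letters = ["h", "i", "j", "k", "b", "c", "d", "e", "d'"]
    assigns = [_assign("p", i + 1, l) for i, l in enumerate(letters)]
    arch = architecture_string("p", assigns)
    assert arch.render() == "h-i-j-k-b-c-d-e-d'"
    assert ArchitectureString.parse("p", arch.render()).letters == letters


def test_architecture_string_undesignated_renders_x():
    assigns = [_assign("p", 1, "a"),
               _assign("p", 2, "undesignated", "undesignated", None),
               _assign("p", 3, "e")]
    arch = architecture_string("p", assigns)
    assert arch.render() == "a-x-e"
    parsed = ArchitectureString.parse("p", "a-x-e")
    assert parsed.letters == ["a", "undesignated", "e"]


def test_architecture_string_errors():
    with pytest.raises(NomenclatureError, match="no assignments"):
        architecture_string("p", [])
    with pytest.raises(NomenclatureError, match="gap"):
        architecture_string("p", [_assign("p", 1, "a"), _assign("p", 3, "b")])


@pytest.mark.parametrize("arch,call", [
    ("h-i-j-k-b-c-d-e-d'", "CD163A_like"),
    ("m-l-b-c-n-d-e-d'", "CD163c_alpha_like"),
    ("a-b-c-d-e-d-b-c-d-e-d'", "WC1_like"),
    ("a-x-c-n-d-e-d'", "hybrid"),
    ("a-k-n", "CD163A_like"),          # 'k' takes precedence
    ("b-c-d", "unclassified"),
    ("k", "CD163A_like"),
])
def test_classify_family_precedence(arch, call):
    assert classify_family(ArchitectureString.parse("p", arch)) == call


def test_generator_letter_accuracy(support_tree, reference_letters,
                                   default_family):
    """Clade assignment on the default family: >=95% letters correct and
    >=90% architectures exactly recovered."""
    truth = {}
    for rec in default_family.records:
        for t in default_family.truth_domains.for_protein(rec.id):
            truth[(rec.id, t["domain_index"])] = t["letter"]
    assigns = assign_letters(support_tree, reference_letters, threshold=0.70)
    correct = sum(a.letter == truth[(a.protein_id, a.domain_index)]
                  for a in assigns)
    assert correct / len(assigns) >= 0.95
    archs = {rec.id: architecture_string(rec.id, assigns).render()
             for rec in default_family.records}
    exact = sum(archs[p] == default_family.truth_architectures[p]
                for p in archs)
    assert exact / len(archs) >= 0.90
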