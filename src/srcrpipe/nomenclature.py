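"""Reference-guided nomenclature of SRCR domains by clade placement.

Each query domain is named after the reference domains it clusters with:
the smallest supported clade containing the query and at least one
letter-labelled reference domain donates its letter when unanimous.
Query-only supported clusters that sit apart from every single-letter
reference clade are given a fresh letter; leftovers stay undesignated,
with a positional rescue pass that fills an interior gap whose flanking
letters pin a unique reference-architecture context.  Architecture
strings (N-to-C letters joined by ``-``) and family-type calls are
derived from the assignments.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

from .njtree import node_support

#: letters already in use by the published reference nomenclature
REFERENCE_ALPHABET = ("a", "b", "c", "d", "d'", "e",
                      "h", "i", "j", "k", "l", "m", "n")

UNDESIGNATED = "undesignated"


class NomenclatureError(ValueError):
    pass


@dataclass
class LetterAssignment:
    protein_id: str
    domain_index: int
    letter: str                       # a nomenclature letter or "undesignated"
    method: str                       # clade | positional | new_letter | undesignated
    support: float | None = None


def parse_domain_leaf(label: str):
    """Split a domain leaf label ``<protein>|<ordinal>[|<letter>]`` into
    ``(protein_id, ordinal, letter_or_None)``."""
    parts = label.split("|")
    if len(parts) < 2:
        raise NomenclatureError(f"cannot parse domain leaf label {label!r}")
    letter = parts[2] if len(parts) > 2 else None
    return parts[0], int(parts[1]), letter


def reference_letters_from_alignment(alignment) -> dict[str, str]:
    """Reference alignment row IDs encode letters as
    ``<protein>|<ordinal>|<letter>``; returns leaf-label -> letter."""
    out = {}
    for label, _ in alignment.rows:
        _, _, letter = parse_domain_leaf(label)
        if letter is None:
            raise NomenclatureError(f"reference row {label!r} lacks a letter")
        out[label] = letter
    return out


def _new_letter_source(reference_letters: set[str]):
    """Fresh letters: alphabetical from 'o' onward, then o2, p2, ...;
    never reuses a reference letter."""
    base = [c for c in string.ascii_lowercase if c >= "o"]
    suffix = 0
    while True:
        for c in base:
            cand = c if suffix == 0 else f"{c}{suffix + 1}"
            if cand not in reference_letters:
                yield cand
        suffix += 1


def assign_letters(tree, reference_labels: dict[str, str],
                   threshold: float = 0.70,
                   query_order: list[str] | None = None
                   ) -> list[LetterAssignment]:
    """Assign nomenclature letters to the query leaves of a support-
    annotated tree.

    ``reference_labels`` maps reference leaf labels to their letters.
    Supported means internal-node support >= ``threshold``.  Per query:
    the smallest supported ancestor containing a reference donates its
    letter when its references are unanimous (d/d' mixtures resolve by
    the membrane-proximal convention: d' only for a protein's C-terminal
    domain); queries without such an assignment that form supported
    query-only clusters of >= 2 share a newly allocated letter; the rest
    are undesignated.
    """
    bad = set(reference_labels.values()) - set(REFERENCE_ALPHABET)
    if bad:
        raise NomenclatureError(f"reference letters outside alphabet: {bad}")

    leaves = list(tree.leaf_node_iter())
    all_labels = frozenset(l.taxon.label for l in leaves)
    queries = [l for l in leaves if l.taxon.label not in reference_labels]
    query_labels = [l.taxon.label for l in queries]
    # terminal-domain lookup for the d/d' convention
    max_index: dict[str, int] = {}
    for lab in query_labels:
        pid, idx, _ = parse_domain_leaf(lab)
        max_index[pid] = max(max_index.get(pid, 0), idx)

    # Clades on the (unrooted) tree are bipartition sides.  Each internal
    # non-root node contributes one supported bipartition; the clade
    # containing a given query is the node's subtree when the query sits
    # inside it, and the complement otherwise.  Working with sides rather
    # than rooted ancestors keeps the inference independent of where the
    # trifurcating NJ root happens to fall.
    sides: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        sup = node_support(node)
        if sup is None or sup < threshold:
            continue
        sub = frozenset(l.taxon.label for l in node.leaf_iter())
        for side in (sub, all_labels - sub):
            if 1 < len(side) < len(all_labels):
                sides[side] = max(sides.get(side, 0.0), sup)

    # two-leaf degenerate tree: no internal edges to test
    if len(leaves) == 2 and len(queries) == 1 and len(reference_labels) == 1:
        pid, idx, _ = parse_domain_leaf(query_labels[0])
        letter = next(iter(reference_labels.values()))
        return [LetterAssignment(pid, idx, letter, "clade", 1.0)]

    def assignability(letters: set[str]) -> int:
        """Rank competing minimal clades: unanimous beats a d/d' pair
        beats letter-mixed (the only mixture the positional convention
        can resolve is d with d')."""
        if len(letters) == 1:
            return 0
        if letters == {"d", "d'"}:
            return 1
        return 2

    assignments: dict[str, LetterAssignment] = {}
    for lab in query_labels:
        pid, idx, _ = parse_domain_leaf(lab)
        cands = []
        for side, sup in sides.items():
            if lab not in side:
                continue
            ref_in = side & reference_labels.keys()
            if not ref_in:
                continue
            letters = {reference_labels[r] for r in ref_in}
            cands.append((len(side), assignability(letters), -sup,
                          sorted(side), side, sup, letters))
        result = None
        if cands:
            _, _, _, _, side, sup, letters = min(
                cands, key=lambda c: c[:4])
            if len(letters) == 1:
                result = LetterAssignment(pid, idx, letters.pop(),
                                          "clade", sup)
            elif letters == {"d", "d'"}:
                choice = "d'" if idx == max_index[pid] else "d"
                result = LetterAssignment(pid, idx, choice, "clade", sup)
            else:
                result = LetterAssignment(pid, idx, UNDESIGNATED,
                                          "undesignated", sup)
        if result is None:
            result = LetterAssignment(pid, idx, UNDESIGNATED, "undesignated")
        assignments[lab] = result

    # supported query-only clusters of >=2 still-unassigned queries get a
    # shared fresh letter; only inclusion-maximal clusters count
    unassigned = {lab for lab, a in assignments.items()
                  if a.letter == UNDESIGNATED}
    ref_free = [(side, sup) for side, sup in sides.items()
                if not side & reference_labels.keys()]
    clusters = []
    for side, sup in ref_free:
        if len([m for m in side if m in unassigned]) < 2:
            continue
        if any(side < other for other, _ in ref_free):
            continue
        clusters.append((side, sup))

    order = query_order or query_labels
    rank = {lab: k for k, lab in enumerate(order)}
    clusters.sort(key=lambda c: min(rank.get(m, 1 << 30) for m in c[0]))
    fresh = _new_letter_source(set(reference_labels.values()))
    for side, sup in clusters:
        members = sorted(m for m in side if m in unassigned)
        if len(members) < 2:
            continue
        letter = next(fresh)
        for m in members:
            pid, idx, _ = parse_domain_leaf(m)
            assignments[m] = LetterAssignment(pid, idx, letter,
                                              "new_letter", sup)
            unassigned.discard(m)

    return [assignments[lab] for lab in query_labels]


def positional_refine(assignments: list[LetterAssignment],
                      reference_architectures: list[list[str]]
                      ) -> list[LetterAssignment]:
    """Promote undesignated interior domains whose flanking letters match
    a unique reference context.

    A domain at position i with assigned neighbours (left, right) becomes
    letter L if every occurrence of the context ``left-?-right`` across
    the reference architectures shows the same middle letter L.  Clade
    and new-letter assignments are never overridden.
    """
    contexts: dict[tuple[str, str], set[str]] = {}
    for arch in reference_architectures:
        for k in range(1, len(arch) - 1):
            contexts.setdefault((arch[k - 1], arch[k + 1]),
                                set()).add(arch[k])

    by_protein: dict[str, dict[int, LetterAssignment]] = {}
    for a in assignments:
        by_protein.setdefault(a.protein_id, {})[a.domain_index] = a

    out = []
    for a in assignments:
        if a.letter != UNDESIGNATED:
            out.append(a)
            continue
        prot = by_protein[a.protein_id]
        left = prot.get(a.domain_index - 1)
        right = prot.get(a.domain_index + 1)
        if (left is None or right is None
                or left.letter == UNDESIGNATED
                or right.letter == UNDESIGNATED):
            out.append(a)
            continue
        middles = contexts.get((left.letter, right.letter), set())
        if len(middles) == 1:
            out.append(LetterAssignment(a.protein_id, a.domain_index,
                                        next(iter(middles)), "positional",
                                        a.support))
        else:
            out.append(a)
    return out


@dataclass
class ArchitectureString:
    """N-to-C domain letters of one protein; rendered joined by ``-``
    with undesignated domains as ``x``."""

    protein_id: str
    letters: list[str]

    def render(self) -> str:
        return "-".join("x" if l == UNDESIGNATED else l for l in self.letters)

    @classmethod
    def parse(cls, protein_id: str, rendered: str) -> "ArchitectureString":
        letters = [UNDESIGNATED if t == "x" else t
                   for t in rendered.split("-")]
        return cls(protein_id, letters)


def architecture_string(protein_id: str,
                        assignments: list[LetterAssignment]
                        ) -> ArchitectureString:
    """Order a protein's assignments into its architecture string."""
    mine = sorted((a for a in assignments if a.protein_id == protein_id),
                  key=lambda a: a.domain_index)
    if not mine:
        raise NomenclatureError(f"no assignments for {protein_id}")
    if [a.domain_index for a in mine] != list(range(1, len(mine) + 1)):
        raise NomenclatureError(f"{protein_id}: gap in domain indices")
    return ArchitectureString(protein_id, [a.letter for a in mine])


#: diagnostic letters: 'k' marks CD163A/CD163b; 'a' marks WC1;
#: 'm'/'l'/'n' mark CD163c-alpha
def classify_family(arch: ArchitectureString) -> str:
    """Call the receptor family type from an architecture string."""
    letters = set(arch.letters)
    if not letters:
        raise NomenclatureError("empty architecture")
    cd163c = letters & {"m", "l", "n"}
    if "k" in letters:
        return "CD163A_like"
    if "a" in letters and cd163c:
        return "hybrid"
    if "a" in letters:
        return "WC1_like"
    if cd163c:
        return "CD163c_alpha_like"
    return "unclassified"
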