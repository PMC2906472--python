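"""Shared fixtures: synthetic families and derived pipeline stages.

Heavy artifacts are session-scoped; everything is generated in-process
from fixed seeds, no external data.
"""

import pytest

from srcrpipe.msa import progressive_align, trim_to_core
from srcrpipe.njtree import bootstrap_tree
from srcrpipe.nomenclature import reference_letters_from_alignment
from srcrpipe.srcr_scan import build_domain_model, scan_protein
from srcrpipe.synthetic_data import (FamilyConfig, bovine_cd163a_standin,
                                     bovine_cd163c_alpha_standin,
                                     generate_family)

FAMILY_SEED = 17


@pytest.fixture(scope="session")
def default_family():
    """Default study conditions: 3 published architectures x 4 copies."""
    return generate_family(FamilyConfig(seed=FAMILY_SEED))


@pytest.fixture(scope="session")
def domain_model(default_family):
    return build_domain_model(default_family.reference_alignment)


@pytest.fixture(scope="session")
def scanned_family(default_family, domain_model):
    """(family, hits_by_protein) for the default family."""
    hits = {rec.id: scan_protein(rec, domain_model)
            for rec in default_family.records}
    return default_family, hits


@pytest.fixture(scope="session")
def core_alignment(scanned_family, domain_model):
    """Reference + query domains progressively aligned and trimmed to the
    78-column core."""
    fam, hits = scanned_family
    ref = fam.reference_alignment
    seqs = [(lab, ref.ungapped(lab)) for lab in ref.labels]
    for rec in fam.records:
        for h in hits[rec.id]:
            seqs.append((f"{rec.id}|{h.domain_index}",
                         rec.sequence[h.start - 1:h.end]))
    aln = progressive_align(seqs)
    return trim_to_core(aln, domain_model, reference_label=ref.labels[0])


@pytest.fixture(scope="session")
def support_tree(core_alignment):
    return bootstrap_tree(core_alignment, B=100, seed=5)


@pytest.fixture(scope="session")
def reference_letters(default_family):
    return reference_letters_from_alignment(
        default_family.reference_alignment)


@pytest.fixture(scope="session")
def cd163a_standin():
    return bovine_cd163a_standin()


@pytest.fixture(scope="session")
def cd163c_standin():
    return bovine_cd163c_alpha_standin()
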