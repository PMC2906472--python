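"""p-distances, bootstrap/analytic standard errors, model corrections."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srcrpipe.distance import (DistanceError, DistanceMatrix, analytic_se,
                               bootstrap_se, correct_distance,
                               distance_matrix, jtt_saturation, p_distance,
                               read_distance_tsv, render_paper_table,
                               write_distance_tsv, _jtt_expected_p)
from srcrpipe.msa import DomainAlignment

ROW_A = "A" * 78
ROW_B = "C" * 14 + "A" * 64          # 14/78 differing columns -> 0.179


def test_p_distance_identical_rows():
    assert p_distance("ACDEF", "ACDEF") == (0.0, 5)


def test_p_distance_printed_table_value():
    p, L = p_distance(ROW_A, ROW_B)
    assert L == 78
    assert round(p, 3) == 0.179


def test_p_distance_excludes_gap_and_x_columns():
    assert p_distance("AC-E", "ACDE") == (0.0, 3)
    assert p_distance("ACXE", "ACDE") == (0.0, 3)
    p, L = p_distance("WC-E", "ACDE")
    assert (p, L) == (pytest.approx(1 / 3), 3)


def test_p_distance_undefined_not_zero():
    p, L = p_distance("----", "ACDE")
    assert p is None and L == 0


def test_p_distance_errors():
    with pytest.raises(DistanceError):
        p_distance("ACD", "AC")
    with pytest.raises(DistanceError):
        p_distance("ACD", "ACD", deletion_mode="jackknife")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 30), st.integers(3, 20))
def test_p_distance_is_a_metric_on_gapfree_rows(seed, n):
    """Symmetry, identity and triangle inequality on random triples."""
    rng = np.random.default_rng(seed)
    aas = list("ACDE")
    x, y, z = ("".join(rng.choice(aas, n)) for _ in range(3))
    dxy = p_distance(x, y)[0]
    dyx = p_distance(y, x)[0]
    dxz = p_distance(x, z)[0]
    dzy = p_distance(z, y)[0]
    assert dxy == dyx
    assert p_distance(x, x)[0] == 0
    assert dxy <= dxz + dzy + 1e-12


def test_analytic_se_values():
    assert analytic_se(0.0, 78) == 0.0
    assert round(analytic_se(0.115, 78), 3) == 0.036
    assert round(analytic_se(0.692, 78), 3) == 0.052
    assert analytic_se(14 / 78, 78) == pytest.approx(0.0434, abs=5e-4)


def test_bootstrap_se_identical_rows_zero():
    assert bootstrap_se("ACDEF" * 16, "ACDEF" * 16, B=200, seed=1) == 0.0


def test_bootstrap_se_matches_printed_table_cell():
    se = bootstrap_se(ROW_A, ROW_B, B=10_000, seed=11)
    assert se == pytest.approx(0.043, abs=0.002)


def test_bootstrap_se_reproducible_and_converges_to_analytic():
    a = bootstrap_se(ROW_A, ROW_B, B=2000, seed=5)
    assert a == bootstrap_se(ROW_A, ROW_B, B=2000, seed=5)
    p, L = p_distance(ROW_A, ROW_B)
    assert a == pytest.approx(analytic_se(p, L), abs=3 * a / math.sqrt(2 * 2000))


def test_bootstrap_spread_shrinks_with_B():
    def spread(B):
        vals = [bootstrap_se(ROW_A, ROW_B, B=B, seed=s) for s in range(12)]
        return np.std(vals)

    assert spread(3200) < spread(200)


def test_bootstrap_requires_seed_and_enough_replicates():
    with pytest.raises(DistanceError):
        bootstrap_se(ROW_A, ROW_B, B=50, seed=1)
    with pytest.raises(DistanceError):
        bootstrap_se(ROW_A, ROW_B, B=200, seed=None)


def test_corrections_at_zero_and_closed_forms():
    for tag in ("p", "poisson", "jtt_like"):
        assert correct_distance(0.0, tag) == 0.0
    assert correct_distance(0.35, "p") == 0.35
    assert correct_distance(0.5, "poisson") == pytest.approx(math.log(2))
    assert math.isinf(correct_distance(1.0, "poisson"))
    assert math.isinf(correct_distance(jtt_saturation() + 1e-6, "jtt_like"))
    with pytest.raises(DistanceError):
        correct_distance(0.5, "kimura")


@pytest.mark.parametrize("p0", [0.05, 0.30, 0.60, 0.85])
def test_jtt_inversion_matches_ml_oracle(p0):
    """The JTT distance maximizes the differ/agree binomial likelihood;
    an independent 1-D numerical optimization must agree to 1e-4."""
    from scipy.optimize import minimize_scalar

    d = correct_distance(p0, "jtt_like")
    n = 10_000
    k = round(n * p0)

    def nll(t):
        q = _jtt_expected_p(t)
        return -(k * math.log(q) + (n - k) * math.log(1 - q))

    res = minimize_scalar(nll, bounds=(1e-6, 40.0), method="bounded",
                          options={"xatol": 1e-10})
    assert d == pytest.approx(float(res.x), abs=1e-4)


def test_distance_matrix_symmetric_and_matches_pairwise(core_alignment):
    aln = DomainAlignment(core_alignment.rows[:6])
    m = distance_matrix(aln, B=150, seed=3)
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 0.0)
    p, _ = p_distance(aln.rows[0][1], aln.rows[1][1])
    assert m.values[0, 1] == pytest.approx(p)
    assert (m.se >= 0).all()


def test_distance_matrix_rectangular_extraction(core_alignment):
    aln = DomainAlignment(core_alignment.rows[:5])
    m = distance_matrix(aln)
    rows, cols = m.labels[:2], m.labels[2:5]
    sub = m.submatrix(rows, cols)
    assert sub.shape == (2, 3)
    assert sub.loc[rows[0], cols[0]] == m.get(rows[0], cols[0])


def test_distance_tsv_round_trip(tmp_path, core_alignment):
    m = distance_matrix(DomainAlignment(core_alignment.rows[:5]))
    path = tmp_path / "d.tsv"
    write_distance_tsv(m, path)
    back = read_distance_tsv(path)
    assert back.labels == m.labels
    assert np.allclose(back.values, m.values, atol=1e-6)


def test_paper_table_renderer(core_alignment):
    m = distance_matrix(DomainAlignment(core_alignment.rows[:4]),
                        B=150, seed=2)
    text = render_paper_table(m, m.labels[:2], m.labels[2:4])
    lines = text.splitlines()
    assert len(lines) == 1 + 2 * 2          # header + (value, se) per row
    assert "(" in lines[2]


def test_generator_family_distances_near_truth(core_alignment,
                                               default_family):
    """Recovered within-letter distances should sit within 2 analytic SEs
    of the configured within-letter expectation."""
    rate = default_family.config.within_letter_rate
    expected = rate * (1 - 8 / 78)
    prot_rows = {}
    truth = {}
    for rec in default_family.records:
        for t in default_family.truth_domains.for_protein(rec.id):
            truth[f"{rec.id}|{t['domain_index']}"] = t["letter"]
    ref_rows = [(l, s) for l, s in core_alignment.rows
                if l.startswith("Ref")]
    by_letter = {}
    for lab, s in core_alignment.rows:
        if lab in truth:
            by_letter.setdefault(truth[lab], []).append(s)
    checked = 0
    for letter, rows in by_letter.items():
        for a, b in itertools.combinations(rows[:3], 2):
            p, L = p_distance(a, b)
            # two independent copies: expected pairwise ~ 2*rate*(1-8/78)
            e = 2 * expected * (1 - expected / 2)
            assert abs(p - e) <= 2.5 * analytic_se(max(e, 0.05), L) + 0.02
            checked += 1
    assert checked >= 10
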