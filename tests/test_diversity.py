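import numpy as np
import pytest
from hypothesis import given, strategies as st

from resurvey import diversity as dv
from resurvey import errors

from conftest import make_cover, make_pair


# ---- independent brute-force oracles (plain loops, no shared code paths) --

def mh_brute(p, q):
    num = 0.0
    sp = 0.0
    sq = 0.0
    for a, b in zip(p, q):
        num += a * b
        sp += a * a
        sq += b * b
    return 2.0 * num / (sp + sq)


def hill2_brute(p):
    s = 0.0
    for a in p:
        s += a * a
    return 1.0 / s


def multi_turnover_brute(rel_rows):
    n = len(rel_rows)
    S = len(rel_rows[0])
    pooled = [sum(row[j] for row in rel_rows) / n for j in range(S)]
    d_gamma = hill2_brute(pooled)
    d_alpha = 1.0 / (sum(sum(a * a for a in row) for row in rel_rows) / n)
    d_beta = d_gamma / d_alpha
    overlap = (1.0 / d_beta - 1.0 / n) / (1.0 - 1.0 / n)
    return 1.0 - overlap


# ---- relative abundance ---------------------------------------------------

def test_relative_abundance():
    np.testing.assert_allclose(dv.relative_abundance([50, 50]), [0.5, 0.5])
    np.testing.assert_allclose(
        dv.relative_abundance([30, 10, 0]), [0.75, 0.25, 0.0]
    )
    with pytest.raises(errors.EmptyCommunityError):
        dv.relative_abundance([0.0, 0.0])


# ---- Morisita-Horn --------------------------------------------------------

@pytest.mark.parametrize(
    "p,q,expected",
    [
        ([0.5, 0.5], [0.5, 0.5], 1.0),
        ([1.0, 0.0], [0.0, 1.0], 0.0),
        ([0.5, 0.5], [1.0, 0.0], 2 * 0.5 / 1.5),
    ],
)
def test_morisita_horn_examples(p, q, expected):
    assert dv.morisita_horn(p, q) == pytest.approx(expected, abs=1e-12)


def test_morisita_horn_length_mismatch():
    with pytest.raises(errors.ValidationError):
        dv.morisita_horn([0.5, 0.5], [1.0])


@given(
    st.lists(st.floats(0.01, 100), min_size=2, max_size=8),
    st.lists(st.floats(0.01, 100), min_size=2, max_size=8),
    st.floats(0.01, 50),
)
def test_morisita_horn_symmetric_scale_free_zero_invariant(cp, cq, k):
    m = max(len(cp), len(cq))
    cp = np.resize(np.asarray(cp), m)
    cq = np.resize(np.asarray(cq), m)
    p = dv.relative_abundance(cp)
    q = dv.relative_abundance(cq)
    s = dv.morisita_horn(p, q)
    assert s == pytest.approx(dv.morisita_horn(q, p), abs=1e-12)
    # scale-free: computing from raw covers and k*covers is identical
    assert dv.morisita_horn(
        dv.relative_abundance(k * cp), dv.relative_abundance(cq)
    ) == pytest.approx(s, abs=1e-12)
    # adding an all-zero species column changes nothing
    assert dv.morisita_horn(
        np.append(p, 0.0), np.append(q, 0.0)
    ) == pytest.approx(s, abs=1e-12)


# ---- Hill-Simpson ---------------------------------------------------------

def test_hill_simpson_examples():
    assert dv.hill_simpson([0.1] * 10) == pytest.approx(10.0, abs=1e-12)
    assert dv.hill_simpson([0.5, 0.5]) == pytest.approx(2.0, abs=1e-12)
    assert dv.hill_simpson([0.8, 0.2]) == pytest.approx(1 / 0.68, abs=1e-9)


@given(st.lists(st.floats(0.01, 100), min_size=2, max_size=10), st.randoms())
def test_hill_simpson_permutation_invariant_and_bounded(c, rnd):
    p = dv.relative_abundance(np.asarray(c))
    d = dv.hill_simpson(p)
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    assert dv.hill_simpson(p[perm]) == pytest.approx(d, abs=1e-12)
    assert 1.0 - 1e-9 <= d <= len(p) + 1e-9


def test_hill_simpson_decreases_under_concentration():
    # moving mass from a rarer to a more abundant species concentrates
    assert dv.hill_simpson([0.6, 0.4]) > dv.hill_simpson([0.7, 0.3])
    assert dv.hill_simpson([0.4, 0.3, 0.3]) > dv.hill_simpson([0.6, 0.2, 0.2])


# ---- pairwise turnover ----------------------------------------------------

def test_pairwise_turnover_extremes():
    ps = make_pair([[10.0, 5.0], [1.0, 9.0]], [[10.0, 5.0], [1.0, 9.0]])
    assert dv.pairwise_turnover(ps)["d"].abs().max() < 1e-12
    ps = make_pair([[10.0, 0.0], [8.0, 0.0]], [[0.0, 5.0], [0.0, 9.0]])
    np.testing.assert_allclose(dv.pairwise_turnover(ps)["d"], 1.0)


def test_pairwise_turnover_matches_brute_force():
    rng = np.random.default_rng(42)
    old = rng.uniform(0, 20, size=(6, 5))
    new = 0.6 * old + 0.4 * rng.uniform(0, 20, size=(6, 5))
    ps = make_pair(old, new)
    table = dv.pairwise_turnover(ps)
    for i, d in enumerate(table["d"]):
        p = old[i] / old[i].sum()
        q = new[i] / new[i].sum()
        assert d == pytest.approx(1.0 - mh_brute(p, q), abs=1e-12)


def test_pairwise_turnover_carries_metadata():
    ps = make_pair([[1.0, 2.0]], [[2.0, 1.0]], subregion="NBn",
                   year_old=1958, year_new=2014)
    row = dv.pairwise_turnover(ps).iloc[0]
    assert row["subregion"] == "NBn"
    assert row["sampling_time"] == 56


# ---- multiple-assemblage turnover ----------------------------------------

def test_multi_assemblage_examples():
    identical = np.tile([5.0, 3.0, 2.0], (3, 1))
    assert dv.multi_assemblage_turnover(identical) == pytest.approx(0.0, abs=1e-12)
    disjoint = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert dv.multi_assemblage_turnover(disjoint) == pytest.approx(1.0, abs=1e-12)
    two = np.array([[1.0, 0.0], [0.5, 0.5]])
    assert dv.multi_assemblage_turnover(two) == pytest.approx(1 / 3, abs=1e-9)


@pytest.mark.parametrize("n", range(2, 11))
def test_multi_assemblage_identical_copies_zero(n):
    plots = np.tile([7.0, 2.0, 1.0], (n, 1))
    assert dv.multi_assemblage_turnover(plots) == pytest.approx(0.0, abs=1e-12)


def test_multi_assemblage_single_plot_undefined():
    with pytest.raises(errors.UndefinedError):
        dv.multi_assemblage_turnover(np.array([[1.0, 2.0]]))


def test_multi_assemblage_matches_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(50):
        covers = rng.uniform(0.01, 10, size=(rng.integers(2, 6), rng.integers(2, 7)))
        rel = [list(row / row.sum()) for row in covers]
        assert dv.multi_assemblage_turnover(covers) == pytest.approx(
            multi_turnover_brute(rel), abs=1e-12
        )


def test_two_plot_extremes_agree_with_pairwise():
    identical = np.array([[3.0, 1.0], [3.0, 1.0]])
    disjoint = np.array([[3.0, 0.0], [0.0, 1.0]])
    for covers, target in ((identical, 0.0), (disjoint, 1.0)):
        p = covers[0] / covers[0].sum()
        q = covers[1] / covers[1].sum()
        assert dv.multi_assemblage_turnover(covers) == pytest.approx(target, abs=1e-12)
        assert 1 - dv.morisita_horn(p, q) == pytest.approx(target, abs=1e-12)


# ---- bootstrap SE ---------------------------------------------------------

def test_bootstrap_se_identical_plots_zero():
    plots = np.tile([5.0, 5.0], (4, 1))
    assert dv.bootstrap_se_beta(plots, reps=100, seed=0) == 0.0


def test_bootstrap_se_deterministic():
    rng = np.random.default_rng(3)
    covers = rng.uniform(0.1, 10, size=(5, 4))
    a = dv.bootstrap_se_beta(covers, reps=200, seed=11)
    b = dv.bootstrap_se_beta(covers, reps=200, seed=11)
    assert a == b > 0


def test_bootstrap_se_shrinks_with_homogeneity():
    """SE trends downward as between-plot heterogeneity shrinks."""
    rng = np.random.default_rng(5)
    base = rng.uniform(1, 10, size=6)
    ses = []
    for spread in (2.0, 0.5, 0.05):
        covers = np.abs(base + rng.normal(0, spread, size=(6, 6)))
        ses.append(dv.bootstrap_se_beta(covers, reps=300, seed=1))
    assert ses[2] < ses[0]


# ---- beta change ----------------------------------------------------------

def test_delta_beta_arithmetic():
    assert dv.delta_beta(0.198, 0.283) == pytest.approx(0.085)
    assert dv.delta_beta(0.078, 0.131) == pytest.approx(0.053)
    assert dv.delta_beta(0.5, 0.5) == 0.0
    with pytest.raises(errors.ValidationError):
        dv.delta_beta(-0.1, 0.5)


def test_beta_change_no_change_is_zero():
    covers = np.array([[5.0, 1.0, 0.5], [2.0, 3.0, 1.0], [1.0, 1.0, 4.0]])
    ps = make_pair(covers, covers)
    out = dv.beta_change(ps, bootstrap_reps=50, seed=0)
    assert out["delta_beta"].abs().max() < 1e-12
    assert set(out.columns) >= {
        "site", "beta_old", "se_old", "beta_new", "se_new", "delta_beta"
    }
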