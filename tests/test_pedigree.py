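import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lynxrescue.pedigree import Pedigree, PedigreeError, read_pedigree, write_pedigree
from lynxrescue.synthetic import generate_test_pedigree


def gene_drop_inbreeding(ped: Pedigree, ids, n_drops: int, rng) -> dict:
    """Monte-Carlo oracle: drop founder alleles through the pedigree and
    estimate F as the fraction of drops where an individual's two alleles
    are copies of the same founder allele.  Founder baselines and declared
    founder kinships must be zero (plain founders only)."""
    order = sorted(ped.members, key=ped._depth)
    alleles = {}
    for k, i in enumerate(order):
        s, d = ped.parents[i]
        if ped.is_founder(i):
            a = np.full(n_drops, 2 * k)
            b = np.full(n_drops, 2 * k + 1)
        else:
            pa = alleles[s]
            pb = alleles[d]
            a = np.where(rng.integers(0, 2, n_drops) == 0, pa[0], pa[1])
            b = np.where(rng.integers(0, 2, n_drops) == 0, pb[0], pb[1])
        alleles[i] = (a, b)
    return {i: float(np.mean(alleles[i][0] == alleles[i][1])) for i in ids}


@pytest.mark.parametrize(
    "pattern, expected",
    [("full-sib", 0.25), ("parent-offspring", 0.25), ("cousins", 0.0625)],
)
def test_classical_inbreeding_values(pattern, expected):
    ped, exp = generate_test_pedigree(pattern)
    (target, value), = exp.items()
    assert value == expected
    assert ped.inbreeding_coefficient(target) == pytest.approx(expected)


def test_kinship_classics():
    ped = Pedigree()
    ped.add_founder(1), ped.add_founder(2)
    ped.add_member(3, 1, 2)
    assert ped.kinship(1, 2) == 0.0  # unrelated founders
    assert ped.kinship(1, 3) == 0.25  # parent-offspring
    assert ped.kinship(3, 3) == 0.5  # outbred self-kinship


def test_founder_baseline_inbreeding():
    ped = Pedigree()
    ped.add_founder(1, founder_f=0.3)
    ped.add_founder(2)
    assert ped.inbreeding_coefficient(1) == 0.3
    assert ped.kinship(1, 1) == pytest.approx(0.65)  # (1 + 0.3)/2


def test_declared_founder_kinship_equals_explicit_ancestry():
    """Declaring kinship 0.25 between two founders is equivalent to making
    them full sibs of explicit (phantom) unrelated parents."""
    shortcut = Pedigree()
    shortcut.add_founder(10), shortcut.add_founder(11)
    shortcut.declare_founder_kinship(10, 11, 0.25)
    shortcut.add_member(12, 10, 11)

    explicit = Pedigree()
    explicit.add_founder(1), explicit.add_founder(2)
    explicit.add_member(10, 1, 2), explicit.add_member(11, 1, 2)
    explicit.add_member(12, 10, 11)

    assert shortcut.kinship(10, 11) == explicit.kinship(10, 11) == 0.25
    assert shortcut.inbreeding_coefficient(12) == explicit.inbreeding_coefficient(12)


def test_gene_dropping_agreement_on_random_pedigree(rng):
    """Tabular kinship vs the gene-dropping Monte-Carlo oracle on a random
    30-member pedigree: |F_tab - F_mc| < 0.01 at 1e5 drops."""
    ped, _ = generate_test_pedigree("random", seed=5, n=30)
    mc = gene_drop_inbreeding(ped, ped.members, n_drops=100_000, rng=rng)
    for i in ped.members:
        assert ped.inbreeding_coefficient(i) == pytest.approx(mc[i], abs=0.01)


def test_inbreeding_accumulates_in_closed_line():
    """Repeated full-sib matings: F follows the classic recurrence
    F_t = 1/4 (1 + 2 F_{t-1} + F_{t-2}), monotonically increasing."""
    ped = Pedigree()
    ped.add_founder(1), ped.add_founder(2)
    sire, dam = 1, 2
    nxt = 3
    values = []
    for _ in range(6):
        a, b = nxt, nxt + 1
        ped.add_member(a, sire, dam)
        ped.add_member(b, sire, dam)
        values.append(ped.inbreeding_coefficient(a))
        sire, dam, nxt = a, b, nxt + 2
    assert values[0] == 0.0
    assert all(x < y for x, y in zip(values, values[1:]))
    f1, f2 = 0.0, 0.0
    for v in values[1:]:
        f1, f2 = 0.25 * (1 + 2 * f1 + f2), f1
        assert v == pytest.approx(f1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_kinship_symmetric_and_bounded(seed):
    ped, _ = generate_test_pedigree("random", seed=seed, n=18)
    rng = np.random.default_rng(seed)
    ids = rng.choice(ped.members, size=4, replace=False)
    for i in ids:
        for j in ids:
            k = ped.kinship(int(i), int(j))
            assert k == ped.kinship(int(j), int(i))
            assert 0.0 <= k <= 1.0


def test_cycle_rejected():
    ped = Pedigree()
    ped.add_founder(1), ped.add_founder(2)
    ped.add_member(3, 1, 2)
    ped.parents[1] = (3, 2)  # corrupt: 1 becomes its own descendant
    with pytest.raises(PedigreeError, match="cycle"):
        ped.validate()


def test_unknown_id_errors():
    ped = Pedigree()
    ped.add_founder(1)
    with pytest.raises(PedigreeError, match="unknown"):
        ped.kinship(1, 99)
    with pytest.raises(PedigreeError, match="not in pedigree"):
        ped.add_member(5, 1, 42)


def test_pedigree_csv_round_trip(tmp_path):
    ped, _ = generate_test_pedigree("cousins")
    ped.founder_f[1] = 0.2
    path = tmp_path / "ped.csv"
    write_pedigree(ped, path)
    back = read_pedigree(path)
    assert set(back.members) == set(ped.members)
    for i in ped.members:
        assert back.inbreeding_coefficient(i) == pytest.approx(
            ped.inbreeding_coefficient(i)
        )
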