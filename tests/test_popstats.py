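"""Summary statistics against independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import integrate

from nbselect.errors import InputError
from nbselect.popstats import (
    TailSpec,
    chi_square_enrichment,
    empirical_tail,
    hudson_fst,
    nucleotide_diversity,
    tajimas_d,
    watterson_theta,
    windowed_stats,
)
from nbselect.genome_io import GeneModel

from conftest import make_panel, random_panel


# ---------------------------------------------------------------------------
# oracles (independent implementations)


def pi_oracle(calls: np.ndarray, length: int) -> float:
    """All-pairs Hamming mean with per-site pairwise deletion."""
    n, s = calls.shape
    skipped = 0
    total = 0.0
    for j in range(s):
        col = calls[:, j]
        present = [c for c in col if c != -1]
        if len(present) < 2:
            skipped += 1
            continue
        diffs = pairs = 0
        for a, b in itertools.combinations(present, 2):
            pairs += 1
            diffs += a != b
        total += diffs / pairs
    eff = length - skipped
    return total / eff if eff > 0 else math.nan


def tajima_d_oracle(calls: np.ndarray) -> float:
    """Independent implementation of the 1989 variance constants."""
    n = calls.shape[0]
    if n < 4:
        return math.nan
    s = 0
    pi_total = 0.0
    for j in range(calls.shape[1]):
        col = [c for c in calls[:, j] if c != -1]
        if len(col) < 2:
            continue
        k1 = sum(col)
        m = len(col)
        if 0 < k1 < m:
            s += 1
            pi_total += k1 * (m - k1) / (m * (m - 1) / 2)
    if s == 0:
        return math.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_total - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def fst_oracle(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Hudson 1 - Hw/Hb from explicit pair loops."""
    hw = hb = 0.0
    any_site = False
    for j in range(calls_a.shape[1]):
        ca = [c for c in calls_a[:, j] if c != -1]
        cb = [c for c in calls_b[:, j] if c != -1]
        if len(ca) < 2 or len(cb) < 2:
            continue
        any_site = True
        wa = np.mean([x != y for x, y in itertools.combinations(ca, 2)])
        wb = np.mean([x != y for x, y in itertools.combinations(cb, 2)])
        hb_site = np.mean([x != y for x in ca for y in cb])
        hw += 0.5 * (wa + wb)
        hb += hb_site
    if not any_site:
        return math.nan
    return 1.0 - hw / hb if hb > 0 else 0.0


# ---------------------------------------------------------------------------
# forced examples


def test_diversity_forced_cases():
    # two haplotypes, one difference over 100 accessible sites
    p = make_panel([[0], [1]], ["wild_weedy"] * 2)
    assert nucleotide_diversity(p, "wild_weedy", 100) == pytest.approx(0.01)
    # identical haplotypes
    p = make_panel([[0], [0], [0]], ["wild_weedy"] * 3)
    assert nucleotide_diversity(p, "wild_weedy", 100) == 0.0
    # n=4, allele counts 2/2 at one site, L=1 -> 4/6
    p = make_panel([[0], [0], [1], [1]], ["wild_weedy"] * 4)
    assert nucleotide_diversity(p, "wild_weedy", 1) == pytest.approx(4 / 6)


def test_diversity_requires_two_samples():
    p = make_panel([[0], [1]], ["wild_weedy", "landrace"])
    with pytest.raises(InputError):
        nucleotide_diversity(p, "wild_weedy", 10)


def test_watterson_forced_cases():
    assert watterson_theta(0, 5, 100) == 0.0
    assert watterson_theta(3, 2, 100) == pytest.approx(0.03)
    assert watterson_theta(11, 4, 1000) == pytest.approx(0.006)
    with pytest.raises(InputError):
        watterson_theta(1, 1, 100)


def test_tajimas_d_sign_and_undefined(rng):
    # no segregating sites -> undefined
    p = make_panel(np.zeros((10, 3)), ["wild_weedy"] * 10)
    assert math.isnan(tajimas_d(p, "wild_weedy"))
    # all singletons -> negative
    calls = np.zeros((10, 8), dtype=int)
    for j in range(8):
        calls[j % 10, j] = 1
    p = make_panel(calls, ["wild_weedy"] * 10)
    assert tajimas_d(p, "wild_weedy") < 0
    # all variants at frequency 5/10 -> positive
    calls = np.zeros((10, 8), dtype=int)
    calls[:5, :] = 1
    p = make_panel(calls, ["wild_weedy"] * 10)
    assert tajimas_d(p, "wild_weedy") > 0


def test_fst_forced_cases():
    # identical allele frequencies -> ~0 (exactly 0 up to the unbiased
    # within-group correction, which vanishes with sample size)
    n = 40
    groups = ["wild_weedy"] * n + ["landrace"] * n
    calls = np.array([[0, 1]] * (n // 2) + [[1, 0]] * (n // 2), dtype=int)
    p = make_panel(np.vstack([calls, calls]), groups)
    assert abs(hudson_fst(p, "wild_weedy", "landrace")) < 0.03
    # fixed difference -> 1
    groups4 = ["wild_weedy"] * 4 + ["landrace"] * 4
    p = make_panel(np.array([[0]] * 4 + [[1]] * 4), groups4)
    assert hudson_fst(p, "wild_weedy", "landrace") == pytest.approx(1.0)
    # FST = 1 iff zero within-group diversity with between-group diversity
    p = make_panel(np.array([[0], [1]] * 2 + [[1]] * 4), groups4)
    assert hudson_fst(p, "wild_weedy", "landrace") < 1.0


def test_fst_bounds_random(rng):
    groups = ["wild_weedy"] * 5 + ["landrace"] * 5
    for _ in range(200):
        p = random_panel(rng, 10, int(rng.integers(1, 20)), groups, missing_rate=0.1)
        fst = hudson_fst(p, "wild_weedy", "landrace")
        if math.isnan(fst):
            continue
        assert -0.5 <= fst <= 1.0


# ---------------------------------------------------------------------------
# oracle equivalence suite


def test_estimators_match_oracles(rng):
    """theta_pi, D and FST agree with brute-force oracles on random panels."""
    groups5 = ["wild_weedy"] * 5 + ["landrace"] * 5
    for rep in range(500):
        n = int(rng.integers(4, 11))
        s = int(rng.integers(1, 25))
        length = int(rng.integers(s * 10, 1001))
        panel = random_panel(rng, n, s, ["wild_weedy"] * n, missing_rate=0.1)
        pi = nucleotide_diversity(panel, "wild_weedy", length)
        expected = pi_oracle(panel.calls, length)
        assert pi == pytest.approx(expected, abs=1e-10) or (
            math.isnan(pi) and math.isnan(expected)
        )
        d = tajimas_d(panel, "wild_weedy")
        d_exp = tajima_d_oracle(panel.calls)
        assert d == pytest.approx(d_exp, abs=1e-10) or (
            math.isnan(d) and math.isnan(d_exp)
        )
        if rep % 2 == 0:
            p2 = random_panel(rng, 10, s, groups5, missing_rate=0.1)
            fst = hudson_fst(p2, "wild_weedy", "landrace")
            f_exp = fst_oracle(p2.calls[:5], p2.calls[5:])
            assert fst == pytest.approx(f_exp, abs=1e-10) or (
                math.isnan(fst) and math.isnan(f_exp)
            )


# ---------------------------------------------------------------------------
# empirical tails


def test_tail_forced_rank():
    values = {f"g{i}": float(i) for i in range(1, 101)}
    up = empirical_tail(values, TailSpec("x", "upper", 0.05))
    assert up == {f"g{i}" for i in range(96, 101)}
    # all equal -> nothing strictly beyond the threshold
    same = {f"g{i}": 1.0 for i in range(50)}
    assert empirical_tail(same, TailSpec("x", "upper", 0.05)) == set()
    with pytest.raises(InputError):
        empirical_tail({f"g{i}": float(i) for i in range(10)}, TailSpec("x", "upper", 0.05))


def test_tail_matches_sort_oracle(rng):
    for _ in range(300):
        n = int(rng.integers(20, 120))
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.integers(0, 30, size=n))}
        frac = float(rng.choice([0.05, 0.1, 0.25]))
        side = str(rng.choice(["upper", "lower"]))
        got = empirical_tail(vals, TailSpec("x", side, frac))
        arr = sorted(vals.values())
        if side == "upper":
            thr = arr[math.ceil((1 - frac) * n) - 1]
            exp = {g for g, v in vals.items() if v > thr}
        else:
            thr = arr[math.ceil(frac * n) - 1]
            exp = {g for g, v in vals.items() if v < thr}
        assert got == exp
        assert len(got) <= math.ceil(frac * n)


def test_tail_excludes_undefined(rng):
    vals = {f"g{i}": float(i) for i in range(40)}
    vals["bad"] = math.nan
    got = empirical_tail(vals, TailSpec("x", "upper", 0.25))
    assert "bad" not in got


# ---------------------------------------------------------------------------
# chi-square


def test_chi2_forced_cases():
    chi2, p = chi_square_enrichment(50, 50, 50, 50)
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    chi2, p = chi_square_enrichment(30, 10, 10, 30)
    assert chi2 == pytest.approx(20.0)


def test_chi2_zero_expected_undefined():
    with pytest.warns(UserWarning):
        chi2, p = chi_square_enrichment(0, 0, 5, 5)
    assert math.isnan(chi2) and math.isnan(p)


def test_chi2_p_matches_quadrature(rng):
    """p-value equals numerical integration of the chi2(1) density."""

    def density(x):
        return math.exp(-x / 2.0) / math.sqrt(2.0 * math.pi * x)

    for _ in range(40):
        table = rng.integers(1, 60, size=4)
        chi2, p = chi_square_enrichment(*table)
        if chi2 == 0 or chi2 > 40:  # quadrature loses precision in the far tail
            continue
        val, err = integrate.quad(density, chi2, np.inf)
        assert p == pytest.approx(val, rel=1e-4, abs=2 * err)


# ---------------------------------------------------------------------------
# windowed scans


def _gene(gid, chrom, start, end):
    return GeneModel(gid, chrom, "+", start, end, [(start, start + 3)])


def test_window_truncated_at_chromosome_start():
    panel = random_panel(np.random.default_rng(0), 6, 10)
    gene = _gene("g1", "chr01", 2, 30)
    gs, _ = windowed_stats(
        {"chr01": panel}, [gene], "flanking_100kb", groups=("wild_weedy",)
    )
    # left flank truncated to [0, 2): window length 2 + right flank
    assert gs[0].n_sites == 2 + 100_000


def test_pad_window_rescales_gene_stats(rng):
    panel = random_panel(rng, 8, 12)
    start, end = 0, int(panel.positions[-1]) + 1
    gene = GeneModel("g1", "chr01", "+", start, end, [(start, start + 3)])
    g_span, _ = windowed_stats({"chr01": panel}, [gene], "gene_span", groups=("wild_weedy",))
    g_pad, _ = windowed_stats({"chr01": panel}, [gene], "gene_pad10kb", groups=("wild_weedy",))
    # no variants in the pad: S identical, theta scales with window length
    assert g_pad[0].s == g_span[0].s
    ratio = g_span[0].n_sites / g_pad[0].n_sites
    assert g_pad[0].theta_pi == pytest.approx(g_span[0].theta_pi * ratio, rel=1e-9)


def test_windowed_s_matches_direct_count(rng):
    panel = random_panel(rng, 6, 40)
    genes = [
        _gene("g1", "chr01", 0, 100),
        _gene("g2", "chr01", 100, 250),
        _gene("g3", "chr01", 250, 500),
    ]
    gs, _ = windowed_stats({"chr01": panel}, genes, "gene_span", groups=("wild_weedy",))
    for st, gene in zip(gs, genes):
        cols = [
            j
            for j, p in enumerate(panel.positions)
            if gene.start <= p < gene.end
        ]
        direct = 0
        for j in cols:
            col = panel.calls[:, j]
            k = (col == 1).sum()
            m = (col != -1).sum()
            if 0 < k < m:
                direct += 1
        assert st.s == direct
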