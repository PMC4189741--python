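"""Codon-level analyses against translation / pathway / rule oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from nbselect.coding_effects import (
    annotate_variant_effect,
    call_pseudogene,
    count_protein_variants,
    fourfold_tv,
    FunctionalStatus,
    functional_statuses,
    gene_loss_from_depth,
    ng86_kaks,
    nonfunctional_frequency,
    presence_absence_profile,
)
from nbselect.errors import InputError
from nbselect.genome_io import GeneModel, revcomp

from conftest import make_panel

STOPS = {"TAA", "TAG", "TGA"}
SENSE = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOPS
]


def _gene_plus(region_len=60, cds=(10, 40)):
    return GeneModel("g", "chr01", "+", 0, region_len, [cds])


def _region_with_cds(cds_seq, cds_start=10, region_len=None, rng=None):
    rng = rng or np.random.default_rng(0)
    region_len = region_len or cds_start + len(cds_seq) + 10
    region = list(rng.choice(list("ACGT"), size=region_len))
    region[cds_start : cds_start + len(cds_seq)] = list(cds_seq)
    return "".join(region)


def test_effect_forced_classes():
    cds = "ATG" + "CAA" + "TTT" + "TAA"  # M Q F *
    region = _region_with_cds(cds)
    gene = GeneModel("g", "c", "+", 0, len(region), [(10, 10 + 12)])
    # CAA -> TAA mid-CDS: premature stop
    eff = annotate_variant_effect(gene, 13, "C", "T", region)
    assert eff.effect == "premature_stop" and eff.large_effect
    # ATG -> ATA at codon 1: start loss
    eff = annotate_variant_effect(gene, 12, "G", "A", region)
    assert eff.effect == "start_loss"
    # TAA -> CAA at terminal stop: stop loss
    eff = annotate_variant_effect(gene, 19, "T", "C", region)
    assert eff.effect == "stop_loss"
    # 2-bp deletion inside CDS: frameshift
    eff = annotate_variant_effect(gene, 14, region[14:17], region[14], region)
    assert eff.effect == "frameshift" and eff.large_effect
    # outside the CDS: noncoding
    eff = annotate_variant_effect(gene, 2, region[2], "A" if region[2] != "A" else "C", region)
    assert eff.effect == "noncoding"


def test_splice_site_positions():
    cds = [(10, 22), (30, 45)]  # intron = [22, 30)
    region = _region_with_cds("ATG" + "AAA" * 8 + "TAA", cds_start=10, region_len=60)
    gene = GeneModel("g", "c", "+", 0, 60, cds)
    for pos in (22, 23, 28, 29):
        eff = annotate_variant_effect(gene, pos, region[pos], "A" if region[pos] != "A" else "C", region)
        assert eff.effect == "splice_site", pos
    eff = annotate_variant_effect(gene, 25, region[25], "A" if region[25] != "A" else "C", region)
    assert eff.effect == "noncoding"


def test_effect_matches_translation_oracle(rng):
    """syn/nonsyn labels agree with a translate-and-compare oracle."""
    for _ in range(150):
        n_codons = int(rng.integers(4, 20))
        cds = "ATG" + "".join(rng.choice(SENSE) for _ in range(n_codons)) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        cds_start = 7
        if strand == "+":
            region = _region_with_cds(cds, cds_start, rng=rng)
        else:
            region = _region_with_cds(revcomp(cds), cds_start, rng=rng)
        gene = GeneModel(
            "g", "c", strand, 0, len(region), [(cds_start, cds_start + len(cds))]
        )
        # mutate an internal codon position
        i = int(rng.integers(3, len(cds) - 3))
        pos_genomic = (
            cds_start + i if strand == "+" else cds_start + len(cds) - 1 - i
        )
        ref = region[pos_genomic]
        alt = str(rng.choice([n for n in "ACGT" if n != ref]))
        eff = annotate_variant_effect(gene, pos_genomic, ref, alt, region)
        alt_base = alt if strand == "+" else revcomp(alt)
        mutated = cds[:i] + alt_base + cds[i + 1 :]
        p_ref = str(Seq(cds).translate())
        p_alt = str(Seq(mutated).translate())
        if eff.effect == "synonymous":
            assert p_ref == p_alt
        elif eff.effect == "nonsynonymous":
            assert p_ref != p_alt and "*" not in p_alt[:-1]
        elif eff.effect == "premature_stop":
            # alternate protein is a strict truncated prefix
            trunc = p_alt.split("*")[0]
            assert p_ref.startswith(trunc) and len(trunc) < len(p_ref) - 1


def test_protein_variant_counts(rng):
    cds = "ATGAAACCCGGGTAA"
    region = _region_with_cds(cds, 0, region_len=20, rng=rng)
    gene = GeneModel("g", "chr01", "+", 0, 20, [(0, 15)])
    groups = ["wild_weedy"] * 4
    # no variants -> 1 protein
    panel = make_panel(np.zeros((4, 0)), groups, positions=np.array([], dtype=int))
    assert count_protein_variants(gene, panel, region) == 1
    # one nonsynonymous SNP segregating -> 2
    panel = make_panel(np.array([[0], [0], [1], [1]]), groups, positions=np.array([4]))
    panel.ref[0], panel.alt[0] = region[4], "T"  # AAA -> ATA (K -> I)
    assert count_protein_variants(gene, panel, region) == 2
    # a synonymous SNP does not add a protein variant
    panel = make_panel(np.array([[0], [0], [1], [1]]), groups, positions=np.array([5]))
    panel.ref[0], panel.alt[0] = region[5], "G"  # AAA -> AAG (K)
    assert count_protein_variants(gene, panel, region) == 1


def test_protein_variants_match_translation_set_oracle(rng):
    for _ in range(40):
        n_codons = int(rng.integers(3, 8))
        cds = "ATG" + "".join(rng.choice(SENSE) for _ in range(n_codons)) + "TAA"
        region = cds
        gene = GeneModel("g", "chr01", "+", 0, len(cds), [(0, len(cds))])
        n, s = 6, int(rng.integers(1, 4))
        pos = np.sort(rng.choice(np.arange(3, len(cds) - 3), size=s, replace=False))
        calls = rng.integers(0, 2, size=(n, s))
        panel = make_panel(calls, ["wild_weedy"] * n, positions=pos)
        alts = []
        for p in pos:
            alts.append(str(rng.choice([c for c in "ACGT" if c != cds[p]])))
        panel.ref[:] = [cds[p] for p in pos]
        panel.alt[:] = alts
        got = count_protein_variants(gene, panel, region)
        proteins = set()
        for i in range(n):
            hap = list(cds)
            ok = True
            for j, p in enumerate(pos):
                if calls[i, j] == 1:
                    hap[p] = alts[j]
            proteins.add(str(Seq("".join(hap)).translate()))
        assert got == len(proteins)


# ---------------------------------------------------------------------------
# NG86


def test_ng86_forced_cases():
    ident = "ATGAAACCCTAA"
    rec = ng86_kaks(ident, ident)
    assert rec.ka == 0.0 and rec.ks == 0.0 and math.isnan(rec.ratio)
    # a Phe codon TTT vs TTC difference is forced synonymous
    rec = ng86_kaks("ATGTTTAAACCC", "ATGTTCAAACCC")
    assert rec.ka == 0.0 and rec.ks > 0.0
    # on a single saturated codon the Jukes-Cantor correction is undefined
    rec = ng86_kaks("TTT", "TTC")
    assert math.isnan(rec.ks)
    with pytest.raises(InputError):
        ng86_kaks("ATG", "ATGAAA")
    with pytest.raises(InputError):
        ng86_kaks("ATGTAAAAA", "ATGTAAAAA")  # internal stop


def test_ng86_two_difference_pathway_oracle(rng):
    """Counts equal the mean over the two substitution orderings."""

    def aa(codon):
        return str(Seq(codon).translate())

    checked = 0
    for ca in SENSE:
        for cb in SENSE:
            diffs = [i for i in range(3) if ca[i] != cb[i]]
            if len(diffs) != 2:
                continue
            if checked % 17 != 0:  # subsample the ~3k pairs
                checked += 1
                continue
            checked += 1
            paths = []
            for order in itertools.permutations(diffs):
                cur, sd, nd, blocked = ca, 0, 0, False
                for p in order:
                    nxt = cur[:p] + cb[p] + cur[p + 1 :]
                    if aa(nxt) == "*":
                        blocked = True
                    if aa(nxt) == aa(cur):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                paths.append((sd, nd, blocked))
            open_paths = [p for p in paths if not p[2]] or paths
            exp_sd = sum(p[0] for p in open_paths) / len(open_paths)
            exp_nd = sum(p[1] for p in open_paths) / len(open_paths)
            rec = ng86_kaks(ca, cb)
            # recover the raw counts from pS = Sd/S via the site counts
            from nbselect.coding_effects import _codon_sites, _pathway_counts

            sd_got, nd_got = _pathway_counts(ca, cb)
            assert sd_got == pytest.approx(exp_sd)
            assert nd_got == pytest.approx(exp_nd)


def simulate_neutral_pair(rng, n_codons=500, n_mut=40):
    """Two sequences diverged by mutations uniform over the non-stop space."""
    cds = ["ATG"] + [str(rng.choice(SENSE)) for _ in range(n_codons - 2)] + ["TAA"]
    seqs = []
    for _ in range(2):
        seq = list("".join(cds))
        applied = 0
        while applied < n_mut:
            p = int(rng.integers(3, len(seq) - 3))
            old = seq[p]
            alts = []
            for nt in "ACGT":
                if nt == old:
                    continue
                seq[p] = nt
                codon = "".join(seq[p - p % 3 : p - p % 3 + 3])
                seq[p] = old
                if codon not in STOPS:
                    alts.append(nt)
            if not alts:
                continue
            seq[p] = str(rng.choice(alts))
            applied += 1
        seqs.append("".join(seq))
    return seqs


def test_ng86_neutral_omega_unbiased(rng):
    """Mean omega within 3 SE of 1 under neutral codon evolution.

    Long, well-diverged pairs keep the Jensen bias of the plug-in ratio
    (order 1/Sd) well below the Monte-Carlo standard error.
    """
    ratios = []
    for _ in range(200):
        a, b = simulate_neutral_pair(rng, n_codons=1500, n_mut=400)
        rec = ng86_kaks(a, b)
        if math.isfinite(rec.ratio):
            ratios.append(rec.ratio)
    mean = float(np.mean(ratios))
    se = float(np.std(ratios, ddof=1) / math.sqrt(len(ratios)))
    assert abs(mean - 1.0) <= 3 * se


def test_ng86_omega_monotone_in_selection(rng):
    """Estimated omega orders with the simulated acceptance ratio."""

    def simulate_with_omega(omega, n_codons=300, n_mut=30):
        cds = ["ATG"] + [str(rng.choice(SENSE)) for _ in range(n_codons - 2)] + ["TAA"]
        seq = list("".join(cds))
        applied = 0
        accept_nonsyn = min(omega, 1.0)
        accept_syn = min(1.0 / omega, 1.0)
        while applied < n_mut:
            p = int(rng.integers(3, len(seq) - 3))
            old = seq[p]
            nt = str(rng.choice([c for c in "ACGT" if c != old]))
            start = p - p % 3
            before = "".join(seq[start : start + 3])
            seq[p] = nt
            after = "".join(seq[start : start + 3])
            if after in STOPS:
                seq[p] = old
                continue
            syn = str(Seq(before).translate()) == str(Seq(after).translate())
            acc = accept_syn if syn else accept_nonsyn
            if rng.random() > acc:
                seq[p] = old
                continue
            applied += 1
        return "".join(cds), "".join(seq)

    means = []
    for omega in (0.2, 1.0, 2.0):
        vals = []
        for _ in range(40):
            a, b = simulate_with_omega(omega)
            rec = ng86_kaks(a, b)
            if math.isfinite(rec.ratio):
                vals.append(rec.ratio)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# 4DTv


def test_fourfold_forced_cases():
    ratio, recent = fourfold_tv("GGG", "GGG")
    assert ratio == 0.0 and recent
    ratio, recent = fourfold_tv("GGA", "GGT")  # A<->T transversion at 4D site
    assert ratio == 1.0 and not recent
    ratio, _ = fourfold_tv("ATG", "ATG")  # no fourfold sites
    assert math.isnan(ratio)


def test_fourfold_matches_degeneracy_oracle(rng):
    def is_fourfold(codon):
        aas = {str(Seq(codon[:2] + nt).translate()) for nt in "ACGT"}
        return len(aas) == 1 and str(Seq(codon).translate()) != "*"

    for _ in range(100):
        n = int(rng.integers(2, 30))
        a = "".join(rng.choice(SENSE) for _ in range(n))
        b = "".join(rng.choice(SENSE) for _ in range(n))
        got, _ = fourfold_tv(a, b)
        got_swap, _ = fourfold_tv(b, a)
        sites = tv = 0
        for i in range(0, 3 * n, 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            if is_fourfold(ca) and is_fourfold(cb):
                sites += 1
                x, y = ca[2], cb[2]
                if x != y and ((x in "AG") != (y in "AG")):
                    tv += 1
        if sites == 0:
            assert math.isnan(got)
        else:
            assert got == pytest.approx(tv / sites)
            assert got_swap == pytest.approx(got)  # symmetric
            assert 0.0 <= got <= 1.0


# ---------------------------------------------------------------------------
# functional statuses / pseudogenes / loss / presence


def test_functional_status_and_pseudogene_rules():
    sts = [
        FunctionalStatus("g", "s1", False, ("frameshift",)),
        FunctionalStatus("g", "s2", True),
    ]
    assert call_pseudogene(sts) is False
    sts = [FunctionalStatus("g", s, False, ("premature_stop",)) for s in ("s1", "s2")]
    assert call_pseudogene(sts) is True
    assert call_pseudogene([]) is None


def test_pseudogene_matches_all_of_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(1, 10))
        flags = rng.random(n) < 0.5
        sts = [
            FunctionalStatus("g", f"s{i}", bool(f), () if f else ("frameshift",))
            for i, f in enumerate(flags)
        ]
        got = call_pseudogene(sts)
        assert got == (not flags.any())
        # permutation invariance
        perm = rng.permutation(n)
        assert call_pseudogene([sts[i] for i in perm]) == got


def test_nonfunctional_frequency_counts(rng):
    groups = {f"s{i}": ("wild_weedy" if i < 3 else "landrace") for i in range(6)}
    sts = [
        FunctionalStatus("g", f"s{i}", i % 2 == 0, () if i % 2 == 0 else ("frameshift",))
        for i in range(6)
    ]
    freqs = nonfunctional_frequency(sts, groups)
    assert freqs["overall"] == pytest.approx(0.5)
    assert freqs["wild_weedy"] == pytest.approx(1 / 3)
    # all functional / all broken
    sts_all = [FunctionalStatus("g", f"s{i}", True) for i in range(6)]
    assert nonfunctional_frequency(sts_all, groups)["overall"] == 0.0


def test_gene_loss_from_depth_rules():
    gene = GeneModel("g", "chr01", "+", 100, 400, [(100, 400)])
    bins = list(range(100, 400, 100))
    rows = []
    for b in bins:
        rows.append(("lost", "chr01", b, 0))
        rows.append(("ok", "chr01", b, 30))
    # exactly 50% low bins stays not-lost (strict >)
    for i, b in enumerate(bins):
        rows.append(("half", "chr01", b, 0 if i == 0 else 30))
    depth = pd.DataFrame(rows, columns=["sample", "chrom", "bin_start", "depth"])
    calls = gene_loss_from_depth(depth, gene)
    assert calls["lost"] == (True, 1.0)
    assert calls["ok"][0] is False
    gene2 = GeneModel("g2", "chr01", "+", 100, 300, [(100, 300)])
    depth2 = depth[depth["bin_start"] < 300]
    half = gene_loss_from_depth(depth2, gene2)["half"]
    assert half == (False, 0.5)  # boundary: exactly half low -> not lost
    with pytest.raises(InputError, match="tile"):
        gene_loss_from_depth(depth.iloc[:2], gene)


def test_functional_statuses_from_panel():
    groups = ["wild_weedy"] * 3
    gene = GeneModel("g", "chr01", "+", 0, 30, [(0, 30)])
    panel = make_panel(np.array([[1], [0], [-1]]), groups, positions=np.array([5]))
    from nbselect.coding_effects import EffectAnnotation

    effects = [EffectAnnotation("g", 5, "A", "T", "premature_stop")]
    sts = functional_statuses(gene, panel, effects, {"s02": 0.9})
    by = {s.sample: s for s in sts}
    assert not by["s00"].functional and "premature_stop" in by["s00"].reasons
    assert by["s01"].functional
    assert not by["s02"].functional and "large_deletion" in by["s02"].reasons


def test_presence_absence_labels(rng):
    groups = {
        "w1": "wild_weedy", "w2": "wild_weedy",
        "l1": "landrace", "i1": "improved", "o1": "outgroup",
    }

    def label(present):
        return presence_absence_profile({s: s in present for s in groups}, groups)

    assert label({"o1"}) == "outgroup_only"
    assert label({"w1", "w2"}) == "wild_only"
    assert label({"w1", "o1"}) == "absent_all_cultivated"
    assert label({"w1", "l1", "i1"}) == "widespread"
    assert label({"l1"}) == "other"
    # rule oracle on random matrices
    for _ in range(200):
        present = {s for s in groups if rng.random() < 0.5}
        got = label(present)
        cult = present & {"l1", "i1"}
        if present == {"o1"}:
            exp = "outgroup_only"
        elif present == {"w1", "w2"} or present == {"w1"} or present == {"w2"}:
            exp = "wild_only"
        elif present and not cult:
            exp = "absent_all_cultivated"
        elif (present & {"w1", "w2"}) and "l1" in present and "i1" in present:
            exp = "widespread"
        elif not present:
            exp = "absent_all_cultivated" if False else got  # empty: no presence at all
        else:
            exp = "other"
        if present:
            assert got == exp
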