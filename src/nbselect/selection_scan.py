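"""Selection classification and maximum-likelihood HKA validation.

Genes are classified as purifying / balancing / neutral from empirical-tail
membership of their summary statistics:

* purifying: nucleotide diversity in the lower 5% tail of the derived
  (cultivated) group AND FST in the upper 5% tail for the matching group
  comparison; the comparison(s) that fire determine the phase
  (domestication / improvement / both).
* balancing: theta_pi and theta_w in the upper 25% and Tajima's D in the
  upper 5% jointly in at least one group, with FST below the 90th
  percentile of the per-gene distribution in every comparison (alleles
  maintained in ancestral and descendant populations).

Tails are built from the full filtered gene set, mirroring genome-wide
empirical distributions.  The HKA test fits a Poisson polymorphism /
divergence model with per-locus selection parameters k and compares the
selection model to the nested neutral model by likelihood ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .errors import InputError
from .genome_io import GeneModel, VariantPanel, CULTIVATED, INGROUPS
from .popstats import (
    COMPARISONS,
    DERIVED_GROUP,
    FstRecord,
    GeneStats,
    TailSpec,
    chi_square_enrichment,
    empirical_tail,
    harmonic,
    segregating_sites,
    tail_threshold,
)


@dataclass
class SelectionCall:
    gene_id: str
    call: str  # purifying | balancing | neutral
    phase: str  # domestication | improvement | both | none
    evidence: dict = field(default_factory=dict)


@dataclass
class HKAResult:
    lnl_neutral: float
    lnl_selection: float
    lrt: float
    df: int
    p_value: float
    k_hat: dict[str, float]
    theta_hat: dict[str, float]
    t_hat: float
    converged: bool = True


@dataclass
class SelectionTails:
    """Precomputed empirical tail sets over the full gene universe."""

    pi_upper25: dict[str, set[str]]
    pi_lower5: dict[str, set[str]]
    w_upper25: dict[str, set[str]]
    d_upper5: dict[str, set[str]]
    fst_upper5: dict[str, set[str]]
    fst_below90: dict[str, set[str]]


def build_tail_sets(
    gene_stats: Iterable[GeneStats],
    fst_records: Iterable[FstRecord],
    groups: tuple[str, ...] = INGROUPS,
) -> SelectionTails:
    """Tail sets per group/comparison from the genome-wide distributions."""
    by_group: dict[str, dict[str, float]] = {g: {} for g in groups}
    w_by_group: dict[str, dict[str, float]] = {g: {} for g in groups}
    d_by_group: dict[str, dict[str, float]] = {g: {} for g in groups}
    for st in gene_stats:
        if st.group in by_group:
            by_group[st.group][st.gene_id] = st.theta_pi
            w_by_group[st.group][st.gene_id] = st.theta_w
            d_by_group[st.group][st.gene_id] = st.tajima_d
    fst_by_comp: dict[str, dict[str, float]] = {c: {} for c in COMPARISONS}
    for fr in fst_records:
        fst_by_comp[fr.comparison][fr.gene_id] = fr.fst
    tails = SelectionTails({}, {}, {}, {}, {}, {})
    for g in groups:
        tails.pi_upper25[g] = empirical_tail(by_group[g], TailSpec("theta_pi", "upper", 0.25))
        tails.pi_lower5[g] = empirical_tail(by_group[g], TailSpec("theta_pi", "lower", 0.05))
        tails.w_upper25[g] = empirical_tail(w_by_group[g], TailSpec("theta_w", "upper", 0.25))
        tails.d_upper5[g] = empirical_tail(d_by_group[g], TailSpec("tajima_d", "upper", 0.05))
    for c in COMPARISONS:
        finite = {k: v for k, v in fst_by_comp[c].items() if np.isfinite(v)}
        tails.fst_upper5[c] = empirical_tail(finite, TailSpec("fst", "upper", 0.05))
        thr90 = tail_threshold(finite.values(), TailSpec("fst", "upper", 0.10))
        tails.fst_below90[c] = {k for k, v in finite.items() if v < thr90}
    return tails


def classify_selection(
    gene_stats: Iterable[GeneStats],
    fst_records: Iterable[FstRecord],
    tails: SelectionTails,
    gene_ids: Iterable[str] | None = None,
) -> list[SelectionCall]:
    """Pure rule-based classification from precomputed tail sets."""
    stats_by_gene: dict[str, dict[str, GeneStats]] = {}
    for st in gene_stats:
        stats_by_gene.setdefault(st.gene_id, {})[st.group] = st
    fst_by_gene: dict[str, dict[str, float]] = {}
    for fr in fst_records:
        fst_by_gene.setdefault(fr.gene_id, {})[fr.comparison] = fr.fst
    universe = sorted(gene_ids) if gene_ids is not None else sorted(stats_by_gene)
    calls: list[SelectionCall] = []
    for gid in universe:
        gstats = stats_by_gene.get(gid, {})
        gfst = fst_by_gene.get(gid, {})
        evidence = {
            f"theta_pi_{g}": (s.theta_pi, gid in tails.pi_upper25[g], gid in tails.pi_lower5[g])
            for g, s in gstats.items()
        }
        evidence.update({f"fst_{c}": (gfst.get(c, math.nan), gid in tails.fst_upper5[c]) for c in COMPARISONS})
        # purifying: low derived-group diversity + high matching differentiation
        fired = [
            comp
            for comp in COMPARISONS
            if gid in tails.pi_lower5.get(DERIVED_GROUP[comp], set())
            and gid in tails.fst_upper5[comp]
        ]
        if fired:
            dom = "wild_vs_landrace" in fired or "wild_vs_improved" in fired
            imp = "landrace_vs_improved" in fired or "wild_vs_improved" in fired
            phase = "both" if (dom and imp) else ("domestication" if dom else "improvement")
            calls.append(SelectionCall(gid, "purifying", phase, evidence))
            continue
        # balancing: intermediate-frequency alleles in the ancestral group,
        # diversity maintained in at least one descendant group, and
        # non-extreme differentiation everywhere
        fst_ok = all(gid in tails.fst_below90[c] for c in COMPARISONS)
        wild_sig = (
            gid in tails.pi_upper25.get("wild_weedy", set())
            and gid in tails.w_upper25.get("wild_weedy", set())
            and gid in tails.d_upper5.get("wild_weedy", set())
        )
        maintained = [
            g
            for g in CULTIVATED
            if gid in tails.pi_upper25.get(g, set())
        ]
        if fst_ok and wild_sig and maintained:
            evidence["balancing_groups"] = ("wild_weedy", *maintained)
            calls.append(SelectionCall(gid, "balancing", "none", evidence))
            continue
        calls.append(SelectionCall(gid, "neutral", "none", evidence))
    return calls


def invariance_report(
    panels: Mapping[str, VariantPanel], genes: Iterable[GeneModel]
) -> dict[str, str]:
    """Per-gene fixation status across wild and cultivated groups."""
    out: dict[str, str] = {}
    for gene in genes:
        panel = panels.get(gene.chrom)
        if panel is None:
            out[gene.gene_id] = "invariant_all"
            continue
        win = panel.window(gene.start, gene.end)
        s_by_group = {g: segregating_sites(win, g) for g in INGROUPS}
        if all(s == 0 for s in s_by_group.values()):
            out[gene.gene_id] = "invariant_all"
        elif all(s_by_group[g] == 0 for g in CULTIVATED):
            out[gene.gene_id] = "invariant_cultivated_only"
        else:
            out[gene.gene_id] = "variable"
    return out


# ---------------------------------------------------------------------------
# maximum-likelihood HKA

_K_BOUNDS = (1e-3, 1e3)
_T_BOUNDS = (1e-6, 1e5)


def _pois_ll(x: float, lam: float) -> float:
    if lam <= 0:
        return -math.inf if x > 0 else 0.0
    return x * math.log(lam) - lam - float(gammaln(x + 1))


def _locus_ll(s: float, d: float, a1: float, t: float, k: float) -> float:
    theta = (s + d) / (a1 * k + t + 1.0)
    if theta <= 0:
        # S = D = 0: likelihood maximized in the theta -> 0 limit
        return 0.0
    return _pois_ll(s, a1 * k * theta) + _pois_ll(d, theta * (t + 1.0))


def _selected_k(s: float, d: float, a1: float, t: float) -> float:
    if d > 0 and s > 0:
        k = s * (t + 1.0) / (a1 * d)
    elif s == 0:
        k = _K_BOUNDS[0]
    else:  # d == 0, s > 0
        k = _K_BOUNDS[1]
    return float(min(max(k, _K_BOUNDS[0]), _K_BOUNDS[1]))


def hka_fit(
    s_counts: Mapping[str, float],
    d_counts: Mapping[str, float],
    n: int,
    selected: Iterable[str] = (),
) -> HKAResult:
    """Fit neutral and selection HKA models and report the LRT.

    Polymorphism at locus i is Poisson with mean a1*k_i*theta_i and
    divergence Poisson with mean theta_i*(T+1); k_i = 1 for neutral loci
    (and for every locus under the neutral model).  theta_i and k_i are
    profiled out analytically; T is maximized numerically (coarse log grid
    plus bounded Brent refinement), which makes the selection model nest
    the neutral model pointwise in T.
    """
    loci = sorted(s_counts)
    if sorted(d_counts) != loci:
        raise InputError("S and D counts must cover the same loci")
    if len(loci) < 2:
        raise InputError("HKA requires at least 2 loci")
    selected = set(selected)
    unknown = selected - set(loci)
    if unknown:
        raise InputError(f"selected loci not in count tables: {sorted(unknown)}")
    neutral = [l for l in loci if l not in selected]
    if not neutral:
        raise InputError("HKA requires at least one neutral locus")
    if n < 2:
        raise InputError("HKA requires sample size n >= 2")
    a1 = harmonic(n - 1)
    s = {l: float(s_counts[l]) for l in loci}
    d = {l: float(d_counts[l]) for l in loci}
    if any(v < 0 for v in list(s.values()) + list(d.values())):
        raise InputError("negative counts")

    def profile_ll(t: float, sel: set[str]) -> float:
        total = 0.0
        for l in loci:
            k = _selected_k(s[l], d[l], a1, t) if l in sel else 1.0
            total += _locus_ll(s[l], d[l], a1, t, k)
        return total

    def maximize(sel: set[str]) -> tuple[float, float, bool]:
        grid = np.geomspace(_T_BOUNDS[0], _T_BOUNDS[1], 60)
        vals = np.array([profile_ll(t, sel) for t in grid])
        best = int(np.argmax(vals))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda t: -profile_ll(t, sel), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        ok = bool(res.success)
        t_hat = float(res.x) if ok else float(grid[best])
        ll = profile_ll(t_hat, sel)
        if vals[best] > ll:  # keep the better of grid/refined points
            t_hat, ll = float(grid[best]), float(vals[best])
        return ll, t_hat, ok

    lnl_neutral, _, ok0 = maximize(set())
    lnl_selection, t_hat, ok1 = maximize(selected)
    if lnl_selection < lnl_neutral:  # numerical guard; nesting is structural
        lnl_selection = lnl_neutral
    lrt = 2.0 * (lnl_selection - lnl_neutral)
    df = max(len(selected), 1)
    k_hat = {l: _selected_k(s[l], d[l], a1, t_hat) for l in sorted(selected)}
    theta_hat = {
        l: (s[l] + d[l]) / (a1 * k_hat.get(l, 1.0) + t_hat + 1.0) for l in loci
    }
    return HKAResult(
        lnl_neutral=lnl_neutral,
        lnl_selection=lnl_selection,
        lrt=lrt,
        df=df,
        p_value=float(chi2_dist.sf(lrt, df=df)) if selected else math.nan,
        k_hat=k_hat,
        theta_hat=theta_hat,
        t_hat=t_hat,
        converged=ok0 and ok1,
    )


def hka_divergence_counts(
    panels: Mapping[str, VariantPanel],
    genes: Iterable[GeneModel],
    ingroup_groups: tuple[str, ...] = INGROUPS,
) -> dict[str, int]:
    """Fixed differences between the ingroup consensus and the outgroup.

    Sites missing in the outgroup are excluded; the ingroup consensus is the
    majority allele over all ingroup samples.
    """
    out: dict[str, int] = {}
    for gene in genes:
        panel = panels.get(gene.chrom)
        if panel is None:
            out[gene.gene_id] = 0
            continue
        win = panel.window(gene.start, gene.end)
        og = win.group_indices("outgroup")
        ig = np.concatenate([win.group_indices(g) for g in ingroup_groups])
        count = 0
        for j in range(win.n_sites):
            oc = win.calls[og, j]
            oc = oc[oc != -1]
            if len(oc) == 0 or len(set(oc.tolist())) > 1:
                continue
            ic = win.calls[ig, j]
            ic = ic[ic != -1]
            if len(ic) == 0:
                continue
            consensus = 1 if (ic == 1).sum() * 2 > len(ic) else 0
            if consensus != int(oc[0]):
                count += 1
        out[gene.gene_id] = count
    return out


# ---------------------------------------------------------------------------
# flanking sweep profiles


@dataclass
class FlankProfile:
    gene_id: str
    flank_genes: tuple[str, ...]
    mean_flank_pi: dict[str, float]
    in_lower_tail: dict[str, bool]  # per group: mean flank pi in lower 5% tail


def sweep_flank_profile(
    focal_genes: Iterable[GeneModel],
    all_genes: Iterable[GeneModel],
    gene_stats: Iterable[GeneStats],
    flank: int = 100_000,
    groups: tuple[str, ...] = INGROUPS,
) -> tuple[list[FlankProfile], dict[str, tuple[float, float]]]:
    """Flanking-gene diversity around focal genes plus tail enrichment.

    For each focal gene, the genes whose span lies within ``flank`` bp are
    collected; their per-group theta_pi is summarized and their membership
    in the genome-wide lower 5% tail is tested for enrichment with a
    chi-square against all non-focal genes.  Focal genes with no flanking
    genes are excluded.
    """
    all_genes = list(all_genes)
    focal = list(focal_genes)
    focal_ids = {g.gene_id for g in focal}
    pi: dict[str, dict[str, float]] = {g: {} for g in groups}
    for st in gene_stats:
        if st.group in pi:
            pi[st.group][st.gene_id] = st.theta_pi
    # the low-diversity tail is built over non-focal genes: the focal genes
    # themselves are the swept candidates whose flanks are under test
    tails = {
        g: empirical_tail(
            {k: v for k, v in pi[g].items() if k not in focal_ids},
            TailSpec("theta_pi", "lower", 0.05),
        )
        for g in groups
    }
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in all_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    profiles: list[FlankProfile] = []
    flank_ids: set[str] = set()
    for fg in focal:
        near = [
            g.gene_id
            for g in by_chrom.get(fg.chrom, [])
            if g.gene_id != fg.gene_id
            and g.end > fg.start - flank
            and g.start < fg.end + flank
        ]
        if not near:
            continue
        flank_ids.update(near)
        mean_pi = {}
        in_tail = {}
        for grp in groups:
            vals = [pi[grp][g] for g in near if np.isfinite(pi[grp].get(g, math.nan))]
            mean_pi[grp] = float(np.mean(vals)) if vals else math.nan
            in_tail[grp] = bool(set(near) & tails[grp])
        profiles.append(FlankProfile(fg.gene_id, tuple(sorted(near)), mean_pi, in_tail))
    flank_ids -= focal_ids
    enrichment: dict[str, tuple[float, float]] = {}
    for grp in groups:
        background = set(pi[grp]) - focal_ids
        inside = flank_ids
        outside = background - inside
        t = tails[grp]
        enrichment[grp] = chi_square_enrichment(
            len(inside & t), len(inside - t), len(outside & t), len(outside - t)
        )
    return profiles, enrichment
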