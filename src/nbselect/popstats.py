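"""Population summary statistics and empirical-distribution machinery.

theta_pi, Watterson's theta_w and Tajima's D are computed per group under
pairwise deletion of missing data; FST uses Hudson's ratio-of-sums
estimator 1 - Hw/Hb, the natural choice for a haploid-coded panel.  The
empirical-tail helper implements the nearest-rank quantile with strict
membership, so ties at the threshold never inflate a tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .errors import InputError
from .genome_io import GeneModel, VariantPanel, INGROUPS

COMPARISONS = ("wild_vs_landrace", "landrace_vs_improved", "wild_vs_improved")
COMPARISON_GROUPS = {
    "wild_vs_landrace": ("wild_weedy", "landrace"),
    "landrace_vs_improved": ("landrace", "improved"),
    "wild_vs_improved": ("wild_weedy", "improved"),
}
#: group whose diversity is expected to drop under the sweep each comparison probes
DERIVED_GROUP = {
    "wild_vs_landrace": "landrace",
    "landrace_vs_improved": "improved",
    "wild_vs_improved": "improved",
}


@dataclass
class GeneStats:
    gene_id: str
    group: str
    n_samples: int
    n_sites: int
    s: int
    theta_pi: float
    theta_w: float
    tajima_d: float  # nan when undefined (s == 0 or n < 4)


@dataclass
class FstRecord:
    gene_id: str
    comparison: str
    fst: float  # nan for empty/undefined windows


@dataclass
class TailSpec:
    statistic: str
    side: str  # "upper" | "lower"
    fraction: float

    def __post_init__(self) -> None:
        if self.side not in ("upper", "lower"):
            raise InputError(f"bad tail side {self.side!r}")
        if not 0.0 < self.fraction < 1.0:
            raise InputError(f"bad tail fraction {self.fraction}")


# ---------------------------------------------------------------------------
# core estimators


def _site_pair_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (#non-missing, #alt) for a group slice of the call matrix."""
    present = calls != -1
    m = present.sum(axis=0)
    nalt = np.where(present, calls == 1, False).sum(axis=0)
    return m, nalt


def nucleotide_diversity(
    panel: VariantPanel, group: str, accessible_length: int
) -> float:
    """Mean per-site pairwise difference (theta_pi) within a group.

    Sites with fewer than two non-missing calls are skipped and removed
    from the accessible length.
    """
    idx = panel.group_indices(group)
    if len(idx) < 2:
        raise InputError(f"group {group!r} has fewer than 2 samples")
    m, nalt = _site_pair_stats(panel.calls[idx])
    ok = m >= 2
    length = accessible_length - int((~ok).sum())
    if length <= 0:
        return math.nan
    m, nalt = m[ok], nalt[ok]
    contrib = 2.0 * nalt * (m - nalt) / (m * (m - 1.0))
    return float(contrib.sum() / length)


def segregating_sites(panel: VariantPanel, group: str) -> int:
    idx = panel.group_indices(group)
    m, nalt = _site_pair_stats(panel.calls[idx])
    return int(((nalt > 0) & (nalt < m)).sum())


def harmonic(k: int) -> float:
    return float(sum(1.0 / i for i in range(1, k + 1)))


def watterson_theta(s: int, n: int, accessible_length: int) -> float:
    """Watterson's estimator per site: S / a1 / L with a1 = sum_{i<n} 1/i."""
    if n < 2:
        raise InputError("watterson_theta requires n >= 2")
    if accessible_length <= 0:
        return math.nan
    return s / harmonic(n - 1) / accessible_length


def tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic(n - 1)
    a2 = float(sum(1.0 / i**2 for i in range(1, n)))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1,
        "a2": a2,
        "e1": c1 / a1,
        "e2": c2 / (a1**2 + a2),
    }


def tajimas_d(panel: VariantPanel, group: str) -> float:
    """Tajima's D for a group; nan when undefined (S = 0 or n < 4).

    The variance constants use the group sample size; per-site pairwise
    differences use the non-missing calls at each site.
    """
    idx = panel.group_indices(group)
    n = len(idx)
    if n < 4:
        return math.nan
    m, nalt = _site_pair_stats(panel.calls[idx])
    ok = (m >= 2) & (nalt > 0) & (nalt < m)
    s = int(ok.sum())
    if s == 0:
        return math.nan
    m, nalt = m[ok], nalt[ok]
    pi_total = float((2.0 * nalt * (m - nalt) / (m * (m - 1.0))).sum())
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    if var <= 0:
        return math.nan
    return (pi_total - s / c["a1"]) / math.sqrt(var)


def hudson_fst(panel: VariantPanel, group_a: str, group_b: str) -> float:
    """Hudson ratio-of-sums FST over the window: 1 - sum(Hw)/sum(Hb).

    Hw averages the within-group per-site pairwise diversities of the two
    groups; Hb is the between-group pairwise diversity.  Sites with fewer
    than two non-missing calls in either group are dropped.  Returns 0.0
    when Hb sums to 0, nan for an empty window.
    """
    ia, ib = panel.group_indices(group_a), panel.group_indices(group_b)
    ma, aa = _site_pair_stats(panel.calls[ia])
    mb, ab = _site_pair_stats(panel.calls[ib])
    ok = (ma >= 2) & (mb >= 2)
    if not ok.any():
        return math.nan
    ma, aa, mb, ab = ma[ok], aa[ok], mb[ok], ab[ok]
    hw_a = 2.0 * aa * (ma - aa) / (ma * (ma - 1.0))
    hw_b = 2.0 * ab * (mb - ab) / (mb * (mb - 1.0))
    hb = (aa * (mb - ab) + (ma - aa) * ab) / (ma * mb)
    hb_sum = float(hb.sum())
    if hb_sum == 0.0:
        return 0.0
    return 1.0 - float((0.5 * (hw_a + hw_b)).sum()) / hb_sum


# ---------------------------------------------------------------------------
# empirical tails and enrichment


def tail_threshold(values: Iterable[float], spec: TailSpec) -> float:
    """Nearest-rank empirical quantile used as the tail threshold."""
    arr = np.sort(np.asarray(list(values), dtype=float))
    n = len(arr)
    if spec.side == "upper":
        rank = int(math.ceil((1.0 - spec.fraction) * n))
    else:
        rank = int(math.ceil(spec.fraction * n))
    rank = min(max(rank, 1), n)
    return float(arr[rank - 1])


def empirical_tail(values: Mapping[str, float], spec: TailSpec) -> set[str]:
    """Genes strictly beyond the nearest-rank threshold of the distribution.

    Undefined (nan/None) values are excluded from both the distribution and
    the returned set.  Requires at least 20 finite values.
    """
    finite = {g: float(v) for g, v in values.items() if v is not None and np.isfinite(v)}
    if len(finite) < 20:
        raise InputError(f"too few finite values ({len(finite)}) for an empirical tail")
    thr = tail_threshold(finite.values(), spec)
    if spec.side == "upper":
        return {g for g, v in finite.items() if v > thr}
    return {g for g, v in finite.items() if v < thr}


def chi_square_enrichment(
    k11: int, k12: int, k21: int, k22: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Returns (nan, nan) with a warning when any expected cell is zero.
    """
    obs = np.array([[k11, k12], [k21, k22]], dtype=float)
    if (obs < 0).any():
        raise InputError("negative count in contingency table")
    total = obs.sum()
    if total <= 0:
        raise InputError("empty contingency table")
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (exp == 0).any():
        import warnings

        warnings.warn("chi-square undefined: zero expected cell")
        return math.nan, math.nan
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(chi2_dist.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# windowed scans

WINDOW_SPECS = ("gene_span", "gene_pad10kb", "flanking_100kb")


def _window_intervals(
    gene: GeneModel,
    window_spec: str,
    chrom_length: int | None,
    pad: int = 10_000,
    flank: int = 100_000,
) -> list[tuple[int, int]]:
    hi = chrom_length if chrom_length is not None else None
    if window_spec == "gene_span":
        ivs = [(gene.start, gene.end)]
    elif window_spec == "gene_pad10kb":
        ivs = [(gene.start - pad, gene.end + pad)]
    elif window_spec == "flanking_100kb":
        ivs = [(gene.start - flank, gene.start), (gene.end, gene.end + flank)]
    else:
        raise InputError(f"unknown window spec {window_spec!r}")
    out = []
    for s, e in ivs:
        s = max(s, 0)
        if hi is not None:
            e = min(e, hi)
        if e > s:
            out.append((s, e))
    return out


def windowed_stats(
    panels: Mapping[str, VariantPanel],
    genes: Iterable[GeneModel],
    window_spec: str = "gene_span",
    groups: tuple[str, ...] = INGROUPS,
    comparisons: tuple[str, ...] = COMPARISONS,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[list[GeneStats], list[FstRecord]]:
    """Per-gene, per-group summary stats plus per-comparison FST records.

    Windows are truncated at chromosome ends; empty windows yield nan
    statistics rather than records being dropped.
    """
    gene_stats: list[GeneStats] = []
    fst_records: list[FstRecord] = []
    for gene in genes:
        panel = panels.get(gene.chrom)
        clen = (chrom_lengths or {}).get(gene.chrom)
        ivs = _window_intervals(gene, window_spec, clen)
        length = sum(e - s for s, e in ivs)
        if panel is None or length == 0:
            for grp in groups:
                gene_stats.append(
                    GeneStats(gene.gene_id, grp, 0, 0, 0, math.nan, math.nan, math.nan)
                )
            for comp in comparisons:
                fst_records.append(FstRecord(gene.gene_id, comp, math.nan))
            continue
        sub_panels = [panel.window(s, e) for s, e in ivs]
        for grp in groups:
            idx = panel.group_indices(grp)
            n = len(idx)
            s_count = sum(segregating_sites(sp, grp) for sp in sub_panels)
            pi_parts = []
            for sp in sub_panels:
                m, nalt = _site_pair_stats(sp.calls[idx])
                ok = m >= 2
                pi_parts.append(
                    (
                        float((2.0 * nalt[ok] * (m[ok] - nalt[ok]) / (m[ok] * (m[ok] - 1.0))).sum()),
                        int((~ok).sum()),
                    )
                )
            eff_len = length - sum(skip for _, skip in pi_parts)
            pi = sum(p for p, _ in pi_parts) / eff_len if eff_len > 0 else math.nan
            tw = watterson_theta(s_count, n, eff_len) if n >= 2 and eff_len > 0 else math.nan
            if len(sub_panels) == 1:
                d = tajimas_d(sub_panels[0], grp)
            else:
                merged = _merge_panels(sub_panels)
                d = tajimas_d(merged, grp)
            gene_stats.append(
                GeneStats(gene.gene_id, grp, n, length, s_count, pi, tw, d)
            )
        for comp in comparisons:
            ga, gb = COMPARISON_GROUPS[comp]
            merged = _merge_panels(sub_panels) if len(sub_panels) > 1 else sub_panels[0]
            fst_records.append(FstRecord(gene.gene_id, comp, hudson_fst(merged, ga, gb)))
    return gene_stats, fst_records


def _merge_panels(panels: list[VariantPanel]) -> VariantPanel:
    if len(panels) == 1:
        return panels[0]
    base = panels[0]
    return VariantPanel(
        chrom=base.chrom,
        positions=np.concatenate([p.positions for p in panels]),
        ref=[r for p in panels for r in p.ref],
        alt=[a for p in panels for a in p.alt],
        calls=np.concatenate([p.calls for p in panels], axis=1),
        samples=base.samples,
        groups=base.groups,
    )
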