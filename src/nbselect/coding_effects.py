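"""Codon-level analyses: variant effects, Ka/Ks, 4DTv, functional status.

Effects are computed on the strand-corrected CDS under the standard nuclear
codon table.  Large-effect SNP classes follow the usual resistance-gene
screening set: premature stop, start-codon loss, stop-codon loss and
splice-site changes; indels whose length is not a multiple of 3 inside the
CDS are frameshifts.  Point changes that would create a stop codon are
excluded from the per-site mutational opportunity in the NG86 Ka/Ks
counting (see docs/methods.md).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .errors import InputError
from .genome_io import (
    GROUPS,
    CULTIVATED,
    GeneModel,
    VariantPanel,
    extract_cds,
    revcomp,
)

_CODON_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"
START_CODON = "ATG"
NUCS = "ACGT"

LARGE_EFFECT = frozenset(
    {"premature_stop", "start_loss", "stop_loss", "splice_site", "frameshift"}
)
_PURINES = frozenset("AG")


def translate(cds: str) -> str:
    return "".join(_CODON_AA[cds[i : i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3))


@dataclass
class EffectAnnotation:
    gene_id: str
    position: int  # genomic, 0-based
    ref: str
    alt: str
    effect: str
    codon_index: int | None = None

    @property
    def large_effect(self) -> bool:
        return self.effect in LARGE_EFFECT


@dataclass
class KaKsRecord:
    pair_id: tuple[str, str]
    ka: float
    ks: float
    ratio: float  # nan when undefined (ks == 0 or saturated)
    method: str = "NG86"


@dataclass
class FunctionalStatus:
    gene_id: str
    sample: str
    functional: bool
    reasons: tuple[str, ...] = ()
    deleted_fraction: float = 0.0


# ---------------------------------------------------------------------------
# variant effect annotation


def _splice_positions(gene: GeneModel) -> set[int]:
    """The 2-bp intron edges (GT-AG positions) between CDS intervals."""
    pos: set[int] = set()
    ivs = gene.cds_intervals
    for (_, left_end), (right_start, _) in zip(ivs, ivs[1:]):
        pos.update(range(left_end, min(left_end + 2, right_start)))
        pos.update(range(max(right_start - 2, left_end), right_start))
    return pos


def annotate_variant_effect(
    gene: GeneModel,
    position: int,
    ref: str,
    alt: str,
    region_seq: str,
    region_start: int | None = None,
) -> EffectAnnotation:
    """Classify one variant's effect on the gene.

    ``region_seq`` is the + strand reference sequence covering the gene span
    starting at ``region_start`` (default: gene.start).  Variants outside
    the gene span are labelled noncoding.
    """
    if region_start is None:
        region_start = gene.start
    is_snp = len(ref) == 1 == len(alt)
    splice = _splice_positions(gene)
    if not is_snp:
        span = range(position, position + max(len(ref), 1))
        in_cds = any(
            any(s <= p < e for s, e in gene.cds_intervals) for p in span
        )
        # an insertion anchored at the base before the affected position
        ins_in_cds = len(alt) > len(ref) and any(
            s <= position + 1 <= e for s, e in gene.cds_intervals
        )
        if in_cds or ins_in_cds:
            shift = abs(len(alt) - len(ref)) % 3
            effect = "frameshift" if shift else "inframe_indel"
        elif any(p in splice for p in span):
            effect = "splice_site"
        else:
            effect = "noncoding"
        return EffectAnnotation(gene.gene_id, position, ref, alt, effect)
    if position in splice:
        return EffectAnnotation(gene.gene_id, position, ref, alt, "splice_site")
    gpos = gene.cds_genomic_positions()
    where = np.nonzero(gpos == position)[0]
    if len(where) == 0:
        return EffectAnnotation(gene.gene_id, position, ref, alt, "noncoding")
    if not gene.in_frame:
        raise InputError(f"{gene.gene_id}: CDS phase broken; exclude upstream")
    i = int(where[0])
    cds = extract_cds(gene, region_seq, region_start)
    ref_base, alt_base = (ref, alt) if gene.strand == "+" else (revcomp(ref), revcomp(alt))
    if cds[i] != ref_base:
        raise InputError(
            f"{gene.gene_id}: reference allele mismatch at {gene.chrom}:{position}"
        )
    ci, off = divmod(i, 3)
    ref_codon = cds[3 * ci : 3 * ci + 3]
    alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1 :]
    last = len(cds) // 3 - 1
    ref_aa, alt_aa = _CODON_AA[ref_codon], _CODON_AA[alt_codon]
    if ci == 0 and ref_codon == START_CODON and alt_codon != START_CODON:
        effect = "start_loss"
    elif ref_aa == "*" and alt_aa != "*" and ci == last:
        effect = "stop_loss"
    elif alt_aa == "*" and ref_aa != "*" and ci < last:
        effect = "premature_stop"
    elif ref_aa == alt_aa:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return EffectAnnotation(gene.gene_id, position, ref, alt, effect, codon_index=ci)


# ---------------------------------------------------------------------------
# protein variants


def count_protein_variants(
    gene: GeneModel,
    panel: VariantPanel,
    region_seq: str,
    groups: Iterable[str] | None = None,
    region_start: int | None = None,
) -> int:
    """Number of distinct translated CDS haplotypes across samples.

    Substitution (SNP) alleles inside the CDS are applied per sample;
    samples with a missing call at any such site are excluded.  Only
    amino-acid level differences distinguish variants.
    """
    if region_start is None:
        region_start = gene.start
    if not gene.in_frame:
        raise InputError(f"{gene.gene_id}: out-of-frame CDS")
    win = panel.window(gene.start, gene.end)
    gpos = gene.cds_genomic_positions()
    index_of = {int(p): i for i, p in enumerate(gpos)}
    sites = [
        (j, index_of[int(win.positions[j])])
        for j in range(win.n_sites)
        if len(win.ref[j]) == 1 == len(win.alt[j]) and int(win.positions[j]) in index_of
    ]
    cds_ref = extract_cds(gene, region_seq, region_start)
    if groups is None:
        sample_idx = range(win.n_samples)
    else:
        wanted = set(groups)
        sample_idx = [
            i for i, s in enumerate(win.samples) if win.groups[s] in wanted
        ]
    proteins = set()
    for i in sample_idx:
        row = win.calls[i]
        if any(row[j] == -1 for j, _ in sites):
            continue
        hap = list(cds_ref)
        for j, ci in sites:
            if row[j] == 1:
                alt = win.alt[j]
                hap[ci] = alt if gene.strand == "+" else revcomp(alt)
        proteins.add(translate("".join(hap)))
    return len(proteins)


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


@functools.lru_cache(maxsize=None)
def _valid_alts(codon: str, pos: int) -> list[str]:
    """Point changes at ``pos`` that do not create a stop codon."""
    out = []
    for nt in NUCS:
        if nt == codon[pos]:
            continue
        new = codon[:pos] + nt + codon[pos + 1 :]
        if _CODON_AA[new] != "*":
            out.append(new)
    return out


@functools.lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes one site, split by the fraction of its
    non-stop alternatives that are synonymous.
    """
    syn = 0.0
    for pos in range(3):
        alts = _valid_alts(codon, pos)
        if alts:
            syn += sum(_CODON_AA[a] == _CODON_AA[codon] for a in alts) / len(alts)
    return syn, 3.0 - syn


@functools.lru_cache(maxsize=None)
def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """(syn, nonsyn) difference counts averaged over mutational pathways."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in itertools.permutations(diffs):
        cur = ca
        sd = nd = 0.0
        hit_stop = False
        for pos in order:
            new = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _CODON_AA[new] == "*" and new != cb:
                hit_stop = True
            if _CODON_AA[new] == _CODON_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = new
        (blocked if hit_stop else results).append((sd, nd))
    use = results if results else blocked
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return abs(-0.75 * math.log(1.0 - 4.0 * p / 3.0))


def ng86_kaks(cds_a: str, cds_b: str, pair_id: tuple[str, str] = ("a", "b")) -> KaKsRecord:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Requires equal-length, gap-free, in-frame CDS; internal stop codons are
    rejected.  The ratio is nan when ks is 0 or a correction saturates.
    """
    if len(cds_a) != len(cds_b):
        raise InputError("CDS length mismatch")
    if len(cds_a) % 3:
        raise InputError("CDS length not divisible by 3")
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if (_CODON_AA[ca] == "*" or _CODON_AA[cb] == "*") and i < len(cds_a) - 3:
            raise InputError(f"internal stop codon at codon {i // 3}")
        if _CODON_AA[ca] == "*" or _CODON_AA[cb] == "*":
            continue  # terminal stop codon carries no sites
        sa = _codon_sites(ca)
        sb = _codon_sites(cb)
        s_sites += 0.5 * (sa[0] + sb[0])
        n_sites += 0.5 * (sa[1] + sb[1])
        dsd, dnd = _pathway_counts(ca, cb)
        sd += dsd
        nd += dnd
    ks = _jc_correct(sd / s_sites) if s_sites > 0 else math.nan
    ka = _jc_correct(nd / n_sites) if n_sites > 0 else math.nan
    if not math.isfinite(ka) or not math.isfinite(ks) or ks == 0.0:
        ratio = math.nan
    else:
        ratio = ka / ks
    return KaKsRecord(pair_id=pair_id, ka=ka, ks=ks, ratio=ratio)


# ---------------------------------------------------------------------------
# 4DTv

_FOURFOLD = frozenset(
    c
    for c in _CODON_AA
    if _CODON_AA[c] != "*"
    and len({_CODON_AA[c[:2] + nt] for nt in NUCS}) == 1
)


def _is_transversion(a: str, b: str) -> bool:
    return (a in _PURINES) != (b in _PURINES)


def fourfold_tv(cds_a: str, cds_b: str) -> tuple[float, bool]:
    """4DTv ratio and the 'recent duplicate' flag (ratio < 0.497).

    Ratio = transversion differences at third positions fourfold-degenerate
    in both sequences, divided by the number of such sites; uncorrected.
    Returns (nan, False) when no fourfold sites exist.
    """
    if len(cds_a) != len(cds_b) or len(cds_a) % 3:
        raise InputError("in-frame equal-length CDS required")
    sites = tv = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if ca in _FOURFOLD and cb in _FOURFOLD:
            sites += 1
            if ca[2] != cb[2] and _is_transversion(ca[2], cb[2]):
                tv += 1
    if sites == 0:
        return math.nan, False
    ratio = tv / sites
    return ratio, ratio < 0.497


# ---------------------------------------------------------------------------
# functional status, pseudogenes, gene loss, presence/absence


def functional_statuses(
    gene: GeneModel,
    panel: VariantPanel,
    effects: Iterable[EffectAnnotation],
    deleted_fraction: Mapping[str, float] | None = None,
) -> list[FunctionalStatus]:
    """Per-sample functional status from disabling alleles and deletions.

    A sample is non-functional iff it carries the alternate allele of a
    large-effect/frameshift variant or has lost more than half the gene.
    Samples missing at every disabling site with no depth evidence keep
    their (possibly vacuous) functional=True status only if they have at
    least one non-missing disabling-site call or there are no disabling
    sites; otherwise they are skipped.
    """
    win = panel.window(gene.start, gene.end)
    pos_index = {int(p): j for j, p in enumerate(win.positions)}
    disabling = [
        (e, pos_index[e.position])
        for e in effects
        if e.gene_id == gene.gene_id and e.large_effect and e.position in pos_index
    ]
    out: list[FunctionalStatus] = []
    for i, sample in enumerate(win.samples):
        reasons = []
        any_called = not disabling
        for e, j in disabling:
            c = win.calls[i, j]
            if c != -1:
                any_called = True
            if c == 1:
                reasons.append(e.effect)
        frac = float((deleted_fraction or {}).get(sample, 0.0))
        if frac > 0.5:
            reasons.append("large_deletion")
        if not any_called and frac <= 0.5:
            continue  # all-missing sample: status unknown
        out.append(
            FunctionalStatus(
                gene.gene_id, sample, not reasons, tuple(sorted(set(reasons))), frac
            )
        )
    return out


def nonfunctional_frequency(
    statuses: Iterable[FunctionalStatus], groups: Mapping[str, str]
) -> dict[str, float]:
    """Fraction of non-functional samples per group plus 'overall'."""
    counts: dict[str, list[int]] = {g: [0, 0] for g in GROUPS}
    overall = [0, 0]
    for st in statuses:
        g = groups.get(st.sample)
        if g is None:
            continue
        counts[g][0] += not st.functional
        counts[g][1] += 1
        overall[0] += not st.functional
        overall[1] += 1
    out = {
        g: (c[0] / c[1] if c[1] else math.nan) for g, c in counts.items()
    }
    out["overall"] = overall[0] / overall[1] if overall[1] else math.nan
    return out


def call_pseudogene(statuses: Iterable[FunctionalStatus]) -> bool | None:
    """True iff every sample with a known status is non-functional.

    Returns None (undefined) when no statuses are available.
    """
    statuses = list(statuses)
    if not statuses:
        return None
    return all(not st.functional for st in statuses)


def gene_loss_from_depth(
    depth: pd.DataFrame,
    gene: GeneModel,
    depth_threshold: float = 2.0,
    fraction_cutoff: float = 0.5,
    bin_size: int = 100,
) -> dict[str, tuple[bool, float]]:
    """Per-sample (lost, deleted_fraction) from binned read depth.

    A sample is flagged lost when the fraction of gene bins with depth
    below ``depth_threshold`` strictly exceeds ``fraction_cutoff``.
    """
    first_bin = gene.start // bin_size * bin_size
    bins = np.arange(first_bin, gene.end, bin_size)
    sub = depth[(depth["chrom"] == gene.chrom) & depth["bin_start"].isin(bins)]
    out: dict[str, tuple[bool, float]] = {}
    for sample, grp in sub.groupby("sample"):
        have = set(grp["bin_start"])
        if have != set(bins.tolist()):
            raise InputError(
                f"{gene.gene_id}: depth bins do not tile the gene span for {sample}"
            )
        frac = float((grp["depth"] < depth_threshold).mean())
        out[str(sample)] = (frac > fraction_cutoff, frac)
    if not out:
        raise InputError(f"{gene.gene_id}: no depth bins cover the gene")
    return out


PRESENCE_LABELS = (
    "absent_all_cultivated",
    "outgroup_only",
    "wild_only",
    "widespread",
    "other",
)


def presence_absence_profile(
    presence: Mapping[str, bool], groups: Mapping[str, str]
) -> str:
    """Label a gene's presence pattern across genotype groups."""
    frac: dict[str, float] = {}
    for g in GROUPS:
        members = [s for s, grp in groups.items() if grp == g and s in presence]
        frac[g] = (
            sum(presence[s] for s in members) / len(members) if members else 0.0
        )
    present = {g for g in GROUPS if frac[g] > 0}
    if present == {"outgroup"}:
        return "outgroup_only"
    if present == {"wild_weedy"}:
        return "wild_only"
    if not present & set(CULTIVATED):
        return "absent_all_cultivated"
    if {"wild_weedy", "landrace", "improved"} <= present:
        return "widespread"
    return "other"
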