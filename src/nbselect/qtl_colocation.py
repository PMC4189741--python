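"""QTL projection from genetic to physical coordinates and co-location.

QTL spans reported in centimorgans on a consensus map are projected to
physical bp by linear interpolation between framework markers; endpoints
outside the marker range extrapolate from the terminal marker pair and are
clamped to the chromosome.  Co-location uses half-open interval overlap;
enrichment reuses the Pearson chi-square helper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .genome_io import GeneModel
from .popstats import chi_square_enrichment


@dataclass
class FrameworkMarker:
    marker_id: str
    chrom: str
    cm: float
    bp: int


@dataclass
class QTLInterval:
    qtl_id: str
    trait: str
    chrom: str
    cm_start: float
    cm_end: float
    bp_start: int | None = None
    bp_end: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.cm_start > self.cm_end:
            raise InputError(f"{self.qtl_id}: cM start > end")


def read_markers(path: str) -> list[FrameworkMarker]:
    df = pd.read_csv(path, sep="\t")
    need = {"marker", "chrom", "cm", "bp"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: expected columns {sorted(need)}")
    return [
        FrameworkMarker(str(r.marker), str(r.chrom), float(r.cm), int(r.bp))
        for r in df.itertuples(index=False)
    ]


def read_qtl_table(path: str, point_halfwidth_cm: float = 1.0) -> list[QTLInterval]:
    df = pd.read_csv(path, sep="\t")
    need = {"qtl_id", "trait", "chrom", "cm_start", "cm_end"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: expected columns {sorted(need)}")
    out = []
    for r in df.itertuples(index=False):
        cm0, cm1 = float(r.cm_start), float(r.cm_end)
        if cm0 == cm1:  # point estimate: expand by the configured half-width
            cm0, cm1 = cm0 - point_halfwidth_cm, cm1 + point_halfwidth_cm
        out.append(
            QTLInterval(
                str(r.qtl_id), str(r.trait), str(r.chrom), cm0, cm1,
                source=str(getattr(r, "study", "")),
            )
        )
    return out


def validate_markers(markers: Iterable[FrameworkMarker]) -> dict[str, list[FrameworkMarker]]:
    """Per-chromosome marker lists, monotone in both cM and bp.

    Markers are sorted by cM; any marker whose bp breaks monotonicity is
    dropped with a warning (reordering would fabricate map structure).
    """
    by_chrom: dict[str, list[FrameworkMarker]] = {}
    for m in markers:
        by_chrom.setdefault(m.chrom, []).append(m)
    out: dict[str, list[FrameworkMarker]] = {}
    for chrom, ms in by_chrom.items():
        ms = sorted(ms, key=lambda m: (m.cm, m.bp))
        kept: list[FrameworkMarker] = []
        for m in ms:
            if kept and (m.bp <= kept[-1].bp or m.cm <= kept[-1].cm):
                warnings.warn(f"dropping non-monotone marker {m.marker_id} on {chrom}")
                continue
            kept.append(m)
        out[chrom] = kept
    return out


def project_cm(
    cm: float, markers: Sequence[FrameworkMarker], chrom_length: int
) -> float:
    """Map one cM coordinate to bp by piecewise-linear interpolation."""
    if len(markers) < 2:
        raise InputError("need >= 2 framework markers on the chromosome")
    cms = np.array([m.cm for m in markers])
    bps = np.array([m.bp for m in markers], dtype=float)
    if cm <= cms[0]:
        slope = (bps[1] - bps[0]) / (cms[1] - cms[0])
        bp = bps[0] + (cm - cms[0]) * slope
    elif cm >= cms[-1]:
        slope = (bps[-1] - bps[-2]) / (cms[-1] - cms[-2])
        bp = bps[-1] + (cm - cms[-1]) * slope
    else:
        bp = float(np.interp(cm, cms, bps))
    return float(min(max(bp, 0.0), chrom_length))


def project_qtl(
    qtls: Iterable[QTLInterval],
    markers: Iterable[FrameworkMarker],
    chrom_lengths: Mapping[str, int],
) -> list[QTLInterval]:
    """Project every QTL's genetic span to a physical span."""
    marker_map = validate_markers(markers)
    out = []
    for q in qtls:
        ms = marker_map.get(q.chrom, [])
        if len(ms) < 2:
            raise InputError(f"{q.qtl_id}: fewer than 2 markers on {q.chrom}")
        clen = chrom_lengths[q.chrom]
        b0 = int(round(project_cm(q.cm_start, ms, clen)))
        b1 = int(round(project_cm(q.cm_end, ms, clen)))
        out.append(
            QTLInterval(
                q.qtl_id, q.trait, q.chrom, q.cm_start, q.cm_end,
                bp_start=min(b0, b1), bp_end=max(b0, b1), source=q.source,
            )
        )
    return out


def colocate(
    genes: Iterable[GeneModel], qtls: Sequence[QTLInterval]
) -> dict[str, list[str]]:
    """Gene -> overlapping QTL ids (half-open overlap; empty list if none)."""
    out: dict[str, list[str]] = {}
    for g in genes:
        hits = [
            q.qtl_id
            for q in qtls
            if q.chrom == g.chrom
            and q.bp_start is not None
            and g.start < q.bp_end
            and q.bp_start < g.end
        ]
        out[g.gene_id] = sorted(hits)
    return out


def trait_gene_sets(
    colocation: Mapping[str, list[str]], qtls: Sequence[QTLInterval]
) -> dict[str, set[str]]:
    trait_of = {q.qtl_id: q.trait for q in qtls}
    out: dict[str, set[str]] = {}
    for gid, hits in colocation.items():
        for qid in hits:
            out.setdefault(trait_of[qid], set()).add(gid)
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def qdr_fraction(
    qtls: Sequence[QTLInterval], chrom_lengths: Mapping[str, int]
) -> dict[str, float]:
    """Genome fraction under projected QTL, plus overlap structure.

    Returns the union fraction, the fraction of QDR space covered by >= 2
    QTL, and the fraction covered by >= 2 distinct traits.
    """
    genome = sum(chrom_lengths.values())
    if genome <= 0:
        raise InputError("empty genome")
    by_chrom: dict[str, list[QTLInterval]] = {}
    for q in qtls:
        if q.bp_start is None:
            raise InputError(f"{q.qtl_id}: not projected")
        by_chrom.setdefault(q.chrom, []).append(q)
    union = multi_qtl = multi_trait = 0
    for chrom, qs in by_chrom.items():
        events: list[tuple[int, int, str]] = []
        for q in qs:
            events.append((q.bp_start, 1, q.trait))
            events.append((q.bp_end, -1, q.trait))
        events.sort(key=lambda e: (e[0], -e[1]))
        depth = 0
        traits: dict[str, int] = {}
        prev = None
        for pos, delta, trait in events:
            if prev is not None and pos > prev and depth > 0:
                seg = pos - prev
                union += seg
                if depth >= 2:
                    multi_qtl += seg
                if sum(1 for c in traits.values() if c > 0) >= 2:
                    multi_trait += seg
            depth += delta
            traits[trait] = traits.get(trait, 0) + delta
            prev = pos
    return {
        "qdr_fraction": union / genome,
        "multi_qtl_fraction": multi_qtl / union if union else math.nan,
        "multi_trait_fraction": multi_trait / union if union else math.nan,
    }


def qtl_enrichment(
    gene_set: set[str],
    background: Mapping[str, bool],
) -> tuple[float, float]:
    """Chi-square enrichment of a gene set inside QTL space.

    ``background`` maps every background gene id to its in-QTL status and
    must contain the gene set.
    """
    if not gene_set <= set(background):
        raise InputError("gene set not contained in background")
    k11 = sum(1 for g in gene_set if background[g])
    k12 = len(gene_set) - k11
    rest = [g for g in background if g not in gene_set]
    k21 = sum(1 for g in rest if background[g])
    k22 = len(rest) - k21
    return chi_square_enrichment(k11, k12, k21, k22)
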