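"""Labelled synthetic inputs emulating a structured resequencing panel.

The generator emulates a three-group inbred panel (wild/weedy, landrace,
improved) with an outgroup, neutral / purifying-swept / balanced genes,
coding variants including large-effect classes, clustered gene layouts,
framework marker maps and planted disease QTL.  Every output is a pure
function of (config, seed).

Model sketch (details in docs/methods.md):

* neutral genes — haplotypes drawn for a founder pool from a single-locus
  Kingman coalescent with infinite-sites mutation at per-site theta; the
  wild group samples the pool directly (hence is exactly calibrated at
  theta), cultivated groups resample restricted founder subsets
  (domestication/improvement bottlenecks with shared polymorphism).
* purifying genes — the swept group(s) are fixed for one founder haplotype
  carrying additional sweep-divergence substitutions, plus rare private
  mutations (diversity reduced ~10x, rare-skewed AFS, elevated FST).
* balancing genes — two deep haplotype classes at intermediate frequency
  in every group with fixed between-class differences (elevated diversity,
  positive Tajima's D, low FST).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .genome_io import (
    GROUPS,
    NBS_CLASSES,
    GeneModel,
    VariantPanel,
)
from .qtl_colocation import FrameworkMarker, QTLInterval

NUCS = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel (defaults are the ones the
    acceptance checks run under)."""

    seed: int
    # panel composition (44 ingroup genotypes + outgroup)
    n_wild: int = 14
    n_landrace: int = 15
    n_improved: int = 15
    n_outgroup: int = 2
    # gene-class counts
    n_neutral: int = 180
    n_purifying: int = 10
    n_balancing: int = 10
    n_pseudogene: int = 4
    n_novel: int = 4
    # mutation / selection parameters
    theta: float = 0.005                 # ancestral per-site diversity
    pool_extra: int = 10                 # founder pool size = n_wild + extra
    landrace_founders: int = 7
    improved_founders: int = 4
    sweep_factor: float = 0.1            # residual diversity in swept groups
    sweep_divergence: float = 0.006      # per-site fixed drift of the swept haplotype
    flank_sweep_factor: float = 1.0      # hitchhiking of neutral neighbours (1 = off)
    balancing_divergence: float = 0.025  # per-site fixed differences between classes
    balancing_class_theta: float = 0.3   # within-class theta as fraction of theta
    outgroup_divergence: float = 0.02    # per-site outgroup-branch substitutions
    missing_rate: float = 0.01
    # gene structure / layout
    gene_length: int = 1500
    cds_length: int = 900
    two_exon_fraction: float = 0.4
    n_chromosomes: int = 5
    chromosome_length: int = 30_000_000
    cluster_fraction: float = 0.55
    cluster_size_range: tuple[int, int] = (2, 6)
    cluster_spacing: tuple[int, int] = (40_000, 150_000)
    isolation_gap: int = 220_000
    nbs_fraction: float = 0.4
    # coding-variant injection
    large_effect_rate: float = 0.08      # per-gene prob of a segregating large-effect SNP
    frameshift_rate: float = 0.08
    benign_snps_per_gene: float = 1.5
    gene_loss_rate: float = 0.02
    mean_depth: float = 25.0
    # cross-species family structure
    n_maize: int = 15
    n_rice: int = 15
    n_ancestral_families: int = 6
    n_cross_species_pairs: int = 4
    within_family_divergence: float = 0.05
    cross_species_divergence: float = 0.10
    # QTL map
    n_qtl: int = 30
    qtl_traits: tuple[str, ...] = ("rust", "anthracnose", "ergot")
    qtl_nbs_bias: float = 0.95
    qtl_halfwidth_cm: tuple[float, float] = (0.15, 0.4)
    markers_per_chromosome: int = 40
    map_length_cm: float = 150.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InputError("seed is mandatory")
        for name in ("sweep_factor", "flank_sweep_factor", "missing_rate",
                     "nbs_fraction", "qtl_nbs_bias", "large_effect_rate",
                     "frameshift_rate", "gene_loss_rate", "cluster_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")
        for name in ("n_wild", "n_landrace", "n_improved", "n_outgroup",
                     "n_neutral", "n_purifying", "n_balancing",
                     "n_pseudogene", "n_novel"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    @property
    def sample_names(self) -> list[str]:
        names = []
        for grp, n in (
            ("wild_weedy", self.n_wild),
            ("landrace", self.n_landrace),
            ("improved", self.n_improved),
            ("outgroup", self.n_outgroup),
        ):
            names.extend(f"{grp}_{i:02d}" for i in range(n))
        return names

    @property
    def sample_groups(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_names}

    @property
    def n_genes(self) -> int:
        return (
            self.n_neutral + self.n_purifying + self.n_balancing
            + self.n_pseudogene + self.n_novel
        )


@dataclass
class TruthLabels:
    selection_class: dict[str, str] = field(default_factory=dict)
    phase: dict[str, str] = field(default_factory=dict)
    cluster_id: dict[str, str | None] = field(default_factory=dict)
    family_id: dict[str, str] = field(default_factory=dict)
    pseudogene: dict[str, bool] = field(default_factory=dict)
    presence: dict[str, dict[str, bool]] = field(default_factory=dict)
    qtl_target_genes: set[str] = field(default_factory=set)
    effect_truth: list[tuple] = field(default_factory=list)  # (gene, pos, ref, alt, effect)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# coalescent haplotypes


def simulate_neutral_haplotypes(
    n: int, length: int, theta: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Infinite-sites haplotypes from a single-locus Kingman coalescent.

    Time is in units of 2N generations (coalescence rate k(k-1)/2 for k
    lineages) and mutations fall on branches at rate theta/2 per site, so
    E[pairwise diversity] = theta per site and E[S] = theta*L*a1.
    Returns (sorted unique positions in [0, length), n x S 0/1 matrix).
    """
    if n < 2:
        raise InputError("need n >= 2 haplotypes")
    lineages: list[set[int]] = [{i} for i in range(n)]
    blens = [0.0] * n
    branches: list[tuple[set[int], float]] = []
    while len(lineages) > 1:
        k = len(lineages)
        t = rng.exponential(2.0 / (k * (k - 1)))
        blens = [b + t for b in blens]
        i, j = sorted(rng.choice(k, size=2, replace=False))
        branches.append((lineages[i], blens[i]))
        branches.append((lineages[j], blens[j]))
        merged = lineages[i] | lineages[j]
        lineages = [l for x, l in enumerate(lineages) if x not in (i, j)] + [merged]
        blens = [b for x, b in enumerate(blens) if x not in (i, j)] + [0.0]
    carriers: list[set[int]] = []
    for leafset, blen in branches:
        nmut = rng.poisson(0.5 * theta * length * blen)
        carriers.extend([leafset] * nmut)
    s = min(len(carriers), length)
    carriers = carriers[:s]
    positions = np.sort(rng.choice(length, size=s, replace=False))
    haps = np.zeros((n, s), dtype=np.int8)
    for col, leafset in enumerate(carriers):
        haps[sorted(leafset), col] = 1
    return positions, haps


class _OffsetPool:
    """Disjoint random offsets within one gene span."""

    def __init__(self, length: int, rng: np.random.Generator):
        self._perm = rng.permutation(length)
        self._next = 0

    def take(self, k: int) -> np.ndarray:
        if self._next + k > len(self._perm):
            raise InputError("gene span too short for the requested variant count")
        out = self._perm[self._next : self._next + k]
        self._next += k
        return out


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class _GeneRecord:
    gene: GeneModel
    sel_class: str  # neutral | purifying | balancing
    phase: str      # domestication | improvement | none
    cluster_id: str | None
    family_id: str
    is_pseudogene: bool
    is_novel: bool


@dataclass
class SyntheticAnnotation:
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    region_seqs: dict[str, str]      # gene_id -> + strand span sequence
    cds_seqs: dict[str, str]         # gene_id -> strand-corrected CDS
    markers: list[FrameworkMarker]
    qtls: list[QTLInterval]
    truth: TruthLabels


def simulate_genome(config: SimulationConfig) -> tuple[list[_GeneRecord], dict[str, int]]:
    """Deterministic gene layout with planted clusters and class labels."""
    rng = _rng(config, 0)
    n_genes = config.n_genes
    # class labels; pseudogene/novel genes are neutral for selection truth
    labels = (
        ["purifying"] * config.n_purifying
        + ["balancing"] * config.n_balancing
        + ["neutral"] * (config.n_neutral + config.n_pseudogene + config.n_novel)
    )
    flags = (
        [("", False, False)] * (config.n_purifying + config.n_balancing + config.n_neutral)
        + [("", True, False)] * config.n_pseudogene
        + [("", False, True)] * config.n_novel
    )
    # purifying phases: ~60% domestication (both cultivated groups swept)
    n_dom = int(round(0.6 * config.n_purifying))
    phases = ["domestication"] * n_dom + ["improvement"] * (config.n_purifying - n_dom)
    phases += ["none"] * (n_genes - config.n_purifying)
    order = rng.permutation(n_genes)
    # blocks: swept genes isolated unless hitchhiking is enabled
    sweep_isolated = config.flank_sweep_factor >= 1.0
    cluster_lo, cluster_hi = config.cluster_size_range
    assignments: list[tuple[int, str, str, bool, bool]] = []  # idx, class, phase, pseudo, novel
    for idx in order:
        assignments.append(
            (int(idx), labels[idx], phases[idx], flags[idx][1], flags[idx][2])
        )
    blocks: list[list[tuple[int, str, str, bool, bool]]] = []
    pending = [a for a in assignments if not (sweep_isolated and a[1] == "purifying")]
    for a in assignments:
        if sweep_isolated and a[1] == "purifying":
            blocks.append([a])
    i = 0
    while i < len(pending):
        if rng.random() < config.cluster_fraction and len(pending) - i >= cluster_lo:
            size = int(rng.integers(cluster_lo, cluster_hi + 1))
            size = min(size, len(pending) - i)
            blocks.append(pending[i : i + size])
            i += size
        else:
            blocks.append([pending[i]])
            i += 1
    blocks = [blocks[k] for k in rng.permutation(len(blocks))]
    chroms = [f"chr{c + 1:02d}" for c in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chromosome_length for c in chroms}
    records: list[_GeneRecord] = []
    chrom_idx = 0
    cursor = config.isolation_gap
    n_clusters = 0
    gene_counter = 0
    for block in blocks:
        width = (len(block) - 1) * config.cluster_spacing[1] + config.gene_length
        if cursor + width + config.isolation_gap > config.chromosome_length:
            chrom_idx += 1
            cursor = config.isolation_gap
            if chrom_idx >= len(chroms):
                raise InputError("layout infeasible for chromosome length")
        chrom = chroms[chrom_idx]
        cluster_id = None
        if len(block) >= 2:
            cluster_id = f"truth_cl{n_clusters:03d}"
            n_clusters += 1
        pos = cursor
        for b, (idx, sel_class, phase, pseudo, novel) in enumerate(block):
            gid = f"gene{gene_counter:04d}"
            gene_counter += 1
            start = pos
            end = start + config.gene_length
            two_exon = rng.random() < config.two_exon_fraction
            cds_half = config.cds_length // 2
            cds_half -= cds_half % 3
            if two_exon:
                cds = [
                    (start + 100, start + 100 + cds_half),
                    (start + 100 + cds_half + 200, start + 300 + 2 * cds_half),
                ]
            else:
                cds = [(start + 150, start + 150 + config.cds_length)]
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                cds_intervals=cds,
                nbs_class="non_nbs",
                species="sorghum",
            )
            records.append(
                _GeneRecord(gene, sel_class, phase, cluster_id, "", pseudo, novel)
            )
            if b + 1 < len(block):
                pos += int(rng.integers(*config.cluster_spacing))
        cursor = pos + config.gene_length + config.isolation_gap
    # NBS classes: all selected/pseudo/novel genes are NBS, plus random
    # neutral genes up to the configured fraction
    rng_cls = _rng(config, 6)
    n_nbs_target = int(round(config.nbs_fraction * len(records)))
    forced = [
        r for r in records
        if r.sel_class != "neutral" or r.is_pseudogene or r.is_novel
    ]
    others = [r for r in records if r not in forced]
    extra = max(n_nbs_target - len(forced), 0)
    chosen = list(rng_cls.choice(len(others), size=min(extra, len(others)), replace=False))
    nbs_records = forced + [others[i] for i in chosen]
    for r in nbs_records:
        if r.is_novel:  # novel genes carry no LRR domain
            r.gene.nbs_class = str(rng_cls.choice(["N", "CN"]))
        else:
            r.gene.nbs_class = str(rng_cls.choice(NBS_CLASSES))
        dom_start = 90
        r.gene.nbs_domain = (dom_start, min(dom_start + 300, r.gene.cds_length))
    return records, chrom_lengths


# ---------------------------------------------------------------------------
# panel simulation


def _private_mutations(
    row: np.ndarray, rate: float, pool: _OffsetPool, rng: np.random.Generator,
    extra: list[tuple[int, np.ndarray]], n_total: int, sample_index: int,
) -> None:
    k = rng.poisson(rate)
    if k:
        for off in pool.take(k):
            col = np.zeros(n_total, dtype=np.int8)
            col[sample_index] = 1
            extra.append((int(off), col))


def simulate_panel(
    config: SimulationConfig,
    annotation: SyntheticAnnotation | None = None,
) -> tuple[dict[str, VariantPanel], TruthLabels]:
    """Simulate the variant panel for every gene; labels carry the truth."""
    records, chrom_lengths = simulate_genome(config)
    rng = _rng(config, 2)
    samples = config.sample_names
    groups = config.sample_groups
    n_total = len(samples)
    idx_wild = [i for i, s in enumerate(samples) if groups[s] == "wild_weedy"]
    idx_land = [i for i, s in enumerate(samples) if groups[s] == "landrace"]
    idx_impr = [i for i, s in enumerate(samples) if groups[s] == "improved"]
    idx_out = [i for i, s in enumerate(samples) if groups[s] == "outgroup"]
    pool_n = config.n_wild + config.pool_extra
    L = config.gene_length
    truth = TruthLabels()
    per_chrom: dict[str, list[tuple[int, str, str, np.ndarray]]] = {
        c: [] for c in chrom_lengths
    }
    # neutral genes hitchhiking within 100 kb of a swept gene (only when
    # enabled): the sweep's footprint is physical distance, not cluster id
    hitchhiker: set[str] = set()
    if config.flank_sweep_factor < 1.0:
        swept = [r.gene for r in records if r.sel_class == "purifying"]
        for r in records:
            if r.sel_class != "neutral":
                continue
            g = r.gene
            for sg in swept:
                if (
                    sg.chrom == g.chrom
                    and g.end > sg.start - 100_000
                    and g.start < sg.end + 100_000
                ):
                    hitchhiker.add(g.gene_id)
                    break
    for rec in records:
        gene = rec.gene
        truth.selection_class[gene.gene_id] = rec.sel_class
        truth.phase[gene.gene_id] = rec.phase
        truth.cluster_id[gene.gene_id] = rec.cluster_id
        truth.pseudogene[gene.gene_id] = rec.is_pseudogene
        pool = _OffsetPool(L, rng)
        sites: list[tuple[int, np.ndarray]] = []

        def add_sites(offsets: np.ndarray, cols: np.ndarray) -> None:
            for c, off in enumerate(offsets):
                sites.append((int(off), cols[:, c].astype(np.int8)))

        if rec.sel_class == "balancing":
            theta_c = config.balancing_class_theta * config.theta
            posA, hapsA = simulate_neutral_haplotypes(pool_n, L, theta_c, rng)
            posB, hapsB = simulate_neutral_haplotypes(pool_n, L, theta_c, rng)
            n_div = max(1, round(config.balancing_divergence * L))
            class_of = np.zeros(n_total, dtype=np.int8)
            for idx in (idx_wild, idx_land, idx_impr):
                half = len(idx) // 2 + int(rng.integers(-1, 2))
                half = min(max(half, 1), len(idx) - 1)
                chosen = rng.choice(idx, size=half, replace=False)
                class_of[chosen] = 1
            calls = np.zeros((n_total, 0), dtype=np.int8)
            colsA = np.zeros((n_total, hapsA.shape[1]), dtype=np.int8)
            colsB = np.zeros((n_total, hapsB.shape[1]), dtype=np.int8)
            for i in idx_wild + idx_land + idx_impr:
                if class_of[i] == 0:
                    colsA[i] = hapsA[rng.integers(pool_n)]
                else:
                    colsB[i] = hapsB[rng.integers(pool_n)]
            for i in idx_out:
                colsA[i] = hapsA[0]
            offA = pool.take(hapsA.shape[1])
            offB = pool.take(hapsB.shape[1])
            add_sites(offA, colsA)
            add_sites(offB, colsB)
            div_cols = np.zeros((n_total, n_div), dtype=np.int8)
            div_cols[class_of == 1] = 1
            add_sites(pool.take(n_div), div_cols)
        else:
            pos, haps = simulate_neutral_haplotypes(pool_n, L, config.theta, rng)
            s = haps.shape[1]
            offs = pool.take(s)
            hap_of = np.zeros(n_total, dtype=np.intp)
            for c, i in enumerate(idx_wild):
                hap_of[i] = c
            lf = rng.choice(pool_n, size=config.landrace_founders, replace=False)
            imf = rng.choice(lf, size=min(config.improved_founders, len(lf)), replace=False)
            swept_groups: list[list[int]] = []
            residual = config.sweep_factor
            add_drift = False
            if rec.sel_class == "purifying" and config.sweep_factor < 1.0:
                # sweep factor 1 means no sweep: the gene is generated as
                # neutral, making the calibration contract exact
                swept_groups = (
                    [idx_land, idx_impr] if rec.phase == "domestication" else [idx_impr]
                )
                add_drift = True
            elif rec.gene.gene_id in hitchhiker:
                # hitchhiking: cultivated diversity collapses with the sweep
                # but without the swept gene's own drift substitutions
                swept_groups = [idx_land, idx_impr]
                residual = config.flank_sweep_factor
            swept_idx = {i for grp in swept_groups for i in grp}
            swept_founder = int(rng.integers(pool_n))
            for i in idx_land:
                hap_of[i] = swept_founder if i in swept_idx else int(rng.choice(lf))
            for i in idx_impr:
                hap_of[i] = swept_founder if i in swept_idx else int(rng.choice(imf))
            for i in idx_out:
                hap_of[i] = 0
            cols = haps[hap_of].astype(np.int8)
            add_sites(offs, cols)
            if swept_idx:
                n_drift = rng.poisson(config.sweep_divergence * L) if add_drift else 0
                if n_drift:
                    drift_cols = np.zeros((n_total, n_drift), dtype=np.int8)
                    drift_cols[sorted(swept_idx)] = 1
                    add_sites(pool.take(n_drift), drift_cols)
                extra: list[tuple[int, np.ndarray]] = []
                for i in sorted(swept_idx):
                    _private_mutations(
                        cols[i], 0.5 * residual * config.theta * L,
                        pool, rng, extra, n_total, i,
                    )
                sites.extend(extra)
        # outgroup divergence: substitutions private to the outgroup branch
        n_og = rng.poisson(config.outgroup_divergence * L)
        if n_og and idx_out:
            og_cols = np.zeros((n_total, n_og), dtype=np.int8)
            og_cols[idx_out] = 1
            add_sites(pool.take(n_og), og_cols)
        # missing data
        for off, col in sites:
            if config.missing_rate > 0:
                mask = rng.random(n_total) < config.missing_rate
                col[mask] = -1
            per_chrom[gene.chrom].append((gene.start + off, gene.gene_id, "", col))
    panels: dict[str, VariantPanel] = {}
    rng_alleles = _rng(config, 3)
    gene_by_id = (
        {g.gene_id: g for g in annotation.genes} if annotation is not None else {}
    )
    for chrom in sorted(per_chrom):
        rows = sorted(per_chrom[chrom], key=lambda r: r[0])
        if not rows:
            continue
        positions = np.array([r[0] for r in rows], dtype=np.int64)
        keep = np.ones(len(rows), dtype=bool)
        keep[1:] = np.diff(positions) > 0
        rows = [r for r, k in zip(rows, keep) if k]
        positions = positions[keep]
        refs, alts = [], []
        for pos, gid, _, _ in rows:
            base = None
            if annotation is not None and gid in annotation.region_seqs:
                g = gene_by_id[gid]
                base = annotation.region_seqs[gid][pos - g.start]
            ref = base or str(rng_alleles.choice(NUCS))
            alt = str(rng_alleles.choice([n for n in "ACGT" if n != ref]))
            refs.append(ref)
            alts.append(alt)
        calls = np.stack([r[3] for r in rows], axis=1)
        panels[chrom] = VariantPanel(
            chrom=chrom,
            positions=positions,
            ref=refs,
            alt=alts,
            calls=calls,
            samples=samples,
            groups=groups,
        )
    return panels, truth


# ---------------------------------------------------------------------------
# annotation, sequences, markers, QTL


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = _STOPS[int(rng.integers(3))]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def _mutate_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Random substitutions avoiding internal stops and start/stop codons."""
    seq = list(cds)
    k = rng.poisson(rate * len(cds))
    for _ in range(k):
        pos = int(rng.integers(3, len(cds) - 3))
        old = seq[pos]
        choices = [n for n in "ACGT" if n != old]
        rng.shuffle(choices)
        for nt in choices:
            seq[pos] = nt
            codon = "".join(seq[pos - pos % 3 : pos - pos % 3 + 3])
            if codon not in _STOPS:
                break
            seq[pos] = old
    return "".join(seq)


def simulate_annotation(
    config: SimulationConfig, with_sequences: bool = True
) -> SyntheticAnnotation:
    """Gene models, CDS/region sequences, family truth, markers and QTL."""
    records, chrom_lengths = simulate_genome(config)
    rng = _rng(config, 1)
    truth = TruthLabels()
    genes = [r.gene for r in records]
    for r in records:
        truth.selection_class[r.gene.gene_id] = r.sel_class
        truth.phase[r.gene.gene_id] = r.phase
        truth.cluster_id[r.gene.gene_id] = r.cluster_id
        truth.pseudogene[r.gene.gene_id] = r.is_pseudogene
    region_seqs: dict[str, str] = {}
    cds_seqs: dict[str, str] = {}
    if with_sequences:
        # family ancestors: NBS genes sharing a cluster share an ancestor CDS
        nbs_records = [r for r in records if r.gene.is_nbs]
        by_cluster: dict[str, list[_GeneRecord]] = {}
        singles: list[_GeneRecord] = []
        for r in nbs_records:
            if r.cluster_id is not None:
                by_cluster.setdefault(r.cluster_id, []).append(r)
            else:
                singles.append(r)
        n_codons = config.cds_length // 3
        ancestors: dict[str, str] = {}
        fam_counter = 0
        for cid in sorted(by_cluster):
            fam = f"fam{fam_counter:03d}"
            fam_counter += 1
            ancestors[fam] = _random_cds(n_codons, rng)
            for r in by_cluster[cid]:
                r.family_id = fam
        for r in singles:
            fam = f"fam{fam_counter:03d}"
            fam_counter += 1
            ancestors[fam] = _random_cds(n_codons, rng)
            r.family_id = fam
        for r in nbs_records:
            cds = _mutate_cds(
                ancestors[r.family_id], config.within_family_divergence, rng
            )
            cds_seqs[r.gene.gene_id] = _fit_cds(cds, r.gene.cds_length, rng)
            truth.family_id[r.gene.gene_id] = r.family_id
        for r in records:
            if not r.gene.is_nbs:
                cds_seqs[r.gene.gene_id] = _random_cds(r.gene.cds_length // 3, rng)
                truth.family_id[r.gene.gene_id] = f"bg_{r.gene.gene_id}"
        # region sequences with the CDS planted strand-correctly
        for r in records:
            g = r.gene
            span = g.end - g.start
            seq = rng.choice(NUCS, size=span)
            cds = cds_seqs[g.gene_id]
            genomic_cds = cds if g.strand == "+" else _revcomp(cds)
            cursor = 0
            for s, e in g.cds_intervals:
                seq[s - g.start : e - g.start] = list(genomic_cds[cursor : cursor + e - s])
                cursor += e - s
            region_seqs[g.gene_id] = "".join(seq)
        # cross-species genes for family/ancestry analysis
        genes_extra, extra_fams = _cross_species_genes(config, ancestors, rng, truth)
        genes = genes + genes_extra
        for gid, cds in extra_fams.items():
            cds_seqs[gid] = cds
    markers, qtls, qtl_targets = _marker_map_and_qtl(config, records, chrom_lengths)
    truth.qtl_target_genes = qtl_targets
    return SyntheticAnnotation(
        genes=genes,
        chrom_lengths=chrom_lengths,
        region_seqs=region_seqs,
        cds_seqs=cds_seqs,
        markers=markers,
        qtls=qtls,
        truth=truth,
    )


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _fit_cds(cds: str, target_len: int, rng: np.random.Generator) -> str:
    """Trim/extend a CDS to the annotated length, keeping frame and stops."""
    if len(cds) == target_len:
        return cds
    n_codons = target_len // 3
    body = cds[3:-3]
    need = n_codons - 2
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    while len(codons) < need:
        codons.append(_SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))])
    return cds[:3] + "".join(codons[:need]) + cds[-3:]


def _cross_species_genes(
    config: SimulationConfig,
    ancestors: dict[str, str],
    rng: np.random.Generator,
    truth: TruthLabels,
) -> tuple[list[GeneModel], dict[str, str]]:
    genes: list[GeneModel] = []
    cds_out: dict[str, str] = {}
    fam_ids = sorted(ancestors)
    n_anc = min(config.n_ancestral_families, len(fam_ids))
    anc_fams = [fam_ids[i] for i in rng.choice(len(fam_ids), size=n_anc, replace=False)]
    rest = [f for f in fam_ids if f not in anc_fams]
    n_cross = min(config.n_cross_species_pairs, len(rest))
    cross_fams = rest[:n_cross]
    counter = {"maize": 0, "rice": 0}

    def make(species: str, fam: str | None) -> None:
        gid = f"{species}_gene{counter[species]:03d}"
        counter[species] += 1
        if fam is not None:
            cds = _mutate_cds(ancestors[fam], config.cross_species_divergence, rng)
            truth.family_id[gid] = fam
        else:
            cds = _random_cds(config.cds_length // 3, rng)
            truth.family_id[gid] = f"{species}_{gid}"
        cds = _fit_cds(cds, config.cds_length, rng)
        cds_out[gid] = cds
        start = 1000 + 500_000 * counter[species]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=f"{species}_chr1",
                strand="+",
                start=start,
                end=start + len(cds),
                cds_intervals=[(start, start + len(cds))],
                nbs_class="NL",
                species=species,
                nbs_domain=(90, min(390, len(cds))),
            )
        )

    for fam in anc_fams:
        make("maize", fam)
        make("rice", fam)
    for fam in cross_fams:
        make("maize", fam)
    while counter["maize"] < config.n_maize:
        make("maize", None)
    while counter["rice"] < config.n_rice:
        make("rice", None)
    return genes, cds_out


def _marker_map_and_qtl(
    config: SimulationConfig,
    records: list[_GeneRecord],
    chrom_lengths: dict[str, int],
) -> tuple[list[FrameworkMarker], list[QTLInterval], set[str]]:
    rng = _rng(config, 5)
    markers: list[FrameworkMarker] = []
    marker_map: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in sorted(chrom_lengths):
        clen = chrom_lengths[chrom]
        bp = np.sort(rng.choice(clen, size=config.markers_per_chromosome, replace=False))
        bp[0] = min(bp[0], 1000)  # anchor near the telomeres
        bp[-1] = max(bp[-1], clen - 1000)
        cm = np.sort(rng.uniform(0, config.map_length_cm, size=config.markers_per_chromosome))
        marker_map[chrom] = (cm, bp.astype(float))
        for i, (c, b) in enumerate(zip(cm, bp)):
            markers.append(FrameworkMarker(f"{chrom}_m{i:03d}", chrom, float(c), int(b)))
    qtls: list[QTLInterval] = []
    targets: set[str] = set()
    nbs = [r for r in records if r.gene.is_nbs]
    other = [r for r in records if not r.gene.is_nbs]
    for q in range(config.n_qtl):
        pick_nbs = rng.random() < config.qtl_nbs_bias and nbs
        rec = (
            nbs[int(rng.integers(len(nbs)))]
            if pick_nbs
            else other[int(rng.integers(len(other)))]
        )
        gene = rec.gene
        targets.add(gene.gene_id)
        cm_arr, bp_arr = marker_map[gene.chrom]
        center_cm = float(np.interp(gene.midpoint, bp_arr, cm_arr))
        hw = float(rng.uniform(*config.qtl_halfwidth_cm))
        trait = str(config.qtl_traits[int(rng.integers(len(config.qtl_traits)))])
        qtls.append(
            QTLInterval(
                qtl_id=f"qtl{q:03d}",
                trait=trait,
                chrom=gene.chrom,
                cm_start=max(center_cm - hw, 0.0),
                cm_end=min(center_cm + hw, config.map_length_cm),
                source="synthetic",
            )
        )
    return markers, qtls, targets


# ---------------------------------------------------------------------------
# coding variants + depth


@dataclass
class CodingVariants:
    variants: list[tuple]  # (chrom, pos, ref, alt, gene_id, effect, carriers array)
    depth: pd.DataFrame
    presence: dict[str, dict[str, bool]]


def _stop_candidates(cds: str) -> list[tuple[int, str]]:
    """(cds position, alt base) choices creating a premature stop."""
    out = []
    for ci in range(1, len(cds) // 3 - 1):
        codon = cds[3 * ci : 3 * ci + 3]
        for off in range(3):
            for nt in "ACGT":
                if nt == codon[off]:
                    continue
                new = codon[:off] + nt + codon[off + 1 :]
                if new in _STOPS:
                    out.append((3 * ci + off, nt))
    return out


def simulate_coding_variants(
    config: SimulationConfig, annotation: SyntheticAnnotation
) -> CodingVariants:
    """Inject effect-class variants, depth bins, and presence truth."""
    rng = _rng(config, 4)
    samples = config.sample_names
    groups = config.sample_groups
    n_total = len(samples)
    ingroup = [i for i, s in enumerate(samples) if groups[s] != "outgroup"]
    variants: list[tuple] = []
    presence: dict[str, dict[str, bool]] = {}
    depth_rows: list[tuple] = []
    truth = annotation.truth
    novel = _novel_flags(config)
    sorghum = [g for g in annotation.genes if g.species == "sorghum"]
    for gene in sorghum:
        gid = gene.gene_id
        cds = annotation.cds_seqs[gid]
        region = annotation.region_seqs[gid]
        gpos = gene.cds_genomic_positions()
        used: set[int] = set()

        def genomic_alt(cds_pos: int, alt_base: str) -> tuple[int, str, str]:
            p = int(gpos[cds_pos])
            ref = region[p - gene.start]
            alt = alt_base if gene.strand == "+" else _revcomp(alt_base)
            return p, ref, alt

        # carriers of injected variants: swept (purifying) genes only vary in
        # the wild group, preserving the planted sweep signature
        wild_idx = [i for i, s in enumerate(samples) if groups[s] == "wild_weedy"]
        carrier_pool = (
            wild_idx
            if truth.selection_class.get(gid) == "purifying"
            else ingroup
        )

        def carriers(freq: float) -> np.ndarray:
            k = max(1, int(round(freq * len(carrier_pool))))
            col = np.zeros(n_total, dtype=np.int8)
            col[rng.choice(carrier_pool, size=k, replace=False)] = 1
            return col

        def add(pos: int, ref: str, alt: str, effect: str, col: np.ndarray) -> bool:
            if pos in used:
                return False
            used.add(pos)
            variants.append((gene.chrom, pos, ref, alt, gid, effect, col))
            truth.effect_truth.append((gid, pos, ref, alt, effect))
            return True

        if truth.pseudogene.get(gid):
            # a frameshift fixed across all genotypes
            p = int(gpos[3 * (len(cds) // 6)])
            lo = p if gene.strand == "+" else p - 2
            ref3 = region[lo - gene.start : lo - gene.start + 3]
            col = np.ones(n_total, dtype=np.int8)
            add(lo, ref3, ref3[0], "frameshift", col)
        else:
            if rng.random() < config.large_effect_rate:
                kind = str(rng.choice(["premature_stop", "start_loss", "stop_loss", "splice_site"]))
                freq = float(rng.beta(0.8, 3.0))
                if kind == "splice_site" and len(gene.cds_intervals) < 2:
                    kind = "premature_stop"
                if kind == "premature_stop":
                    cands = _stop_candidates(cds)
                    if cands:
                        cp, nt = cands[int(rng.integers(len(cands)))]
                        p, ref, alt = genomic_alt(cp, nt)
                        add(p, ref, alt, "premature_stop", carriers(freq))
                elif kind == "start_loss":
                    p, ref, alt = genomic_alt(0, "C")
                    add(p, ref, alt, "start_loss", carriers(freq))
                elif kind == "stop_loss":
                    last = len(cds) - 3
                    stop = cds[last:]
                    for off in range(3):
                        for nt in "ACGT":
                            if nt != stop[off] and stop[:off] + nt + stop[off + 1 :] not in _STOPS:
                                p, ref, alt = genomic_alt(last + off, nt)
                                add(p, ref, alt, "stop_loss", carriers(freq))
                                off = 99
                                break
                        if off == 99:
                            break
                else:  # splice_site
                    left_end = gene.cds_intervals[0][1]
                    p = left_end  # first intron base (donor site)
                    ref = region[p - gene.start]
                    alt = str(rng.choice([n for n in "ACGT" if n != ref]))
                    add(p, ref, alt, "splice_site", carriers(freq))
            if rng.random() < config.frameshift_rate:
                cp = int(rng.integers(3, len(cds) - 6))
                p = int(gpos[cp])
                lo = min(p, int(gpos[min(cp + 2, len(cds) - 1)]))
                ref3 = region[lo - gene.start : lo - gene.start + 3]
                if len(ref3) == 3:
                    add(lo, ref3, ref3[0], "frameshift", carriers(float(rng.beta(0.8, 3.0))))
            n_benign = rng.poisson(config.benign_snps_per_gene)
            for _ in range(n_benign):
                cp = int(rng.integers(3, len(cds) - 3))
                old = cds[cp]
                nt = str(rng.choice([n for n in "ACGT" if n != old]))
                codon_start = cp - cp % 3
                new_codon = (
                    cds[codon_start:cp] + nt + cds[cp + 1 : codon_start + 3]
                )
                if new_codon in _STOPS:
                    continue
                p, ref, alt = genomic_alt(cp, nt)
                add(p, ref, alt, "benign", carriers(float(rng.beta(0.8, 3.0))))
        # presence truth + depth
        pres = {s: True for s in samples}
        if novel.get(gid, False):
            pattern = ["outgroup_only", "wild_only", "wild_and_outgroup", "cultivated_some"][
                int(rng.integers(4))
            ]
            for i, s in enumerate(samples):
                g = groups[s]
                if pattern == "outgroup_only":
                    pres[s] = g == "outgroup"
                elif pattern == "wild_only":
                    pres[s] = g == "wild_weedy"
                elif pattern == "wild_and_outgroup":
                    pres[s] = g in ("wild_weedy", "outgroup")
                else:  # cultivated_some: present widely, lost in a few lines
                    pres[s] = not (g in ("landrace", "improved") and rng.random() < 0.3)
        elif rng.random() < config.gene_loss_rate:
            lost = rng.choice(ingroup, size=int(rng.integers(1, 4)), replace=False)
            for i in lost:
                pres[samples[i]] = False
        presence[gid] = pres
        first_bin = gene.start // 100 * 100
        bins = np.arange(first_bin, gene.end, 100)
        for s in samples:
            base = rng.poisson(config.mean_depth, size=len(bins))
            if not pres[s]:
                base[:] = 0
            for b, dp in zip(bins, base):
                depth_rows.append((s, gene.chrom, int(b), int(dp)))
    truth.presence = presence
    depth = pd.DataFrame(depth_rows, columns=["sample", "chrom", "bin_start", "depth"])
    return CodingVariants(variants=variants, depth=depth, presence=presence)


def _novel_flags(config: SimulationConfig) -> dict[str, bool]:
    records, _ = simulate_genome(config)
    return {r.gene.gene_id: r.is_novel for r in records}


def merge_coding_variants(
    panels: dict[str, VariantPanel], coding: CodingVariants
) -> dict[str, VariantPanel]:
    """Merge injected coding variants into the panels (injected sites win
    position collisions with background sites)."""
    by_chrom: dict[str, list[tuple]] = {}
    for v in coding.variants:
        by_chrom.setdefault(v[0], []).append(v)
    out: dict[str, VariantPanel] = {}
    for chrom, panel in panels.items():
        extra = by_chrom.get(chrom, [])
        if not extra:
            out[chrom] = panel
            continue
        inj_pos = {v[1] for v in extra}
        keep = [j for j in range(panel.n_sites) if int(panel.positions[j]) not in inj_pos]
        rows = [
            (int(panel.positions[j]), panel.ref[j], panel.alt[j], panel.calls[:, j])
            for j in keep
        ]
        rows += [(v[1], v[2], v[3], v[6]) for v in extra]
        rows.sort(key=lambda r: r[0])
        out[chrom] = VariantPanel(
            chrom=chrom,
            positions=np.array([r[0] for r in rows], dtype=np.int64),
            ref=[r[1] for r in rows],
            alt=[r[2] for r in rows],
            calls=np.stack([r[3] for r in rows], axis=1),
            samples=panel.samples,
            groups=panel.groups,
        )
    return out


# ---------------------------------------------------------------------------
# HKA count sampler (used by the validation harness)


def simulate_hka_counts(
    n_loci: int,
    n: int,
    t: float,
    rng: np.random.Generator,
    theta_range: tuple[float, float] = (2.0, 10.0),
    selected_k: dict[int, float] | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Poisson polymorphism/divergence counts at the model's parameters.

    ``selected_k`` maps locus index -> selection parameter k (k scales the
    polymorphism mean a1*theta_i).
    """
    from .popstats import harmonic

    a1 = harmonic(n - 1)
    s_counts: dict[str, int] = {}
    d_counts: dict[str, int] = {}
    for i in range(n_loci):
        theta = rng.uniform(*theta_range)
        k = (selected_k or {}).get(i, 1.0)
        name = f"locus{i:03d}"
        s_counts[name] = int(rng.poisson(a1 * k * theta))
        d_counts[name] = int(rng.poisson(theta * (t + 1.0)))
    return s_counts, d_counts
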