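"""Standard-format readers/writers and the internal data model.

All internal coordinates are 0-based half-open; the 1-based conventions of
VCF and GFF3 are converted at the boundary.  Variant panels are haploid
coded: the sorghum-style panel consists of inbred lines, so homozygous
diploid genotypes collapse to a single allele and heterozygotes are treated
as missing (or rejected under ``strict_het``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

GROUPS = ("wild_weedy", "landrace", "improved", "outgroup")
INGROUPS = ("wild_weedy", "landrace", "improved")
CULTIVATED = ("landrace", "improved")

#: the 14 domain-architecture letter codes plus the non-NBS marker
NBS_CLASSES = (
    "NL", "CNL", "NLC", "NLX", "NXL", "CNLX", "CNXL", "TN",
    "N", "CN", "NC", "CNX", "NCX", "XCN", "XN",
)
LRR_CLASSES = frozenset({"NL", "CNL", "NLC", "NLX", "NXL", "CNLX", "CNXL", "TN"})
SPECIES = ("sorghum", "maize", "rice")

MISSING = -1  # call matrix code


@dataclass
class VariantPanel:
    """Per-site biallelic calls for haploid-coded samples on one chromosome.

    ``calls`` is a samples x sites int8 matrix with values 0 (ref), 1 (alt)
    and -1 (missing).  ``positions`` are 0-based and strictly increasing.
    """

    chrom: str
    positions: np.ndarray
    ref: list[str]
    alt: list[str]
    calls: np.ndarray
    samples: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.positions)):
            raise InputError(
                f"calls matrix {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.positions)} sites"
            )
        if np.any(np.diff(self.positions) <= 0):
            raise InputError(f"positions not strictly increasing on {self.chrom}")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise InputError(f"samples without group assignment: {missing}")
        bad = set(self.groups.values()) - set(GROUPS)
        if bad:
            raise InputError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.groups[s] == group],
            dtype=np.intp,
        )

    def window(self, start: int, end: int) -> "VariantPanel":
        """Slice to sites with start <= pos < end (half-open)."""
        lo, hi = np.searchsorted(self.positions, [start, end])
        return replace(
            self,
            positions=self.positions[lo:hi],
            ref=self.ref[lo:hi],
            alt=self.alt[lo:hi],
            calls=self.calls[:, lo:hi],
        )


@dataclass
class GeneModel:
    """A gene with CDS structure and its NBS domain-architecture class."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_intervals: list[tuple[int, int]]
    nbs_class: str = "non_nbs"
    species: str = "sorghum"
    nbs_domain: tuple[int, int] | None = None  # CDS-local, half-open
    in_frame: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.nbs_class != "non_nbs" and self.nbs_class not in NBS_CLASSES:
            raise InputError(f"{self.gene_id}: unknown NBS class {self.nbs_class!r}")
        ivs = sorted(tuple(iv) for iv in self.cds_intervals)
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise InputError(f"{self.gene_id}: overlapping CDS intervals")
        for s, e in ivs:
            if s < self.start or e > self.end:
                raise InputError(f"{self.gene_id}: CDS outside gene span")
        self.cds_intervals = ivs
        if self.cds_length % 3 != 0:
            warnings.warn(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3;"
                " excluded from codon analyses"
            )
            self.in_frame = False

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def is_nbs(self) -> bool:
        return self.nbs_class != "non_nbs"

    @property
    def has_lrr(self) -> bool:
        return self.nbs_class in LRR_CLASSES

    def cds_genomic_positions(self) -> np.ndarray:
        """Genomic position of each CDS base, in 5'->3' transcript order."""
        parts = [np.arange(s, e) for s, e in self.cds_intervals]
        pos = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        return pos[::-1] if self.strand == "-" else pos


@dataclass
class RegionSet:
    """A named set of half-open genomic intervals (selection regions, QTL...)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, s, e in self.intervals:
            if s >= e:
                raise InputError(f"{self.name}: empty interval {chrom}:{s}-{e}")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds(gene: GeneModel, region_seq: str, region_start: int = 0) -> str:
    """Strand-corrected CDS sequence from a sequence covering the gene span."""
    parts = [region_seq[s - region_start : e - region_start] for s, e in gene.cds_intervals]
    cds = "".join(parts)
    return revcomp(cds) if gene.strand == "-" else cds


# ---------------------------------------------------------------------------
# VCF


def _collapse_gt(gt, sample: str, chrom: str, pos1: int, strict_het: bool) -> int:
    alleles = [a for a in gt if a is not None] if gt is not None else []
    if not alleles:
        return MISSING
    if len(set(alleles)) > 1:
        if strict_het:
            raise InputError(
                f"heterozygous call for {sample} at {chrom}:{pos1} under strict mode"
            )
        return MISSING
    return int(alleles[0])


def read_groups_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise InputError(f"{path}: expected columns 'sample' and 'group'")
    groups = dict(zip(df["sample"], df["group"]))
    bad = set(groups.values()) - set(GROUPS)
    if bad:
        raise InputError(f"{path}: unknown group labels {sorted(bad)}")
    return groups


def read_variant_panel(
    vcf_path: str | Path,
    groups_path: str | Path,
    strict_het: bool = False,
) -> dict[str, VariantPanel]:
    """Read a sorted biallelic VCF into per-chromosome panels.

    Diploid genotypes collapse by the inbred rule; multi-allelic records are
    rejected.  Returns an insertion-ordered mapping chrom -> VariantPanel.
    """
    import pysam

    groups = read_groups_table(groups_path)
    panels: dict[str, VariantPanel] = {}
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        unknown = [s for s in samples if s not in groups]
        if unknown:
            raise InputError(f"VCF samples missing from groups table: {unknown}")
        acc: dict[str, list] = {}
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise InputError(
                    f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos};"
                    " split or filter upstream"
                )
            entry = acc.setdefault(rec.chrom, [])
            pos0 = rec.pos - 1
            if entry and pos0 <= entry[-1][0]:
                raise InputError(f"VCF not sorted at {rec.chrom}:{rec.pos}")
            calls = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                calls[i] = _collapse_gt(
                    rec.samples[s].get("GT"), s, rec.chrom, rec.pos, strict_het
                )
            entry.append((pos0, rec.ref, rec.alts[0], calls))
    for chrom, rows in acc.items():
        panels[chrom] = VariantPanel(
            chrom=chrom,
            positions=np.array([r[0] for r in rows], dtype=np.int64),
            ref=[r[1] for r in rows],
            alt=[r[2] for r in rows],
            calls=(
                np.stack([r[3] for r in rows], axis=1)
                if rows
                else np.empty((len(samples), 0), dtype=np.int8)
            ),
            samples=samples,
            groups={s: groups[s] for s in samples},
        )
    return panels


def write_variant_panel(
    panels: dict[str, VariantPanel],
    vcf_path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write panels as a plain-text haploid VCF (deterministic byte output)."""
    chroms = list(panels)
    first = panels[chroms[0]]
    lines = ["##fileformat=VCFv4.2", "##source=nbselect"]
    for chrom in chroms:
        length = (contig_lengths or {}).get(
            chrom, int(panels[chrom].positions[-1]) + 1 if panels[chrom].n_sites else 1
        )
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(first.samples)
    )
    code = {0: "0", 1: "1", MISSING: "."}
    for chrom in chroms:
        p = panels[chrom]
        for j in range(p.n_sites):
            gts = "\t".join(code[int(c)] for c in p.calls[:, j])
            lines.append(
                f"{chrom}\t{p.positions[j] + 1}\t.\t{p.ref[j]}\t{p.alt[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}"
            )
    Path(vcf_path).write_text("\n".join(lines) + "\n")


def write_groups_table(groups: dict[str, str], path: str | Path) -> None:
    df = pd.DataFrame({"sample": list(groups), "group": list(groups.values())})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 + class table


def read_gene_models(
    gff3_path: str | Path, class_table_path: str | Path | None = None
) -> list[GeneModel]:
    """Read gene/mRNA/CDS features; attach NBS classes from the class table.

    Genes absent from the class table become ``non_nbs``.  Genes whose CDS
    length is not divisible by 3 are kept but flagged ``in_frame=False``.
    """
    import gffutils

    classes: dict[str, dict] = {}
    if class_table_path is not None:
        cdf = pd.read_csv(class_table_path, sep="\t", dtype={"gene_id": str})
        for row in cdf.itertuples(index=False):
            d = row._asdict()
            classes[d["gene_id"]] = d
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        cds = [
            (c.start - 1, c.end)
            for c in db.children(g.id, featuretype="CDS", order_by="start")
        ]
        info = classes.get(g.id, {})
        domain = None
        if info.get("domain_start") is not None and not pd.isna(info.get("domain_start")):
            domain = (int(info["domain_start"]), int(info["domain_end"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start - 1,
                end=g.end,
                cds_intervals=cds,
                nbs_class=str(info.get("nbs_class", "non_nbs")),
                species=str(info.get("species", "sorghum")),
                nbs_domain=domain,
            )
        if not model.in_frame:
            warnings.warn(f"{model.gene_id}: out-of-frame CDS, excluded from codon analyses")
        genes.append(model)
    return genes


def write_gene_models(genes: list[GeneModel], gff3_path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda x: (x.chrom, x.start, x.gene_id)):
        attrs = f"ID={g.gene_id}"
        lines.append(
            f"{g.chrom}\tnbselect\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        mrna = f"{g.gene_id}.1"
        lines.append(
            f"{g.chrom}\tnbselect\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.cds_intervals):
            lines.append(
                f"{g.chrom}\tnbselect\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                f"ID={mrna}.cds{i};Parent={mrna}"
            )
    Path(gff3_path).write_text("\n".join(lines) + "\n")


def write_class_table(genes: list[GeneModel], path: str | Path) -> None:
    rows = []
    for g in sorted(genes, key=lambda x: x.gene_id):
        if not g.is_nbs and g.nbs_domain is None:
            continue
        rows.append(
            {
                "gene_id": g.gene_id,
                "nbs_class": g.nbs_class,
                "species": g.species,
                "domain_start": g.nbs_domain[0] if g.nbs_domain else "",
                "domain_end": g.nbs_domain[1] if g.nbs_domain else "",
            }
        )
    pd.DataFrame(rows, columns=["gene_id", "nbs_class", "species", "domain_start", "domain_end"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA / BED / TSV


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        intervals.append((f[0], int(f[1]), int(f[2])))
    return RegionSet(name=name or Path(path).stem, intervals=intervals)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    lines = [
        f"{chrom}\t{s}\t{e}\t{regions.name}"
        for chrom, s, e in sorted(regions.intervals)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_depth_bins(path: str | Path) -> pd.DataFrame:
    """Depth TSV with columns sample, chrom, bin_start, depth (100-bp bins)."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample", "chrom", "bin_start", "depth"}
    if not need <= set(df.columns):
        raise InputError(f"{path}: expected columns {sorted(need)}")
    return df


def write_results_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write named DataFrames as TSVs with deterministic row/column order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        sort_cols = [c for c in ("gene_id", "group", "comparison", "sample") if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="mergesort")
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths.append(p)
    return paths
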